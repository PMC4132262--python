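"""Humanness scoring vs an independent dynamic-programming oracle."""

import numpy as np
import pytest

from fabrefine.antibody_model import AA1, VRegionSequence
from fabrefine.humanness import HumannessError, pairwise_identity, t20_score
from fabrefine.synthetic_data import default_templates, make_human_v_db

NEG = -1e9


def nw_identity_oracle(a: str, b: str, open_pen=10.0, ext_pen=1.0):
    """Independent affine-gap Needleman-Wunsch (match 1 / mismatch 0),
    tracking matches and alignment length through the traceback."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_pen - (i - 1) * ext_pen
    for j in range(1, m + 1):
        Y[0, j] = -open_pen - (j - 1) * ext_pen
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_pen, X[i - 1, j] - ext_pen,
                          Y[i - 1, j] - open_pen)
            Y[i, j] = max(M[i, j - 1] - open_pen, Y[i, j - 1] - ext_pen,
                          X[i, j - 1] - open_pen)
    # traceback from the best terminal state, preferring matches ("high road")
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    matches, cols = 0, 0
    while i > 0 or j > 0:
        if state == 0:
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            matches += int(a[i - 1] == b[j - 1])
            cols += 1
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            cols += 1
            prev = [M[i - 1, j] - 10.0, X[i - 1, j] - 1.0, Y[i - 1, j] - 10.0]
            state = int(np.argmax(prev))
            i -= 1
        else:
            cols += 1
            prev = [M[i, j - 1] - 10.0, Y[i, j - 1] - 1.0]
            state = [0, 2][int(np.argmax(prev))]
            j -= 1
    return 100.0 * matches / cols


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("QVQLVE", "QVQLVE") == 100.0

    def test_three_of_four(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_empty_errors(self):
        with pytest.raises(HumannessError):
            pairwise_identity("", "AAAA")

    def test_matches_dp_oracle_on_substituted_pairs(self):
        """50-mers with ~10% substitutions: gapless optimum, oracle exact."""
        rng = np.random.default_rng(16)
        aas = list(AA1)
        for _ in range(20):
            a = "".join(rng.choice(aas, size=50))
            b = list(a)
            for pos in rng.choice(50, size=5, replace=False):
                b[pos] = rng.choice([x for x in aas if x != a[pos]])
            b = "".join(b)
            assert pairwise_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b), abs=1e-9)

    def test_matches_dp_oracle_with_deletion(self):
        a = "QVQLVESGGGVVQPGRSL"
        b = a[:7] + a[10:]          # 3-residue deletion
        assert pairwise_identity(a, b) == pytest.approx(
            nw_identity_oracle(a, b), abs=1e-9)


class TestT20:
    def test_db_of_query_copies_scores_100(self):
        tpl = default_templates()[0]
        res = t20_score(tpl, [tpl.residues] * 20)
        assert res.t20_full == 100.0

    def test_single_entry_db(self):
        tpl = default_templates()[0]
        other = default_templates()[1]
        res = t20_score(tpl, [other.residues])
        assert res.t20_full == pytest.approx(
            pairwise_identity(tpl.residues, other.residues))

    def test_empty_db_errors(self):
        with pytest.raises(HumannessError):
            t20_score(default_templates()[0], [])

    def test_matches_brute_force_oracle(self):
        """Top-20 mean equals an independent sort-and-average over all
        pairwise identities (n=200 synthetic database)."""
        db = make_human_v_db(200, seed=7)
        query = default_templates()[0]
        res = t20_score(query, db)
        brute = sorted((pairwise_identity(query.residues, e.residues)
                        for e in db), reverse=True)
        assert res.t20_full == pytest.approx(float(np.mean(brute[:20])),
                                             abs=1e-9)

    def test_order_invariance(self):
        db = make_human_v_db(40, seed=3)
        query = default_templates()[1]
        a = t20_score(query, db).t20_full
        b = t20_score(query, list(reversed(db))).t20_full
        assert a == b

    def test_adding_sequences_never_decreases_score(self):
        """Top-k mean monotonicity once the database holds >= k entries."""
        db = make_human_v_db(25, seed=5)
        query = default_templates()[0]
        base = t20_score(query, db).t20_full
        for extra in make_human_v_db(6, substitution_rate=0.25, seed=9):
            assert t20_score(query, db + [extra]).t20_full >= base

    def test_framework_only_masks_cdrs(self):
        query = default_templates()[0]
        db = make_human_v_db(30, seed=11)
        res = t20_score(query, db, framework_only=True)
        assert res.t20_framework is not None and res.t20_full is None
        # masking changes the query, so scores generally differ
        full = t20_score(query, db).t20_full
        assert res.t20_framework != full
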