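"""Sequence/mutation domain types, notation parsing, and PDB round-trips."""

import io

import numpy as np
import pytest

from fabrefine.antibody_model import (
    AA1, MutationParseError, PointMutation, SequenceError, StructureError,
    VRegionSequence, apply_mutations, diff_sequences, parse_mutation_notation,
    read_pdb, write_pdb, read_region_annotations,
)


def make_vregion(residues="QVQLVESGGG", kind="heavy", name="toy"):
    return VRegionSequence(chain_kind=kind, residues=residues,
                           region_map=("FR1",) * len(residues), name=name)


class TestMutationNotation:
    @pytest.mark.parametrize("text,chain,pos,wt,mut", [
        ("HC:G54I", "HC", 54, "G", "I"),
        ("LC: E1S", "LC", 1, "E", "S"),
        ("  lc:K24R ", "LC", 24, "K", "R"),
    ])
    def test_parse(self, text, chain, pos, wt, mut):
        m = parse_mutation_notation(text)
        assert (m.chain, m.position, m.wt_aa, m.mut_aa) == (chain, pos, wt, mut)

    @pytest.mark.parametrize("bad", [
        "LC:A5A",          # identity not allowed by default
        "XC:G54I",         # unknown chain
        "HC:B54I",         # non-standard residue
        "HC:G0I",          # position 0
        "HC:G54",          # malformed
        "G54I",            # missing chain
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(MutationParseError):
            parse_mutation_notation(bad)

    def test_identity_allowed_when_flagged(self):
        m = parse_mutation_notation("LC:A5A", allow_identity=True)
        assert m.identity and m.wt_aa == m.mut_aa == "A"


class TestApplyDiff:
    def test_single_substitution(self):
        seq = make_vregion("QVQLVESGGG")
        out = apply_mutations(seq, [PointMutation("HC", 1, "Q", "E")])
        assert out.residues == "EVQLVESGGG"
        assert out.region_map == seq.region_map

    def test_empty_list_is_identity(self):
        seq = make_vregion()
        assert apply_mutations(seq, []).residues == seq.residues

    def test_duplicate_positions_rejected(self):
        seq = make_vregion()
        muts = [PointMutation("HC", 2, "V", "A"), PointMutation("HC", 2, "V", "L")]
        with pytest.raises(SequenceError):
            apply_mutations(seq, muts)

    def test_wt_mismatch_reports_residues(self):
        seq = make_vregion()
        with pytest.raises(SequenceError, match="expected A, found V"):
            apply_mutations(seq, [PointMutation("HC", 2, "A", "L")])

    def test_diff_identical_is_empty(self):
        seq = make_vregion()
        assert diff_sequences(seq, seq) == []

    def test_diff_length_mismatch(self):
        with pytest.raises(SequenceError):
            diff_sequences(make_vregion("QVQL"), make_vregion("QVQLV"))

    def test_round_trip_random_mutation_sets(self):
        """apply → diff → apply recovers the mutation set, 1000 seeded cases."""
        rng = np.random.default_rng(42)
        aas = list(AA1)
        for _ in range(1000):
            n = 60
            base = "".join(rng.choice(aas, size=n))
            seq = make_vregion(base)
            k = int(rng.integers(0, 8))
            positions = rng.choice(n, size=k, replace=False)
            muts = []
            for p in positions:
                wt = base[p]
                mut = rng.choice([a for a in aas if a != wt])
                muts.append(PointMutation("HC", int(p) + 1, wt, mut))
            mutated = apply_mutations(seq, muts)
            recovered = diff_sequences(seq, mutated)
            assert sorted((m.position, m.wt_aa, m.mut_aa) for m in muts) == \
                [(m.position, m.wt_aa, m.mut_aa) for m in recovered]
            assert apply_mutations(seq, recovered).residues == mutated.residues


class TestRegionMap:
    def test_canonical_order_enforced(self):
        with pytest.raises(SequenceError):
            VRegionSequence("heavy", "QVQL", ("CDR1", "FR1", "FR1", "FR1"))

    def test_framework_masking(self):
        seq = VRegionSequence("heavy", "QVKLAB".replace("B", "S"),
                              ("FR1", "FR1", "CDR1", "CDR1", "FR2", "FR2"))
        assert seq.framework_only() == "QVAS"

    def test_region_annotation_csv(self, tmp_path):
        path = tmp_path / "regions.csv"
        path.write_text("chain,start,end,label\nH,1,2,FR1\nH,3,4,CDR1\n")
        regions = read_region_annotations(str(path))
        assert regions["H"] == ("FR1", "FR1", "CDR1", "CDR1")


MINIMAL_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.760  -1.200  1.00  0.00           C
END
"""


class TestPdbIO:
    def test_minimal_alanine(self):
        s = read_pdb(MINIMAL_ALA)
        assert len(s.chains) == 1
        assert len(s.chains[0].residues) == 1
        assert s.chains[0].residues[0].name == "ALA"
        assert len(s.chains[0].residues[0].atoms) == 5

    def test_empty_input_errors(self):
        with pytest.raises(StructureError):
            read_pdb("REMARK nothing here\n")

    def test_incomplete_backbone_collected_as_warning(self):
        trimmed = "\n".join(MINIMAL_ALA.splitlines()[1:])  # drop the N atom
        with pytest.raises(StructureError):
            # the lone residue is excluded -> empty structure
            read_pdb(trimmed)

    def test_toy_fab_write_read_idempotent(self, toy_fab):
        text1 = write_pdb(toy_fab)
        s2 = read_pdb(text1)
        text2 = write_pdb(s2)
        assert text1 == text2
        # coordinates equal to PDB precision (3 decimals)
        for c1, c2 in zip(toy_fab.chains, s2.chains):
            assert c1.chain_id == c2.chain_id
            for r1, r2 in zip(c1.residues, c2.residues):
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    assert np.allclose(a1.xyz, a2.xyz, atol=5e-4)

    def test_atom_count_matches_atom_records(self, toy_fab):
        text = write_pdb(toy_fab)
        n_records = sum(1 for line in text.splitlines()
                        if line.startswith("ATOM  "))
        assert read_pdb(text).n_atoms() == n_records == toy_fab.n_atoms()
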