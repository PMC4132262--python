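"""Mutation-energy scanner: mutant construction, energy terms, ΔΔG properties."""

import numpy as np
import pytest

from fabrefine.antibody_model import PointMutation, StructureError
from fabrefine.ddg_scanner import (
    DEFAULT_CONFIG, TermWeights, build_mutant_structure, fold_energy,
    lj_pair_energy, mutation_energy, rotamer_clash_counts, scan_mutations,
    shrake_rupley_sasa, get_params,
)
from fabrefine._geometry import ROTAMER_LIBRARY


def _all_xyz(s):
    return np.array([a.xyz for c in s.chains for r in c.residues for a in r.atoms])


class TestMutantConstruction:
    def test_identity_mutation_rmsd_zero(self, toy_fab):
        m = PointMutation("HC", 4, "I", "I", identity=True)
        mut = build_mutant_structure(toy_fab, m)
        assert np.array_equal(_all_xyz(mut), _all_xyz(toy_fab))

    def test_backbone_unchanged_by_mutation(self, toy_fab):
        seq = toy_fab.chain("H").sequence()
        pos = seq.index("K") + 1
        mut = build_mutant_structure(toy_fab, PointMutation("HC", pos, "K", "W"))
        for bb in ("N", "CA", "C", "O"):
            a = toy_fab.chain("H").residues[pos - 1].atom(bb)
            b = mut.chain("H").residues[pos - 1].atom(bb)
            assert np.array_equal(a.xyz, b.xyz)

    def test_mutation_to_glycine_strips_sidechain(self, toy_fab):
        seq = toy_fab.chain("H").sequence()
        pos = seq.index("A") + 1 if "A" in seq else seq.index("S") + 1
        wt = seq[pos - 1]
        mut = build_mutant_structure(toy_fab, PointMutation("HC", pos, wt, "G"))
        names = {a.name for a in mut.chain("H").residues[pos - 1].atoms}
        assert names == {"N", "CA", "C", "O"}

    def test_glycine_target_gets_reconstructed_cb(self, toy_fab):
        seq = toy_fab.chain("H").sequence()
        pos = seq.index("G") + 1
        mut = build_mutant_structure(toy_fab, PointMutation("HC", pos, "G", "L"))
        res = mut.chain("H").residues[pos - 1]
        assert res.has_atom("CB") and res.has_atom("CD1")

    def test_chosen_rotamer_minimizes_clashes(self, toy_fab):
        """Exhaustive enumeration: the placed rotamer's clash count is the
        minimum over the whole library (buried site, bulky mutant)."""
        # a buried core position (heptad 'a' site)
        pos = 4
        wt = toy_fab.chain("H").residues[pos - 1].aa1
        mut = build_mutant_structure(toy_fab, PointMutation("HC", pos, wt, "F"))
        counts = rotamer_clash_counts(mut, "H", pos, "PHE")
        # recompute the chosen rotamer's count on the mutant itself
        chosen = int(np.argmin(rotamer_clash_counts(toy_fab, "H", pos, "PHE")))
        assert counts[chosen] == min(counts)

    def test_wt_mismatch_raises(self, toy_fab):
        with pytest.raises(StructureError, match="expected"):
            build_mutant_structure(toy_fab, PointMutation("HC", 4, "W", "F"))

    def test_missing_chain_raises(self, toy_fab):
        with pytest.raises(StructureError):
            build_mutant_structure(toy_fab, PointMutation("HC", 4, "I", "F"),
                                   chain_map={"HC": "Z", "LC": "L"})


class TestEnergyFunction:
    def test_deterministic(self, toy_fab):
        assert fold_energy(toy_fab) == fold_energy(toy_fab)

    def test_lj_minimum_closed_form(self):
        """At r = rmin the pair energy equals −sqrt(eps_i·eps_j) exactly."""
        p = get_params()
        e_c, r_c = p.lj_eps["C"], p.lj_rmin_half["C"]
        e_n, r_n = p.lj_eps["N"], p.lj_rmin_half["N"]
        assert lj_pair_energy(r_c + r_n, e_c, r_c, e_n, r_n) == \
            pytest.approx(-np.sqrt(e_c * e_n), abs=1e-12)
        # repulsive wall positive, long range attractive
        assert lj_pair_energy(0.8 * (r_c + r_n), e_c, r_c, e_n, r_n) > 0
        assert lj_pair_energy(1.5 * (r_c + r_n), e_c, r_c, e_n, r_n) < 0

    def test_isolated_alanine_vdw_zero(self):
        """A lone alanine has no pairs beyond the 1-2/1-3/1-4 exclusions."""
        from fabrefine.antibody_model import read_pdb
        from test_antibody_model import MINIMAL_ALA
        s = read_pdb(MINIMAL_ALA)
        assert fold_energy(s).vdw == 0.0

    def test_sasa_single_atom_is_full_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert area[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_weighted_total_is_dot_product(self, toy_fab):
        w = TermWeights(1.5, 0.5, 2.0, 0.0, 3.0)
        e = fold_energy(toy_fab, w)
        assert e.weighted_total == pytest.approx(w.as_array() @ e.terms(),
                                                 abs=1e-9)


class TestMutationEnergy:
    def test_identity_ddg_exactly_zero_sampled(self, toy_fab):
        """Identity substitutions cost exactly nothing (sampled positions;
        the full sweep runs in the acceptance suite)."""
        seq = toy_fab.chain("H").sequence()
        for pos in (1, 10, 25, 40, 52):
            m = PointMutation("HC", pos, seq[pos - 1], seq[pos - 1],
                              identity=True)
            rec = mutation_energy(toy_fab, m)
            assert rec.ddg_murine_context == 0.0

    def test_weight_linearity_exact(self, toy_fab, rng):
        seq = toy_fab.chain("H").sequence()
        pos = seq.index("S") + 1
        m = PointMutation("HC", pos, "S", "A")
        base = mutation_energy(toy_fab, m).breakdown_murine
        for _ in range(3):
            w = TermWeights(*rng.uniform(0.1, 3.0, size=5))
            rec = mutation_energy(toy_fab, m, w)
            assert rec.ddg_murine_context == pytest.approx(
                w.as_array() @ base.terms(), abs=1e-9)

    def test_approximate_involution(self, toy_fab):
        """ΔΔG(A→B) + ΔΔG(B→A on the mutant) ≈ 0 (within 0.5 kcal/mol)."""
        seq = toy_fab.chain("L").sequence()
        pos = seq.index("T") + 1
        fwd = PointMutation("LC", pos, "T", "A")
        mut = build_mutant_structure(toy_fab, fwd)
        r_fwd = mutation_energy(toy_fab, fwd).ddg_murine_context
        r_bwd = mutation_energy(
            mut, PointMutation("LC", pos, "A", "T")).ddg_murine_context
        assert abs(r_fwd + r_bwd) < 0.5

    def test_distant_pair_additivity(self, toy_fab):
        """Mutations >12 Å apart are energetically additive (<0.1 kcal/mol)."""
        ma = PointMutation("HC", 2, toy_fab.chain("H").residues[1].aa1, "A")
        mb_pos, mb_wt = None, None
        ca_a = toy_fab.chain("H").residues[1].atom("CA").xyz
        for r in toy_fab.chain("L").residues:
            if r.aa1 not in ("G", "A", "P") and \
                    np.linalg.norm(r.atom("CA").xyz - ca_a) > 16.0:
                mb_pos, mb_wt = r.seq_number, r.aa1
                break
        assert mb_pos is not None
        mb = PointMutation("LC", mb_pos, mb_wt, "A")
        da = mutation_energy(toy_fab, ma).ddg_murine_context
        db = mutation_energy(toy_fab, mb).ddg_murine_context
        dboth = mutation_energy(toy_fab, [ma, mb]).ddg_murine_context
        assert abs(dboth - da - db) < 0.1

    def test_scan_consistent_with_individual_calls(self, toy_fab, toy_fab_copy):
        rng = np.random.default_rng(3)
        seqH = toy_fab.chain("H").sequence()
        cands = []
        while len(cands) < 5:
            pos = int(rng.integers(1, len(seqH) + 1))
            wt = seqH[pos - 1]
            aa = rng.choice([a for a in "ASTLFV" if a != wt])
            cands.append(PointMutation("HC", pos, wt, str(aa)))
        records = scan_mutations(toy_fab, toy_fab_copy, cands)
        assert [r.error for r in records] == [None] * 5
        for m, rec in zip(cands, records):
            solo = mutation_energy(toy_fab, m)
            assert rec.ddg_murine_context == solo.ddg_murine_context

    def test_scan_empty_candidates(self, toy_fab, toy_fab_copy):
        assert scan_mutations(toy_fab, toy_fab_copy, []) == []

    def test_scan_collects_per_candidate_failures(self, toy_fab, toy_fab_copy):
        cands = [PointMutation("HC", 999, "A", "S"),
                 PointMutation("HC", 4, "I", "V")]
        records = scan_mutations(toy_fab, toy_fab_copy, cands)
        assert records[0].error is not None
        assert records[1].error is None
        assert records[1].ddg_murine_context is not None


class TestRotamerLibrary:
    def test_all_residues_covered(self):
        assert set(ROTAMER_LIBRARY) == {
            "GLY", "ALA", "SER", "CYS", "THR", "VAL", "PRO", "LEU", "ILE",
            "PHE", "TYR", "TRP", "HIS", "ASP", "ASN", "MET", "GLU", "GLN",
            "LYS", "ARG"}

    def test_entropy_table_matches_library(self):
        p = get_params()
        for res, rots in ROTAMER_LIBRARY.items():
            assert p.n_rotamers[res] == len(rots)
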