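"""Selection rules reproduce the published candidate tables' decisions."""

import itertools

import pytest

from fabrefine.antibody_model import PointMutation
from fabrefine.ddg_scanner import MutationEnergyRecord
from fabrefine.design_engine import (
    DesignError, DesignRules, classify_backmutation, classify_humanizing,
    decisions_for, design_construct, load_fixture_phenotypes,
    load_table_fixture, net_mutation_energy, round_half_away,
    v5_epitope_ablations,
)


def rec(notation, ddg_m, ddg_h, direction="humanizing"):
    from fabrefine.antibody_model import parse_mutation_notation
    return MutationEnergyRecord(mutation=parse_mutation_notation(notation),
                                ddg_murine_context=ddg_m,
                                ddg_humanized_context=ddg_h,
                                direction=direction)


class TestBackMutationRule:
    def test_parental_stabilizing(self):
        d = classify_backmutation(rec("LC:S12L", -1.26, 0.79, "back"))
        assert d.action == "revert_to_murine"
        assert d.rule_fired == "parental-context stabilizing"

    def test_model_strongly_stabilizing(self):
        d = classify_backmutation(rec("LC:T10F", 0.17, -0.95, "back"))
        assert d.action == "revert_to_murine"
        assert d.rule_fired == "model-context strongly stabilizing"

    def test_gly_pro_backbone(self):
        d = classify_backmutation(rec("LC:Q100G", 1.06, 2.94, "back"))
        assert d.action == "revert_to_murine"
        assert d.rule_fired == "Gly/Pro backbone"
        d2 = classify_backmutation(rec("LC:P40A", 0.22, 1.41, "back"))
        assert d2.rule_fired == "Gly/Pro backbone"

    def test_no_rule_fires_excludes(self):
        d = classify_backmutation(rec("HC:T5L", 0.3, 0.2, "back"))
        assert d.action == "exclude"

    def test_missing_context_errors(self):
        bad = rec("LC:S12L", -1.26, 0.79, "back")
        bad.ddg_humanized_context = None
        with pytest.raises(DesignError):
            classify_backmutation(bad)


class TestHumanizingRule:
    @pytest.mark.parametrize("notation,ddg_m,ddg_h", [
        ("LC:K24R", -0.21, -0.17),
        ("HC:I20L", 0.43, -0.86),
        ("LC:V58I", -0.64, 0.01),    # stabilizing parental, negligible model
        ("LC:S56T", -0.05, 0.04),
    ])
    def test_accepted(self, notation, ddg_m, ddg_h):
        assert classify_humanizing(rec(notation, ddg_m, ddg_h)).action == "humanize"

    def test_destabilizing_in_both_excluded(self):
        assert classify_humanizing(rec("HC:A7S", 1.2, 0.8)).action == "exclude"

    def test_destabilizing_in_one_context_excluded(self):
        assert classify_humanizing(rec("HC:F63V", 1.91, 1.80)).action == "exclude"


class TestNetEnergy:
    def test_table1_sums(self):
        records = load_table_fixture("v3")
        assert net_mutation_energy(records, "murine") == -3.55
        assert net_mutation_energy(records, "humanized") == 4.61

    def test_single_record(self):
        assert net_mutation_energy([rec("HC:A7S", 0.10, 0.0)], "murine") == 0.10

    def test_permutation_invariance(self):
        records = load_table_fixture("v3")
        for perm in itertools.islice(itertools.permutations(records), 5):
            assert net_mutation_energy(list(perm), "murine") == -3.55

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(1.75, 1) == 1.8
        assert round_half_away(-9.05, 1) == -9.1


class TestConstructDesign:
    def test_v3_reproduces_table1(self):
        design = design_construct(load_table_fixture("v3"), name="V3")
        assert len(design.mutations) == 12
        assert design.net_energy_murine_context == -3.55
        assert design.net_energy_humanized_context == 4.61
        assert design.phenotype_per_mutation == load_fixture_phenotypes("v3")

    def test_v5_reproduces_table2(self):
        design = design_construct(load_table_fixture("v5"),
                                  epitope_ablations=v5_epitope_ablations(),
                                  name="V5")
        assert len(design.mutations) == 9
        assert design.net_energy_murine_context == 1.62
        assert design.net_energy_humanized_context == 0.90
        assert design.phenotype_per_mutation == load_fixture_phenotypes("v5")

    def test_v5_without_ablations_drops_destabilizing_cdr_mutations(self):
        design = design_construct(load_table_fixture("v5"))
        notations = [m.notation() for m in design.mutations]
        assert "HC:F63V" not in notations and "HC:S65G" not in notations

    def test_empty_candidates(self):
        design = design_construct([])
        assert design.mutations == []
        assert design.net_energy_murine_context == 0.0

    def test_duplicate_positions_rejected(self):
        records = [rec("HC:A7S", -1.0, -1.0), rec("HC:A7T", -1.0, -1.0)]
        with pytest.raises(DesignError):
            design_construct(records)

    def test_tightening_threshold_never_adds_humanizing_mutations(self):
        records = load_table_fixture("v5")
        baseline = {m.notation() for m in design_construct(
            records, DesignRules(negligible_threshold=0.5)).mutations}
        for thr in (0.4, 0.2, 0.05, 0.0):
            tighter = {m.notation() for m in design_construct(
                records, DesignRules(negligible_threshold=thr)).mutations}
            assert tighter <= baseline
            baseline = tighter

    def test_decisions_name_one_rule_each(self):
        decisions = decisions_for(load_table_fixture("v3"))
        assert all(d.rule_fired for d in decisions)
        assert {d.action for d in decisions} <= {
            "revert_to_murine", "humanize", "exclude"}
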