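"""Mutation-selection rules for framework refinement constructs.

Given a candidate table of point mutations scored in two structural
contexts — the parental murine Fab crystal structure and the humanized
homology model — the engine decides, per candidate:

* **back mutations** (restoring the murine residue) are accepted when the
  parental-context energy is stabilizing, when the model context is strongly
  stabilizing, or when a Gly/Pro residue is involved (backbone-conformation
  rule);
* **humanizing mutations** are accepted when each context is stabilizing
  (ΔΔG ≤ 0) or negligible (ΔΔG below the negligibility threshold,
  default 0.5 kcal/mol);
* **epitope-ablating mutations** (e.g. CDR-H2 changes removing a predicted
  MHC-II epitope) bypass energy gating entirely.

The thresholds live in :class:`DesignRules`; each decision records which
rule fired.  Net construct energies are exact sums over the selected rows,
reported to 2 decimals with half-away-from-zero rounding.  Note the rule
set is a reconstruction from narrated criteria, not a published algorithm;
in particular the "model-context strongly stabilizing" clause exists to
admit back mutations that are mildly destabilizing in the parental context
but strongly stabilizing in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .antibody_model import ConstructDesign, PointMutation, parse_mutation_notation
from .ddg_scanner import MutationEnergyRecord


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignRules:
    """Thresholds of the selection rules (kcal/mol)."""

    negligible_threshold: float = 0.5
    emphasize_parental_context: bool = True
    strong_model_stabilization: float = 0.5
    glycine_proline_backmutation: bool = True

    def __post_init__(self) -> None:
        if self.negligible_threshold < 0 or self.strong_model_stabilization < 0:
            raise DesignError("thresholds must be >= 0")


@dataclass(frozen=True)
class Decision:
    mutation: PointMutation
    action: str            # "revert_to_murine" | "humanize" | "exclude"
    rule_fired: str


DEFAULT_RULES = DesignRules()


def _require_contexts(rec: MutationEnergyRecord) -> tuple[float, float]:
    if rec.ddg_murine_context is None and rec.ddg_humanized_context is None:
        raise DesignError(f"record {rec.mutation.notation()} has no context energies")
    if rec.ddg_murine_context is None or rec.ddg_humanized_context is None:
        raise DesignError(
            f"record {rec.mutation.notation()} needs both context energies "
            "for classification")
    return rec.ddg_murine_context, rec.ddg_humanized_context


def classify_backmutation(rec: MutationEnergyRecord,
                          rules: DesignRules = DEFAULT_RULES) -> Decision:
    """Decide whether a candidate back mutation is reverted to murine."""
    ddg_m, ddg_h = _require_contexts(rec)
    m = rec.mutation
    if ddg_m < 0:
        return Decision(m, "revert_to_murine", "parental-context stabilizing")
    if ddg_h < -rules.strong_model_stabilization:
        return Decision(m, "revert_to_murine", "model-context strongly stabilizing")
    if rules.glycine_proline_backmutation and ("G" in (m.wt_aa, m.mut_aa) or
                                               "P" in (m.wt_aa, m.mut_aa)):
        return Decision(m, "revert_to_murine", "Gly/Pro backbone")
    return Decision(m, "exclude", "no back-mutation rule fired")


def classify_humanizing(rec: MutationEnergyRecord,
                        rules: DesignRules = DEFAULT_RULES) -> Decision:
    """Accept a humanizing mutation when each context is stabilizing or
    negligible (< negligible_threshold kcal/mol)."""
    ddg_m, ddg_h = _require_contexts(rec)
    thr = rules.negligible_threshold
    ok_m = ddg_m <= 0 or ddg_m < thr
    ok_h = ddg_h <= 0 or ddg_h < thr
    if ok_m and ok_h:
        if ddg_m <= 0 and ddg_h <= 0:
            return Decision(rec.mutation, "humanize", "stabilizing in both contexts")
        return Decision(rec.mutation, "humanize", "stabilizing or negligible")
    return Decision(rec.mutation, "exclude", "destabilizing beyond threshold")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def net_mutation_energy(records: list[MutationEnergyRecord],
                        context: str) -> float:
    """Exact sum of the chosen context energies, 2 decimals,
    half away from zero."""
    key = {"murine": "ddg_murine_context",
           "humanized": "ddg_humanized_context"}.get(context)
    if key is None:
        raise DesignError(f"unknown context {context!r}")
    vals = []
    for rec in records:
        v = getattr(rec, key)
        if v is None:
            raise DesignError(
                f"record {rec.mutation.notation()} missing {context} context")
        vals.append(v)
    return round_half_away(math.fsum(vals), 2)


def design_construct(candidates: list[MutationEnergyRecord],
                     rules: DesignRules = DEFAULT_RULES,
                     epitope_ablations: list[PointMutation] | None = None,
                     name: str = "construct") -> ConstructDesign:
    """Apply the selection rules to a candidate table.

    Records with ``direction == "back"`` run through the back-mutation rule,
    the rest through the humanizing rule.  Mutations listed in
    ``epitope_ablations`` are included regardless of their energies.
    """
    ablation_keys = {(m.chain, m.position) for m in (epitope_ablations or [])}
    selected: list[MutationEnergyRecord] = []
    phenotypes: list[str] = []
    for rec in candidates:
        key = (rec.mutation.chain, rec.mutation.position)
        if key in ablation_keys:
            selected.append(rec)
            phenotypes.append("Human")
            continue
        if rec.direction == "back":
            decision = classify_backmutation(rec, rules)
            if decision.action == "revert_to_murine":
                selected.append(rec)
                phenotypes.append("Murine")
        else:
            decision = classify_humanizing(rec, rules)
            if decision.action == "humanize":
                selected.append(rec)
                phenotypes.append("Human")
    mutations = [r.mutation for r in selected]
    keys = [(m.chain, m.position) for m in mutations]
    if len(set(keys)) != len(keys):
        raise DesignError("duplicate (chain, position) across selections")
    if selected:
        net_m = net_mutation_energy(selected, "murine")
        net_h = net_mutation_energy(selected, "humanized")
    else:
        net_m = net_h = 0.0
    return ConstructDesign(name=name, mutations=mutations,
                           phenotype_per_mutation=phenotypes,
                           net_energy_murine_context=net_m,
                           net_energy_humanized_context=net_h)


def decisions_for(candidates: list[MutationEnergyRecord],
                  rules: DesignRules = DEFAULT_RULES,
                  epitope_ablations: list[PointMutation] | None = None
                  ) -> list[Decision]:
    """Per-candidate decisions (including excluded rows), for reporting."""
    ablation_keys = {(m.chain, m.position) for m in (epitope_ablations or [])}
    out = []
    for rec in candidates:
        key = (rec.mutation.chain, rec.mutation.position)
        if key in ablation_keys:
            out.append(Decision(rec.mutation, "humanize", "epitope ablation"))
        elif rec.direction == "back":
            out.append(classify_backmutation(rec, rules))
        else:
            out.append(classify_humanizing(rec, rules))
    return out


# ---------------------------------------------------------------------------
# candidate-table I/O


def load_candidate_table(path_or_buffer) -> list[MutationEnergyRecord]:
    """Read a candidate CSV (mutation, location, ddg_parental, ddg_model,
    direction) into energy records."""
    df = pd.read_csv(path_or_buffer)
    need = {"mutation", "ddg_parental", "ddg_model", "direction"}
    if not need.issubset(df.columns):
        raise DesignError(f"candidate CSV must have columns {sorted(need)}")
    out = []
    for _, row in df.iterrows():
        mut = parse_mutation_notation(str(row["mutation"]),
                                      location_label=str(row.get("location", "")))
        out.append(MutationEnergyRecord(
            mutation=mut,
            ddg_murine_context=float(row["ddg_parental"]),
            ddg_humanized_context=float(row["ddg_model"]),
            direction=str(row["direction"]),
            location=str(row.get("location", "")),
        ))
    return out


def load_table_fixture(which: str) -> list[MutationEnergyRecord]:
    """Bundled candidate tables: ``"v3"`` (12 rows) or ``"v5"`` (9 rows)."""
    name = {"v3": "table1_v3.csv", "v5": "table2_v5.csv"}.get(which.lower())
    if name is None:
        raise DesignError(f"unknown fixture {which!r} (use 'v3' or 'v5')")
    with resources.files("fabrefine.data").joinpath(name).open() as fh:
        return load_candidate_table(fh)


def load_fixture_phenotypes(which: str) -> list[str]:
    """The published per-row phenotype column of a bundled table."""
    name = {"v3": "table1_v3.csv", "v5": "table2_v5.csv"}[which.lower()]
    with resources.files("fabrefine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)["phenotype"].tolist()


def v5_epitope_ablations() -> list[PointMutation]:
    """The four CDR-H2 epitope-ablating mutations of the V5 design."""
    return [rec.mutation for rec in load_table_fixture("v5")
            if rec.location == "CDR H2"]
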