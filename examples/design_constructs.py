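"""Apply the back-mutation/humanizing selection rules to the bundled
candidate tables and print the resulting construct designs.

The V3 design maximizes stability: destabilizing humanizing mutations are
reverted to murine (plus Gly/Pro backbone reverts) and benign humanizing
mutations are added.  The V5 design minimizes predicted immunogenicity:
four CDR-H2 epitope-ablating mutations are included regardless of energy.
"""

from fabrefine.design_engine import (decisions_for, design_construct,
                                     load_table_fixture, v5_epitope_ablations)

for which, ablations in (("v3", None), ("v5", v5_epitope_ablations())):
    candidates = load_table_fixture(which)
    design = design_construct(candidates, epitope_ablations=ablations,
                              name=which.upper())
    print(f"\n{design.name}: {len(design.mutations)} mutations, "
          f"net ΔΔG {design.net_energy_murine_context:+.2f} kcal/mol (parental) / "
          f"{design.net_energy_humanized_context:+.2f} kcal/mol (humanized model)")
    for decision in decisions_for(candidates, epitope_ablations=ablations):
        print(f"  {decision.mutation.notation():>10s}  {decision.action:<17s}"
              f" [{decision.rule_fired}]")

# Negative net energy = the selected set stabilizes that structural context.
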