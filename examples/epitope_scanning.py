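"""Scan a V-region sequence for predicted MHC class II epitope cores.

Every 15-mer window is scored by its best 9-mer core under a 9x20
position-specific scoring matrix; windows above the moderate threshold are
reported.  Mutations that fall inside a hit's 9-mer core are candidate
epitope-ablating substitutions (the rationale behind CDR-H2 redesigns).
"""

import numpy as np
import pandas as pd

from fabrefine.antibody_model import AA1, parse_mutation_notation
from fabrefine.epitope_scan import epitope_overlap, scan_epitopes
from fabrefine.synthetic_data import default_templates

rng = np.random.default_rng(0)
matrix = pd.DataFrame(rng.normal(0.0, 1.0, size=(9, 20)), columns=list(AA1))

query = default_templates()[0]
hits = scan_epitopes(query.residues, matrix, thresholds=(8.0, 5.5))
print(f"{len(hits)} window(s) at or above the moderate threshold:")
for h in hits:
    print(f"  window {h.start:>3d}  core {h.core_start}-{h.core_end - 1}"
          f"  score {h.score:5.2f}  [{h.affinity_class}]")

if hits:
    core = hits[0].core_start
    wt = query.residues[core - 1]
    mutation = parse_mutation_notation(f"HC:{wt}{core}A")
    pairs = epitope_overlap(hits, [mutation])
    print(f"\n{mutation.notation()} overlaps {len(pairs)} epitope core(s) — "
          "a candidate ablation site.")
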