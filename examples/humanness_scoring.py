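"""T20-style humanness of V regions against a synthetic human V database.

The score is the mean percent identity of the query's top 20 matches —
computed full-length and framework-only (CDR positions masked).  Scores are
only comparable within one database.
"""

from fabrefine.humanness import t20_score
from fabrefine.synthetic_data import default_templates, make_human_v_db

db = make_human_v_db(n=300, substitution_rate=0.05, seed=7)

for query in default_templates():
    full = t20_score(query, db, framework_only=False)
    framework = t20_score(query, db, framework_only=True)
    print(f"{query.name:>16s} ({query.chain_kind}):  "
          f"T20 full = {full.t20_full:5.1f}   "
          f"T20 framework = {framework.t20_framework:5.1f}")

# Templates seeded the database, so scores are high (~95); a murine query
# would sit far lower, and humanizing mutations push the score up.
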