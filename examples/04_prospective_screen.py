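"""Hierarchical prospective screening of a peptide database.

Screens a mixed database (near-query mutants, exact query copies, unrelated
peptides) through the length/tag filter, 95% redundancy filter, MAX-SIM
search at 0.60, and perfect-match removal, then reports each hit's nearest
known neighbors in descriptor space.
"""

import numpy as np

from pepcsn import (
    PeptideRecord,
    ScreeningConfig,
    build_query_model,
    nearest_known_neighbors,
    prospective_screen,
)

rng = np.random.default_rng(5)
AA = list("ACDEFGHIKLMNPQRSTVWY")
queries = [PeptideRecord(f"q{i}", "".join(rng.choice(AA, 18))) for i in range(4)]
model = build_query_model("screenDemo", [queries], theta=0.60)

near = []
for i, q in enumerate(queries):
    mut = list(q.sequence)
    for p in rng.integers(0, len(mut), size=3):
        mut[p] = "W" if mut[p] != "W" else "Y"
    near.append(PeptideRecord(f"near{i}", "".join(mut)))
exact = [PeptideRecord(f"copy{i}", q.sequence) for i, q in enumerate(queries[:2])]
unrelated = [PeptideRecord(f"u{i}", "".join(rng.choice(AA, 15))) for i in range(30)]

db = near + exact + unrelated
hits, log = prospective_screen(db, model, ScreeningConfig(exclude_tags=frozenset()))
print("stage log:", log)
print("hits:", [(h.target_id, round(h.fused_score, 3)) for h in hits])
# exact copies are dropped by the score-1 rule (already-known sequences);
# only novel-but-similar peptides survive as candidate leads

hit_records = [r for r in db if r.id in {h.target_id for h in hits}]
neighbors = nearest_known_neighbors(hit_records, queries, threshold=0.3, k=3)
print(neighbors.to_string(index=False))
# each hit's 3 nearest known peptides in descriptor space; hits sharing 2+
# neighbors are flagged as redundant candidates
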