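"""Rank survival features of a fitted two-stage Cox network.

Hidden-node importances (partial-likelihood drop under mean-masking) are
propagated back to the original features through the stage-1 weights and
thresholded per set (densities at 0.5, interactions at 0.75) to pick the
top survival features.  Six features carry planted hazard effects; the
example reports where they land in the importance ranking.
"""

import spatialsurv as ss

effects = {
    "density|Macrophages 2": 1.5,
    "density|B cells": -1.5,
    "ccis|B cells|Endothelial": 1.5,
    "ccis|T and B cells|Vimentin-hi fibroblasts": -1.5,
    "ccis|Hypoxic epithelial|Apoptotic epithelial": 1.5,
    "ccis|Proliferative epithelial|p53+ EGFR+ epithelial": -1.5,
}
cohort = ss.generate_cohort(
    ss.SimConfig(n_patients=150, seed=0, effect_vector=effects)
)
matrix = ss.drop_zero_features(
    ss.assemble_features(cohort.images, cohort.palette)
)
blocks = {s: matrix.subset(s) for s in ("CP", "TMI", "TCI")}
model = ss.fit_twostage(
    blocks["CP"], blocks["TMI"], blocks["TCI"], cohort.outcome,
    l2_lambda=0.01, seed=0,
)

hidden = ss.hidden_importance(model, blocks, cohort.outcome)
print(f"{len(hidden)} hidden-node scores (6 CP + 17 TMI + 11 TCI)")

vectors = ss.split_and_propagate(model, hidden)
table = ss.normalize_and_select(vectors)
table["pct"] = table.groupby("set")["normalized"].rank(pct=True)
print(f"{int(table.selected.sum())} features selected "
      f"(normalized score > 0.5 for CP, > 0.75 for TMI/TCI)")

print("planted features, percentile within their set:")
for name in effects:
    row = table[table.feature == name].iloc[0]
    print(f"  {name}: {row.pct:.0%}"
          f"{' (selected)' if row.selected else ''}")
print(
    "\nSingle-run attribution through a small network is noisy — planted "
    "features concentrate in the upper tail rather than occupying the top "
    "six slots outright; across repeated seeded cohorts the enrichment is "
    "highly significant (see the acceptance tests)."
)
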