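# Methods

This note records the models implemented in `spatialsurv`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data experiments do and do not establish.

## Spatial interaction features

A patient image is a set of cell centroids (μm) with phenotype labels
from a palette that assigns each phenotype to the immune, stromal or
epithelial class.  The default palette has 27 phenotypes (6 immune, 7
stromal, 14 epithelial).

**Neighbor graph.**  Cells at Euclidean distance ≤ `neighbor_radius`
(default 4 μm, matching the typical segmentation pixel pitch of imaging
mass cytometry) are joined by an undirected edge; the threshold is
inclusive, so ties at exactly the radius are edges.  *Cellular
communities* are the connected components of this graph.  This is a
deterministic, geometry-only definition; pipelines that inherit
community labels from an upstream neighborhood-clustering step can
attach their own `community` node attribute instead.

**Clustering coefficient.**  The community weight *C* is the mean local
clustering coefficient over the community's nodes, with nodes of degree
< 2 contributing 0.  Community transitivity (global triangle fraction)
is available via `clustering="global"`; the local mean is the default
because it is defined node-wise and degrades gracefully on sparse
communities.  Either way, tree-like communities carry zero weight, so
images without triangles produce identically zero interaction scores.

**Pair counts.**  `B_xy` counts each undirected edge between a cell of
phenotype x and one of phenotype y exactly once.  An equivalent per-cell
enumeration would count cross-phenotype edges twice (once from each
endpoint), inflating off-diagonal pairs by a constant factor of 2;
single counting is used because it makes `B_xy` a true edge count, and
the factor is irrelevant to any rank-based downstream use.

**Area.**  CCIS and densities are normalized by the tissue area *A*
(μm²).  The provided `area_um2` is used when present; otherwise the
convex hull of the cell centroids is the fallback, since "area occupied
by the cells" has no unique operational definition.  All scores scale
exactly as 1/A, which the tests verify.

**Taxonomy.**  The k(k+1)/2 unordered pairs (self-pairs included) are
categorized by the classes of their members.  For the default palette:
21 immune-immune, 42 immune-stromal, 84 immune-epithelial, 28
stromal-stromal, 98 stromal-epithelial, 105 epithelial-epithelial = 378.
Feature sets: CP = the 27 densities, TCI = the epithelial-epithelial
pairs, TMI = all other pairs (273).  Features identically zero across a
cohort are dropped (with the dropped names recorded), since pairs whose
phenotypes never touch carry no information and break min-max scaling.

## Survival models

**Outcome.**  Right-censored overall survival (months, event ∈ {0,1}).
All fitting requires ≥ 10 patients and ≥ 3 events.

**Partial likelihood.**  Breslow's convention for tied event times: all
patients with time ≥ t belong to the risk set of an event at t, and tied
events share the same denominator.  Breslow is the standard choice for
neural Cox losses because it is smooth and cheap; the implementation is
verified against an explicit risk-set loop at n ≤ 20.

**Network.**  One hidden layer, tanh activation, hidden width
`ceil(sqrt(p))`.  tanh keeps the stage-2 inputs bounded in (−1, 1), so
no re-standardization between stages is needed (a
`restandardize_hidden` switch exists).  Inputs are z-scored per column
with training-split statistics (constant columns get unit scale);
interaction scores have arbitrary scale, so standardization is required
for stable optimization.  The objective is the mean per-event negative
partial log-likelihood plus `l2_lambda` times the squared norm of all
parameters, minimized by L-BFGS-B with analytic gradients (max 2000
iterations, relative tolerance 1e-6).  Initialization is small uniform
(±1/√p) from the seed, making fits exactly reproducible.  `l2_lambda`
can be a number or `"auto"`, which selects over {1e-3, 1e-2, 1e-1, 1} by
partial likelihood on an inner 75/25 split.

**Two-stage composite.**  The CP, TMI and TCI networks are fitted
independently and frozen; their hidden activations (6 + 17 + 11 = 34
columns) are concatenated and a second network with hidden width
`ceil(sqrt(34)) = 6` is fitted on them.  Freezing stage 1 keeps the
composite modular and mirrors how per-modality models are combined in
practice.

**Evaluation.**  Harrell's C-index (score ties count ½; lifelines
backend, verified against an exhaustive pair oracle).  `evaluate_models`
draws repeated 80/20 splits stratified by the event indicator (default
20 repeats) and emits a tidy (model, repeat, c_index) table.  The
clinical baseline is a lifelines Cox-PH on ER/PR/HER2/grade with a small
ridge penalty (0.01) to tolerate near-separation.

## Importance and feature selection

Stage-2 input node j is scored by the drop in the stage-2 partial
log-likelihood when column j is replaced by its cohort mean
(mean-masking, no refit).  A permutation variant (`method="permute"`)
averages the drop over within-column shuffles.  Mean-masking is
deterministic and exact for dead pathways (a node the second stage
ignores scores exactly 0).

The 34 node scores are partitioned by originating network (6/17/11) and
propagated to the input features by `O = Wᵀ H` using each network's
input weights.  Because the product can be negative, absolute values are
taken before per-set min-max normalization to [0, 1]; normalization is
per-set (not global) so that the dense CP set and the sparse interaction
sets are thresholded on comparable scales.  Selection keeps features
whose normalized score strictly exceeds the set threshold (0.5 for CP,
0.75 for TMI and TCI), with a configurable cap (default 50) applied by
descending score when the union is larger.  Constant importance vectors
normalize to zero with a warning.

## Consensus NMF subtyping

Input: the selected features, min-max scaled to [0, 1] per feature
(guaranteeing the non-negativity NMF requires).  Each of `n_runs`
(default 30) seeded runs factorizes the matrix with multiplicative
updates under Frobenius loss (scikit-learn NMF, `solver="mu"`, random
init, 500 iterations, tolerance 1e-5) and assigns every patient to its
largest factor.  The consensus matrix is the co-assignment frequency;
final labels cut the average-linkage tree of (1 − consensus) at K.

Rank search (default 3–15) scores each K by the cophenetic correlation
between the consensus distances and their average-linkage cophenetic
distances, and by the mean silhouette of the labels under the consensus
distance.  The chosen K maximizes the cophenetic score with silhouette
as tie-breaker.  Metrics are compared after rounding to 9 decimals, and
exact ties resolve toward the **larger** rank: on very crisp data a
coarse merge can be as reproducible as the true partition (both metrics
exactly 1), whereas over-splitting is never perfectly reproducible, so
ranks above the truth do not join the tie.  A degenerate all-one-cluster
consensus (all distances 0) is defined to have cophenetic score 1.

Subtypes are renumbered 1..K by decreasing Kaplan-Meier median survival,
with the KM survival probability at the last observed time breaking
ties (relevant when medians are unreached).  Downstream statistics:
(K−1)-df multi-group log-rank; Harrell's C of the subtype index used as
a risk score; per-(subtype, feature) two-sided Mann-Whitney U of the
subtype against the rest on 0–1-normalized features with
Benjamini-Hochberg adjustment across all tests; within-subtype Spearman
correlation edges above a threshold (default 0.5); and good (1–4) vs bad
(5–7) dichotomization tested by 2-group log-rank within each
receptor-defined molecular subtype (TNBC = ER−/PR−/HER2−; HER2-enriched
= ER−/PR−/HER2+; Luminal A = (ER+ or PR+)/HER2−; Luminal B = (ER+ or
PR+)/HER2+ — defined from receptors only, as no Ki-67 measurement is
assumed).

Significance marks in the characterization table follow an inverted
convention — `*` for adjusted p < 0.01 and `**` for 0.01 ≤ p < 0.05 —
kept deliberately for continuity with the figure legends this table is
designed to feed; note that it is the reverse of common usage.

## Cross-cohort label transfer

Pseudo-bulk profiles are the per-patient arithmetic means of cell-level
marker intensities.  Marker/gene names are harmonized through an
optional protein→gene map, case-insensitively; unmatched markers are
reported and dropped.  Both cohorts are z-scored per shared feature and
cross-cohort distances are computed (default: correlation distance,
1 − Pearson r; any callable returning a distance matrix can be plugged
in — the published joint-embedding aligner used in the original analysis
is one such provider and is intentionally not re-implemented here).

A similarity cutoff `c` retains the `floor((1 − c)·n_pairs)` smallest
distances — at 0.995, the 0.5% most similar pairs — including boundary
ties (with a 1e-12 float-noise tolerance, which is what lets a cohort
matched against itself always retain its zero-distance diagonal).  The
cutoff applies globally over all cross pairs by default; a
`per_source` mode applies it within each source patient's row.  Matched
external patients are compared with the remaining patients (optionally
within a stratum such as one molecular subtype) by 2-group log-rank, and
group-wise differential markers use two-sided rank-sum tests with BH
adjustment and the sign of the median difference — a distribution-free
stand-in for moderated-t pipelines, adequate at validation scale.

## Synthetic cohort generator

The generator emulates the data-generating structure the analysis
assumes, with ground truth for recovery tests.

* **Geometry** — per patient, `communities_per_patient` (default 4–8)
  community centers uniform in a 1000×1000 μm box; cell positions
  isotropic Gaussian (σ = `community_spread`, default 12 μm) around
  centers, clipped to the box; `cells_per_community` default 30–60.
  These defaults give nearest-neighbor distances ≈ 2 μm in community
  cores, so the 4 μm radius graph is locally dense (triangles exist and
  the interaction scores are non-degenerate) while communities stay
  disconnected from each other.  The image area is the full box, so the
  1/A normalization is exactly bookkept.
* **Composition** — each patient draws a latent subtype (default 4,
  uniform); phenotypes are multinomial from the subtype's mixture.  The
  default mixtures give every phenotype a uniform base weight and boost
  a subtype-specific signature (one immune, one stromal, two epithelial
  phenotypes, cycling through the palette) eight-fold: subtypes are
  distinct but overlapping, as real compositional subtypes are.
* **Clinical covariates** — ER/PR/HER2/grade are drawn conditionally on
  the latent subtype from four fixed profiles (luminal-A-like,
  luminal-B-like, TNBC-like, HER2-like), so molecular-subtype
  cross-tabulations are non-degenerate.
* **Survival** — exponential death times with rate `baseline_hazard ·
  exp(lp)` (default baseline 0.01/month), where the linear predictor
  applies `effect_vector` to the patient's *actual computed* feature
  values, z-scored across the cohort so coefficients are per standard
  deviation.  Censoring is uniform on (0, `censoring_window`] (default
  240 months), independent of survival, so the partial likelihood
  remains correctly specified.  With the defaults this yields roughly
  half observed events.  The exponential baseline is the simplest
  proportional-hazards generator; only the rank structure of survival
  matters for concordance and log-rank recovery.

Identical configs (including the seed) regenerate byte-identical
cohorts; all randomness flows from one `numpy` generator.

**What the generator does not emulate:** marker-intensity noise,
segmentation errors, irregular tissue boundaries, spatially varying cell
density gradients, non-proportional hazards, or informative censoring.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and statistically calibrated under its stated
assumptions — not that any particular biological finding transfers to
real cohorts.

## Problem sizes used in tests

The recovery experiments run at sizes chosen to make their statistical
assertions stable: planted-effect enrichment pools 10 seeded cohorts of
150 patients; rank recovery uses 10 cohorts of 80 patients with 4
latent subtypes searched over ranks 3–8; the held-out concordance check
uses one 300-patient cohort with strong (±1.0–1.5 SD) planted effects;
null calibration averages 5 splits of a 200-patient effect-free cohort
and 200 replicates of the all-null differential-marker simulation.

## Known limitations

* Communities are connected components; a long chain of touching cells
  is one community even if biologically heterogeneous.
* The Cox networks are deliberately small (one hidden layer, full-batch
  optimization); they are not meant for cohorts of tens of thousands.
* Importance is attribution through a single trained network and is
  noisy run-to-run; conclusions should be drawn from repeated seeded
  fits, as the tests do.
* The NMF rank criteria saturate on perfectly crisp data (see the
  tie-break note above); rank selection is most informative when the
  consensus is imperfect.
* The built-in matcher is linear (correlation on z-scored features);
  nonlinear cross-cohort structure requires plugging in an external
  aligner.
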