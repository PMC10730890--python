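"""Cross-cohort patient matching and subpopulation validation.

A source cohort's single-cell marker intensities are averaged per patient
into pseudo-bulk profiles, harmonized with an external expression matrix
through a protein→gene name map, and matched to external patients by
correlation distance on z-scored shared features.  A similarity cutoff
(default 99.5%) retains the smallest fraction of cross-cohort distances.
Matched external patients are compared against the remainder by log-rank
test, and differential markers between groups are found with rank-sum
tests under Benjamini-Hochberg correction.

The distance computation is pluggable: any callable mapping two
(patients × features) arrays to a distance matrix can replace the
built-in correlation matcher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .survival import SurvivalOutcome

__all__ = [
    "MatchResult",
    "pseudo_bulk",
    "harmonize_markers",
    "correlation_distance",
    "match_patients",
    "compare_matched_survival",
    "differential_markers",
]


@dataclass
class MatchResult:
    """Retained cross-cohort patient pairs and the cutoff that produced them."""

    pairs: pd.DataFrame  # columns: source, target, distance
    cutoff: float
    threshold_distance: float | None

    @property
    def matched_targets(self) -> list[str]:
        return sorted(set(self.pairs["target"]))

    @property
    def matched_sources(self) -> list[str]:
        return sorted(set(self.pairs["source"]))


def pseudo_bulk(cell_expression: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean marker expression from a cell-level table.

    Expects a ``patient_id`` column (and optionally ``cell_id``); all
    remaining columns are treated as markers.  Patients contributing zero
    cells are absent from the result by construction.
    """
    if "patient_id" not in cell_expression.columns:
        raise ValueError("cell expression table must have a patient_id column")
    markers = [
        c for c in cell_expression.columns if c not in ("cell_id", "patient_id")
    ]
    if not markers:
        raise ValueError("no marker columns in cell expression table")
    values = cell_expression[["patient_id", *markers]]
    if values[markers].isna().any().any():
        raise ValueError("missing marker values in cell expression table")
    out = values.groupby("patient_id", sort=False)[markers].mean()
    out.index.name = "patient_id"
    return out


def harmonize_markers(
    internal_markers: Sequence[str],
    external_genes: Sequence[str],
    marker_map: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Shared feature list under a protein→gene name map.

    ``marker_map`` has columns ``protein, gene``; without it, names are
    matched directly.  Matching is case-insensitive.  Returns the retained
    internal marker names and the internal markers that found no external
    counterpart.
    """
    ext = {str(g).lower() for g in external_genes}
    if marker_map is not None:
        gene_of = {
            str(p).lower(): str(g).lower()
            for p, g in zip(marker_map["protein"], marker_map["gene"])
        }
    else:
        gene_of = {}
    shared, dropped = [], []
    for m in internal_markers:
        gene = gene_of.get(str(m).lower(), str(m).lower())
        (shared if gene in ext else dropped).append(m)
    if not shared:
        raise ValueError("no shared features between cohorts")
    return shared, dropped


def _zscore(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def correlation_distance(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance (1 − Pearson r) between cohort rows."""
    return cdist(source, target, metric="correlation")


def match_patients(
    source: pd.DataFrame,
    target: pd.DataFrame,
    cutoff: float = 0.995,
    matcher: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    mode: str = "global",
) -> MatchResult:
    """Match source patients to external patients at a similarity cutoff.

    Both matrices must share columns; each feature is z-scored within its
    cohort before the distance computation.  With ``mode="global"`` the
    retained pairs are those whose distance is at most the k-th smallest
    of all cross-cohort distances, ``k = floor((1 - cutoff) * n_pairs)``
    (ties at the boundary are kept); ``mode="per_source"`` applies the
    same rule within each source patient's row.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    shared = [c for c in source.columns if c in set(target.columns)]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared features, got {len(shared)}")
    S = _zscore(source[shared].to_numpy(dtype=float))
    T = _zscore(target[shared].to_numpy(dtype=float))
    matcher = matcher or correlation_distance
    D = np.asarray(matcher(S, T), dtype=float)
    if D.shape != (len(source), len(target)):
        raise ValueError("matcher returned a distance matrix of the wrong shape")

    src_ids = [str(i) for i in source.index]
    tgt_ids = [str(i) for i in target.index]
    rows = []
    threshold = None
    eps = 1e-12  # tolerate float noise in tied distances at the boundary
    if mode == "global":
        flat = np.sort(D.ravel())
        k = int(np.floor((1 - cutoff) * flat.size))
        if k > 0:
            threshold = float(flat[k - 1])
            keep = np.argwhere(D <= threshold + eps)
            rows = [
                (src_ids[i], tgt_ids[j], float(D[i, j])) for i, j in keep
            ]
    elif mode == "per_source":
        thresholds = []
        for i in range(D.shape[0]):
            row = np.sort(D[i])
            k = int(np.floor((1 - cutoff) * row.size))
            if k > 0:
                thr = float(row[k - 1])
                thresholds.append(thr)
                for j in np.flatnonzero(D[i] <= thr + eps):
                    rows.append((src_ids[i], tgt_ids[j], float(D[i, j])))
        threshold = max(thresholds) if thresholds else None
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    pairs = pd.DataFrame(rows, columns=["source", "target", "distance"])
    return MatchResult(pairs=pairs, cutoff=cutoff, threshold_distance=threshold)


def compare_matched_survival(
    matches: MatchResult | Sequence[str],
    external_outcome: SurvivalOutcome,
    stratum: Sequence[str] | None = None,
):
    """Log-rank comparison of matched vs unmatched external patients.

    ``stratum`` optionally restricts the comparison to a subset of
    external patients (e.g. one molecular subtype); the matched and
    unmatched arms partition that stratum.  Returns ``(result_row,
    curves)`` where ``result_row`` holds the arm sizes, statistic and p
    (NaN with ``computable=False`` when an arm is empty).
    """
    matched_ids = (
        set(matches.matched_targets)
        if isinstance(matches, MatchResult)
        else set(map(str, matches))
    )
    ids = [str(p) for p in external_outcome.patient_ids]
    in_stratum = (
        np.isin(ids, [str(s) for s in stratum])
        if stratum is not None
        else np.ones(len(ids), dtype=bool)
    )
    matched = np.isin(ids, list(matched_ids)) & in_stratum
    unmatched = ~np.isin(ids, list(matched_ids)) & in_stratum
    curves = {}
    if matched.sum() == 0 or unmatched.sum() == 0:
        row = {"n_matched": int(matched.sum()), "n_unmatched": int(unmatched.sum()),
               "statistic": np.nan, "p": np.nan, "computable": False}
        return row, curves
    t, e = external_outcome.time, external_outcome.event
    for name, mask in (("matched", matched), ("unmatched", unmatched)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        curves[name] = kmf.survival_function_
    res = logrank_test(t[matched], t[unmatched], e[matched], e[unmatched])
    row = {"n_matched": int(matched.sum()), "n_unmatched": int(unmatched.sum()),
           "statistic": float(res.test_statistic), "p": float(res.p_value),
           "computable": True}
    return row, curves


def differential_markers(
    group_a: Sequence[str],
    group_b: Sequence[str],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Rank-sum differential markers between two patient groups.

    Per marker: two-sided Mann-Whitney test of group A vs group B,
    Benjamini-Hochberg adjustment across markers, and the sign of the
    median difference (positive = higher in A).  Constant markers are
    skipped.  Both groups need at least 3 patients.
    """
    group_a = [str(g) for g in group_a]
    group_b = [str(g) for g in group_b]
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 patients")
    expr = expression.copy()
    expr.index = expr.index.map(str)
    A = expr.loc[group_a]
    B = expr.loc[group_b]
    rows = []
    for marker in expression.columns:
        a, b = A[marker].to_numpy(dtype=float), B[marker].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"marker {marker!r} constant; skipped", stacklevel=2)
            continue
        _, p = mannwhitneyu(a, b, alternative="two-sided")
        diff = float(np.median(a) - np.median(b))
        rows.append(
            {"marker": marker, "direction": int(np.sign(diff)), "p": float(p)}
        )
    table = pd.DataFrame(rows, columns=["marker", "direction", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
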