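"""Feature-importance ranking for the two-stage Cox network.

Hidden-node importance is the drop in the stage-2 partial log-likelihood
when one stage-2 input column is replaced by its cohort mean
(mean-masking, no refitting); a permutation variant is available.  The
34 hidden scores are split by originating stage-1 network and propagated
back to the original features through each network's input weights,
``O = W' H``.  Per-set scores are then min-max normalized on absolute
value and thresholded (densities at 0.5, interaction sets at 0.75) to
select the top survival features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalOutcome, TwoStageModel, cox_partial_loglik

__all__ = [
    "ImportanceVector",
    "hidden_importance",
    "propagate_importance",
    "split_and_propagate",
    "normalize_and_select",
]

DEFAULT_THRESHOLDS = {"CP": 0.5, "TMI": 0.75, "TCI": 0.75}


@dataclass
class ImportanceVector:
    """Raw and min-max-normalized importance scores for one feature set."""

    feature_set: str
    feature_names: list[str]
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if len(self.feature_names) != len(self.raw) or len(self.raw) != len(
            self.normalized
        ):
            raise ValueError("importance vector fields must align")


def hidden_importance(
    two_stage: TwoStageModel,
    X_by_set: dict,
    y: SurvivalOutcome,
    method: str = "mask",
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Importance of each stage-2 input node.

    ``method="mask"`` (default) scores node j as the stage-2 partial
    log-likelihood drop when column j is replaced by its cohort mean.
    ``method="permute"`` averages the drop over random within-column
    permutations instead.
    """
    H = two_stage.stage2_inputs(X_by_set)
    base = cox_partial_loglik(two_stage.stage2.predict_pi(H), y)
    scores = np.empty(H.shape[1])
    rng = np.random.default_rng(seed)
    for j in range(H.shape[1]):
        if method == "mask":
            Hm = H.copy()
            Hm[:, j] = H[:, j].mean()
            scores[j] = base - cox_partial_loglik(two_stage.stage2.predict_pi(Hm), y)
        elif method == "permute":
            drops = []
            for _ in range(n_permutations):
                Hm = H.copy()
                Hm[:, j] = rng.permutation(H[:, j])
                drops.append(
                    base - cox_partial_loglik(two_stage.stage2.predict_pi(Hm), y)
                )
            scores[j] = float(np.mean(drops))
        else:
            raise ValueError(f"unknown importance method {method!r}")
    return scores


def propagate_importance(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Back-propagate hidden-node importance to input features: ``O = W' H``."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.ndim != 2 or H.shape != (W.shape[0],):
        raise ValueError(
            f"shape mismatch: W is {W.shape}, H is {H.shape}; need H of length h"
        )
    return W.T @ H


def split_and_propagate(
    two_stage: TwoStageModel, hidden_scores: np.ndarray
) -> dict[str, ImportanceVector]:
    """Partition hidden scores by stage-1 network and propagate each block.

    The concatenation order of the stage-2 inputs (CP, TMI, TCI by
    default) determines the partition; each block is propagated through
    its own network's input weights and normalized within its set.
    """
    hidden_scores = np.asarray(hidden_scores, dtype=float)
    widths = two_stage.stage1_widths
    if hidden_scores.shape != (sum(widths),):
        raise ValueError(
            f"expected {sum(widths)} hidden scores "
            f"(stage-1 widths {widths}), got {hidden_scores.shape}"
        )
    out: dict[str, ImportanceVector] = {}
    offset = 0
    for set_name, width in zip(two_stage.set_order, widths):
        model = two_stage.stage1[set_name]
        block = hidden_scores[offset : offset + width]
        raw = propagate_importance(model.W, block)
        out[set_name] = ImportanceVector(
            feature_set=set_name,
            feature_names=list(model.feature_names)
            or [f"{set_name}_{i}" for i in range(len(raw))],
            raw=raw,
            normalized=_minmax_abs(raw),
        )
        offset += width
    return out


def _minmax_abs(raw: np.ndarray) -> np.ndarray:
    a = np.abs(np.asarray(raw, dtype=float))
    span = a.max() - a.min()
    if span == 0:
        warnings.warn("constant importance vector; normalized scores set to 0",
                      stacklevel=3)
        return np.zeros_like(a)
    return (a - a.min()) / span


def normalize_and_select(
    vectors: dict[str, ImportanceVector],
    thresholds: dict[str, float] | None = None,
    cap: int | None = 50,
) -> pd.DataFrame:
    """Threshold normalized importances and return the selected-feature table.

    Scores are min-max normalized (on absolute value) within each set;
    a feature is selected when its normalized score strictly exceeds the
    set's threshold.  When the union exceeds ``cap`` features, the
    highest-scoring ones are kept.  Returns columns
    ``feature, set, raw, normalized, selected``.
    """
    if not vectors:
        raise ValueError("no importance vectors provided")
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    frames = []
    for set_name, iv in vectors.items():
        thr = thresholds.get(set_name, 0.75)
        frames.append(
            pd.DataFrame(
                {
                    "feature": iv.feature_names,
                    "set": set_name,
                    "raw": iv.raw,
                    "normalized": _minmax_abs(iv.raw),
                    "selected": _minmax_abs(iv.raw) > thr,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if cap is not None and int(table["selected"].sum()) > cap:
        chosen = (
            table[table["selected"]]
            .sort_values("normalized", ascending=False)
            .head(cap)
            .index
        )
        table["selected"] = False
        table.loc[chosen, "selected"] = True
    return table
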