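"""Neural and classical Cox proportional-hazards survival models.

The core model is a one-hidden-layer Cox network: a prognostic index
``pi = beta' tanh(W x + b)`` fitted by maximizing the Breslow-tie Cox
partial log-likelihood with an L2 penalty on all parameters.  The hidden
width follows the square-root sizing rule ``h = ceil(sqrt(p))``.  A
two-stage composite trains one network per feature set (CP, TMI, TCI),
freezes them, concatenates their hidden activations, and trains a second
network on the concatenation.

A linear Cox model on clinical covariates serves as the baseline, and
repeated train/test splits compare models by Harrell's concordance index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy.optimize import minimize

__all__ = [
    "SurvivalOutcome",
    "CoxNet",
    "TwoStageModel",
    "hidden_size",
    "cox_partial_loglik",
    "fit_onestage",
    "hidden_outputs",
    "fit_twostage",
    "predict_pi",
    "c_index",
    "fit_cox_baseline",
    "evaluate_models",
]


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcomes aligned to patient ids."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match patient ids")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx: Sequence[int]) -> "SurvivalOutcome":
        idx = np.asarray(idx)
        return SurvivalOutcome(
            [self.patient_ids[i] for i in idx], self.time[idx], self.event[idx]
        )

    def reindex(self, patient_ids: Sequence[str]) -> "SurvivalOutcome":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        try:
            idx = [pos[p] for p in patient_ids]
        except KeyError as exc:
            raise KeyError(f"patient {exc.args[0]!r} missing from outcome") from exc
        return self.subset(idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "os_months": self.time, "event": self.event}
        )


def hidden_size(p: int) -> int:
    """Hidden-layer width: the square root of the input count, rounded up."""
    if p < 1:
        raise ValueError("feature count must be at least 1")
    return math.ceil(math.sqrt(p))


def _risk_set_terms(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Sorted-by-descending-time views plus tie-group bookkeeping."""
    order = np.argsort(-time, kind="stable")
    t_s, e_s, eta_s = time[order], event[order], eta[order]
    _, inv, counts = np.unique(-t_s, return_inverse=True, return_counts=True)
    last = np.cumsum(counts) - 1  # last index of each tied-time group
    first = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return order, t_s, e_s, eta_s, inv, first, last


def cox_partial_loglik(pi: np.ndarray, y: SurvivalOutcome) -> float:
    """Breslow-tie Cox partial log-likelihood of risk scores ``pi``.

    Invariant to adding a constant to all scores; requires at least one
    observed event.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(y),):
        raise ValueError("risk scores must align with the outcome")
    if not np.isfinite(pi).all():
        raise ValueError("non-finite risk scores")
    if y.event.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    eta = pi - pi.max()  # shift invariance, numerical guard
    _, _, e_s, eta_s, inv, _, last = _risk_set_terms(y.time, y.event, eta)
    lse = np.logaddexp.accumulate(eta_s)
    ev = e_s == 1
    return float(eta_s[ev].sum() - lse[last[inv]][ev].sum())


def _pll_and_grad_eta(eta: np.ndarray, y: SurvivalOutcome):
    """Partial log-likelihood and its gradient with respect to the scores."""
    shift = eta.max()
    order, _, e_s, eta_s, inv, first, last = _risk_set_terms(
        y.time, y.event, eta - shift
    )
    lse = np.logaddexp.accumulate(eta_s)
    risk_lse = lse[last[inv]]
    ev = e_s == 1
    ll = float(eta_s[ev].sum() - risk_lse[ev].sum())
    # d ll / d eta_j = e_j - exp(eta_j) * sum over events with t_i <= t_j of 1/S_i
    w = np.where(ev, np.exp(-risk_lse), 0.0)
    suffix = np.cumsum(w[::-1])[::-1]
    grad_s = e_s - np.exp(eta_s) * suffix[first[inv]]
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return ll, grad


@dataclass
class CoxNet:
    """One-hidden-layer Cox network with tanh activation.

    ``W`` is h×p, ``b`` length h, ``beta`` length h.  Prognostic index of a
    standardized input row x is ``beta' tanh(W x + b)``; higher values mean
    higher hazard.  ``mu``/``sigma`` record the training-column statistics
    applied before the forward pass (identity when fitted with
    ``standardize=False``).
    """

    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    l2_lambda: float
    feature_names: list[str] = field(default_factory=list)
    activation: str = "tanh"

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_features(self) -> int:
        return self.W.shape[1]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sigma

    def hidden(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        return np.tanh(self._standardize(X) @ self.W.T + self.b)

    def predict_pi(self, X) -> np.ndarray:
        return self.hidden(X) @ self.beta


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing[:5]}")
            X = X[feature_names]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _unpack(theta: np.ndarray, h: int, p: int):
    W = theta[: h * p].reshape(h, p)
    b = theta[h * p : h * p + h]
    beta = theta[h * p + h :]
    return W, b, beta


def _objective(theta, X, y, l2, h, p):
    W, b, beta = _unpack(theta, h, p)
    Z = X @ W.T + b
    Hm = np.tanh(Z)
    eta = Hm @ beta
    ll, g_eta = _pll_and_grad_eta(eta, y)
    n_ev = max(int(y.event.sum()), 1)
    # negative mean (per event) penalized log-likelihood
    obj = -ll / n_ev + l2 * (np.sum(W**2) + np.sum(b**2) + np.sum(beta**2))
    g_eta = -g_eta / n_ev
    g_beta = Hm.T @ g_eta + 2 * l2 * beta
    g_hidden = np.outer(g_eta, beta) * (1 - Hm**2)  # n×h
    g_W = g_hidden.T @ X + 2 * l2 * W
    g_b = g_hidden.sum(axis=0) + 2 * l2 * b
    grad = np.concatenate([g_W.ravel(), g_b, g_beta])
    return obj, grad


_L2_GRID = (1e-3, 1e-2, 1e-1, 1.0)


def fit_onestage(
    X,
    y: SurvivalOutcome,
    l2_lambda: float | str = "auto",
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    standardize: bool = True,
    n_hidden: int | None = None,
) -> CoxNet:
    """Fit a one-hidden-layer Cox network by penalized partial likelihood.

    Columns are z-scored with training statistics (constant columns get
    unit scale).  Parameters are initialized small-uniform from ``seed``
    and optimized with L-BFGS-B using analytic gradients.  With
    ``l2_lambda="auto"`` the penalty is chosen on an inner 75/25
    validation split over the grid 1e-3…1 by validation partial
    likelihood.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    Xm = _as_matrix(X, feature_names)
    n, p = Xm.shape
    if n != len(y):
        raise ValueError("feature rows must align with the outcome")
    if n < 10 or y.event.sum() < 3:
        raise ValueError("need at least 10 patients and 3 events to fit")
    if standardize:
        mu = Xm.mean(axis=0)
        sigma = Xm.std(axis=0)
        sigma[sigma == 0] = 1.0
    else:
        mu = np.zeros(p)
        sigma = np.ones(p)
    Xs = (Xm - mu) / sigma

    if l2_lambda == "auto":
        l2_lambda = _select_l2(Xs, y, seed, max_iter, tol, n_hidden)
    l2 = float(l2_lambda)
    if l2 < 0:
        raise ValueError("l2_lambda must be non-negative")

    h = n_hidden if n_hidden is not None else hidden_size(p)
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(p)
    theta0 = rng.uniform(-scale, scale, size=h * p + h + h)
    res = minimize(
        _objective,
        theta0,
        args=(Xs, y, l2, h, p),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun) or not np.isfinite(res.x).all():
        raise RuntimeError(
            f"Cox network training diverged (objective={res.fun!r}, "
            f"status={res.status}, message={res.message!r})"
        )
    W, b, beta = _unpack(res.x, h, p)
    return CoxNet(
        W=W, b=b, beta=beta, mu=mu, sigma=sigma, l2_lambda=l2,
        feature_names=feature_names,
    )


def _select_l2(Xs, y, seed, max_iter, tol, n_hidden) -> float:
    """Inner-split selection of the L2 penalty by validation partial likelihood."""
    n = Xs.shape[0]
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(n)
    n_val = max(n // 4, 3)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    y_tr, y_val = y.subset(tr_idx), y.subset(val_idx)
    if y_tr.event.sum() < 3 or y_val.event.sum() < 1:
        return 1e-2
    best, best_ll = 1e-2, -np.inf
    for l2 in _L2_GRID:
        try:
            model = fit_onestage(
                Xs[tr_idx], y_tr, l2_lambda=l2, seed=seed,
                max_iter=max_iter, tol=tol, standardize=False,
                n_hidden=n_hidden,
            )
            ll = cox_partial_loglik(model.predict_pi(Xs[val_idx]), y_val)
        except (RuntimeError, ValueError):
            continue
        if ll > best_ll:
            best, best_ll = l2, ll
    return best


def hidden_outputs(model: CoxNet, X) -> np.ndarray:
    """Hidden-layer activations ``tanh(W x + b)`` for each row of X."""
    H = model.hidden(X)
    if not np.isfinite(H).all():
        raise ValueError("non-finite hidden activations")
    return H


@dataclass
class TwoStageModel:
    """Composite survival model: per-set Cox networks feeding a second stage.

    Stage-1 networks (one per feature set, in ``set_order``) are trained
    independently and frozen; their hidden activations are concatenated and
    a stage-2 network is trained on the concatenation.
    """

    stage1: dict[str, CoxNet]
    stage2: CoxNet
    set_order: tuple[str, ...]

    @property
    def stage1_widths(self) -> tuple[int, ...]:
        return tuple(self.stage1[s].n_hidden for s in self.set_order)

    def stage2_inputs(self, X_by_set: dict[str, "pd.DataFrame | np.ndarray"]) -> np.ndarray:
        blocks = [hidden_outputs(self.stage1[s], X_by_set[s]) for s in self.set_order]
        return np.hstack(blocks)

    def predict_pi(self, X_by_set: dict) -> np.ndarray:
        return self.stage2.predict_pi(self.stage2_inputs(X_by_set))


def fit_twostage(
    X_cp,
    X_tmi,
    X_tci,
    y: SurvivalOutcome,
    l2_lambda: float | str = "auto",
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    restandardize_hidden: bool = False,
) -> TwoStageModel:
    """Train the two-stage composite on CP, TMI and TCI feature blocks.

    The three stage-1 networks are fitted independently, frozen, and their
    hidden activations concatenated as stage-2 inputs.  By default the raw
    activations are used; ``restandardize_hidden=True`` z-scores them
    before the stage-2 fit.
    """
    blocks = {"CP": X_cp, "TMI": X_tmi, "TCI": X_tci}
    n_rows = {k: len(v) for k, v in blocks.items()}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"patient misalignment across feature blocks: {n_rows}")
    for k, v in blocks.items():
        if isinstance(v, pd.DataFrame):
            for other_k, other in blocks.items():
                if isinstance(other, pd.DataFrame) and list(v.index) != list(other.index):
                    raise ValueError(
                        f"patient ids of {k} and {other_k} blocks disagree"
                    )
            break
    stage1 = {}
    for i, (name, X) in enumerate(blocks.items()):
        stage1[name] = fit_onestage(
            X, y, l2_lambda=l2_lambda, seed=seed + i,
            max_iter=max_iter, tol=tol,
        )
    H = np.hstack([hidden_outputs(stage1[s], blocks[s]) for s in blocks])
    stage2 = fit_onestage(
        H, y, l2_lambda=l2_lambda, seed=seed + 10,
        max_iter=max_iter, tol=tol, standardize=restandardize_hidden,
    )
    return TwoStageModel(stage1=stage1, stage2=stage2, set_order=tuple(blocks))


def predict_pi(model, X) -> np.ndarray:
    """Prognostic index (log relative hazard) for new data.

    Accepts a :class:`CoxNet` with a feature matrix or a
    :class:`TwoStageModel` with a dict of per-set matrices.
    """
    if isinstance(model, TwoStageModel):
        return model.predict_pi(X)
    return model.predict_pi(X)


def c_index(pi: np.ndarray, y: SurvivalOutcome) -> float:
    """Harrell's concordance index of risk scores against the outcome.

    Higher scores are treated as higher risk (shorter survival); ties in
    score count one half.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(y),):
        raise ValueError("risk scores must align with the outcome")
    try:
        return float(concordance_index(y.time, -pi, y.event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs in the outcome") from exc


@dataclass
class CoxBaseline:
    """Linear Cox proportional-hazards model on clinical covariates."""

    fitter: CoxPHFitter
    covariates: list[str]

    def predict_pi(self, clinical: pd.DataFrame) -> np.ndarray:
        lp = self.fitter.predict_log_partial_hazard(clinical[self.covariates])
        return lp.to_numpy(dtype=float)

    @property
    def coefficients(self) -> pd.Series:
        return self.fitter.params_


def fit_cox_baseline(
    clinical: pd.DataFrame,
    y: SurvivalOutcome,
    covariates: Sequence[str] = ("er", "pr", "her2", "grade"),
    penalizer: float = 0.01,
) -> CoxBaseline:
    """Fit the clinical-covariate Cox-PH baseline (lifelines backend)."""
    covariates = [c for c in covariates if c in clinical.columns]
    if not covariates:
        raise ValueError("no clinical covariates found")
    df = clinical[covariates].astype(float).copy()
    df["_time"] = y.time
    df["_event"] = y.event
    fitter = CoxPHFitter(penalizer=penalizer)
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # convergence/separation
        raise RuntimeError(f"clinical Cox baseline failed to converge: {exc}") from exc
    return CoxBaseline(fitter=fitter, covariates=list(covariates))


def _split_event_stratified(n, event, test_size, rng):
    """Indices of a train/test split stratified by the event indicator."""
    test = []
    for value in (0, 1):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        k = int(round(test_size * len(idx)))
        test.extend(idx[:k])
    test = np.sort(np.asarray(test, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def evaluate_models(
    features,
    clinical: pd.DataFrame,
    y: SurvivalOutcome,
    models: Sequence[str] = ("coxph", "cp", "tmi", "tci", "two-stage"),
    n_repeats: int = 20,
    test_size: float = 0.2,
    seed: int = 0,
    l2_lambda: float | str = 1e-2,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Compare survival models over repeated stratified train/test splits.

    Each repeat draws an 80/20 split stratified by the event indicator,
    fits every requested model on the training patients and scores
    Harrell's C on the held-out patients.  Returns a tidy table with
    columns ``model, repeat, c_index``.
    """
    from .features import FeatureMatrix  # local import to avoid cycle

    if not isinstance(features, FeatureMatrix):
        raise TypeError("features must be a FeatureMatrix")
    clinical = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    clinical = clinical.loc[features.patient_ids]
    y = y.reindex(features.patient_ids)
    n = len(y)
    rng = np.random.default_rng(seed)
    blocks = {s: features.subset(s) for s in ("CP", "TMI", "TCI")}
    records = []
    for rep in range(n_repeats):
        for _attempt in range(20):
            train, test = _split_event_stratified(n, y.event, test_size, rng)
            if y.event[train].sum() >= 3 and y.event[test].sum() >= 1:
                break
            warnings.warn("too few events in split; resampling", stacklevel=2)
        y_tr, y_te = y.subset(train), y.subset(test)
        fit_seed = seed + 1000 * rep
        for name in models:
            try:
                if name == "coxph":
                    mdl = fit_cox_baseline(clinical.iloc[train], y_tr)
                    pi = mdl.predict_pi(clinical.iloc[test])
                elif name in ("cp", "tmi", "tci"):
                    X = blocks[name.upper()]
                    mdl = fit_onestage(
                        X.iloc[train], y_tr, l2_lambda=l2_lambda,
                        seed=fit_seed, max_iter=max_iter,
                    )
                    pi = mdl.predict_pi(X.iloc[test])
                elif name == "two-stage":
                    mdl = fit_twostage(
                        blocks["CP"].iloc[train], blocks["TMI"].iloc[train],
                        blocks["TCI"].iloc[train], y_tr,
                        l2_lambda=l2_lambda, seed=fit_seed, max_iter=max_iter,
                    )
                    pi = mdl.predict_pi(
                        {s: blocks[s].iloc[test] for s in ("CP", "TMI", "TCI")}
                    )
                else:
                    raise ValueError(f"unknown model {name!r}")
                ci = c_index(pi, y_te)
            except (RuntimeError, ValueError) as exc:
                warnings.warn(f"model {name!r} failed on repeat {rep}: {exc}",
                              stacklevel=2)
                ci = np.nan
            records.append({"model": name, "repeat": rep, "c_index": ci})
    return pd.DataFrame(records)
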