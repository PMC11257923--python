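"""Penalized logistic modelling primitives shared by all strategies.

``fit_lasso_logistic`` minimizes mean negative log-likelihood plus an L1
penalty lambda * sum(|beta_j|) with an unpenalized intercept; continuous
predictors are standardized internally before penalization and the
coefficients are reported back on the original scale (the L1 penalty is
scale-sensitive, so standardization is part of the estimator, not a caller
responsibility).

Logistic recalibration follows the two-parameter construction: the observed
outcome is regressed on the logit of the predicted probability (the linear
predictor), giving an intercept shift ``a`` and slope multiplier ``b``; a
well-calibrated model has (a, b) = (0, 1).  A raw-probability covariate scale
is available via ``scale="probability"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics

__all__ = [
    "FitFailure",
    "FittedModel",
    "RecalibrationFunction",
    "fit_lasso_logistic",
    "select_lambda",
    "predict_proba",
    "fit_recalibration",
]

_SEPARATION_COEF = 30.0  # |standardized coefficient| beyond which we declare separation


class FitFailure(RuntimeError):
    """Model fitting failed (single outcome class or data separation).

    Mirrors the situation where a hospital-local model cannot be derived for
    lack of events; callers record the failure and continue.
    """


@dataclass
class RecalibrationFunction:
    """Post-hoc logistic adjustment p -> expit(a + b * logit(p)).

    mode ``"local"`` carries one (a, b) pair per hospital in ``per_center``;
    ``"central"`` and ``"federated"`` use the single global pair.
    """

    a: float
    b: float
    mode: str = "central"
    per_center: dict[str, tuple[float, float]] | None = None
    scale: str = "logit"

    def __post_init__(self) -> None:
        if not np.isfinite(self.b):
            raise ValueError("recalibration slope must be finite")
        if self.mode == "local" and not self.per_center:
            raise ValueError("local recalibration requires per-center (a, b) pairs")

    def apply_to_lp(self, lp: np.ndarray, hospital_ids=None) -> np.ndarray:
        cov = expit(lp) if self.scale == "probability" else lp
        if self.mode == "local":
            if hospital_ids is None:
                raise ValueError("local recalibration needs hospital ids")
            a = np.array([self.per_center[h][0] for h in hospital_ids])
            b = np.array([self.per_center[h][1] for h in hospital_ids])
            return expit(a + b * cov)
        return expit(self.a + self.b * cov)

    def to_json(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "mode": self.mode,
            "per_center": self.per_center,
        }


@dataclass
class FittedModel:
    """Sparse logistic model: unpenalized intercept plus coefficients over the
    selected variables, with provenance and an optional recalibration."""

    intercept: float
    coefficients: dict[str, float]
    selected_variables: list[str]
    lam: float | None = None
    training_meta: dict = field(default_factory=dict)
    recalibration: RecalibrationFunction | None = None

    def __post_init__(self) -> None:
        if not set(self.coefficients) <= set(self.selected_variables):
            raise ValueError("coefficient keys must be a subset of selected variables")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        for v in self.selected_variables:
            if v not in X.columns:
                raise KeyError(f"predictor {v!r} required by the model is missing")
        lp = np.full(len(X), self.intercept, dtype=float)
        for v in self.selected_variables:
            lp += self.coefficients.get(v, 0.0) * X[v].to_numpy(dtype=float)
        return lp

    def to_json(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "selected_variables": self.selected_variables,
            "lambda": self.lam,
            "training_meta": self.training_meta,
            "recalibration": self.recalibration.to_json() if self.recalibration else None,
        }

    @classmethod
    def from_json(cls, d: dict) -> "FittedModel":
        rc = d.get("recalibration")
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            selected_variables=list(d["selected_variables"]),
            lam=d.get("lambda"),
            training_meta=d.get("training_meta", {}),
            recalibration=RecalibrationFunction(
                rc["a"], rc["b"], rc["mode"],
                {k: tuple(v) for k, v in rc["per_center"].items()} if rc.get("per_center") else None,
            )
            if rc
            else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_classes(y: np.ndarray, context: str = "") -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitFailure(
            f"outcome has a single class ({int(classes[0])}){context and f' [{context}]'}"
        )


def _standardize(X: np.ndarray, continuous: np.ndarray):
    mean = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    sd = X.std(axis=0)
    usable = continuous & (sd > 0)
    mean[usable] = X[:, usable].mean(axis=0)
    scale[usable] = sd[usable]
    return (X - mean) / scale, mean, scale


def _lasso_cd(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    outer_tol: float = 1e-9,
    max_outer: int = 100,
    divergence_bound: float = 35.0,
) -> tuple[float, np.ndarray]:
    """Penalized IRLS with a weighted-LASSO inner solve (glmnet-style).

    Minimizes (1/n) NLL + lam * ||beta||_1 with an unpenalized intercept.
    Each outer step forms the weighted least-squares surrogate at the current
    parameters and solves it exactly with cyclic coordinate descent
    (scikit-learn's ``Lasso``, which is deterministic).  The surrogate
    objective (1/(2n)) sum_i w_i (z_i - b0 - x_i beta)^2 + lam ||beta||_1
    matches ``Lasso(alpha=lam * n / sum(w))`` under sklearn's sample-weight
    normalization.

    If any coefficient grows past ``divergence_bound`` the iteration stops
    early: the path is diverging towards (quasi-)separation and the caller's
    separation guard will reject the fit anyway.
    """
    from sklearn.linear_model import Lasso

    n, p = X.shape
    b0 = float(logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    beta = np.zeros(p)
    lp = np.full(n, b0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max_outer):
            mu = expit(lp)
            w = np.clip(mu * (1.0 - mu), 1e-5, None)
            z = lp + (y - mu) / w
            alpha = lam * n / float(w.sum())
            if alpha > 0:
                inner = Lasso(alpha=alpha, fit_intercept=True, tol=1e-12, max_iter=100_000)
                inner.fit(X, z, sample_weight=w)
                b0_new, beta_new = float(inner.intercept_), np.asarray(inner.coef_, float)
            else:  # lam == 0: plain weighted least squares on the surrogate
                Xa = np.column_stack([np.ones(n), X]) * np.sqrt(w)[:, None]
                sol = np.linalg.lstsq(Xa, z * np.sqrt(w), rcond=None)[0]
                b0_new, beta_new = float(sol[0]), sol[1:]
            delta = abs(b0_new - b0) + float(np.abs(beta_new - beta).sum())
            b0, beta = b0_new, beta_new
            lp = b0 + X @ beta
            if delta < outer_tol:
                break
            if np.max(np.abs(beta), initial=0.0) > divergence_bound:
                break
    return b0, beta


def fit_lasso_logistic(
    X: pd.DataFrame,
    y,
    lam: float,
    standardize: bool = True,
    meta: dict | None = None,
) -> FittedModel:
    """L1-penalized logistic regression.

    Minimizes (1/n) * NLL(beta0, beta) + lam * sum_j |beta_j| with the
    intercept unpenalized.  ``lam = 0`` gives the unpenalized maximum
    likelihood fit.  Variables whose (standardized-scale) coefficient is zero
    are excluded from ``selected_variables``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    if np.isnan(Xa).any():
        raise ValueError("predictor matrix contains missing values; impute first")
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    n = len(y)

    continuous = np.array([X[c].nunique() > 2 for c in names])
    if standardize:
        Xs, mean, scale = _standardize(Xa, continuous)
    else:
        Xs, mean, scale = Xa, np.zeros(len(names)), np.ones(len(names))

    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-8)
        clf.fit(Xs, y)
        coef_std = clf.coef_.ravel()
        b0_std = float(clf.intercept_[0])
    else:
        b0_std, coef_std = _lasso_cd(Xs, y.astype(float), lam)
    if np.max(np.abs(coef_std), initial=0.0) > _SEPARATION_COEF:
        raise FitFailure("apparent data separation (unbounded coefficients)")

    nz = np.abs(coef_std) > 1e-8
    coef = coef_std / scale
    intercept = b0_std - float(np.sum(coef_std[nz] * mean[nz] / scale[nz]))
    selected = [names[j] for j in range(len(names)) if nz[j]]
    coefficients = {names[j]: float(coef[j]) for j in range(len(names)) if nz[j]}
    training_meta = {"n": int(n), "n_events": int(y.sum())}
    training_meta.update(meta or {})
    return FittedModel(
        intercept=float(intercept),
        coefficients=coefficients,
        selected_variables=selected,
        lam=lam,
        training_meta=training_meta,
    )


def select_lambda(
    X: pd.DataFrame, y, grid, k_inner: int = 5, seed: int = 0
) -> float:
    """Pick the penalty maximizing mean inner-CV out-of-fold AUC.

    Ties (within 1e-12) break toward the larger penalty (sparser model).
    Deterministic given ``seed``.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("lambda grid is empty")
    y = np.asarray(y, dtype=int)
    _check_classes(y, "lambda selection")
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    scores = {g: [] for g in grid}
    any_fit = False
    with warnings.catch_warnings():
        # tiny centers can have fewer events than inner folds; the degenerate
        # splits are skipped below
        warnings.simplefilter("ignore", UserWarning)
        splits = list(skf.split(X, y))
    for tr, te in splits:
        ytr, yte = y[tr], y[te]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            continue
        for g in grid:
            try:
                model = fit_lasso_logistic(X.iloc[tr], ytr, g)
                p = predict_proba(model, X.iloc[te])
                scores[g].append(_metrics.auc(p, yte))
                any_fit = True
            except FitFailure:
                scores[g].append(-np.inf)
    if not any_fit:
        raise FitFailure("all inner-CV fits failed during lambda selection")
    means = {g: (np.mean(s) if s else -np.inf) for g, s in scores.items()}
    best = max(means.values())
    return max(g for g, m in means.items() if m >= best - 1e-12)


def predict_proba(
    model: FittedModel, X: pd.DataFrame, hospital_ids=None
) -> np.ndarray:
    """Predicted probabilities; applies the attached recalibration (if any) to
    the linear predictor."""
    lp = model.linear_predictor(X)
    if model.recalibration is not None:
        return model.recalibration.apply_to_lp(lp, hospital_ids)
    return expit(lp)


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------

def _recal_fit(preds: np.ndarray, y: np.ndarray, scale: str) -> tuple[float, float]:
    preds = np.asarray(preds, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.any(preds <= 0) or np.any(preds >= 1):
        raise ValueError("predictions must lie strictly in (0, 1)")
    if np.ptp(preds) < 1e-12:
        raise ValueError("constant predictions: recalibration slope unidentifiable")
    _check_classes(y, "recalibration")
    cov = logit(preds) if scale == "logit" else preds
    res = sm.Logit(y, sm.add_constant(cov)).fit(disp=0, maxiter=200)
    return float(res.params[0]), float(res.params[1])


def fit_recalibration(
    preds,
    y,
    mode: str = "central",
    hospital_ids=None,
    scale: str = "logit",
) -> RecalibrationFunction:
    """Fit the two-parameter logistic recalibration of outcomes on predicted
    risk.

    ``mode="central"`` fits one (a, b) on all records; ``mode="local"`` fits
    one pair per hospital (requires ``hospital_ids``).  The federated variant
    lives in :mod:`fedcpm.federation` since it reuses the FedAvg loop.
    """
    if scale not in ("logit", "probability"):
        raise ValueError("scale must be 'logit' or 'probability'")
    if mode == "central":
        a, b = _recal_fit(np.asarray(preds), np.asarray(y), scale)
        return RecalibrationFunction(a, b, mode="central", scale=scale)
    if mode == "local":
        if hospital_ids is None:
            raise ValueError("local recalibration needs hospital ids")
        hospital_ids = np.asarray(hospital_ids)
        per_center = {}
        for label in np.unique(hospital_ids):
            m = hospital_ids == label
            per_center[str(label)] = _recal_fit(
                np.asarray(preds)[m], np.asarray(y)[m], scale
            )
        a, b = (float(np.mean([v[0] for v in per_center.values()])),
                float(np.mean([v[1] for v in per_center.values()])))
        return RecalibrationFunction(a, b, mode="local", per_center=per_center, scale=scale)
    raise ValueError(f"unknown recalibration mode {mode!r}")
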