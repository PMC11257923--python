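"""Federated model-development strategies.

Two federated schemes are implemented alongside the pooled (central) and
per-hospital (local) baselines:

* **FedAvg** — per-center LASSO selections are merged by center-weighted
  voting with an agreement-strength threshold tau; coefficients over the
  voted variable set are then fitted by iterating {broadcast -> one
  full-batch gradient epoch per center on the unpenalized logistic loss ->
  size-weighted parameter averaging} until convergence.
* **Ensemble** — each center's LASSO model is kept; the prediction is the
  volume-weighted mean of the member predictions.

Both federated strategies default to central recalibration (a single logistic
recalibration fitted on the pooled training predictions and outcomes), with
local and federated recalibration switchable.

Strategy construction takes an optional ``audit`` object (see
:mod:`fedcpm.validation`); every point where record-level data, outcomes,
model parameters, or predictions actually cross a center boundary emits an
event, so the sharing ledger reflects execution rather than intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model_core import (
    FitFailure,
    FittedModel,
    RecalibrationFunction,
    fit_lasso_logistic,
    fit_recalibration,
    predict_proba,
    select_lambda,
)
from .synthetic_cohort import CohortTable

__all__ = [
    "FedAvgConfig",
    "StrategyConfig",
    "EnsembleModel",
    "StrategyModel",
    "vote_select_variables",
    "fedavg_aggregate",
    "fedavg_train",
    "ensemble_predict",
    "build_strategy",
    "fit_recalibration_federated",
]

STRATEGIES = ("central", "local", "fedavg", "ensemble")


@dataclass(frozen=True)
class FedAvgConfig:
    """FedAvg hyperparameters: learning rate eta, epoch budget E, variable
    selection agreement strength tau, and the convergence tolerance on the
    parameter-change norm.  One epoch is ``steps_per_epoch`` full-batch
    gradient steps at every center (eta = 0 is a degenerate no-op allowed for
    testing)."""

    learning_rate: float = 1.0
    max_epochs: int = 500
    agreement_strength: float = 0.5
    convergence_tol: float = 1e-7
    steps_per_epoch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 <= self.agreement_strength <= 1.0:
            raise ValueError("agreement strength must lie in [0, 1]")


@dataclass
class EnsembleModel:
    """Volume-weighted mean ensemble of per-center models."""

    members: dict[str, FittedModel]
    weights: dict[str, float]
    recalibration: RecalibrationFunction | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble requires at least one member")
        if set(self.members) != set(self.weights):
            raise ValueError("members and weights must cover the same centers")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("ensemble weights must be nonnegative")


# ---------------------------------------------------------------------------
# Aggregation primitives
# ---------------------------------------------------------------------------

def _check_weights(weights: dict[str, float]) -> None:
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")


def vote_select_variables(
    selections: dict[str, set | list],
    weights: dict[str, float],
    tau: float,
) -> list[str]:
    """Center-weighted voting: a variable is selected iff the total weight of
    centers that selected it reaches the agreement strength tau (and at least
    one center selected it, so tau = 0 yields the union and tau = 1 the
    intersection)."""
    if not selections:
        raise ValueError("no center selections to vote over")
    _check_weights(weights)
    support: dict[str, float] = {}
    for center in sorted(selections):
        for v in selections[center]:
            support[v] = support.get(v, 0.0) + weights[center]
    return sorted(v for v, s in support.items() if s >= tau - 1e-12 and s > 0)


def fedavg_aggregate(
    models: list[FittedModel], weights: list[float] | np.ndarray
) -> FittedModel:
    """Weighted arithmetic mean of intercepts and coefficients (all members
    must share one variable set)."""
    if not models:
        raise ValueError("nothing to aggregate")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    varset = set(models[0].selected_variables)
    for m in models[1:]:
        if set(m.selected_variables) != varset:
            raise ValueError("member models use different variable sets")
    variables = list(models[0].selected_variables)
    intercept = float(np.sum(w * [m.intercept for m in models]))
    coefficients = {
        v: float(np.sum(w * [m.coefficients.get(v, 0.0) for m in models]))
        for v in variables
    }
    return FittedModel(
        intercept=intercept,
        coefficients=coefficients,
        selected_variables=variables,
        lam=None,
        training_meta={"aggregated_from": len(models)},
    )


# ---------------------------------------------------------------------------
# FedAvg training loop
# ---------------------------------------------------------------------------

def _grad_step(theta, Xc, yc, eta, steps):
    n = len(yc)
    for _ in range(steps):
        p = expit(Xc @ theta)
        theta = theta - eta * (Xc.T @ (p - yc)) / n
    return theta


def fedavg_train(
    center_data: dict[str, tuple[pd.DataFrame, np.ndarray]],
    variables: list[str],
    config: FedAvgConfig,
    audit=None,
) -> FittedModel:
    """Federated averaging over unpenalized logistic loss.

    Centers with a single outcome class are skipped (flagged in provenance)
    and the remaining centers reweighted by size.  Initialization is the
    all-zero coefficient vector with the intercept at the logit of the
    size-weighted event rate.  Iterates broadcast / local epoch / aggregate
    until the parameter-change norm drops below ``convergence_tol`` or
    ``max_epochs`` is reached.
    """
    usable, skipped = {}, {}
    for label in sorted(center_data):
        X, y = center_data[label]
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            skipped[label] = "single outcome class"
            continue
        usable[label] = (np.column_stack([np.ones(len(y)), X[variables].to_numpy(dtype=float)]), y)
    if not usable:
        raise FitFailure("all centers degenerate: FedAvg cannot train")
    sizes = {c: len(usable[c][1]) for c in usable}
    total = sum(sizes.values())
    w = {c: sizes[c] / total for c in usable}

    event_rate = sum(w[c] * usable[c][1].mean() for c in usable)
    event_rate = min(max(event_rate, 1e-12), 1 - 1e-12)
    theta = np.zeros(len(variables) + 1)
    theta[0] = logit(event_rate)

    if audit is not None:
        for c in usable:
            audit.share("model_parameters", source=c, context="fedavg")

    epochs_run = 0
    delta = np.inf
    for _ in range(config.max_epochs):
        locals_ = [
            _grad_step(theta, Xc, yc, config.learning_rate, config.steps_per_epoch)
            for Xc, yc in (usable[c] for c in usable)
        ]
        theta_new = np.sum([w[c] * t for c, t in zip(usable, locals_)], axis=0)
        delta = float(np.linalg.norm(theta_new - theta))
        theta = theta_new
        epochs_run += 1
        if delta < config.convergence_tol:
            break

    return FittedModel(
        intercept=float(theta[0]),
        coefficients={v: float(b) for v, b in zip(variables, theta[1:])},
        selected_variables=list(variables),
        lam=None,
        training_meta={
            "strategy": "fedavg",
            "n": total,
            "n_events": int(sum(usable[c][1].sum() for c in usable)),
            "epochs_run": epochs_run,
            "final_delta": delta,
            "skipped_centers": skipped,
            "weights": w,
        },
    )


def fit_recalibration_federated(
    preds_by_center: dict[str, np.ndarray],
    y_by_center: dict[str, np.ndarray],
    config: FedAvgConfig | None = None,
    audit=None,
) -> RecalibrationFunction:
    """Learn the (a, b) recalibration by the FedAvg loop on the single
    covariate logit(p), so uncalibrated predictions never leave their
    centers (only the two recalibration parameters are exchanged)."""
    config = config or FedAvgConfig(learning_rate=0.5, max_epochs=5000, convergence_tol=1e-9)
    center_data = {}
    for c in preds_by_center:
        p = np.asarray(preds_by_center[c], dtype=float)
        center_data[c] = (pd.DataFrame({"lp": logit(p)}), np.asarray(y_by_center[c]))
    model = fedavg_train(center_data, ["lp"], config, audit=audit)
    return RecalibrationFunction(model.intercept, model.coefficients["lp"], mode="federated")


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def ensemble_predict(
    model: EnsembleModel, X: pd.DataFrame, audit=None
) -> np.ndarray:
    """Volume-weighted mean of member predictions, then the ensemble-level
    recalibration if attached.  Scoring a record logically sends it to every
    member center and collects the member's prediction, which is what the
    audit records."""
    p = np.zeros(len(X))
    for c in sorted(model.members):
        p += model.weights[c] * predict_proba(model.members[c], X)
        if audit is not None:
            audit.share("predictions", source=c, context="ensemble scoring")
    if model.recalibration is not None:
        eps = 1e-12
        return model.recalibration.apply_to_lp(logit(np.clip(p, eps, 1 - eps)))
    return p


# ---------------------------------------------------------------------------
# Strategy construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyConfig:
    """Settings shared by the four strategies.

    ``lam=None`` triggers inner-CV selection over ``lambda_grid``;
    ``recalibration`` applies to the federated strategies only (central
    recalibration is the main-analysis default; None disables it)."""

    lam: float | None = None
    lambda_grid: tuple[float, ...] = tuple(np.geomspace(1e-4, 0.3, 20).round(6))
    k_inner: int = 3
    fedavg: FedAvgConfig = field(default_factory=FedAvgConfig)
    recalibration: str | None = "central"
    recalibration_scale: str = "logit"
    seed: int = 0


@dataclass
class StrategyModel:
    """A trained strategy: the underlying model object plus per-center fit
    failures and a unified prediction interface.

    For the local strategy, records belonging to a center whose model failed
    receive NaN predictions (callers drop them from stacked prediction sets).
    """

    name: str
    model: object  # FittedModel | EnsembleModel | dict[str, FittedModel]
    failures: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame, hospital_ids=None, audit=None) -> np.ndarray:
        if self.name in ("central", "fedavg"):
            p = predict_proba(self.model, X, hospital_ids=hospital_ids)
            if self.name == "central" and audit is not None:
                audit.share("predictions", source="pooled", context="central scoring")
            return p
        if self.name == "ensemble":
            return ensemble_predict(self.model, X, audit=audit)
        if self.name == "local":
            if hospital_ids is None:
                raise ValueError("local strategy needs hospital ids to predict")
            hospital_ids = np.asarray(hospital_ids)
            p = np.full(len(X), np.nan)
            for label, m in self.model.items():
                mask = hospital_ids == label
                if mask.any():
                    p[mask] = predict_proba(m, X.loc[mask])
            return p
        raise ValueError(f"unknown strategy {self.name!r}")


def _pick_lambda(X, y, config: StrategyConfig) -> float:
    if config.lam is not None:
        return config.lam
    return select_lambda(X, y, config.lambda_grid, k_inner=config.k_inner, seed=config.seed)


def _per_center_lasso(
    train: CohortTable, config: StrategyConfig
) -> tuple[dict[str, FittedModel], dict[str, str]]:
    fits, failures = {}, {}
    for label, sub in train.iter_centers():
        try:
            lam = _pick_lambda(sub.predictors, sub.outcome, config)
            fits[label] = fit_lasso_logistic(
                sub.predictors, sub.outcome, lam,
                meta={"strategy": "per_center", "center": label},
            )
        except (FitFailure, ValueError) as exc:
            failures[label] = str(exc)
    return fits, failures


def _central_recalibration(model_kind, predict_fn, train: CohortTable, config, audit):
    """Fit the pooled recalibration on training predictions; pooling the
    per-center predictions and outcomes is exactly the sharing this mode
    costs, so the audit events are emitted here."""
    preds, ys = [], []
    for label, sub in train.iter_centers():
        p = predict_fn(sub)
        preds.append(p)
        ys.append(sub.outcome)
        if audit is not None:
            audit.share("predictions", source=label, context=f"{model_kind} recalibration")
            audit.share("outcome_data", source=label, context=f"{model_kind} recalibration")
    preds = np.clip(np.concatenate(preds), 1e-12, 1 - 1e-12)
    y_all = np.concatenate(ys)
    try:
        return fit_recalibration(
            preds, y_all, mode="central", scale=config.recalibration_scale
        )
    except ValueError:
        # constant predictions (e.g. an intercept-only model): slope is
        # unidentifiable, so fall back to calibration-in-the-large
        rate = float(np.clip(y_all.mean(), 1e-12, 1 - 1e-12))
        a = float(logit(rate) - np.mean(logit(preds)))
        return RecalibrationFunction(a, 1.0, mode="central")


def _attach_recalibration(kind, model, train, config: StrategyConfig, audit):
    mode = config.recalibration
    if mode is None:
        return None
    if kind == "fedavg":
        raw = lambda sub: predict_proba(model, sub.predictors)  # noqa: E731
    else:
        raw = lambda sub: ensemble_predict(
            EnsembleModel(model.members, model.weights), sub.predictors, audit=audit
        )  # noqa: E731
    if mode == "central":
        return _central_recalibration(kind, raw, train, config, audit)
    if mode == "local":
        per_center = {}
        for label, sub in train.iter_centers():
            p = np.clip(raw(sub), 1e-12, 1 - 1e-12)
            rc = fit_recalibration(p, sub.outcome, mode="central",
                                   scale=config.recalibration_scale)
            per_center[label] = (rc.a, rc.b)
        a = float(np.mean([v[0] for v in per_center.values()]))
        b = float(np.mean([v[1] for v in per_center.values()]))
        return RecalibrationFunction(a, b, mode="local", per_center=per_center,
                                     scale=config.recalibration_scale)
    if mode == "federated":
        preds_by_center, y_by_center = {}, {}
        for label, sub in train.iter_centers():
            preds_by_center[label] = np.clip(raw(sub), 1e-12, 1 - 1e-12)
            y_by_center[label] = sub.outcome
        return fit_recalibration_federated(preds_by_center, y_by_center, audit=audit)
    raise ValueError(f"unknown recalibration mode {mode!r}")


def build_strategy(
    name: str,
    train: CohortTable,
    config: StrategyConfig | None = None,
    audit=None,
) -> StrategyModel:
    """Train one of the four model-development strategies on an imputed
    (complete) training table.

    central   — one LASSO fit on the pooled data (predictors, outcomes, the
                model, and its predictions all cross center boundaries by
                design).
    local     — one LASSO fit per hospital; centers where fitting fails are
                flagged, never fatal.  Nothing is shared.
    fedavg    — per-center LASSO selections -> center-weighted vote ->
                federated coefficient fitting -> recalibration.
    ensemble  — per-center LASSO fits -> volume weights -> recalibration.
    """
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGIES}")
    config = config or StrategyConfig()

    if name == "central":
        if audit is not None:
            for label in train.hospitals():
                audit.share("predictor_data", source=label, context="central pooling")
                audit.share("outcome_data", source=label, context="central pooling")
        lam = _pick_lambda(train.predictors, train.outcome, config)
        model = fit_lasso_logistic(
            train.predictors, train.outcome, lam, meta={"strategy": "central"}
        )
        if audit is not None:
            audit.share("model_parameters", source="pooled", context="central broadcast")
        return StrategyModel("central", model, meta={"lambda": lam})

    if name == "local":
        fits, failures = _per_center_lasso(train, config)
        if not fits:
            raise FitFailure("no hospital-local model could be fitted")
        return StrategyModel("local", fits, failures=failures)

    fits, failures = _per_center_lasso(train, config)
    if not fits:
        raise FitFailure(f"no per-center model could be fitted for {name}")
    sizes = {label: train.center(label).n for label in fits}
    total = sum(sizes.values())
    weights = {label: sizes[label] / total for label in fits}

    if name == "fedavg":
        selections = {label: set(m.selected_variables) for label, m in fits.items()}
        if audit is not None:
            for label in fits:
                audit.share("model_parameters", source=label, context="selection voting")
        variables = vote_select_variables(
            selections, weights, config.fedavg.agreement_strength
        )
        center_data = {
            label: (train.center(label).predictors, train.center(label).outcome)
            for label in fits
        }
        model = fedavg_train(center_data, variables, config.fedavg, audit=audit)
        model.recalibration = _attach_recalibration("fedavg", model, train, config, audit)
        return StrategyModel(
            "fedavg", model, failures=failures,
            meta={"voted_variables": variables, "weights": weights},
        )

    # ensemble
    model = EnsembleModel(members=fits, weights=weights)
    model.recalibration = _attach_recalibration("ensemble", model, train, config, audit)
    return StrategyModel("ensemble", model, failures=failures, meta={"weights": weights})
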