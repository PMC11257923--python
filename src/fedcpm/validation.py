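"""Validation designs and the cross-center sharing audit.

``run_cv`` executes 10-fold cross-validation per strategy (global
outcome-stratified folds for the central strategy, per-hospital stratified
folds for the others, matching how the registry analysis partitioned the
data) and stacks the held-out predictions.  ``run_lcoa`` performs
leave-center-out external validation: for each hospital, train on all others
and predict the excluded one.  Train and test tables are imputed separately,
with the outcome used in training-set imputation models only.

The :class:`AuditTrail` collects every event where record-level predictor
data, outcomes, model parameters, or predictions cross a center boundary
during execution; :func:`audit_sharing` condenses a trail into the
four-boolean :class:`SharingLedger` that characterizes each strategy's
data-sharing contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .federation import StrategyConfig, StrategyModel, build_strategy
from .metrics import auc
from .model_core import FitFailure
from .preprocess import (
    ImputationError,
    ImputationPlan,
    assign_cv_folds,
    filter_variables,
    impute,
    make_lcoa_splits,
    split_by_fold,
)
from .synthetic_cohort import CohortTable

__all__ = [
    "AuditTrail",
    "SharingLedger",
    "PredictionSet",
    "run_cv",
    "run_lcoa",
    "tune_grid",
    "audit_sharing",
]

logger = logging.getLogger(__name__)

INFO_CLASSES = ("predictor_data", "outcome_data", "model_parameters", "predictions")


class AuditTrail:
    """Execution trace of information crossing center boundaries."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def share(self, info_class: str, source: str = "", context: str = "") -> None:
        if info_class not in INFO_CLASSES:
            raise ValueError(f"unknown information class {info_class!r}")
        self.events.append({"class": info_class, "source": source, "context": context})

    def classes_shared(self) -> set[str]:
        return {e["class"] for e in self.events}


@dataclass(frozen=True)
class SharingLedger:
    """Which information classes crossed center boundaries during a run."""

    predictor_data_shared: bool
    outcome_data_shared: bool
    model_parameters_shared: bool
    predictions_shared: bool

    def as_dict(self) -> dict[str, bool]:
        return {
            "predictor_data_shared": self.predictor_data_shared,
            "outcome_data_shared": self.outcome_data_shared,
            "model_parameters_shared": self.model_parameters_shared,
            "predictions_shared": self.predictions_shared,
        }


def audit_sharing(trail: AuditTrail) -> SharingLedger:
    """Ledger computed from actual access events, not from intent."""
    shared = trail.classes_shared()
    return SharingLedger(
        predictor_data_shared="predictor_data" in shared,
        outcome_data_shared="outcome_data" in shared,
        model_parameters_shared="model_parameters" in shared,
        predictions_shared="predictions" in shared,
    )


@dataclass
class PredictionSet:
    """Stacked out-of-sample predictions: one row per successfully scored
    record with its fold/split unit, hospital, true outcome, and strategy."""

    data: pd.DataFrame  # record_id, hospital_id, unit, y_true, p, strategy
    failures: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if self.data["record_id"].duplicated().any():
            raise ValueError("a record appears more than once in the stack")
        p = self.data["p"].to_numpy()
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("stacked probabilities must lie strictly in (0, 1)")

    @property
    def y(self) -> np.ndarray:
        return self.data["y_true"].to_numpy(dtype=int)

    @property
    def p(self) -> np.ndarray:
        return self.data["p"].to_numpy(dtype=float)

    def by_unit(self):
        for unit, sub in self.data.groupby("unit"):
            yield unit, sub

    def by_center(self):
        for label, sub in self.data.groupby("hospital_id"):
            yield label, sub

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


_EPS = 1e-9


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1 - _EPS)


def _stack_rows(test: CohortTable, p: np.ndarray, unit, strategy: str) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "record_id": test.data["record_id"].to_numpy(),
            "hospital_id": test.data["hospital_id"].to_numpy(),
            "unit": unit,
            "y_true": test.outcome,
            "p": _clip(p),
            "strategy": strategy,
        }
    )
    return df[np.isfinite(p)]


def _impute_pair(
    train: CohortTable, test: CohortTable, scope: str, n_iterations: int, seed: int
) -> tuple[CohortTable, CohortTable]:
    train_plan = ImputationPlan(scope=scope, n_iterations=n_iterations,
                                use_outcome=True, seed=seed)
    test_plan = ImputationPlan(scope=scope, n_iterations=n_iterations,
                               use_outcome=False, seed=seed + 1)
    return impute(train, train_plan), impute(test, test_plan)


def _scope_for(strategy: str) -> str:
    return "pooled" if strategy == "central" else "per_center"


def run_cv(
    table: CohortTable,
    strategies,
    k: int = 10,
    config: StrategyConfig | dict | None = None,
    n_imputation_iterations: int = 10,
    seed: int = 0,
    audits: dict[str, AuditTrail] | None = None,
) -> dict[str, PredictionSet] | PredictionSet:
    """Stratified k-fold cross-validation of one or more strategies.

    Per fold and strategy: the training and test tables are imputed separately
    under the strategy's scope, the strategy is built on the imputed training
    table, and the held-out fold is scored.  Per-center fit failures (or
    imputation failures in tiny test partitions) are recorded in the
    prediction set, never fatal; the affected records are omitted from the
    local strategy's stack.  Strategies sharing the per-center scope reuse the
    same imputed folds.
    """
    single = isinstance(strategies, str)
    strategy_list = [strategies] if single else list(strategies)
    configs = _resolve_configs(strategy_list, config)
    audits = audits or {}

    table, excluded = filter_variables(table)
    if excluded:
        logger.info("excluded variables over the missingness threshold: %s", excluded)

    assignments = {}
    if "central" in strategy_list:
        assignments["pooled"] = assign_cv_folds(table, k, per_center=False, seed=seed)
    if any(s != "central" for s in strategy_list):
        assignments["per_center"] = assign_cv_folds(table, k, per_center=True, seed=seed)

    stacks: dict[str, list] = {s: [] for s in strategy_list}
    failures: dict[str, list] = {s: [] for s in strategy_list}

    for f in range(1, k + 1):
        imputed: dict[str, tuple[CohortTable, CohortTable]] = {}
        for scope, assignment in assignments.items():
            train, test = split_by_fold(table, assignment, f)
            try:
                imputed[scope] = _impute_pair(
                    train, test, scope, n_imputation_iterations, seed * 1000 + f
                )
            except ImputationError as exc:
                imputed[scope] = None
                for s in strategy_list:
                    if _scope_for(s) == scope:
                        failures[s].append({"unit": f, "center": None, "error": str(exc)})
        for s in strategy_list:
            pair = imputed[_scope_for(s)]
            if pair is None:
                continue
            train_imp, test_imp = pair
            try:
                model = build_strategy(s, train_imp, configs[s], audit=audits.get(s))
            except FitFailure as exc:
                failures[s].append({"unit": f, "center": None, "error": str(exc)})
                continue
            for center, msg in model.failures.items():
                failures[s].append({"unit": f, "center": center, "error": msg})
            p = model.predict(
                test_imp.predictors,
                hospital_ids=test_imp.hospital_id.to_numpy(),
                audit=audits.get(s),
            )
            stacks[s].append(_stack_rows(test_imp, p, f, s))

    out = {}
    for s in strategy_list:
        data = (
            pd.concat(stacks[s], ignore_index=True)
            if stacks[s]
            else pd.DataFrame(columns=["record_id", "hospital_id", "unit", "y_true", "p", "strategy"])
        )
        ps = PredictionSet(data, failures=failures[s])
        ps.validate()
        out[s] = ps
    return out[strategy_list[0]] if single else out


def _resolve_configs(strategy_list, config) -> dict[str, StrategyConfig]:
    if config is None:
        config = StrategyConfig()
    if isinstance(config, StrategyConfig):
        return {s: config for s in strategy_list}
    return {s: config.get(s) or StrategyConfig() for s in strategy_list}


def run_lcoa(
    table: CohortTable,
    strategies,
    config: StrategyConfig | dict | None = None,
    n_imputation_iterations: int = 10,
    seed: int = 0,
    audits: dict[str, AuditTrail] | None = None,
) -> dict[str, dict[str, PredictionSet]] | dict[str, PredictionSet]:
    """Leave-center-out analysis: per hospital, train every strategy on all
    other hospitals and predict the excluded one.

    The local strategy is not a supported design here (a set of center-bound
    models has no defined prediction for an unseen center).
    Returns ``{strategy: {hospital: PredictionSet}}`` (or the inner map for a
    single strategy); pooling across hospitals happens in the metrics layer.
    """
    single = isinstance(strategies, str)
    strategy_list = [strategies] if single else list(strategies)
    if "local" in strategy_list:
        raise ValueError("leave-center-out analysis is not applicable to the local strategy")
    configs = _resolve_configs(strategy_list, config)
    audits = audits or {}

    table, _ = filter_variables(table)
    out: dict[str, dict[str, PredictionSet]] = {s: {} for s in strategy_list}
    for i, (train, test, label) in enumerate(make_lcoa_splits(table)):
        imputed: dict[str, tuple[CohortTable, CohortTable]] = {}
        for scope in {_scope_for(s) for s in strategy_list}:
            # the excluded hospital is always imputed on its own
            imputed[scope] = _impute_pair(
                train, test, scope, n_imputation_iterations, seed * 1000 + i
            )
        for s in strategy_list:
            train_imp, test_imp = imputed[_scope_for(s)]
            failures = []
            try:
                model = build_strategy(s, train_imp, configs[s], audit=audits.get(s))
            except FitFailure as exc:
                out[s][label] = PredictionSet(
                    pd.DataFrame(columns=["record_id", "hospital_id", "unit", "y_true", "p", "strategy"]),
                    failures=[{"unit": label, "center": None, "error": str(exc)}],
                )
                continue
            for center, msg in model.failures.items():
                failures.append({"unit": label, "center": center, "error": msg})
            p = model.predict(
                test_imp.predictors,
                hospital_ids=test_imp.hospital_id.to_numpy(),
                audit=audits.get(s),
            )
            ps = PredictionSet(_stack_rows(test_imp, p, label, s), failures=failures)
            ps.validate()
            out[s][label] = ps
    return out[strategy_list[0]] if single else out


def tune_grid(
    strategy: str,
    train: CohortTable,
    grid: dict[str, list],
    seed: int = 0,
    base_config: StrategyConfig | None = None,
    k_inner: int = 3,
) -> dict:
    """Pick the hyperparameter combination maximizing inner-CV stacked AUC on
    the training data only.

    ``grid`` maps StrategyConfig / FedAvgConfig field names (``lam``,
    ``learning_rate``, ``max_epochs``, ``agreement_strength``) to candidate
    values.  Fit failures score -inf.  Deterministic given ``seed``: the grid
    is traversed in sorted-key order and ties keep the first maximum.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    base_config = base_config or StrategyConfig()
    keys = sorted(grid)
    assignment = assign_cv_folds(
        train, k_inner, per_center=(strategy != "central"), seed=seed
    )
    best_combo, best_score = None, -np.inf
    for values in product(*(grid[k] for k in keys)):
        combo = dict(zip(keys, values))
        config = _config_with(base_config, combo)
        scores = []
        for f in range(1, k_inner + 1):
            tr, te = split_by_fold(train, assignment, f)
            try:
                model = build_strategy(strategy, tr, config)
                p = model.predict(te.predictors, hospital_ids=te.hospital_id.to_numpy())
                ok = np.isfinite(p)
                scores.append(auc(_clip(p[ok]), te.outcome[ok]))
            except (FitFailure, ValueError):
                scores.append(-np.inf)
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_combo, best_score = combo, score
    if best_combo is None:
        raise FitFailure("no hyperparameter combination could be evaluated")
    return best_combo


_FEDAVG_FIELDS = {"learning_rate", "max_epochs", "agreement_strength", "convergence_tol", "steps_per_epoch"}


def _config_with(base: StrategyConfig, combo: dict) -> StrategyConfig:
    from dataclasses import replace

    fed_updates = {k: v for k, v in combo.items() if k in _FEDAVG_FIELDS}
    top_updates = {k: v for k, v in combo.items() if k not in _FEDAVG_FIELDS}
    config = replace(base, **top_updates) if top_updates else base
    if fed_updates:
        config = replace(config, fedavg=replace(config.fedavg, **fed_updates))
    return config
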