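"""Preprocessing: variable exclusion, chained-equations imputation, and
dataset partitioning for both validation designs.

Imputation scope mirrors the model-development strategies: the pooled scope
(one imputation model over the center-combined data) is used by the central
strategy, while the per-center scope (each hospital imputed strictly from its
own rows) is used by the local and federated strategies.  Train and test
tables are always imputed separately, so test imputation cannot leak training
information.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_cohort import CohortTable

__all__ = [
    "ImputationPlan",
    "ImputationError",
    "FoldAssignment",
    "filter_variables",
    "impute",
    "assign_cv_folds",
    "make_lcoa_splits",
]

logger = logging.getLogger(__name__)


class ImputationError(RuntimeError):
    """Raised when imputation is impossible (e.g. a variable 100% missing)."""


@dataclass(frozen=True)
class ImputationPlan:
    """Chained-equations settings.

    scope: ``"pooled"`` imputes on the combined table, ``"per_center"``
    imputes every hospital independently.  Continuous variables use
    predictive mean matching (``n_donors`` nearest donors); binary variables
    use logistic draws.  ``use_outcome`` includes the outcome as a covariate
    in the imputation models (training tables only; test tables are imputed
    without it).
    """

    scope: str = "per_center"
    n_iterations: int = 10
    n_donors: int = 5
    use_outcome: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scope not in ("pooled", "per_center"):
            raise ValueError(f"unknown imputation scope {self.scope!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FoldAssignment:
    """Cross-validation fold map: one fold index in [1..k] per record."""

    k: int
    fold: pd.Series  # indexed by record_id
    stratified_by_outcome: bool = True
    per_center: bool = False

    def records_in_fold(self, f: int) -> pd.Index:
        return self.fold.index[self.fold == f]

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "per_center": self.per_center,
            "fold": {rid: int(f) for rid, f in self.fold.items()},
        }


# ---------------------------------------------------------------------------
# Variable filtering
# ---------------------------------------------------------------------------

def filter_variables(
    table: CohortTable, threshold: float = 0.30
) -> tuple[CohortTable, list[str]]:
    """Drop predictors with strictly more than ``threshold`` missing values.

    A variable at exactly the threshold is retained (the rule is "more
    than").  Returns the filtered table and the excluded variable names.
    """
    frac = table.missing_mask.mean()
    excluded = [name for name in table.predictor_names if frac[name] > threshold]
    return table.drop_variables(excluded), excluded


# ---------------------------------------------------------------------------
# Chained-equations imputation
# ---------------------------------------------------------------------------

def _center_seed(seed: int, label: str) -> np.random.SeedSequence:
    # keyed by label content (not iteration order) so results are invariant
    # to hospital ordering
    return np.random.SeedSequence([seed, zlib.crc32(label.encode())])


def _pmm_draw(pred_obs, obs_values, pred_mis, n_donors, rng):
    """Predictive mean matching: for each missing row pick one of the
    ``n_donors`` observed rows with nearest predicted value and copy its
    observed value."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_val = obs_values[order]
    n = len(sorted_pred)
    k = min(n_donors, n)
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k sorted neighbours around the insertion point;
    # out-of-range slots masked out (at least k in-range slots always remain)
    cand = pos[:, None] + np.arange(-k, k)
    valid = (cand >= 0) & (cand < n)
    cand = np.clip(cand, 0, n - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    dist[~valid] = np.inf
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pick = rng.integers(k, size=len(pred_mis))
    chosen = np.take_along_axis(
        cand, np.take_along_axis(nearest, pick[:, None], axis=1), axis=1
    )[:, 0]
    return sorted_val[chosen]


def _ridge_logistic(A: np.ndarray, y: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """Newton-IRLS fit of logistic regression minimizing
    sum NLL + (lam/2) * ||w||^2 with the intercept (first column of ``A``)
    unpenalized.  Used as the imputation draw model for binary variables."""
    p = A.shape[1]
    w = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(50):
        mu = expit(A @ w)
        g = A.T @ (y - mu) - pen @ w
        wts = np.clip(mu * (1.0 - mu), 1e-9, None)
        H = (A * wts[:, None]).T @ A + pen
        step = np.linalg.solve(H, g)
        w += step
        if float(np.abs(step).max()) < 1e-8:
            break
    return w


def _impute_frame(
    X: pd.DataFrame,
    kinds: dict[str, str],
    plan: ImputationPlan,
    rng: np.random.Generator,
    context: str = "",
) -> pd.DataFrame:
    """Run chained equations on one frame (predictors plus optional outcome
    column named ``outcome`` acting as an always-observed covariate)."""
    cols = list(X.columns)
    M = X.to_numpy(dtype=float).copy()
    miss = np.isnan(M)
    col_of = {c: i for i, c in enumerate(cols)}
    targets = [c for c in cols if miss[:, col_of[c]].any()]
    for c in targets:
        if miss[:, col_of[c]].all():
            raise ImputationError(
                f"variable {c!r} is 100% missing{context and f' in {context}'}"
            )
    if not targets:
        return X.copy()
    targets.sort(key=lambda c: (miss[:, col_of[c]].mean(), c))
    # initial fill: observed mean (continuous) / seeded draw at the observed
    # rate (binary)
    for c in targets:
        j = col_of[c]
        m = miss[:, j]
        obs = M[~m, j]
        if kinds.get(c, "continuous") == "continuous":
            M[m, j] = obs.mean()
        else:
            M[m, j] = rng.binomial(1, obs.mean(), int(m.sum())).astype(float)

    ones = np.ones((len(M), 1))
    for _ in range(plan.n_iterations):
        for c in targets:
            j = col_of[c]
            m = miss[:, j]
            A = np.hstack([ones, np.delete(M, j, axis=1)])
            y = M[:, j]
            if kinds.get(c, "continuous") == "continuous":
                Ao, yo = A[~m], y[~m]
                coef = np.linalg.solve(
                    Ao.T @ Ao + 1e-6 * np.eye(A.shape[1]), Ao.T @ yo
                )
                pred = A @ coef
                M[m, j] = _pmm_draw(pred[~m], yo, pred[m], plan.n_donors, rng)
            else:
                yo = y[~m]
                if len(np.unique(yo)) < 2:
                    M[m, j] = yo[0]
                    continue
                w = _ridge_logistic(A[~m], yo)
                p = expit(A[m] @ w)
                M[m, j] = (rng.random(len(p)) < p).astype(float)
    return pd.DataFrame(M, index=X.index, columns=cols)


def impute(table: CohortTable, plan: ImputationPlan) -> CohortTable:
    """Impute all missing predictor cells by chained equations.

    Observed cells are never altered; the result is deterministic given
    ``plan.seed`` (per-center streams are keyed by hospital label, so the
    result does not depend on hospital ordering).  Raises
    :class:`ImputationError` naming the center and variable when a center's
    variable is entirely missing under the per-center scope.
    """
    names = table.predictor_names
    cols = list(names) + (["outcome"] if plan.use_outcome else [])
    df = table.data.copy()

    if plan.scope == "pooled":
        rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0]))
        frame = _impute_frame(df[cols], table.kinds, plan, rng, context="pooled table")
        df[names] = frame[names]
    else:
        for label in sorted(df["hospital_id"].unique()):
            idx = df.index[df["hospital_id"] == label]
            rng = np.random.default_rng(_center_seed(plan.seed, label))
            frame = _impute_frame(
                df.loc[idx, cols], table.kinds, plan, rng, context=f"center {label}"
            )
            df.loc[idx, names] = frame[names]
    return CohortTable(df, dict(table.kinds))


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _deal_folds(record_ids, y, k, rng) -> dict:
    """Stratified dealing: shuffle events and non-events separately, then deal
    the concatenated sequence round-robin.  Fold sizes and event counts each
    differ by at most one."""
    record_ids = np.asarray(record_ids)
    y = np.asarray(y)
    ev = record_ids[y == 1]
    nev = record_ids[y == 0]
    ev = ev[rng.permutation(len(ev))]
    nev = nev[rng.permutation(len(nev))]
    ordered = np.concatenate([ev, nev])
    return {rid: (i % k) + 1 for i, rid in enumerate(ordered)}


def assign_cv_folds(
    table: CohortTable, k: int = 10, per_center: bool = False, seed: int = 0
) -> FoldAssignment:
    """Assign records to k folds stratified by outcome.

    With ``per_center=True``, stratification and balancing happen within each
    hospital (each hospital's records are spread over all k folds); hospitals
    with fewer than k records leave some folds empty for that hospital, which
    is logged but never fatal.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mapping: dict = {}
    if per_center:
        for label, sub in table.iter_centers():
            if sub.n < k:
                logger.warning(
                    "hospital %s has %d records (< k=%d); some folds will be empty",
                    label, sub.n, k,
                )
            rng = np.random.default_rng(_center_seed(seed, label))
            mapping.update(_deal_folds(sub.data["record_id"], sub.outcome, k, rng))
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        mapping.update(_deal_folds(table.data["record_id"], table.outcome, k, rng))
    fold = pd.Series(mapping, name="fold").reindex(table.data["record_id"])
    fold.index.name = "record_id"
    return FoldAssignment(k=k, fold=fold, per_center=per_center)


def split_by_fold(
    table: CohortTable, assignment: FoldAssignment, f: int
) -> tuple[CohortTable, CohortTable]:
    """(train, test) tables for fold ``f``."""
    in_fold = table.data["record_id"].map(assignment.fold).to_numpy() == f
    return table.subset(~in_fold), table.subset(in_fold)


def make_lcoa_splits(
    table: CohortTable,
) -> list[tuple[CohortTable, CohortTable, str]]:
    """Leave-center-out splits: one (train, test, excluded_hospital) triple
    per hospital, the test set holding exactly that hospital's records."""
    hospitals = table.hospitals()
    if len(hospitals) < 2:
        raise ValueError("leave-center-out analysis requires at least 2 hospitals")
    splits = []
    for label in hospitals:
        is_test = table.data["hospital_id"] == label
        splits.append((table.subset(~is_test), table.subset(is_test), label))
    return splits
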