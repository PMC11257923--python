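"""Performance measurement.

Discrimination is the Mann-Whitney AUC (probability that a random event
outranks a random non-event, ties counted 1/2).  Calibration uses the Cox
two-parameter method: the observed outcome is regressed logistically on the
logit of the predicted probability; intercept 0 and slope 1 indicate perfect
calibration, and the miscalibration rule checks the intercept CI first, then
the slope CI.  Fold-level metrics are pooled as a mean with a normal-theory
CI; per-center metrics are pooled with DerSimonian-Laird random-effects
meta-analysis (hospital as the random effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm, rankdata

__all__ = [
    "MetricResult",
    "PooledResult",
    "CoxCalibration",
    "auc",
    "auc_ci",
    "cox_calibration",
    "classify_miscalibration",
    "calibration_curve",
    "nri",
    "bootstrap_auc_test",
    "pool_folds",
    "rema_pool",
    "compute_metric_result",
]

Z95 = 1.959963984540054


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. a single outcome class)."""


@dataclass
class CoxCalibration:
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    separation: bool = False


@dataclass
class PooledResult:
    mean: float
    ci: tuple[float, float]
    tau2: float | None
    n_units: int
    method: str  # "fold_mean" | "rema"


@dataclass
class MetricResult:
    auc: float
    auc_ci: tuple[float, float]
    cal_intercept: float
    cal_intercept_ci: tuple[float, float]
    cal_slope: float
    cal_slope_ci: tuple[float, float]
    miscalibration: str
    n: int
    n_events: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def _as_arrays(preds, labels):
    p = np.asarray(preds, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both outcome classes are required")
    return p, y


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def auc(preds, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    p, y = _as_arrays(preds, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_ci(preds, labels, n_boot: int = 200, seed: int = 0) -> tuple[float, tuple[float, float], float]:
    """AUC with a normal-theory CI from a record-level bootstrap standard
    error (degenerate resamples redrawn)."""
    p, y = _as_arrays(preds, labels)
    point = auc(p, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(n, size=n)
            if 0 < y[idx].sum() < n:
                break
        vals[b] = auc(p[idx], y[idx])
    se = float(vals.std(ddof=1))
    return point, (point - Z95 * se, point + Z95 * se), se


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def cox_calibration(preds, labels) -> CoxCalibration:
    """Cox two-parameter calibration fit with Wald 95% CIs.

    Perfect separation yields a flagged result with infinite CIs rather than
    an exception.
    """
    p, y = _as_arrays(preds, labels)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predictions must lie strictly in (0, 1)")
    if np.ptp(p) < 1e-12:
        raise ValueError("constant predictions: calibration slope unidentifiable")
    X = sm.add_constant(logit(p))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        a, b = res.params
        se_a, se_b = res.bse
    except Exception:
        return CoxCalibration(np.nan, (-np.inf, np.inf), np.nan, (-np.inf, np.inf), True)
    if not (np.isfinite(se_a) and np.isfinite(se_b)) or max(se_a, se_b) > 1e3:
        return CoxCalibration(
            float(a), (-np.inf, np.inf), float(b), (-np.inf, np.inf), True
        )
    return CoxCalibration(
        float(a), (float(a - Z95 * se_a), float(a + Z95 * se_a)),
        float(b), (float(b - Z95 * se_b), float(b + Z95 * se_b)),
    )


def classify_miscalibration(intercept_ci, slope_ci) -> str:
    """Intercept-first miscalibration rule.

    ``by_intercept`` if the intercept CI excludes 0; otherwise ``by_slope``
    if the slope CI excludes 1; otherwise ``none``.
    """
    lo_a, hi_a = intercept_ci
    lo_b, hi_b = slope_ci
    if not (lo_a <= hi_a and lo_b <= hi_b):
        raise ValueError("malformed confidence interval")
    if not lo_a <= 0.0 <= hi_a:
        return "by_intercept"
    if not lo_b <= 1.0 <= hi_b:
        return "by_slope"
    return "none"


def calibration_curve(
    preds, labels, trim_top: float = 0.025, n_bins: int = 10
) -> pd.DataFrame:
    """Binned calibration pairs after trimming the highest predictions.

    The ``floor(n * trim_top)`` records with the largest predicted
    probabilities are dropped (focusing the graph on the bulk of the risk
    distribution), then the remainder is split into ``n_bins`` equal-count
    bins by predicted probability.
    """
    p = np.asarray(preds, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(p)
    if n < n_bins:
        raise ValueError("need at least n_bins records")
    n_drop = int(np.floor(n * trim_top))
    order = np.argsort(p, kind="stable")
    keep = order[: n - n_drop] if n_drop else order
    p_k, y_k = p[keep], y[keep]
    rows = []
    for chunk in np.array_split(np.arange(len(p_k)), n_bins):
        rows.append(
            {
                "mean_pred": float(p_k[chunk].mean()),
                "event_rate": float(y_k[chunk].mean()),
                "n": int(len(chunk)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def nri(preds_ref, preds_new, labels) -> tuple[float, float, float]:
    """Category-free (continuous) net reclassification improvement.

    Among events: P(new > ref) - P(new < ref); among non-events the reverse;
    total is their sum.
    """
    ref = np.asarray(preds_ref, dtype=float)
    new = np.asarray(preds_new, dtype=float)
    if ref.shape != new.shape:
        raise ValueError("prediction vectors must cover the same records")
    _, y = _as_arrays(ref, labels)
    s = np.sign(new - ref)
    nri_events = float(s[y == 1].mean())
    nri_nonevents = float(-s[y == 0].mean())
    return nri_events, nri_nonevents, nri_events + nri_nonevents


def _auc_rows(p_rows: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    r = rankdata(p_rows, axis=1)
    n1 = y_rows.sum(axis=1)
    n0 = y_rows.shape[1] - n1
    return ((r * y_rows).sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_auc_test(
    preds_a,
    preds_b,
    labels,
    n_boot: int = 3000,
    seed: int = 0,
    record_ids=None,
    method: str = "normal",
) -> tuple[float, float]:
    """Paired bootstrap test for a difference in AUCs.

    Records are resampled with replacement ``n_boot`` times; the statistic is
    D = (AUC_a - AUC_b) / sd_boot(AUC_a - AUC_b), with a two-sided p-value
    from the standard normal (``method="percentile"`` uses the symmetric
    percentile p-value instead).  Resamples with a single outcome class are
    redrawn.  If ``record_ids`` is given, resampling happens in canonical
    sorted-id order, so identically permuting all inputs leaves (D, p)
    unchanged.
    """
    pa, y = _as_arrays(preds_a, labels)
    pb = np.asarray(preds_b, dtype=float)
    if pb.shape != pa.shape:
        raise ValueError("paired predictions must cover identical records")
    if record_ids is not None:
        order = np.argsort(np.asarray(record_ids), kind="stable")
        pa, pb, y = pa[order], pb[order], y[order]
    if np.array_equal(pa, pb):
        return 0.0, 1.0
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(n, size=(n_boot, n))
    # redraw degenerate resamples
    for _ in range(100):
        ysum = y[idx].sum(axis=1)
        bad = (ysum == 0) | (ysum == n)
        if not bad.any():
            break
        idx[bad] = rng.integers(n, size=(int(bad.sum()), n))
    y_rows = y[idx]
    diffs = _auc_rows(pa[idx], y_rows) - _auc_rows(pb[idx], y_rows)
    sd = float(diffs.std(ddof=1))
    d_obs = auc(pa, y) - auc(pb, y)
    if sd < 1e-12:
        return 0.0, 1.0
    D = d_obs / sd
    if method == "percentile":
        shifted = diffs - diffs.mean()
        p = float(np.mean(np.abs(shifted) >= abs(d_obs)))
        return float(D), max(p, 1.0 / n_boot)
    return float(D), float(2.0 * norm.sf(abs(D)))


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool_folds(values, scale: str = "se") -> PooledResult:
    """Mean of per-fold metric values with a normal-theory 95% CI.

    ``scale="se"`` (default) uses mean +/- 1.96 * sd / sqrt(k);
    ``scale="sd"`` uses the raw standard deviation instead.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("pooling requires at least 2 fold values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = Z95 * (sd / np.sqrt(len(vals)) if scale == "se" else sd)
    return PooledResult(mean, (mean - half, mean + half), None, len(vals), "fold_mean")


def rema_pool(estimates, std_errors) -> PooledResult:
    """DerSimonian-Laird random-effects meta-analysis.

    tau^2 = max(0, (Q - df) / C) with inverse-variance weights; the pooled
    mean uses weights 1 / (se^2 + tau^2) and a normal-theory 95% CI.  A single
    unit is returned as itself with its own Wald CI.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    if est.shape != se.shape or est.size == 0:
        raise ValueError("estimates and standard errors must align and be non-empty")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    if est.size == 1:
        m = float(est[0])
        return PooledResult(m, (m - Z95 * se[0], m + Z95 * se[0]), 0.0, 1, "rema")
    w = 1.0 / se**2
    fixed = float(np.sum(w * est) / np.sum(w))
    Q = float(np.sum(w * (est - fixed) ** 2))
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (est.size - 1)) / C) if C > 0 else 0.0
    ws = 1.0 / (se**2 + tau2)
    mean = float(np.sum(ws * est) / np.sum(ws))
    se_pool = float(np.sqrt(1.0 / np.sum(ws)))
    return PooledResult(
        mean, (mean - Z95 * se_pool, mean + Z95 * se_pool), tau2, est.size, "rema"
    )


# ---------------------------------------------------------------------------
# Bundled result
# ---------------------------------------------------------------------------

def compute_metric_result(preds, labels, seed: int = 0, n_boot: int = 200) -> MetricResult:
    """AUC (bootstrap CI), Cox calibration, and the miscalibration class on
    one set of stacked predictions."""
    point, ci, se = auc_ci(preds, labels, n_boot=n_boot, seed=seed)
    cal = cox_calibration(preds, labels)
    y = np.asarray(labels, dtype=int)
    return MetricResult(
        auc=point,
        auc_ci=ci,
        cal_intercept=cal.intercept,
        cal_intercept_ci=cal.intercept_ci,
        cal_slope=cal.slope,
        cal_slope_ci=cal.slope_ci,
        miscalibration=classify_miscalibration(cal.intercept_ci, cal.slope_ci),
        n=len(y),
        n_events=int(y.sum()),
        extra={"auc_se": se},
    )
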