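"""Synthetic multicenter cohort generation.

Emulates the statistical structure of a national cardiac-procedure registry
spread over 16 hospitals: ~16,661 records, a
rare binary outcome (30-day mortality, overall prevalence 3.4%, per-hospital
prevalence spanning roughly 1.2%-5.8%), 33 candidate predictors of mixed
binary/continuous type, hospital case-mix heterogeneity, and missing-at-random
(MAR) missingness with at least one variable above the 30% exclusion
threshold.

The data-generating process is a logistic model

    P(y = 1 | x, c) = expit(beta0 + u_c + x . beta)

with per-hospital intercept offsets ``u_c`` (driving the prevalence spread)
and per-hospital mean shifts on a subset of continuous covariates (case-mix).
Because the truth is known, downstream stages (LASSO selection, FedAvg,
recalibration, calibration metrics) can be tested for parameter recovery and
calibration against it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "PredictorSpec",
    "GeneratorConfig",
    "CohortTable",
    "default_config",
    "generate_cohort",
    "true_risk",
    "inject_missingness",
    "analytic_prevalence",
]

ID_COLUMNS = ("record_id", "hospital_id", "year", "outcome")

# Gauss-Hermite rule (probabilists' weight) used for integrating the logistic
# mean over the continuous part of the linear predictor.
_GH_NODES, _GH_WEIGHTS = hermegauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class PredictorSpec:
    """One candidate predictor variable.

    kind:
      * ``"continuous"`` — Normal(delta_c, 1) with optional per-hospital mean
        shift ``center_shifts`` (case-mix heterogeneity).
      * ``"binary"`` — Bernoulli(prevalence).
      * ``"threshold"`` — indicator that the ``source`` continuous variable
        falls below ``threshold`` (used for the dichotomized body-surface-area
        predictor).
    """

    name: str
    kind: str
    prevalence: float | None = None
    source: str | None = None
    threshold: float | None = None
    center_shifts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "threshold"):
            raise ConfigurationError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise ConfigurationError(
                    f"binary predictor {self.name!r} needs prevalence in [0, 1]"
                )
        if self.kind == "threshold" and (self.source is None or self.threshold is None):
            raise ConfigurationError(
                f"threshold predictor {self.name!r} needs source and threshold"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the synthetic data-generating process."""

    hospital_labels: tuple[str, ...]
    hospital_sizes: tuple[int, ...]
    predictors: tuple[PredictorSpec, ...]
    beta0: float
    beta: tuple[float, ...]
    center_effects: tuple[float, ...]
    missing_rates: tuple[float, ...]
    mar_drivers: tuple[str, ...] = ("age_std", "sex_male")
    mar_strength: float = 1.0
    prevalence_span: tuple[float, float] = (0.012, 0.058)
    overall_prevalence: float = 0.034
    year_range: tuple[int, int] = (2013, 2021)
    start_years: tuple[int, ...] | None = None
    year_weights: tuple[tuple[float, ...], ...] | None = None
    seed: int = 0

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_labels)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.predictors)

    def validate(self) -> None:
        if len(set(self.hospital_labels)) != self.n_hospitals:
            raise ConfigurationError("hospital labels must be unique")
        if len(self.hospital_sizes) != self.n_hospitals:
            raise ConfigurationError("hospital_sizes length mismatch")
        if any(s < 1 for s in self.hospital_sizes):
            raise ConfigurationError("hospital sizes must all be >= 1")
        if len(self.beta) != self.n_predictors:
            raise ConfigurationError("beta length must equal number of predictors")
        if len(self.center_effects) != self.n_hospitals:
            raise ConfigurationError("center_effects length mismatch")
        if len(self.missing_rates) != self.n_predictors:
            raise ConfigurationError("missing_rates length mismatch")
        if any(not 0.0 <= r <= 1.0 for r in self.missing_rates):
            raise ConfigurationError("missing rates must lie in [0, 1]")
        names = self.predictor_names
        for drv in self.mar_drivers:
            if drv not in names:
                raise ConfigurationError(f"MAR driver {drv!r} not a predictor")
            if self.missing_rates[names.index(drv)] > 0:
                raise ConfigurationError(f"MAR driver {drv!r} must never be missing")
        lo, hi = self.prevalence_span
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("prevalence_span must satisfy 0 < lo < hi < 1")

    @property
    def kinds(self) -> dict[str, str]:
        """Variable kind map used by downstream imputation ('binary' covers
        threshold indicators)."""
        return {
            p.name: ("continuous" if p.kind == "continuous" else "binary")
            for p in self.predictors
        }


@dataclass
class CohortTable:
    """Multicenter patient-level table.

    ``data`` holds columns ``record_id``, ``hospital_id``, ``year``,
    ``outcome`` plus one column per predictor; missing predictor values are
    encoded as NaN.  ``kinds`` maps predictor name to ``"continuous"`` or
    ``"binary"`` and travels with the table so imputation knows which model to
    use per variable.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("record_id", "hospital_id", "outcome") if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        if self.data["record_id"].duplicated().any():
            raise ValueError("record_id values must be unique")
        if self.data["hospital_id"].isna().any() or (self.data["hospital_id"] == "").any():
            raise ValueError("hospital_id must be non-empty for every record")
        out = self.data["outcome"]
        if out.isna().any():
            raise ValueError("outcome must never be missing")
        if not set(np.unique(out)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if not self.kinds:
            self.kinds = {
                c: ("binary" if self.data[c].dropna().nunique() <= 2 else "continuous")
                for c in self.predictor_names
            }

    # -- accessors ---------------------------------------------------------
    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def predictors(self) -> pd.DataFrame:
        return self.data[self.predictor_names]

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def hospital_id(self) -> pd.Series:
        return self.data["hospital_id"]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.predictor_names].isna()

    def hospitals(self) -> list[str]:
        return sorted(self.data["hospital_id"].unique())

    def subset(self, row_mask) -> "CohortTable":
        return CohortTable(self.data.loc[row_mask].reset_index(drop=True).copy(), dict(self.kinds))

    def center(self, label: str) -> "CohortTable":
        return self.subset(self.data["hospital_id"] == label)

    def iter_centers(self) -> Iterable[tuple[str, "CohortTable"]]:
        for label in self.hospitals():
            yield label, self.center(label)

    def drop_variables(self, names: Sequence[str]) -> "CohortTable":
        keep = [c for c in self.data.columns if c not in set(names)]
        kinds = {k: v for k, v in self.kinds.items() if k not in set(names)}
        return CohortTable(self.data[keep].copy(), kinds)

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path, config: GeneratorConfig | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        schema = {
            "kinds": self.kinds,
            "predictors": self.predictor_names,
        }
        if config is not None:
            schema["generator_config"] = _config_to_jsonable(config)
        path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        df = pd.read_csv(path, dtype={"hospital_id": str, "record_id": str})
        kinds: dict[str, str] = {}
        sidecar = path.with_suffix(".schema.json")
        if sidecar.exists():
            kinds = json.loads(sidecar.read_text()).get("kinds", {})
        return cls(df, kinds)


def _config_to_jsonable(config: GeneratorConfig) -> dict:
    d = {
        "hospital_labels": list(config.hospital_labels),
        "hospital_sizes": list(config.hospital_sizes),
        "beta0": config.beta0,
        "beta": list(config.beta),
        "center_effects": list(config.center_effects),
        "missing_rates": list(config.missing_rates),
        "mar_drivers": list(config.mar_drivers),
        "mar_strength": config.mar_strength,
        "seed": config.seed,
        "predictors": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(p).items()}
            for p in config.predictors
        ],
    }
    return d


# ---------------------------------------------------------------------------
# Default registry-like schema
# ---------------------------------------------------------------------------

_CONTINUOUS = [
    "age_std", "bmi", "bsa", "creatinine", "hemoglobin", "lvef",
    "aortic_gradient", "sys_bp", "egfr", "euroscore_logit", "albumin",
    "valve_area", "pulm_pressure",
]
_BINARY = {
    "sex_male": 0.55, "diabetes": 0.28, "copd": 0.22, "prior_cabg": 0.14,
    "prior_pci": 0.25, "prior_stroke": 0.09, "peripheral_vascular": 0.16,
    "atrial_fib": 0.30, "dialysis": 0.04, "critical_preop": 0.03,
    "ccs_class_iv": 0.05, "recent_mi": 0.04, "prior_avr": 0.03,
    "pacemaker": 0.10, "nyha_iii_iv": 0.45, "frailty_status": 0.30,
    "access_nonfemoral": 0.15, "anesthesia_general": 0.35, "malignancy": 0.12,
}

# Nonzero true log-odds coefficients; everything else is noise. The frailty
# variable carries a real effect but exceeds the 30% missingness threshold,
# so the preprocessing filter removes it (mirroring how real registries lose
# informative but poorly collected variables).
_BETA_TRUE = {
    "age_std": 0.35, "creatinine": 0.25, "lvef": -0.30, "hemoglobin": -0.15,
    "critical_preop": 1.00, "dialysis": 0.70, "access_nonfemoral": 0.45,
    "nyha_iii_iv": 0.35, "frailty_status": 0.40, "sex_male": -0.20,
    "bsa_low": 0.30,
}

_MISSING_RATES = {
    "frailty_status": 0.35,  # above the 30% exclusion threshold
    "lvef": 0.12, "creatinine": 0.08, "hemoglobin": 0.08, "albumin": 0.14,
    "euroscore_logit": 0.10, "aortic_gradient": 0.06, "valve_area": 0.09,
    "nyha_iii_iv": 0.05, "copd": 0.04,
}

# Fixed default hospital volumes summing to 16,661, with three deliberately
# low-volume centers (N, O, P) to exercise fit-failure paths and the
# low-volume sensitivity analysis.
_DEFAULT_SIZES = (
    1850, 1720, 1600, 1540, 1470, 1380, 1290, 1180,
    1050, 960, 840, 700, 560, 260, 150, 111,
)

# Assignment order for per-hospital prevalence targets so that prevalence is
# not monotone in hospital volume.
_TARGET_PERMUTATION = (7, 3, 11, 5, 13, 1, 9, 15, 0, 8, 4, 12, 2, 10, 6, 14)


def _hospital_labels(n: int) -> tuple[str, ...]:
    if n <= 26:
        return tuple(chr(ord("A") + i) for i in range(n))
    return tuple(f"H{i:02d}" for i in range(n))


def _default_predictors(n_hospitals: int) -> tuple[PredictorSpec, ...]:
    # deterministic case-mix shifts, independent of the cohort seed
    shift_rng = np.random.default_rng(20130101)
    shifted = {"age_std", "bsa", "creatinine", "lvef", "euroscore_logit"}
    specs: list[PredictorSpec] = []
    for name in _CONTINUOUS:
        shifts = None
        if name in shifted:
            shifts = tuple(np.round(shift_rng.uniform(-0.30, 0.30, n_hospitals), 4))
        specs.append(PredictorSpec(name, "continuous", center_shifts=shifts))
    specs.append(PredictorSpec("bsa_low", "threshold", source="bsa", threshold=-0.8))
    for name, prev in _BINARY.items():
        specs.append(PredictorSpec(name, "binary", prevalence=prev))
    return tuple(specs)


def _prevalence_targets(
    sizes: Sequence[int], span: tuple[float, float], overall: float
) -> np.ndarray:
    """Per-hospital outcome-prevalence targets spanning exactly ``span`` with
    size-weighted mean ``overall``.

    Targets sit at expit(logit(lo) + (logit(hi)-logit(lo)) * q_i**t) for an
    even grid q_i in [0, 1]; the exponent t > 0 warps the interior spacing
    (monotonically in the weighted mean) while pinning the endpoints, and is
    solved so the size-weighted mean hits ``overall``.
    """
    n = len(sizes)
    lo, hi = span
    q = np.linspace(0.0, 1.0, n)
    perm = (
        np.array(_TARGET_PERMUTATION)
        if n == len(_TARGET_PERMUTATION)
        else np.argsort(np.sin(np.arange(n) * 2.3), kind="stable")
    )
    w = np.asarray(sizes, float) / np.sum(sizes)
    lo_l, hi_l = logit(lo), logit(hi)

    def targets_for(t: float) -> np.ndarray:
        base = expit(lo_l + (hi_l - lo_l) * q**t)
        out = np.empty(n)
        out[np.asarray(perm)] = base
        return out

    def weighted_mean(log_t: float) -> float:
        return float(np.sum(w * targets_for(np.exp(log_t)))) - overall

    log_t = brentq(weighted_mean, np.log(1e-3), np.log(1e3), xtol=1e-12)
    return targets_for(np.exp(log_t))


def _linear_predictor_parts(config: GeneratorConfig, hospital_index: int):
    """Split x.beta into an enumerable binary part and a Normal continuous
    part for exact numeric integration (covariates are independent)."""
    combos_p: list[np.ndarray] = []
    combos_s: list[np.ndarray] = []
    mu = 0.0
    var = 0.0
    for spec, b in zip(config.predictors, config.beta):
        if b == 0.0:
            continue
        if spec.kind == "continuous":
            shift = spec.center_shifts[hospital_index] if spec.center_shifts else 0.0
            mu += b * shift
            var += b * b
        else:
            if spec.kind == "binary":
                p = spec.prevalence
            else:  # threshold indicator of a Normal(shift, 1) source
                src = next(s for s in config.predictors if s.name == spec.source)
                shift = src.center_shifts[hospital_index] if src.center_shifts else 0.0
                p = float(norm.cdf(spec.threshold - shift))
            combos_p.append(np.array([1.0 - p, p]))
            combos_s.append(np.array([0.0, b]))
    return combos_p, combos_s, mu, np.sqrt(var)


def _binary_combo_arrays(combos_p, combos_s):
    """Enumerate joint states of the binary signal variables into weight and
    linear-predictor-contribution vectors."""
    if not combos_p:
        return np.ones(1), np.zeros(1)
    if len(combos_p) > 14:
        raise ConfigurationError("too many binary signal variables to enumerate")
    W = np.ones(1)
    S = np.zeros(1)
    for p, s in zip(combos_p, combos_s):
        W = np.concatenate([W * p[0], W * p[1]])
        S = np.concatenate([S + s[0], S + s[1]])
    return W, S


def analytic_prevalence(
    config: GeneratorConfig, hospital_index: int, u: float | None = None
) -> float:
    """Exact expected outcome prevalence at a hospital under the DGP.

    Enumerates the (independent) binary signal variables and integrates the
    continuous Normal part with Gauss-Hermite quadrature.
    """
    combos_p, combos_s, mu, sigma = _linear_predictor_parts(config, hospital_index)
    if u is None:
        u = config.center_effects[hospital_index]
    base = config.beta0 + u + mu
    W, S = _binary_combo_arrays(combos_p, combos_s)
    grid = sigma * _GH_NODES if sigma > 0 else np.zeros(1)
    gw = _GH_WEIGHTS if sigma > 0 else np.ones(1)
    vals = expit(base + S[:, None] + grid[None, :])
    return float(W @ vals @ gw)


def _calibrate_center_effects(config: GeneratorConfig) -> GeneratorConfig:
    targets = _prevalence_targets(
        config.hospital_sizes, config.prevalence_span, config.overall_prevalence
    )
    effects = []
    for c, target in enumerate(targets):
        effects.append(
            brentq(lambda u: analytic_prevalence(config, c, u) - target, -8.0, 8.0, xtol=1e-10)
        )
    return replace(config, center_effects=tuple(effects))


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Registry-like default configuration (16 hospitals A-P, ~16,661 records,
    33 predictors, 3.4% overall prevalence spanning 1.2%-5.8%)."""
    n_h = 16
    predictors = _default_predictors(n_h)
    names = [p.name for p in predictors]
    beta = tuple(_BETA_TRUE.get(nm, 0.0) for nm in names)
    rates = tuple(_MISSING_RATES.get(nm, 0.0) for nm in names)
    # three late-starting, front-loaded low-volume centers (N, O, P)
    start_years = tuple([2013] * 13 + [2018, 2019, 2019])
    year_weights = (
        *([None] * 13),
        (0.55, 0.25, 0.17, 0.03),
        (0.80, 0.14, 0.06),
        (0.85, 0.09, 0.06),
    )
    config = GeneratorConfig(
        hospital_labels=_hospital_labels(n_h),
        hospital_sizes=_DEFAULT_SIZES,
        predictors=predictors,
        beta0=float(logit(0.034)),
        beta=beta,
        center_effects=(0.0,) * n_h,
        missing_rates=rates,
        start_years=start_years,
        year_weights=year_weights,
        seed=seed,
    )
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    if "center_effects" not in overrides:
        config = _calibrate_center_effects(config)
    return config


def iid_config(
    n_records: int = 16000,
    n_hospitals: int = 16,
    seed: int = 0,
    beta: dict[str, float] | None = None,
    beta0: float | None = None,
    n_predictors: int = 33,
    prevalence: float = 0.10,
) -> GeneratorConfig:
    """Homogeneous configuration (no center effects, no case-mix shifts, no
    missingness): hospitals are IID partitions of one population.  Used for
    parameter-recovery and FedAvg-vs-pooled equivalence checks."""
    n_cont = max(1, int(round(n_predictors * 0.4)))
    names = [f"x{j:02d}" for j in range(n_predictors)]
    specs = tuple(
        PredictorSpec(nm, "continuous")
        if j < n_cont
        else PredictorSpec(nm, "binary", prevalence=0.3)
        for j, nm in enumerate(names)
    )
    beta = beta or {}
    bvec = tuple(float(beta.get(nm, 0.0)) for nm in names)
    base, rem = divmod(n_records, n_hospitals)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(n_hospitals))
    config = GeneratorConfig(
        hospital_labels=_hospital_labels(n_hospitals),
        hospital_sizes=sizes,
        predictors=specs,
        beta0=float(logit(prevalence)) if beta0 is None else beta0,
        beta=bvec,
        center_effects=(0.0,) * n_hospitals,
        missing_rates=(0.0,) * n_predictors,
        mar_drivers=(),
        seed=seed,
        start_years=(2013,) * n_hospitals,
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _year_counts(size: int, n_years: int, weights: Sequence[float] | None) -> np.ndarray:
    """Largest-remainder apportionment of a hospital's records over its active
    years (deterministic, so yearly volumes are reproducible)."""
    w = np.full(n_years, 1.0 / n_years) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    raw = w * size
    counts = np.floor(raw).astype(int)
    rem = size - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a complete (pre-missingness) cohort from the configured DGP.

    Deterministic given ``config.seed``: records are generated hospital by
    hospital in label order from a single seeded generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    beta = np.asarray(config.beta)
    frames = []
    for c, (label, size) in enumerate(zip(config.hospital_labels, config.hospital_sizes)):
        cols: dict[str, np.ndarray] = {}
        for spec in config.predictors:
            if spec.kind == "continuous":
                shift = spec.center_shifts[c] if spec.center_shifts else 0.0
                cols[spec.name] = rng.normal(shift, 1.0, size)
            elif spec.kind == "binary":
                cols[spec.name] = rng.binomial(1, spec.prevalence, size).astype(float)
            else:
                cols[spec.name] = (cols[spec.source] < spec.threshold).astype(float)
        X = np.column_stack([cols[p.name] for p in config.predictors])
        lp = config.beta0 + config.center_effects[c] + X @ beta
        y = rng.binomial(1, expit(lp))
        start = config.start_years[c] if config.start_years else config.year_range[0]
        years_active = np.arange(start, config.year_range[1] + 1)
        weights = config.year_weights[c] if config.year_weights else None
        counts = _year_counts(size, len(years_active), weights)
        years = np.repeat(years_active, counts)
        rng.shuffle(years)
        df = pd.DataFrame(
            {
                "record_id": [f"{label}-{i:05d}" for i in range(size)],
                "hospital_id": label,
                "year": years,
                "outcome": y,
            }
        )
        for p in config.predictors:
            df[p.name] = cols[p.name]
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data, config.kinds)


def true_risk(x, hospital: str, config: GeneratorConfig) -> float:
    """True outcome probability expit(beta0 + u_c + x.beta) for a complete
    predictor vector ``x`` (ordered as ``config.predictor_names``)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != config.n_predictors:
        raise ValueError(
            f"predictor vector has length {x.shape[-1]}, expected {config.n_predictors}"
        )
    if np.isnan(x).any():
        raise ValueError("true_risk requires a complete predictor vector")
    c = config.hospital_labels.index(hospital)
    lp = config.beta0 + config.center_effects[c] + x @ np.asarray(config.beta)
    return expit(lp)


def inject_missingness(table: CohortTable, config: GeneratorConfig) -> CohortTable:
    """Mask predictor cells missing-at-random.

    The masking probability for variable j is expit(alpha_j + s * z) where z
    is a standardized score built from the never-missing driver covariates and
    alpha_j is calibrated so the expected missing fraction equals the
    configured rate r_j.  Masks are drawn before any value is inspected, so
    masking is conditionally independent of the masked value given the
    observed drivers (MAR by construction).  The outcome is never masked.
    """
    df = table.data.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
    n = len(df)
    if config.mar_drivers:
        z = np.zeros(n)
        for drv in config.mar_drivers:
            col = df[drv].to_numpy(dtype=float)
            sd = col.std()
            z += (col - col.mean()) / (sd if sd > 0 else 1.0)
        z /= len(config.mar_drivers)
    else:
        z = np.zeros(n)
    for name, r in zip(config.predictor_names, config.missing_rates):
        if r <= 0.0:
            continue
        if name in config.mar_drivers:
            raise ConfigurationError(f"driver {name!r} cannot be masked")
        s = config.mar_strength

        def mean_rate(alpha: float) -> float:
            return float(np.mean(expit(alpha + s * z))) - r

        alpha = brentq(mean_rate, -20.0, 20.0, xtol=1e-12)
        mask = rng.random(n) < expit(alpha + s * z)
        df.loc[mask, name] = np.nan
    return CohortTable(df, dict(table.kinds))
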