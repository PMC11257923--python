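"""Configuration-driven execution of the full study design.

``run_study`` evaluates the requested strategies under both validation
designs, pools the results (fold means for CV, random-effects meta-analysis
across hospitals for LCOA), computes pairwise NRI and paired bootstrap AUC
tests, audits cross-center sharing, runs the two sensitivity analyses
(skipping recalibration; excluding low-volume hospitals), and fits the final
models on the complete dataset.

All stage seeds derive deterministically from the master seed via stable
hashing, so identical configurations produce identical report bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .federation import FedAvgConfig, StrategyConfig, build_strategy
from .model_core import FitFailure
from .preprocess import ImputationPlan, filter_variables, impute
from .synthetic_cohort import CohortTable, GeneratorConfig, default_config, generate_cohort, inject_missingness
from .validation import AuditTrail, PredictionSet, audit_sharing, run_cv, run_lcoa

__all__ = ["StudyConfig", "flag_low_volume", "run_study", "fit_final_models", "stage_seed"]

logger = logging.getLogger(__name__)

LCOA_STRATEGIES = ("central", "fedavg", "ensemble")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    master_seed: int = 0
    strategies: tuple[str, ...] = ("central", "local", "fedavg", "ensemble")
    designs: tuple[str, ...] = ("cv", "lcoa")
    k: int = 10
    cohort_csv: str | None = None  # user-supplied table; otherwise synthetic
    generator_seed: int | None = None
    recalibration: str | None = "central"
    lam: float | None = None
    lambda_grid: tuple[float, ...] = (0.001, 0.003, 0.01, 0.03)
    fedavg: FedAvgConfig = field(default_factory=FedAvgConfig)
    n_imputation_iterations: int = 5
    sensitivity_no_recalibration: bool = True
    sensitivity_exclude_low_volume: bool = True
    fit_final: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        if not self.designs:
            raise ValueError("at least one design is required")

    def strategy_config(self, recalibration=...) -> StrategyConfig:
        return StrategyConfig(
            lam=self.lam,
            lambda_grid=tuple(self.lambda_grid),
            fedavg=self.fedavg,
            recalibration=self.recalibration if recalibration is ... else recalibration,
            seed=stage_seed(self.master_seed, "strategy"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "fedavg" in raw:
            raw["fedavg"] = FedAvgConfig(**raw["fedavg"])
        for key in ("strategies", "designs", "lambda_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Low-volume rule
# ---------------------------------------------------------------------------

def flag_low_volume(yearly_counts: dict[str, list | tuple]) -> dict[str, bool]:
    """A hospital is low-volume iff any year of operation *after its first*
    has fewer than 10 procedures."""
    if not yearly_counts:
        raise ValueError("no yearly counts supplied")
    flags = {}
    for label, counts in yearly_counts.items():
        counts = list(counts)
        if not counts:
            raise ValueError(f"hospital {label!r} has no yearly counts")
        flags[label] = any(c < 10 for c in counts[1:])
    return flags


def yearly_counts_from_table(table: CohortTable) -> dict[str, list[int]]:
    if "year" not in table.data.columns:
        raise ValueError("cohort table has no 'year' column")
    out = {}
    for label, sub in table.data.groupby("hospital_id"):
        counts = sub.groupby("year").size().sort_index()
        out[str(label)] = counts.tolist()
    return out


# ---------------------------------------------------------------------------
# Result summarization
# ---------------------------------------------------------------------------

def _metric_json(mr: M.MetricResult) -> dict:
    return {
        "auc": mr.auc, "auc_ci": list(mr.auc_ci),
        "cal_intercept": mr.cal_intercept, "cal_intercept_ci": list(mr.cal_intercept_ci),
        "cal_slope": mr.cal_slope, "cal_slope_ci": list(mr.cal_slope_ci),
        "miscalibration": mr.miscalibration, "n": mr.n, "n_events": mr.n_events,
    }


def _pooled_json(pr: M.PooledResult) -> dict:
    return {"mean": pr.mean, "ci": list(pr.ci), "tau2": pr.tau2,
            "n_units": pr.n_units, "method": pr.method}


def _safe_fold_aucs(ps: PredictionSet) -> list[float]:
    vals = []
    for _, sub in ps.by_unit():
        y = sub["y_true"].to_numpy()
        if 0 < y.sum() < len(y):
            vals.append(M.auc(sub["p"].to_numpy(), y))
    return vals


def summarize_cv(ps: PredictionSet, seed: int = 0) -> dict:
    """CV summary: fold-mean pooled AUC plus stacked-prediction calibration
    (matching how the calibration legend is computed on combined test-set
    predictions)."""
    fold_aucs = _safe_fold_aucs(ps)
    out: dict = {"n_stacked": int(len(ps.data)), "failures": ps.failures}
    if len(fold_aucs) >= 2:
        out["auc_pooled"] = _pooled_json(M.pool_folds(fold_aucs))
    if len(ps.data) and 0 < ps.y.sum() < len(ps.data) and np.ptp(ps.p) > 1e-12:
        out["stacked"] = _metric_json(M.compute_metric_result(ps.p, ps.y, seed=seed))
    return out


def summarize_cv_local(ps: PredictionSet, seed: int = 0) -> dict:
    """Local strategy CV summary: per-center stacked metrics pooled by
    random-effects meta-analysis (hospital as the random effect)."""
    out = summarize_cv(ps, seed=seed)
    estimates, ses, per_center = [], [], {}
    miscal = 0
    for label, sub in ps.by_center():
        y = sub["y_true"].to_numpy()
        if not 0 < y.sum() < len(y) or len(y) < 20 or np.ptp(sub["p"].to_numpy()) < 1e-12:
            continue
        point, ci, se = M.auc_ci(sub["p"].to_numpy(), y, seed=seed)
        cal = M.cox_calibration(sub["p"].to_numpy(), y)
        cls = M.classify_miscalibration(cal.intercept_ci, cal.slope_ci)
        per_center[str(label)] = {"auc": point, "auc_ci": list(ci), "miscalibration": cls}
        miscal += cls != "none"
        if se > 0:
            estimates.append(point)
            ses.append(se)
    out["per_center"] = per_center
    if len(estimates) >= 2:
        out["auc_rema"] = _pooled_json(M.rema_pool(estimates, ses))
    if per_center:
        out["miscalibrated_fraction"] = miscal / len(per_center)
    return out


def summarize_lcoa(per_hospital: dict[str, PredictionSet], seed: int = 0) -> dict:
    """LCOA summary: per-external-hospital metrics pooled by REMA, plus the
    fraction of external hospitals showing miscalibration."""
    auc_est, auc_se = [], []
    int_est, int_se, slope_est, slope_se = [], [], [], []
    per_center = {}
    miscal = 0
    evaluated = 0
    for label in sorted(per_hospital):
        ps = per_hospital[label]
        if not len(ps.data):
            per_center[label] = {"error": ps.failures}
            continue
        y, p = ps.y, ps.p
        if not 0 < y.sum() < len(y):
            per_center[label] = {"skipped": "single outcome class in external set"}
            continue
        if np.ptp(p) < 1e-12:
            per_center[label] = {"skipped": "constant predictions"}
            continue
        point, ci, se = M.auc_ci(p, y, seed=seed)
        cal = M.cox_calibration(p, y)
        cls = M.classify_miscalibration(cal.intercept_ci, cal.slope_ci)
        per_center[label] = {
            "auc": point, "auc_ci": list(ci),
            "cal_intercept": cal.intercept, "cal_slope": cal.slope,
            "miscalibration": cls,
        }
        evaluated += 1
        miscal += cls != "none"
        if se > 0:
            auc_est.append(point); auc_se.append(se)
        if not cal.separation:
            wa = (cal.intercept_ci[1] - cal.intercept_ci[0]) / (2 * M.Z95)
            wb = (cal.slope_ci[1] - cal.slope_ci[0]) / (2 * M.Z95)
            if np.isfinite(wa) and wa > 0:
                int_est.append(cal.intercept); int_se.append(wa)
            if np.isfinite(wb) and wb > 0:
                slope_est.append(cal.slope); slope_se.append(wb)
    out: dict = {"per_center": per_center}
    if len(auc_est) >= 2:
        out["auc_rema"] = _pooled_json(M.rema_pool(auc_est, auc_se))
    if len(int_est) >= 2:
        out["cal_intercept_rema"] = _pooled_json(M.rema_pool(int_est, int_se))
    if len(slope_est) >= 2:
        out["cal_slope_rema"] = _pooled_json(M.rema_pool(slope_est, slope_se))
    if evaluated:
        out["miscalibrated_fraction"] = miscal / evaluated
    return out


def _pairwise_comparisons(pred_sets: dict[str, PredictionSet], seed: int, n_boot: int) -> dict:
    """NRI and per-fold paired bootstrap AUC tests on records common to each
    strategy pair."""
    out: dict = {}
    names = sorted(pred_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da, db = pred_sets[a].data, pred_sets[b].data
            merged = da.merge(
                db[["record_id", "p", "unit"]], on="record_id", suffixes=("_a", "_b")
            )
            if not len(merged):
                continue
            y = merged["y_true"].to_numpy()
            if not 0 < y.sum() < len(y):
                continue
            pa, pb = merged["p_a"].to_numpy(), merged["p_b"].to_numpy()
            ev, nev, tot = M.nri(pb, pa, y)  # NRI of a relative to b
            tests = {}
            for unit, sub in merged.groupby("unit_a"):
                yy = sub["y_true"].to_numpy()
                if not 0 < yy.sum() < len(yy):
                    continue
                D, pval = M.bootstrap_auc_test(
                    sub["p_a"].to_numpy(), sub["p_b"].to_numpy(), yy,
                    n_boot=n_boot, seed=seed,
                    record_ids=sub["record_id"].to_numpy(),
                )
                tests[str(unit)] = {"D": D, "p": pval}
            out[f"{a}_vs_{b}"] = {
                "nri_events": ev, "nri_nonevents": nev, "nri_total": tot,
                "auc_tests": tests,
            }
    return out


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def _load_table(config: StudyConfig) -> CohortTable:
    if config.cohort_csv:
        return CohortTable.read_csv(config.cohort_csv)
    gseed = (
        config.generator_seed
        if config.generator_seed is not None
        else stage_seed(config.master_seed, "generator")
    )
    gen = default_config(seed=gseed)
    return inject_missingness(generate_cohort(gen), gen)


def _evaluate(
    table: CohortTable,
    config: StudyConfig,
    recalibration,
    tag: str,
    n_boot: int,
) -> dict:
    """One full pass (both designs, all strategies) over a table."""
    sc = config.strategy_config(recalibration=recalibration)
    report: dict = {}
    if "cv" in config.designs:
        audits = {s: AuditTrail() for s in config.strategies}
        preds = run_cv(
            table, list(config.strategies), k=config.k, config=sc,
            n_imputation_iterations=config.n_imputation_iterations,
            seed=stage_seed(config.master_seed, f"cv:{tag}"), audits=audits,
        )
        cv: dict = {}
        for s, ps in preds.items():
            cv[s] = (
                summarize_cv_local(ps, seed=stage_seed(config.master_seed, f"cvm:{s}"))
                if s == "local"
                else summarize_cv(ps, seed=stage_seed(config.master_seed, f"cvm:{s}"))
            )
            cv[s]["sharing_ledger"] = audit_sharing(audits[s]).as_dict()
        cv["comparisons"] = _pairwise_comparisons(
            preds, stage_seed(config.master_seed, f"boot:{tag}"), n_boot
        )
        report["cv"] = cv
        report["_cv_predictions"] = preds
    if "lcoa" in config.designs:
        lcoa_strats = [s for s in config.strategies if s in LCOA_STRATEGIES]
        if lcoa_strats and len(table.hospitals()) >= 2:
            audits = {s: AuditTrail() for s in lcoa_strats}
            preds = run_lcoa(
                table, lcoa_strats, config=sc,
                n_imputation_iterations=config.n_imputation_iterations,
                seed=stage_seed(config.master_seed, f"lcoa:{tag}"), audits=audits,
            )
            lcoa: dict = {}
            for s, per_hosp in preds.items():
                lcoa[s] = summarize_lcoa(per_hosp, seed=stage_seed(config.master_seed, f"lm:{s}"))
                lcoa[s]["sharing_ledger"] = audit_sharing(audits[s]).as_dict()
            report["lcoa"] = lcoa
    return report


def fit_final_models(
    table: CohortTable, config: StudyConfig
) -> dict:
    """Fit each strategy's final model on the complete (imputed) dataset and
    report the selected variables per strategy."""
    table, excluded = filter_variables(table)
    out: dict = {"excluded_variables": excluded, "models": {}, "selected_variables": {}}
    sc = config.strategy_config()
    seed = stage_seed(config.master_seed, "final")
    for s in config.strategies:
        scope = "pooled" if s == "central" else "per_center"
        imp = impute(table, ImputationPlan(
            scope=scope, n_iterations=config.n_imputation_iterations,
            use_outcome=True, seed=seed,
        ))
        try:
            model = build_strategy(s, imp, sc)
        except FitFailure as exc:
            out["models"][s] = {"error": str(exc)}
            continue
        if s == "central":
            out["models"][s] = model.model.to_json()
            out["selected_variables"][s] = model.model.selected_variables
        elif s == "fedavg":
            out["models"][s] = model.model.to_json()
            out["selected_variables"][s] = model.model.selected_variables
        elif s == "local":
            out["models"][s] = {c: m.to_json() for c, m in model.model.items()}
            out["models"][s + "_unfittable"] = model.failures
            out["selected_variables"][s] = {
                c: m.selected_variables for c, m in model.model.items()
            }
        else:  # ensemble
            out["models"][s] = {
                "members": {c: m.to_json() for c, m in model.model.members.items()},
                "weights": model.model.weights,
                "recalibration": model.model.recalibration.to_json()
                if model.model.recalibration else None,
            }
            out["selected_variables"][s] = sorted(
                {v for m in model.model.members.values() for v in m.selected_variables}
            )
    out["n_selected"] = {
        s: (len(v) if isinstance(v, list) else {c: len(vs) for c, vs in v.items()})
        for s, v in out["selected_variables"].items()
    }
    return out


def run_study(config: StudyConfig, n_boot: int = 500) -> dict:
    """Execute the full study design and return (and optionally write) the
    report bundle."""
    table = _load_table(config)
    report: dict = {
        "config": _config_json(config),
        "dataset": {
            "n": table.n,
            "n_hospitals": len(table.hospitals()),
            "prevalence": float(table.outcome.mean()),
        },
    }

    main = _evaluate(table, config, config.recalibration, "main", n_boot)
    cv_preds = main.pop("_cv_predictions", None)
    report["main"] = main

    sensitivity: dict = {}
    if config.sensitivity_no_recalibration and any(
        s in config.strategies for s in ("fedavg", "ensemble")
    ):
        sub = replace(
            config,
            strategies=tuple(s for s in config.strategies if s in ("fedavg", "ensemble")),
        )
        res = _evaluate(table, sub, None, "main", n_boot)
        res.pop("_cv_predictions", None)
        sensitivity["no_recalibration"] = res
    if config.sensitivity_exclude_low_volume and "year" in table.data.columns:
        flags = flag_low_volume(yearly_counts_from_table(table))
        keep = [h for h, low in flags.items() if not low]
        if len(keep) >= 2 and len(keep) < len(table.hospitals()):
            reduced = table.subset(table.data["hospital_id"].isin(keep))
            res = _evaluate(table=reduced, config=config,
                            recalibration=config.recalibration,
                            tag="exclude_low_volume", n_boot=n_boot)
            res.pop("_cv_predictions", None)
            sensitivity["exclude_low_volume"] = {
                "flags": flags, "excluded": sorted(set(flags) - set(keep)), **res,
            }
    report["sensitivity"] = sensitivity

    if config.fit_final:
        final = fit_final_models(table, config)
        report["final_models"] = final

    if config.out_dir:
        _write_bundle(report, cv_preds, config)
    return report


def _config_json(config: StudyConfig) -> dict:
    d = asdict(config)
    return d


def _write_bundle(report: dict, cv_preds, config: StudyConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if cv_preds:
        for s, ps in cv_preds.items():
            ps.to_csv(out / f"cv_predictions_{s}.csv")
        _calibration_plot(cv_preds, out / "calibration_cv.png")


def _calibration_plot(cv_preds: dict[str, PredictionSet], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for s, ps in sorted(cv_preds.items()):
        if not len(ps.data):
            continue
        curve = M.calibration_curve(ps.p, ps.y, trim_top=0.025)
        ax.plot(curve["mean_pred"], curve["event_rate"], marker="o", label=s)
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="ideal")
    ax.set_xlabel("predicted probability (top 2.5% trimmed)")
    ax.set_ylabel("observed event rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
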