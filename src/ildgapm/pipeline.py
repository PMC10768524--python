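"""End-to-end analysis pipeline: score, stratify, fit, compare, export.

Reproduces the structure of a prognostic-model evaluation on one cohort:

1. score every subject under ILD-GAP and ILD-GAPM;
2. univariate Cox screens of candidate predictors, split into IPF and
   non-IPF strata;
3. Kaplan-Meier curves with log-rank tests stratified by monocyte group,
   honeycombing, or model stage, in the full cohort and in the IPF,
   non-IPF and low-DLco subpopulations;
4. a paired comparison of ILD-GAP vs ILD-GAPM by time-dependent AUC,
   Harrell's C and Cox AIC, both models evaluated on the identical
   subject set with identical bootstrap resamples.

Significance is reported at unadjusted two-sided P < 0.05, matching the
descriptive screening style of the source setting; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import Cohort, Diagnosis, SchemaError
from .scoring import MONOCYTE_CUT, score_dataframe
from .survival import (
    ConvergenceError,
    CoxFit,
    KmCurve,
    LogrankResult,
    bootstrap_normal_ci,
    cox_fit_univariate,
    harrell_c,
    km_estimate,
    logrank_test,
    td_auc_ipcw,
)

__all__ = [
    "AnalysisPlan",
    "ModelComparison",
    "score_cohort",
    "run_univariate_screen",
    "run_stratified_km",
    "compare_models",
    "run_report",
]

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.05

#: Default univariate screen: candidate predictors of the 3-year event.
DEFAULT_PREDICTORS = (
    "age",
    "sex",
    "ccis",
    "monocyte_ratio",
    "honeycomb_score",
    "ggo_score",
    "ild_gap_score",
    "fvc_pct_pred",
    "dlco_pct_pred",
)

STRATIFIERS = ("monocyte", "honeycomb", "ild_gap_stage", "ild_gapm_stage")
POPULATIONS = ("all", "IPF", "non_IPF", "low_dlco")


@dataclass(frozen=True)
class AnalysisPlan:
    """Tunable settings of the evaluation pipeline.

    ``monocyte_cut`` is the fixed 8.5% dichotomisation constant by
    default; the string ``"median"`` recomputes the split from the cohort
    at hand (sensitivity-analysis mode).  ``dlco_subgroup_threshold`` is a
    fixed percent-predicted bound for the low-diffusing-capacity
    subgroup.  ``score_scale`` selects the Cox covariate used for AIC and
    discrimination: the integer total score (``"continuous"``) or its
    ordinal stage number (``"stage"``).
    """

    monocyte_cut: Union[float, str] = MONOCYTE_CUT
    dlco_subgroup_threshold: float = 90.0
    horizon_days: float = 1095.0
    bootstrap_resamples: int = 2000
    seed: int = 0
    predictors: tuple = DEFAULT_PREDICTORS
    score_scale: str = "continuous"
    use_monocyte_count: bool = False

    def validate(self) -> None:
        if isinstance(self.monocyte_cut, str):
            if self.monocyte_cut != "median":
                raise SchemaError(
                    f"monocyte_cut: expected a number or 'median', got {self.monocyte_cut!r}"
                )
        elif self.monocyte_cut <= 0:
            raise SchemaError(f"monocyte_cut: must be positive, got {self.monocyte_cut}")
        if self.dlco_subgroup_threshold <= 0:
            raise SchemaError(
                f"dlco_subgroup_threshold: must be positive, got {self.dlco_subgroup_threshold}"
            )
        if self.horizon_days <= 0:
            raise SchemaError(f"horizon_days: must be positive, got {self.horizon_days}")
        if self.bootstrap_resamples < 0:
            raise SchemaError(
                f"bootstrap_resamples: must be >= 0, got {self.bootstrap_resamples}"
            )
        if not self.predictors:
            raise SchemaError("predictors: list must be non-empty")
        if self.score_scale not in ("continuous", "stage"):
            raise SchemaError(
                f"score_scale: expected 'continuous' or 'stage', got {self.score_scale!r}"
            )


def resolve_monocyte_cut(cohort: Cohort, plan: AnalysisPlan) -> float:
    if plan.monocyte_cut == "median":
        cut = float(cohort.data["monocyte_ratio"].median())
        logger.info("monocyte cut: cohort median %.2f%%", cut)
        return cut
    return float(plan.monocyte_cut)


def score_cohort(cohort: Cohort, plan: Optional[AnalysisPlan] = None) -> Cohort:
    """Score every subject; returns a new Cohort with score columns appended."""
    plan = plan or AnalysisPlan()
    cut = resolve_monocyte_cut(cohort, plan)
    return cohort.copy_with(score_dataframe(cohort.data, monocyte_cut=cut))


def _analysis_frame(cohort: Cohort) -> pd.DataFrame:
    """Rows usable for survival analysis (positive follow-up), with a log."""
    df = cohort.data
    usable = df["followup_days"] > 0
    dropped = int((~usable).sum())
    if dropped:
        logger.warning("excluding %d subject(s) with zero follow-up", dropped)
    return df.loc[usable].reset_index(drop=True)


def _strata(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    is_ipf = df["diagnosis"] == Diagnosis.IPF.value
    return {"IPF": df.loc[is_ipf], "non_IPF": df.loc[~is_ipf]}


def run_univariate_screen(cohort: Cohort, plan: Optional[AnalysisPlan] = None) -> pd.DataFrame:
    """Univariate Cox screen of each candidate predictor, by IPF stratum.

    Returns one row per (stratum, predictor) with the hazard ratio, 95%
    CI, Wald P and a significance flag at P < 0.05.  Strata without
    events, missing columns and constant predictors are skipped with a
    logged warning rather than failing the screen.
    """
    plan = plan or AnalysisPlan()
    plan.validate()
    scored = score_cohort(cohort, plan)
    df = _analysis_frame(scored)
    predictors = list(plan.predictors)
    if plan.use_monocyte_count and "monocyte_ratio" in predictors:
        predictors[predictors.index("monocyte_ratio")] = "monocyte_count"
    rows = []
    for stratum, sub in _strata(df).items():
        if len(sub) == 0 or sub["event"].sum() == 0:
            logger.warning("univariate screen: stratum %s has no events, skipped", stratum)
            continue
        times = sub["followup_days"].to_numpy(dtype=float)
        events = sub["event"].to_numpy(dtype=bool)
        for name in predictors:
            if name not in sub.columns:
                logger.warning("univariate screen: column %r absent, skipped", name)
                continue
            if name == "sex":
                x = (sub["sex"] == "male").astype(float).to_numpy()
            else:
                x = pd.to_numeric(sub[name], errors="coerce").to_numpy(dtype=float)
            keep = np.isfinite(x)
            if keep.sum() < len(x):
                logger.warning(
                    "univariate screen: %s/%s: %d subject(s) without a value excluded",
                    stratum, name, int((~keep).sum()),
                )
            if keep.sum() == 0 or events[keep].sum() == 0:
                logger.warning(
                    "univariate screen: %s/%s has no usable events, skipped", stratum, name
                )
                continue
            try:
                fit = cox_fit_univariate(times[keep], events[keep], x[keep])
            except (ValueError, ConvergenceError) as exc:
                logger.warning("univariate screen: %s/%s skipped: %s", stratum, name, exc)
                continue
            rows.append(
                {
                    "stratum": stratum,
                    "predictor": name,
                    "hazard_ratio": fit.hazard_ratio,
                    "ci_lower": fit.ci_lower,
                    "ci_upper": fit.ci_upper,
                    "p_value": fit.p_value,
                    "significant": fit.p_value < P_THRESHOLD,
                    "n": fit.n,
                    "n_events": fit.n_events,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum", "predictor", "hazard_ratio", "ci_lower", "ci_upper",
            "p_value", "significant", "n", "n_events",
        ],
    )


@dataclass
class StratifiedKm:
    population: str
    stratifier: str
    curves: dict  # label -> KmCurve
    logrank: LogrankResult
    n: int


def _stratifier_labels(df: pd.DataFrame, stratifier: str, cut: float) -> pd.Series:
    if stratifier == "monocyte":
        return pd.Series(
            np.where(df["monocyte_ratio"] > cut, "high", "low"), index=df.index
        )
    if stratifier == "honeycomb":
        hc = pd.to_numeric(df["honeycomb_score"], errors="coerce")
        return pd.Series(
            np.where(hc > 0, "present", "absent"), index=df.index
        ).where(hc.notna(), other=None)
    if stratifier in ("ild_gap_stage", "ild_gapm_stage"):
        return df[stratifier]
    raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")


def _population_mask(df: pd.DataFrame, population: str, plan: AnalysisPlan) -> pd.Series:
    if population == "all":
        return pd.Series(True, index=df.index)
    if population == "IPF":
        return df["diagnosis"] == Diagnosis.IPF.value
    if population == "non_IPF":
        return df["diagnosis"] != Diagnosis.IPF.value
    if population == "low_dlco":
        dlco = pd.to_numeric(df["dlco_pct_pred"], errors="coerce")
        return dlco <= plan.dlco_subgroup_threshold
    raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")


def km_by_stratum(df: pd.DataFrame, labels: pd.Series) -> tuple[dict, LogrankResult]:
    """KM curve per non-empty stratum plus the k-group log-rank test."""
    keep = labels.notna()
    df = df.loc[keep]
    labels = labels.loc[keep]
    counts = labels.value_counts()
    nonempty = [lab for lab in counts.index if counts[lab] > 0]
    if len(nonempty) < 2:
        raise ValueError(
            f"stratified KM needs >= 2 non-empty strata, found {len(nonempty)}"
        )
    times = df["followup_days"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=bool)
    curves = {}
    for lab in sorted(map(str, nonempty)):
        mask = (labels.astype(str) == lab).to_numpy()
        curves[lab] = km_estimate(times[mask], events[mask])
    lr = logrank_test(times, events, labels.astype(str).to_numpy())
    return curves, lr


def run_stratified_km(
    cohort: Cohort,
    plan: Optional[AnalysisPlan] = None,
    stratifier: str = "ild_gapm_stage",
    populations: tuple = POPULATIONS,
) -> dict[str, StratifiedKm]:
    """KM curves + log-rank per population for one stratifying variable.

    Populations where fewer than two strata are populated (or the test is
    undefined) are skipped with a warning; an error is raised only if no
    requested population can be analysed.
    """
    plan = plan or AnalysisPlan()
    plan.validate()
    scored = score_cohort(cohort, plan)
    df = _analysis_frame(scored)
    cut = resolve_monocyte_cut(cohort, plan)
    results: dict[str, StratifiedKm] = {}
    for population in populations:
        sub = df.loc[_population_mask(df, population, plan)]
        if len(sub) == 0:
            logger.warning("stratified KM: population %s empty, skipped", population)
            continue
        labels = _stratifier_labels(sub, stratifier, cut)
        try:
            curves, lr = km_by_stratum(sub, labels)
        except ValueError as exc:
            logger.warning("stratified KM: population %s skipped: %s", population, exc)
            continue
        results[population] = StratifiedKm(
            population=population,
            stratifier=stratifier,
            curves=curves,
            logrank=lr,
            n=len(sub),
        )
    if not results:
        raise ValueError(
            f"stratified KM by {stratifier!r}: no population had >= 2 usable strata"
        )
    return results


@dataclass
class ModelMetrics:
    auc: float
    auc_se: Optional[float]
    auc_ci: Optional[tuple]
    c_index: float
    c_index_se: Optional[float]
    c_index_ci: Optional[tuple]
    aic: float
    cox: CoxFit


@dataclass
class ModelComparison:
    """Paired ILD-GAP vs ILD-GAPM metrics on one subject set."""

    ild_gap: ModelMetrics
    ild_gapm: ModelMetrics
    n: int
    n_events: int
    horizon_days: float
    n_bootstrap: int
    seed: int
    winners: dict = field(default_factory=dict)


_STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _model_predictor(df: pd.DataFrame, model: str, scale: str) -> np.ndarray:
    col = "ild_gap_score" if model == "ild_gap" else "ild_gapm_score"
    if scale == "continuous":
        return df[col].to_numpy(dtype=float)
    stage_col = "ild_gap_stage" if model == "ild_gap" else "ild_gapm_stage"
    return df[stage_col].map(_STAGE_ORDINAL).to_numpy(dtype=float)


def compare_models(cohort: Cohort, plan: Optional[AnalysisPlan] = None) -> ModelComparison:
    """Paired evaluation of ILD-GAP vs ILD-GAPM on the identical subjects.

    Time-dependent AUC at the plan horizon, Harrell's C and Cox AIC (score
    as a single covariate on the plan's scale) are computed for both
    models; bootstrap CIs for AUC and C use the same seed, hence identical
    resample indices, so differences are paired.  ``bootstrap_resamples=0``
    skips the CIs (point estimates only).
    """
    plan = plan or AnalysisPlan()
    plan.validate()
    scored = score_cohort(cohort, plan)
    df = _analysis_frame(scored)
    times = df["followup_days"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=bool)

    metrics = {}
    for model in ("ild_gap", "ild_gapm"):
        pred = _model_predictor(df, model, plan.score_scale)
        auc_res = td_auc_ipcw(
            times,
            events,
            pred,
            horizon=plan.horizon_days,
            n_bootstrap=plan.bootstrap_resamples,
            seed=plan.seed,
            subject_ids=df["patient_id"].to_numpy(),
        )
        if plan.bootstrap_resamples > 0:
            c, c_se, c_ci, _ = bootstrap_normal_ci(
                harrell_c, times, events, pred,
                n_bootstrap=plan.bootstrap_resamples, seed=plan.seed,
            )
        else:
            c = harrell_c(times, events, pred)
            c_se, c_ci = None, None
        fit = cox_fit_univariate(times, events, pred)
        metrics[model] = ModelMetrics(
            auc=auc_res.auc,
            auc_se=auc_res.se,
            auc_ci=auc_res.ci,
            c_index=c,
            c_index_se=c_se,
            c_index_ci=c_ci,
            aic=fit.aic,
            cox=fit,
        )

    winners = {
        "auc": "ild_gapm" if metrics["ild_gapm"].auc > metrics["ild_gap"].auc
        else "ild_gap" if metrics["ild_gap"].auc > metrics["ild_gapm"].auc else "tie",
        "c_index": "ild_gapm" if metrics["ild_gapm"].c_index > metrics["ild_gap"].c_index
        else "ild_gap" if metrics["ild_gap"].c_index > metrics["ild_gapm"].c_index else "tie",
        "aic": "ild_gapm" if metrics["ild_gapm"].aic < metrics["ild_gap"].aic
        else "ild_gap" if metrics["ild_gap"].aic < metrics["ild_gapm"].aic else "tie",
    }
    return ModelComparison(
        ild_gap=metrics["ild_gap"],
        ild_gapm=metrics["ild_gapm"],
        n=len(df),
        n_events=int(events.sum()),
        horizon_days=plan.horizon_days,
        n_bootstrap=plan.bootstrap_resamples,
        seed=plan.seed,
        winners=winners,
    )


# ---------------------------------------------------------------------------
# Report writer


def _km_to_frame(curves: dict) -> pd.DataFrame:
    frames = []
    for label, curve in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "time_days": curve.times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "n_events": curve.n_events,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_report(
    cohort: Cohort,
    plan: Optional[AnalysisPlan] = None,
    outdir: Union[str, Path] = "results",
) -> dict:
    """Run the full analysis and write all artefacts under ``outdir``.

    Writes the scored cohort, the univariate screen table, the paired
    model comparison (JSON), one KM-curve table per stratifier, and a run
    log with the seed and settings.  Outputs are a deterministic function
    of (cohort, plan), so re-running regenerates them bit-identically.
    """
    from . import __version__
    from .io import write_cohort, write_metrics

    plan = plan or AnalysisPlan()
    plan.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scored = score_cohort(cohort, plan)
    write_cohort(scored, outdir / "scored_cohort.csv")

    screen = run_univariate_screen(cohort, plan)
    screen.to_csv(outdir / "univariate_screen.csv", index=False)

    km_summaries = {}
    for stratifier in STRATIFIERS:
        try:
            results = run_stratified_km(cohort, plan, stratifier=stratifier)
        except ValueError as exc:
            logger.warning("report: stratifier %s skipped: %s", stratifier, exc)
            continue
        for population, res in results.items():
            _km_to_frame(res.curves).to_csv(
                outdir / f"km_{stratifier}_{population}.csv", index=False
            )
            km_summaries[f"{stratifier}/{population}"] = {
                "n": res.n,
                "logrank_statistic": res.logrank.statistic,
                "logrank_df": res.logrank.df,
                "logrank_p": res.logrank.p_value,
            }

    comparison = compare_models(cohort, plan)
    write_metrics(
        {
            "model_comparison": {
                "ild_gap": asdict(comparison.ild_gap),
                "ild_gapm": asdict(comparison.ild_gapm),
                "winners": comparison.winners,
                "n": comparison.n,
                "n_events": comparison.n_events,
                "horizon_days": comparison.horizon_days,
                "n_bootstrap": comparison.n_bootstrap,
            },
            "km_logrank": km_summaries,
        },
        outdir / "model_comparison.json",
        seed=plan.seed,
    )

    run_log = {
        "package_version": __version__,
        "plan": asdict(plan),
        "cohort_provenance": cohort.provenance,
        "n_subjects": len(cohort),
    }
    write_metrics(run_log, outdir / "run_log.json", seed=plan.seed)
    return {
        "screen": screen,
        "comparison": comparison,
        "km": km_summaries,
        "outdir": str(outdir),
    }
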