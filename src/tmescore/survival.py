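"""Kaplan–Meier, log-rank, reverse-KM follow-up and Cox proportional hazards.

Cohort filtering follows the study design: deaths within 30 days of surgery
are post-operative and excluded before any survival model.  Times are in
years from surgery; disease-specific survival (DSS) treats non-cancer deaths
as censorings (cause-specific convention), overall survival (OS) counts any
death.  Cox models use Efron tie handling (lifelines' default) with Wald
confidence intervals; categorical covariates are dummy-coded against an
explicit reference level, and a non-reference level with zero events is
reported as "No event" and removed from the partial likelihood rather than
fitted to an infinite coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

POSTOP_WINDOW_YEARS = 30.0 / 365.25

OUTCOME_COLUMNS = {
    "DSS": ("dss_time", "dss_event"),
    "OS": ("os_time", "os_event"),
}


class ModelConvergenceError(RuntimeError):
    """Cox partial-likelihood fit failed to converge (e.g. separation)."""


class DegenerateModelError(ValueError):
    """A covariate has fewer than two observed levels."""


def exclude_postoperative(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records flagged as post-operative deaths (death ≤ 30 days).

    Returns the filtered cohort and the number of records removed.
    """
    flag = cohort["postoperative_death"].astype(bool)
    return cohort.loc[~flag].copy(), int(flag.sum())


@dataclass
class KMEstimate:
    """Product-limit survival estimate with step coordinates and risk table."""

    times: np.ndarray
    survival: np.ndarray
    fitter: KaplanMeierFitter

    def survival_at(self, t) -> np.ndarray:
        return self.fitter.survival_function_at_times(t).to_numpy()

    def steps(self) -> pd.DataFrame:
        """Step coordinates (time, survival) for plotting or export."""
        return pd.DataFrame({"time": self.times, "survival": self.survival})

    def risk_table(self) -> pd.DataFrame:
        return self.fitter.event_table.reset_index()


def km_estimate(times, events, label: str = "KM") -> KMEstimate:
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int), label=label)
    sf = kmf.survival_function_
    return KMEstimate(sf.index.to_numpy(dtype=float), sf[label].to_numpy(), kmf)


@dataclass(frozen=True)
class FollowUpEstimate:
    median_years: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.median_years)


def reverse_km_median_followup(times, os_events) -> FollowUpEstimate:
    """Median follow-up by the reverse Kaplan–Meier technique.

    Censoring indicators are flipped — deaths become censorings — so the KM
    curve estimates the follow-up-time distribution; the median is the first
    time it drops to ≤ 0.5, with a log-log (exponential Greenwood) 95% CI.
    A cohort where everyone died has no follow-up information: the reversed
    curve never drops and the estimate is flagged undefined (inf median).
    """
    t = np.asarray(times, dtype=float)
    e = 1 - np.asarray(os_events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label="followup")
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return FollowUpEstimate(median, lo, hi)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(groups, times, events) -> LogrankResult:
    """k-sample log-rank test across the levels of ``groups``."""
    g = pd.Series(groups)
    ok = g.notna().to_numpy()
    g = g[ok]
    levels = g.unique()
    if len(levels) < 2:
        raise DegenerateModelError("log-rank test needs at least two groups")
    t = np.asarray(times, dtype=float)[ok]
    e = np.asarray(events, dtype=int)[ok]
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return LogrankResult(float(res.test_statistic), len(levels) - 1, float(res.p_value))


@dataclass(frozen=True)
class CovariateSpec:
    """One model term: a categorical column and its reference level."""

    name: str
    reference: str
    levels: tuple[str, ...] | None = None  # display order; observed order if None


@dataclass
class SurvivalFit:
    """Fitted hazard ratios for one named model specification."""

    label: str
    outcome: str
    table: pd.DataFrame  # variable, level, n, events, hr, ci_low, ci_high, p, note
    n: int
    n_events: int
    model: CoxPHFitter | None = None


def _dummy_name(name: str, level: str) -> str:
    return f"{name}::{level}"


def cox_fit(
    cohort: pd.DataFrame,
    covariates: Sequence[CovariateSpec],
    outcome: str = "DSS",
    label: str | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs) for one model spec.

    The caller is expected to have applied the post-operative exclusion.
    Rows with any missing covariate are dropped.  Non-reference levels with
    zero events are reported as "No event" and their subjects removed from
    the likelihood.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {tuple(OUTCOME_COLUMNS)}")
    time_col, event_col = OUTCOME_COLUMNS[outcome]
    cols = [c.name for c in covariates]
    df = cohort[[time_col, event_col, *cols]].dropna().copy()
    df[event_col] = df[event_col].astype(int)

    no_event_levels: list[tuple[str, str]] = []
    level_lists: dict[str, list[str]] = {}
    for spec in covariates:
        observed = list(pd.unique(df[spec.name].astype(str)))
        if len(observed) < 2:
            raise DegenerateModelError(
                f"covariate {spec.name!r} has a single observed level {observed}"
            )
        if spec.reference not in observed:
            raise ValueError(
                f"reference level {spec.reference!r} not observed for {spec.name!r}"
            )
        levels = [l for l in (spec.levels or observed) if l in observed]
        level_lists[spec.name] = levels
        for lv in levels:
            if lv == spec.reference:
                continue
            sel = df[spec.name].astype(str) == lv
            if int(df.loc[sel, event_col].sum()) == 0:
                no_event_levels.append((spec.name, lv))
                df = df.loc[~sel]

    design = df[[time_col, event_col]].copy()
    level_meta: list[tuple[str, str, str]] = []  # (variable, level, note)
    for spec in covariates:
        values = df[spec.name].astype(str)
        level_meta.append((spec.name, spec.reference, "ref"))
        for lv in level_lists[spec.name]:
            if lv == spec.reference:
                continue
            if (spec.name, lv) in no_event_levels:
                level_meta.append((spec.name, lv, "no event"))
                continue
            design[_dummy_name(spec.name, lv)] = (values == lv).astype(float)
            level_meta.append((spec.name, lv, ""))

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=time_col, event_col=event_col)
    except (_LLConvergenceError, np.linalg.LinAlgError) as exc:
        raise ModelConvergenceError(
            f"Cox model {label or cols} ({outcome}) failed to converge: {exc}"
        ) from exc

    summary = cph.summary
    rows = []
    for var, lv, note in level_meta:
        if note == "ref":
            sel = cohort[[time_col, event_col, *cols]].dropna()
            sel = sel[sel[var].astype(str) == lv]
            rows.append(
                dict(variable=var, level=lv, n=len(sel),
                     events=int(sel[event_col].sum()),
                     hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan, note="ref")
            )
            continue
        sel = cohort[[time_col, event_col, *cols]].dropna()
        sel = sel[sel[var].astype(str) == lv]
        if note == "no event":
            rows.append(
                dict(variable=var, level=lv, n=len(sel), events=0,
                     hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                     note="No event")
            )
            continue
        key = _dummy_name(var, lv)
        s = summary.loc[key]
        rows.append(
            dict(variable=var, level=lv, n=len(sel),
                 events=int(sel[event_col].sum()),
                 hr=float(s["exp(coef)"]),
                 ci_low=float(s["exp(coef) lower 95%"]),
                 ci_high=float(s["exp(coef) upper 95%"]),
                 p=float(s["p"]), note="")
        )

    return SurvivalFit(
        label=label or "+".join(cols),
        outcome=outcome,
        table=pd.DataFrame(rows),
        n=len(design),
        n_events=int(design[event_col].sum()),
        model=cph,
    )


# Covariate specifications mirroring the published univariable battery and the
# four multivariable models (one immune factor each, adjusted for comorbidity
# burden, TNM stage, tumor necrosis and intratumoral stroma).
UNIVARIABLE_SPECS: dict[str, CovariateSpec] = {
    "sex": CovariateSpec("sex", "female"),
    "cci": CovariateSpec("cci_group", "1-2", ("1-2", "3-4", ">=5")),
    "location": CovariateSpec("location", "left"),
    "t_stage": CovariateSpec("t_stage", "3", ("1", "2", "3", "4")),
    "n_stage": CovariateSpec("n_stage", "0", ("0", "1", "2")),
    "tnm": CovariateSpec("tnm_group", "I-II", ("I-II", "III", "IV")),
    "adjuvant": CovariateSpec("adjuvant", "no"),
    "lvi": CovariateSpec("lvi", "no"),
    "budding": CovariateSpec("budding_group", "0-4", ("0-4", "5-9", ">=10")),
    "grade": CovariateSpec("grade", "low"),
    "braf": CovariateSpec("braf", "yes"),
    "necrosis": CovariateSpec("necrosis_group", "<10%", ("<10%", "10-<40%", ">=40%")),
    "stroma": CovariateSpec("stroma_group", "<50%", ("<50%", ">=50%")),
    "clr": CovariateSpec("clr_category", "high", ("low", "high")),
    "proximity": CovariateSpec(
        "proximity_score", "high", ("low", "intermediate", "high")
    ),
    "pdl1_mac_ct": CovariateSpec(
        "pdl1_mac_ct_tertile", "high", ("low", "moderate", "high")
    ),
    "pdl1_mac_im": CovariateSpec(
        "pdl1_mac_im_tertile", "high", ("low", "moderate", "high")
    ),
}

ADJUSTMENT_SPECS: tuple[CovariateSpec, ...] = (
    UNIVARIABLE_SPECS["cci"],
    UNIVARIABLE_SPECS["tnm"],
    UNIVARIABLE_SPECS["necrosis"],
    UNIVARIABLE_SPECS["stroma"],
)

MULTIVARIABLE_IMMUNE_FACTORS: tuple[str, ...] = (
    "clr", "proximity", "pdl1_mac_ct", "pdl1_mac_im"
)


def tnm_group(tnm_stage: pd.Series) -> pd.Series:
    """Collapse TNM stage I/II into the reference group I-II."""
    return tnm_stage.map(
        lambda s: s if pd.isna(s) else ("I-II" if s in ("I", "II") else str(s))
    )


def run_model_battery(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = ("DSS", "OS"),
    univariable: Sequence[str] | None = None,
    multivariable: Sequence[str] | None = None,
    strict: bool = False,
) -> dict[str, SurvivalFit]:
    """Run the univariable battery plus the four adjusted immune-factor models.

    ``cohort`` must already be merged with the score table and post-operative
    deaths excluded; a ``tnm_group`` column is derived from ``tnm_stage`` if
    absent.  Models whose covariates are absent from the cohort are skipped
    (unless ``strict``), so partial cohorts still analyse cleanly.
    """
    df = cohort.copy()
    if "tnm_group" not in df.columns and "tnm_stage" in df.columns:
        df["tnm_group"] = tnm_group(df["tnm_stage"])

    fits: dict[str, SurvivalFit] = {}

    def _try(key: str, specs: Sequence[CovariateSpec], outcome: str) -> None:
        missing = [s.name for s in specs if s.name not in df.columns]
        if missing:
            if strict:
                raise KeyError(f"model {key}: missing columns {missing}")
            return
        try:
            fits[key] = cox_fit(df, specs, outcome=outcome, label=key)
        except (ModelConvergenceError, DegenerateModelError, ValueError):
            # tiny or degenerate cohorts: skip the model unless strict
            if strict:
                raise

    uni = univariable if univariable is not None else tuple(UNIVARIABLE_SPECS)
    multi = (
        multivariable if multivariable is not None else MULTIVARIABLE_IMMUNE_FACTORS
    )
    for outcome in outcomes:
        for name in uni:
            _try(f"uni:{name}:{outcome}", (UNIVARIABLE_SPECS[name],), outcome)
        for name in multi:
            specs = (UNIVARIABLE_SPECS[name], *ADJUSTMENT_SPECS)
            _try(f"multi:{name}:{outcome}", specs, outcome)
    return fits
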