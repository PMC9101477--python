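"""Overall-survival models: Cox regression, Kaplan-Meier, log-rank.

Cox fits use the Efron approximation for tied event times (registry survival
is recorded in months, so ties are heavy). Kaplan-Meier summaries carry
Greenwood-variance confidence bands, the median with its CI from the band
crossings, and the five-year (60-month) survival read directly off the step
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

from .cohort import analysis_view
from .curves import RatioCurve, bin_eln_levels

__all__ = [
    "CoxFit",
    "SurvivalSummary",
    "LogrankResult",
    "fit_cox_continuous",
    "per_count_hr_curve",
    "km_estimate",
    "logrank_test",
    "km_compare_at_cutoff",
]

_Z95 = stats.norm.ppf(0.975)
FIVE_YEARS = 60.0  # months; read off the KM step function, no interpolation


@dataclass
class CoxFit:
    """Continuous-ELN Cox fit within a nodal stratum."""

    hr_per_eln: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    events: int
    stratum: str
    coefficients: dict[str, tuple[float, float]]
    coding: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.hr_per_eln > 0 and self.ci95[0] <= self.hr_per_eln <= self.ci95[1]
        assert self.events <= self.n_used

    def to_dict(self) -> dict:
        return {
            "hr_per_eln": self.hr_per_eln,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n_used": self.n_used,
            "events": self.events,
            "stratum": self.stratum,
            "coefficients": {k: list(v) for k, v in self.coefficients.items()},
            "coding": self.coding,
        }


@dataclass
class SurvivalSummary:
    """Kaplan-Meier summary for one group."""

    label: str
    curve: pd.DataFrame  # time, surv, ci_low, ci_high, at_risk
    median_months: float  # inf when not reached
    median_ci95: tuple[float, float]
    survival_at_60mo: float
    survival_at_60mo_ci95: tuple[float, float]
    n: int
    events: int

    def to_dict(self) -> dict:
        def _num(x):
            return None if not np.isfinite(x) else float(x)

        return {
            "label": self.label,
            "n": self.n,
            "events": self.events,
            "median_months": _num(self.median_months),
            "median_ci95": [_num(v) for v in self.median_ci95],
            "survival_at_60mo": self.survival_at_60mo,
            "survival_at_60mo_ci95": [float(v) for v in self.survival_at_60mo_ci95],
        }


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"chi_square": self.chi_square, "df": self.df, "p_value": self.p_value}


def _stratum_subset(df: pd.DataFrame, stratum: str | None) -> pd.DataFrame:
    if stratum is None:
        return df
    if stratum == "node-negative":
        return df[df["observed_n_stage"] == "N0"]
    if stratum == "node-positive":
        return df[df["observed_n_stage"] != "N0"]
    raise ValueError(f"unknown stratum {stratum!r}")


def _check_times(df: pd.DataFrame) -> None:
    t = df["survival_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("survival_months must be finite and non-negative")


def _cox(df: pd.DataFrame, covariate_cols: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(
        df[["survival_months", "death_event"] + covariate_cols],
        duration_col="survival_months",
        event_col="death_event",
    )
    return cph


def _with_t_dummies(df: pd.DataFrame, adjust: Sequence[str]) -> tuple[pd.DataFrame, list[str], dict]:
    cols: list[str] = []
    coding: dict = {}
    out = df.copy()
    if "t_stage" in adjust:
        cats = sorted(df["t_stage"].unique())
        ref = "T3" if "T3" in cats else cats[0]
        for c in cats:
            if c == ref:
                continue
            name = f"t_stage[{c}]"
            out[name] = (df["t_stage"] == c).astype(float)
            cols.append(name)
        coding["t_stage_reference"] = ref
    return out, cols, coding


def fit_cox_continuous(
    records: pd.DataFrame,
    stratum: str | None = None,
    adjust: Sequence[str] = ("t_stage",),
    histology: str | None = None,
) -> CoxFit:
    """Cox PH fit of overall survival on the continuous ELN count.

    Restricted to a nodal stratum ("node-negative": observed N0;
    "node-positive": observed N1-N3) when given, adjusted for T stage by
    default, Efron tie handling. Returns the hazard ratio per additional
    examined node with a 95% Wald CI.
    """
    df = analysis_view(records)
    if histology is not None:
        df = df[df["histology"] == histology]
    df = _stratum_subset(df, stratum)
    df = df[df["eln_count"] >= 1]
    _check_times(df)
    events = int(df["death_event"].sum())
    if events == 0:
        raise ValueError("no events in stratum; Cox model is not identifiable")
    df, tcols, coding = _with_t_dummies(df, adjust)
    df = df.assign(eln_count=df["eln_count"].astype(float))
    cph = _cox(df, ["eln_count"] + tcols)
    beta = float(cph.params_["eln_count"])
    se = float(cph.standard_errors_["eln_count"])
    return CoxFit(
        hr_per_eln=float(np.exp(beta)),
        ci95=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        n_used=int(len(df)),
        events=events,
        stratum=stratum or "all",
        coefficients={
            k: (float(cph.params_[k]), float(cph.standard_errors_[k]))
            for k in cph.params_.index
        },
        coding={**coding, "ties": "efron", "adjust": list(adjust)},
    )


def per_count_hr_curve(
    records: pd.DataFrame,
    stratum: str | None = None,
    reference_count: int = 16,
    adjust: Sequence[str] = ("t_stage",),
    max_level: int = 60,
    min_per_level: int = 20,
) -> RatioCurve:
    """Hazard ratio of each ELN count >= the reference vs the reference.

    Only patients with ELN count >= ``reference_count`` enter; levels are
    dummy-coded in one Cox fit with sparse-level merging as in the OR curve.
    """
    df = analysis_view(records)
    df = _stratum_subset(df, stratum)
    df = df[df["eln_count"] >= reference_count]
    if len(df) == 0:
        raise ValueError("no records at or above the reference count")
    _check_times(df)
    if int(df["death_event"].sum()) == 0:
        raise ValueError("no events at or above the reference count")
    bin_id, rep, merges = bin_eln_levels(
        df["eln_count"].to_numpy(), reference_count, max_level, min_per_level,
        min_count=reference_count,
    )
    ref_idx = int(np.argmin(np.abs(rep - reference_count)))
    n_levels = len(rep)
    n_per = np.bincount(bin_id, minlength=n_levels)
    df = df.copy()
    dummy_levels = [i for i in range(n_levels) if i != ref_idx]
    names = []
    for i in dummy_levels:
        name = f"level[{rep[i]:g}]"
        df[name] = (bin_id == i).astype(float)
        names.append(name)
    df, tcols, _ = _with_t_dummies(df, adjust)
    cph = _cox(df, names + tcols)
    log_hr = np.zeros(n_levels)
    se = np.zeros(n_levels)
    for name, i in zip(names, dummy_levels):
        log_hr[i] = float(cph.params_[name])
        se[i] = float(cph.standard_errors_[name])
    return RatioCurve(
        reference_count=reference_count,
        levels=rep,
        ratio=np.exp(log_hr),
        ci_low=np.exp(log_hr - _Z95 * se),
        ci_high=np.exp(log_hr + _Z95 * se),
        n_per_level=n_per,
        scale="hazard-ratio",
        log_ratio=log_hr,
        se_log=se,
        merges=merges,
    )


def km_estimate(records: pd.DataFrame, label: str = "all") -> SurvivalSummary:
    """Product-limit survival estimate with Greenwood confidence bands.

    The median CI comes from where the confidence band crosses 0.5
    (Brookmeyer-Crowley-style inversion); five-year survival is the step
    function's value at 60 months. A median that is never reached is
    reported as ``inf``.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate survival on an empty cohort")
    _check_times(records)
    t = records["survival_months"].to_numpy(dtype=float)
    e = records["death_event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label)
    ci = kmf.confidence_interval_
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "surv": kmf.survival_function_[label].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index
            ).to_numpy(),
        }
    )
    med = float(kmf.median_survival_time_)
    med_ci = median_survival_times(ci)
    med_lo, med_hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    s60 = float(kmf.predict(FIVE_YEARS))
    ci_at = ci.asof(FIVE_YEARS) if FIVE_YEARS >= ci.index[0] else ci.iloc[0]
    return SurvivalSummary(
        label=label,
        curve=curve,
        median_months=med,
        median_ci95=(med_lo, med_hi),
        survival_at_60mo=s60,
        survival_at_60mo_ci95=(float(ci_at.iloc[0]), float(ci_at.iloc[1])),
        n=int(len(records)),
        events=int(e.sum()),
    )


def logrank_test(groups: Sequence[pd.DataFrame]) -> LogrankResult:
    """Log-rank test across two or more groups (chi-square, df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    t = np.concatenate([g["survival_months"].to_numpy(dtype=float) for g in groups])
    e = np.concatenate([g["death_event"].to_numpy(dtype=int) for g in groups])
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(t, labels, e)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=int(len(groups) - 1),
        p_value=float(res.p_value),
    )


def km_compare_at_cutoff(
    records: pd.DataFrame, cutoff: int, stratum: str | None = None
) -> tuple[SurvivalSummary, SurvivalSummary, LogrankResult]:
    """KM validation of a cutoff: >=cutoff vs <cutoff with a log-rank test."""
    df = analysis_view(records)
    df = _stratum_subset(df, stratum)
    above = df[df["eln_count"] >= cutoff]
    below = df[df["eln_count"] < cutoff]
    if len(above) == 0 or len(below) == 0:
        raise ValueError(f"cutoff {cutoff} produces a one-sided split")
    s_above = km_estimate(above, label=f"ELN>={cutoff}")
    s_below = km_estimate(below, label=f"ELN<{cutoff}")
    lr = logrank_test([above, below])
    return s_above, s_below, lr
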