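"""Nodal stage migration vs ELN count: logistic models.

Stage migration is quantified two ways, mirroring standard registry
practice: (i) a continuous-ELN logistic model of observed nodal positivity
adjusted for T stage, whose exponentiated ELN coefficient is the odds ratio
per additional examined node; and (ii) a per-count OR curve with dummy-coded
ELN levels against a reference count (one examined node), the input to the
cutpoint analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import analysis_view
from .curves import RatioCurve, bin_eln_levels

__all__ = ["LogisticFit", "fit_continuous_or", "per_count_or_curve"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class LogisticFit:
    """Continuous-ELN logistic fit of observed nodal positivity."""

    or_per_eln: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, se)
    coding: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.ci95
        assert lo <= self.or_per_eln <= hi and self.or_per_eln > 0

    def to_dict(self) -> dict:
        return {
            "or_per_eln": self.or_per_eln,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n_used": self.n_used,
            "coefficients": {k: list(v) for k, v in self.coefficients.items()},
            "coding": self.coding,
        }


def _prepare(records: pd.DataFrame, histology: str | None) -> tuple[pd.DataFrame, dict]:
    """Analysis view, histology subset, and the zero-ELN drop (logged)."""
    df = analysis_view(records)
    if histology is not None:
        df = df[df["histology"] == histology]
        if len(df) == 0:
            raise ValueError(f"empty subset for histology {histology!r}")
    n_zero = int((df["eln_count"] < 1).sum())
    df = df[df["eln_count"] >= 1]
    return df, {"n_dropped_zero_eln": n_zero}


def _t_stage_dummies(df: pd.DataFrame) -> tuple[np.ndarray, list[str], str]:
    cats = sorted(df["t_stage"].unique())
    ref = "T3" if "T3" in cats else cats[0]
    others = [c for c in cats if c != ref]
    cols = np.column_stack(
        [(df["t_stage"] == c).to_numpy(dtype=float) for c in others]
    ) if others else np.empty((len(df), 0))
    return cols, [f"t_stage[{c}]" for c in others], ref


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - separation/edge failures
        raise ValueError(f"logistic fit failed ({exc}); check for separation") from exc
    if not np.all(np.isfinite(res.bse)):
        bad = [names[i] for i in range(len(names)) if not np.isfinite(res.bse[i])]
        raise ValueError(f"complete separation suspected for covariate(s): {bad}")
    return res


def fit_continuous_or(
    records: pd.DataFrame,
    adjust: Sequence[str] = ("t_stage",),
    histology: str | None = None,
) -> LogisticFit:
    """Logistic fit of observed nodal positivity on the continuous ELN count.

    The outcome is node-negative vs node-positive (any positive node
    examined). T-stage enters as indicator covariates when requested, with
    unknown (TX) as its own category. Returns the odds ratio for one
    additional examined node with a 95% Wald CI.
    """
    df, coding = _prepare(records, histology)
    y = (df["positive_nodes_examined"] > 0).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit logistic model")
    names = ["intercept", "eln_count"]
    X = [np.ones(len(df)), df["eln_count"].to_numpy(dtype=float)]
    if "t_stage" in adjust:
        dummies, dnames, ref = _t_stage_dummies(df)
        X.append(dummies)
        names += dnames
        coding["t_stage_reference"] = ref
    X = np.column_stack(X)
    res = _fit_logit(y, X, names)
    beta, se = res.params[1], res.bse[1]
    return LogisticFit(
        or_per_eln=float(np.exp(beta)),
        ci95=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        n_used=int(len(df)),
        coefficients={n: (float(b), float(s)) for n, b, s in zip(names, res.params, res.bse)},
        coding={**coding, "outcome": "observed node-positive", "adjust": list(adjust)},
    )


def per_count_or_curve(
    records: pd.DataFrame,
    reference_count: int = 1,
    adjust: Sequence[str] = ("t_stage",),
    max_level: int = 60,
    min_per_level: int = 20,
    histology: str | None = None,
) -> RatioCurve:
    """Odds ratio of observed nodal positivity per ELN-count level.

    One logistic fit with dummy-coded levels against ``reference_count``.
    Levels where every patient is positive (or every patient negative) would
    separate the likelihood; they are excluded from the joint fit and their
    OR vs the reference is reported from the 2x2 table with the
    Haldane–Anscombe 0.5 continuity correction, flagged in ``flags``.
    """
    df, coding = _prepare(records, histology)
    y = (df["positive_nodes_examined"] > 0).to_numpy(dtype=float)
    bin_id, rep, merges = bin_eln_levels(
        df["eln_count"].to_numpy(), reference_count, max_level, min_per_level
    )
    ref_idx = int(np.argmin(np.abs(rep - reference_count)))
    n_levels = len(rep)
    n_per = np.bincount(bin_id, minlength=n_levels)

    # find degenerate levels (all-positive or all-negative) other than reference
    pos_per = np.bincount(bin_id, weights=y, minlength=n_levels)
    degenerate = [
        i
        for i in range(n_levels)
        if i != ref_idx and (pos_per[i] == 0 or pos_per[i] == n_per[i])
    ]
    if pos_per[ref_idx] in (0, n_per[ref_idx]):
        raise ValueError("reference level has a single outcome class; choose another reference")

    model_levels = [i for i in range(n_levels) if i not in degenerate]
    model_rows = np.isin(bin_id, model_levels)
    dfm, ym, bm = df[model_rows], y[model_rows], bin_id[model_rows]
    names = ["intercept"]
    cols = [np.ones(len(dfm))]
    dummy_levels = [i for i in model_levels if i != ref_idx]
    for i in dummy_levels:
        cols.append((bm == i).astype(float))
        names.append(f"level[{rep[i]:g}]")
    if "t_stage" in adjust:
        dummies, dnames, ref = _t_stage_dummies(dfm)
        cols.append(dummies)
        names += dnames
        coding["t_stage_reference"] = ref
    X = np.column_stack(cols)
    res = _fit_logit(ym, X, names)

    log_or = np.zeros(n_levels)
    se = np.zeros(n_levels)
    flags: dict = {}
    for j, i in enumerate(dummy_levels, start=1):
        log_or[i], se[i] = res.params[j], res.bse[j]
    # continuity-corrected crude OR vs reference for degenerate levels
    a_ref = pos_per[ref_idx]
    b_ref = n_per[ref_idx] - a_ref
    for i in degenerate:
        a, b = pos_per[i] + 0.5, n_per[i] - pos_per[i] + 0.5
        c, d = a_ref + 0.5, b_ref + 0.5
        log_or[i] = np.log((a * d) / (b * c))
        se[i] = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        flags[float(rep[i])] = "haldane-anscombe continuity correction (degenerate level)"

    return RatioCurve(
        reference_count=reference_count,
        levels=rep,
        ratio=np.exp(log_or),
        ci_low=np.exp(log_or - _Z95 * se),
        ci_high=np.exp(log_or + _Z95 * se),
        n_per_level=n_per,
        scale="odds-ratio",
        log_ratio=log_or,
        se_log=se,
        flags=flags,
        merges=merges,
    )
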