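"""Synthetic cohort generation and descriptive summaries.

A cohort is a :class:`pandas.DataFrame` with one row per esophagectomy
patient. The column ``true_node_positive`` records the latent nodal status
used by the generator; analysis modules must never read it — they go through
:func:`analysis_view`, which whitelists the analysis columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    GeneratorConfig,
    HISTOLOGIES,
    N_STAGE_BINS,
    T_STAGES,
    YEAR_GROUPS,
)

__all__ = [
    "COHORT_COLUMNS",
    "ANALYSIS_COLUMNS",
    "generate_cohort",
    "summarize_cohort",
    "analysis_view",
    "n_stage_from_positive",
    "write_cohort",
    "read_cohort",
]

#: Full cohort CSV schema, in column order.
COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "histology",
    "year_group",
    "t_stage",
    "eln_count",
    "positive_nodes_examined",
    "observed_n_stage",
    "true_node_positive",
    "survival_months",
    "death_event",
]

#: Columns the analysis modules are allowed to see. ``true_node_positive`` is
#: deliberately absent: it exists only so tests can check the pipeline against
#: the generating truth without giving the analysis a side channel.
ANALYSIS_COLUMNS = [c for c in COHORT_COLUMNS if c != "true_node_positive"]


def n_stage_from_positive(positive_nodes: np.ndarray) -> np.ndarray:
    """AJCC 7th-edition N stage from the count of positive nodes examined."""
    pos = np.asarray(positive_nodes)
    out = np.empty(pos.shape, dtype=object)
    for lo, hi, label in N_STAGE_BINS:
        mask = pos >= lo if hi is None else (pos >= lo) & (pos <= hi)
        out[mask] = label
    return out


def _shifted_negbin(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    # 1 + NegBin with mean (mean-1) and dispersion k, so counts are >= 1
    m = mean - 1.0
    p = k / (k + m)
    return 1 + rng.negative_binomial(k, p, size=size)


def _categorical(rng, probs: dict[str, float], keys, size: int) -> np.ndarray:
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic cohort with ``config.n_patients`` rows.

    Deterministic given the config (including its seed). See the module
    docstring of :mod:`elncut.config` for the data-generating model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    age = np.clip(np.round(rng.normal(61.0, 9.5, n)), 23, 88).astype(int)
    sex = np.where(rng.random(n) < 0.159, "female", "male").astype(object)
    histology = _categorical(rng, config.histology_probs, HISTOLOGIES, n)
    year_group = _categorical(rng, config.year_group_weights, YEAR_GROUPS, n)
    t_stage = _categorical(rng, config.t_stage_probs, T_STAGES, n)

    eln = np.empty(n, dtype=int)
    for yg in YEAR_GROUPS:
        mask = year_group == yg
        mean, disp = config.eln_dist[yg]
        eln[mask] = _shifted_negbin(rng, mean, disp, int(mask.sum()))

    prev = np.array([config.prev_for(t) for t in t_stage])

    if config.mode == "piecewise":
        pw = config.piecewise
        t_off = np.array([pw.t_offsets.get(t, 0.0) for t in t_stage])
        eta = (
            pw.alpha
            + pw.beta1 * np.minimum(eln, pw.n_star)
            + pw.beta2 * np.maximum(0, eln - pw.n_star)
            + t_off
        )
        p_obs = np.where(prev > 0, expit(eta), 0.0)
        observed_pos = rng.random(n) < p_obs
        # positive node count among the observed-positive: 1 + truncated Poisson
        pos_examined = np.zeros(n, dtype=int)
        k_obs = int(observed_pos.sum())
        if k_obs:
            pos_examined[observed_pos] = np.minimum(
                1 + rng.poisson(1.3, k_obs), eln[observed_pos]
            )
        # latent truth: every detected patient is truly positive; among the
        # undetected, top up toward the target marginal prevalence
        p_extra = np.clip((prev - p_obs) / np.maximum(1.0 - p_obs, 1e-12), 0.0, 1.0)
        true_pos = observed_pos | (rng.random(n) < p_extra)
        true_pos &= prev > 0
        undetected = np.where(true_pos & ~observed_pos, 1 + rng.poisson(1.3, n), 0)
    else:
        mech = config.mechanistic
        true_pos = rng.random(n) < prev
        basin = _shifted_negbin(rng, mech.basin_mean, mech.basin_dispersion, n)
        # a patient cannot have more nodes examined than exist in the basin
        eln = np.minimum(eln, basin)
        m_pos = np.zeros(n, dtype=int)
        k_true = int(true_pos.sum())
        if k_true:
            m_pos[true_pos] = np.minimum(
                _shifted_negbin(rng, mech.pos_mean, mech.pos_dispersion, k_true),
                basin[true_pos],
            )
        pos_examined = np.zeros(n, dtype=int)
        if k_true:
            pos_examined[true_pos] = rng.hypergeometric(
                m_pos[true_pos], basin[true_pos] - m_pos[true_pos], eln[true_pos]
            )
        observed_pos = pos_examined > 0
        undetected = m_pos - pos_examined

    sv = config.survival
    log_hr_t = np.array([sv.log_hr_t_stage[t] for t in t_stage])
    hazard = sv.baseline_hazard * np.exp(
        sv.log_hr_node_positive * true_pos.astype(float)
        + log_hr_t
        + sv.log_hr_residual_pos * undetected
    )
    death_time = rng.exponential(1.0 / hazard)
    if sv.random_censor_rate > 0:
        censor_time = rng.exponential(1.0 / sv.random_censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, sv.admin_censor_months)
    survival_months = np.maximum(np.round(np.minimum(death_time, censor_time), 1), 0.1)
    death_event = (death_time <= censor_time).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "histology": histology,
            "year_group": year_group,
            "t_stage": t_stage,
            "eln_count": eln,
            "positive_nodes_examined": pos_examined,
            "observed_n_stage": n_stage_from_positive(pos_examined),
            "true_node_positive": true_pos.astype(int),
            "survival_months": survival_months,
            "death_event": death_event,
        }
    )
    return df


def analysis_view(records: pd.DataFrame) -> pd.DataFrame:
    """Return the columns an analysis is allowed to consume.

    Drops the generator's latent ``true_node_positive`` column; analysis code
    must call this (directly or via the fitting functions) so latent truth
    can never leak into a fit.
    """
    cols = [c for c in ANALYSIS_COLUMNS if c in records.columns]
    return records[cols].copy()


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Descriptive statistics: counts by category and median ELN with IQR.

    Returns a plain dict (JSON-serializable) with counts by sex, histology,
    T stage, N stage and year group, plus the median and IQR of the ELN count
    overall and per year group.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = analysis_view(records)

    def med_iqr(x: pd.Series) -> dict:
        # quartiles as observed values (nearest-rank), the registry convention
        return {
            "median": float(np.median(x)),
            "iqr": (
                float(np.percentile(x, 25, method="nearest")),
                float(np.percentile(x, 75, method="nearest")),
            ),
        }

    out = {
        "n": int(len(df)),
        "counts": {
            key: df[key].value_counts().sort_index().to_dict()
            for key in ("sex", "histology", "t_stage", "observed_n_stage", "year_group")
        },
        "eln": {"overall": med_iqr(df["eln_count"])},
    }
    for yg, grp in df.groupby("year_group"):
        out["eln"][yg] = med_iqr(grp["eln_count"])
    return out


def write_cohort(records: pd.DataFrame, path: str) -> None:
    """Write the cohort CSV with the canonical column order."""
    cols = [c for c in COHORT_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort CSV."""
    return pd.read_csv(path)
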