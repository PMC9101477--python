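"""End-to-end analysis: eligibility → descriptives → fits → cutoff → validation.

``run_full_analysis`` sequences the whole procedure on a patient-level
cohort table and returns an :class:`AnalysisReport` whose every section
carries an ``op`` provenance key naming the producing operation, so each
number in the report is traceable to one upstream call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from .cohort import ANALYSIS_COLUMNS, summarize_cohort
from .curve_break import find_cutpoint
from .eligibility import apply_eligibility, default_rules
from .migration import fit_continuous_or
from .survival import fit_cox_continuous, km_compare_at_cutoff, per_count_hr_curve

__all__ = ["AnalysisReport", "validate_schema", "run_full_analysis"]

HISTOLOGY_STRATA = ("overall", "AC", "SCC", "other")
NODAL_STRATA = ("node-negative", "node-positive")

_REQUIRED = {
    "eln_count": "numeric",
    "positive_nodes_examined": "numeric",
    "observed_n_stage": "categorical",
    "t_stage": "categorical",
    "histology": "categorical",
    "survival_months": "numeric",
    "death_event": "numeric",
}


def validate_schema(cohort: pd.DataFrame | str) -> list[dict]:
    """Check a cohort table against the analysis schema.

    Returns a list of violation records (empty list = valid); each has a
    ``kind``, the offending ``column`` and, for row-level rules, the
    offending row indices (first 20).
    """
    df = pd.read_csv(cohort) if isinstance(cohort, str) else cohort
    violations: list[dict] = []
    for col, kind in _REQUIRED.items():
        if col not in df.columns:
            violations.append({"kind": "missing-column", "column": col})
    if violations:
        return violations

    def _rows(mask) -> list[int]:
        return [int(i) for i in df.index[mask][:20]]

    for col in [c for c, k in _REQUIRED.items() if k == "numeric"]:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            violations.append(
                {"kind": "non-numeric", "column": col, "rows": _rows(bad)}
            )
    if not violations:
        bad = df["eln_count"] < 0
        if bad.any():
            violations.append({"kind": "negative-eln", "column": "eln_count", "rows": _rows(bad)})
        bad = df["positive_nodes_examined"] > df["eln_count"]
        if bad.any():
            violations.append(
                {
                    "kind": "positive-exceeds-examined",
                    "column": "positive_nodes_examined",
                    "rows": _rows(bad),
                }
            )
        bad = ~df["death_event"].isin([0, 1])
        if bad.any():
            violations.append({"kind": "invalid-event", "column": "death_event", "rows": _rows(bad)})
        bad = df["survival_months"] < 0
        if bad.any():
            violations.append(
                {"kind": "negative-survival", "column": "survival_months", "rows": _rows(bad)}
            )
        bad = (df["positive_nodes_examined"] == 0) != (df["observed_n_stage"] == "N0")
        if bad.any():
            violations.append(
                {"kind": "n-stage-mismatch", "column": "observed_n_stage", "rows": _rows(bad)}
            )
    return violations


@dataclass
class AnalysisReport:
    """All pipeline outputs for one cohort, JSON-serializable via to_dict."""

    metadata: dict
    eligibility: dict
    descriptives: dict
    migration: dict
    survival_continuous: dict
    cutpoint: dict
    km_at_cutoff: dict
    beyond_cutoff_hr: dict
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "eligibility": self.eligibility,
            "descriptives": self.descriptives,
            "migration": self.migration,
            "survival_continuous": self.survival_continuous,
            "cutpoint": self.cutpoint,
            "km_at_cutoff": self.km_at_cutoff,
            "beyond_cutoff_hr": self.beyond_cutoff_hr,
            "warnings": self.warnings,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _pkg_version() -> str:
    from importlib.metadata import version

    try:
        return version("elncut")
    except Exception:
        return "unknown"


def _cohort_hash(df: pd.DataFrame) -> str:
    cols = [c for c in ANALYSIS_COLUMNS if c in df.columns]
    csv = df.sort_values(cols[0] if "patient_id" not in df else "patient_id")[cols]
    return hashlib.sha256(csv.to_csv(index=False).encode()).hexdigest()[:16]


def run_full_analysis(
    cohort: pd.DataFrame | str,
    cutoff: int | None = None,
    adjust=("t_stage",),
    max_level: int = 60,
    min_per_level: int = 20,
    alpha: float = 0.05,
    fraction: float = 2.0 / 3.0,
) -> AnalysisReport:
    """Run the full cutpoint analysis on a cohort table (path or DataFrame).

    Stages: schema validation, eligibility filtering, descriptive table,
    continuous OR/HR fits stratified by histology, OR-curve cutpoint scan
    (unless ``cutoff`` is given), KM validation at the cutoff per nodal
    stratum, and beyond-cutoff HR curves. Deterministic given the inputs;
    per-stratum fit failures (e.g. too few events in a rare histology) are
    recorded as warnings rather than aborting the run.
    """
    df = pd.read_csv(cohort) if isinstance(cohort, str) else cohort
    violations = validate_schema(df)
    if violations:
        raise ValueError(f"cohort fails schema validation: {violations}")
    # deterministic under row permutation: restore canonical order
    if "patient_id" in df.columns:
        df = df.sort_values("patient_id").reset_index(drop=True)

    warnings: list[str] = []
    kept, report = apply_eligibility(df, default_rules())

    descriptives = {"op": "cohort.summarize_cohort", **summarize_cohort(kept)}

    migration: dict = {"op": "migration.fit_continuous_or"}
    for stratum in HISTOLOGY_STRATA:
        histo = None if stratum == "overall" else stratum
        try:
            migration[stratum] = fit_continuous_or(kept, adjust=adjust, histology=histo).to_dict()
        except ValueError as exc:
            migration[stratum] = None
            warnings.append(f"migration[{stratum}]: {exc}")

    survival_cont: dict = {"op": "survival.fit_cox_continuous"}
    for nodal in NODAL_STRATA:
        survival_cont[nodal] = {}
        for stratum in HISTOLOGY_STRATA:
            histo = None if stratum == "overall" else stratum
            try:
                survival_cont[nodal][stratum] = fit_cox_continuous(
                    kept, stratum=nodal, adjust=adjust, histology=histo
                ).to_dict()
            except ValueError as exc:
                survival_cont[nodal][stratum] = None
                warnings.append(f"survival[{nodal}][{stratum}]: {exc}")

    bp = find_cutpoint(
        kept,
        curve_source="migration",
        adjust=adjust,
        max_level=max_level,
        min_per_level=min_per_level,
        fraction=fraction,
        alpha=alpha,
    )
    cutpoint = {"op": "curve_break.find_cutpoint", **bp.to_dict()}
    chosen = int(round(bp.k_hat)) if cutoff is None else int(cutoff)
    cutpoint["cutoff_used_downstream"] = chosen

    km: dict = {"op": "survival.km_compare_at_cutoff", "cutoff": chosen}
    for nodal in NODAL_STRATA:
        try:
            above, below, lr = km_compare_at_cutoff(kept, chosen, stratum=nodal)
            km[nodal] = {
                "above": above.to_dict(),
                "below": below.to_dict(),
                "logrank": lr.to_dict(),
            }
        except ValueError as exc:
            km[nodal] = None
            warnings.append(f"km_at_cutoff[{nodal}]: {exc}")

    beyond: dict = {"op": "survival.per_count_hr_curve", "reference_count": chosen}
    for nodal in NODAL_STRATA:
        try:
            beyond[nodal] = per_count_hr_curve(
                kept,
                stratum=nodal,
                reference_count=chosen,
                adjust=adjust,
                max_level=max_level,
                min_per_level=min_per_level,
            ).to_dict()
        except ValueError as exc:
            beyond[nodal] = None
            warnings.append(f"beyond_cutoff_hr[{nodal}]: {exc}")

    metadata = {
        "package_version": _pkg_version(),
        "cohort_hash": _cohort_hash(df),
        "n_input": int(len(df)),
        "parameters": {
            "adjust": list(adjust),
            "max_level": max_level,
            "min_per_level": min_per_level,
            "alpha": alpha,
            "fraction": fraction,
            "cutoff_requested": cutoff,
        },
    }
    return AnalysisReport(
        metadata=metadata,
        eligibility={"op": "eligibility.apply_eligibility", **report.to_dict()},
        descriptives=descriptives,
        migration=migration,
        survival_continuous=survival_cont,
        cutpoint=cutpoint,
        km_at_cutoff=km,
        beyond_cutoff_hr=beyond,
        warnings=warnings,
    )
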