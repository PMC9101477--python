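"""Declarative inclusion/exclusion rules with an auditable attrition ledger.

Rules are (name, column, predicate) triples applied in order; each rule's
removal count is tallied against the records surviving the prior rules, so
the ledger reconciles exactly: n_input = n_retained + sum(removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Rule", "EligibilityReport", "default_rules", "apply_eligibility"]


@dataclass(frozen=True)
class Rule:
    """A single eligibility rule.

    ``keep`` receives the named column as a Series and returns a boolean mask
    of records that remain eligible under this rule.
    """

    name: str
    column: str
    keep: Callable[[pd.Series], pd.Series]


@dataclass
class EligibilityReport:
    n_input: int
    n_retained: int
    exclusions: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": [{"rule": r, "removed": c} for r, c in self.exclusions],
        }


def _known(x: pd.Series) -> pd.Series:
    # "unknown" is encoded as NaN or a negative sentinel
    return x.notna() & (pd.to_numeric(x, errors="coerce") >= 0)


def default_rules(treatment_column: str | None = None) -> list[Rule]:
    """The standard registry rule set, in application order.

    Excludes surgery-alone patients (only when a treatment-sequence column is
    present), then records with unknown nodes examined, unknown nodes
    positive, and unknown survival time.
    """
    rules: list[Rule] = []
    if treatment_column is not None:
        rules.append(
            Rule(
                "neoadjuvant_radiation",
                treatment_column,
                lambda x: x.astype(str).str.lower().isin(
                    {"ncrt", "neoadjuvant", "preop_rt", "radiation_prior_to_surgery"}
                ),
            )
        )
    rules += [
        Rule("known_nodes_examined", "eln_count", _known),
        Rule("known_nodes_positive", "positive_nodes_examined", _known),
        Rule("known_survival", "survival_months", _known),
    ]
    return rules


def apply_eligibility(
    records: pd.DataFrame, rules: Sequence[Rule] | None = None
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply eligibility rules in order; return retained records and ledger.

    Raises ``KeyError`` naming the missing column if a rule references a
    column the table lacks.
    """
    if rules is None:
        rules = default_rules()
    report = EligibilityReport(n_input=int(len(records)), n_retained=0)
    kept = records
    for rule in rules:
        if rule.column not in kept.columns:
            raise KeyError(
                f"eligibility rule {rule.name!r} requires missing column {rule.column!r}"
            )
        mask = np.asarray(rule.keep(kept[rule.column]), dtype=bool)
        report.exclusions.append((rule.name, int((~mask).sum())))
        kept = kept.loc[mask]
    report.n_retained = int(len(kept))
    assert report.n_input == report.n_retained + sum(c for _, c in report.exclusions)
    return kept.copy(), report
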