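"""Per-ELN-count ratio curves (odds ratios or hazard ratios vs a reference).

A :class:`RatioCurve` is the shared output of the stage-migration and
survival modules: one ratio estimate per ELN-count level against a reference
count, with Wald confidence intervals computed on the log scale. Sparse
levels are merged downward and counts above a cap are pooled, so that every
dummy coefficient rests on a workable number of patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RatioCurve", "bin_eln_levels"]


@dataclass
class RatioCurve:
    """OR or HR per ELN-count level vs ``reference_count``.

    ``levels`` are representative ELN counts (patient-weighted mean within a
    merged bin, so an unmerged bin's level is the count itself), strictly
    increasing. The ratio at the reference level is exactly 1.
    """

    reference_count: int
    levels: np.ndarray  # representative ELN count per bin
    ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_level: np.ndarray
    scale: str  # "odds-ratio" or "hazard-ratio"
    log_ratio: np.ndarray = field(default=None)
    se_log: np.ndarray = field(default=None)
    flags: dict = field(default_factory=dict)  # level -> reason (e.g. continuity corr.)
    merges: list = field(default_factory=list)  # (merged-from, merged-into) pairs

    def __post_init__(self):
        if self.log_ratio is None:
            self.log_ratio = np.log(self.ratio)
        for name in ("levels", "ratio", "ci_low", "ci_high", "n_per_level", "log_ratio"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValueError("ratios must be positive")

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: one row per level."""
        return pd.DataFrame(
            {
                "level": self.levels,
                "n": self.n_per_level.astype(int),
                "ratio": self.ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "log_ratio": self.log_ratio,
            }
        )

    def to_dict(self) -> dict:
        d = self.to_frame().to_dict(orient="list")
        d.update(
            reference_count=self.reference_count,
            scale=self.scale,
            flags={str(k): v for k, v in self.flags.items()},
            merges=[list(m) for m in self.merges],
        )
        return d


def bin_eln_levels(
    eln: np.ndarray,
    reference_count: int,
    max_level: int = 60,
    min_per_level: int = 20,
    min_count: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Assign each patient an ELN level bin.

    Counts at or above ``max_level`` are pooled into the top bin; bins with
    fewer than ``min_per_level`` patients are merged into the nearest lower
    bin (the lowest bin merges upward). ``min_count`` optionally restricts to
    counts >= that value (used by beyond-cutoff HR curves).

    Returns ``(bin_id, representative_level, merges)`` where ``bin_id`` maps
    each patient to an index into ``representative_level`` (patient-weighted
    mean ELN count per bin) and ``merges`` logs (from_level, into_level)
    pairs. Raises if the reference level ends up empty.
    """
    eln = np.asarray(eln)
    if min_count is not None:
        if np.any(eln < min_count):
            raise ValueError("bin_eln_levels received counts below min_count")
    capped = np.minimum(eln, max_level)
    levels = np.unique(capped)
    if reference_count > max_level:
        raise ValueError("reference_count exceeds max_level")
    if reference_count not in levels:
        raise ValueError(f"reference level {reference_count} is empty")
    counts = {int(l): int((capped == l).sum()) for l in levels}
    order = [int(l) for l in levels]
    # merge sparse bins downward (lowest bin merges upward), never the reference
    group_of = {l: l for l in order}
    merges: list[tuple[int, int]] = []
    changed = True
    while changed:
        changed = False
        groups = sorted(set(group_of.values()))
        sizes = {g: 0 for g in groups}
        for l in order:
            sizes[group_of[l]] += counts[l]
        for i in range(len(groups) - 1, -1, -1):
            g = groups[i]
            if g == reference_count or sizes[g] >= min_per_level or len(groups) == 1:
                continue
            target = groups[i - 1] if i > 0 else groups[i + 1]
            if target == reference_count:
                # keep the reference bin pure: merge away from it instead
                alt = groups[i + 1] if i + 1 < len(groups) else (groups[i - 2] if i >= 2 else None)
                if alt is None:
                    continue
                target = alt
            for l in order:
                if group_of[l] == g:
                    group_of[l] = target
            merges.append((g, target))
            changed = True
            break
    groups = sorted(set(group_of.values()))
    gidx = {g: i for i, g in enumerate(groups)}
    bin_id = np.array([gidx[group_of[int(c)]] for c in capped])
    rep = np.zeros(len(groups))
    for i in range(len(groups)):
        rep[i] = eln[bin_id == i].mean()
    # the reference bin is labeled by the reference count itself
    rep[gidx[reference_count]] = reference_count
    if not np.all(np.diff(rep) > 0):  # pooled-top means can collide only if degenerate
        raise ValueError("representative levels are not strictly increasing")
    return bin_id, rep, merges
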