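"""Configuration for the synthetic registry-cohort generator.

The generator emulates a population-based esophagectomy cohort treated with
neoadjuvant chemoradiotherapy: examined-lymph-node (ELN) counts drifting
upward by diagnosis-year group, latent true nodal status only partially
observed through node sampling (stage migration), and right-censored overall
survival with proportional-hazards structure.

Two data-generating modes are supported:

``piecewise``
    Observed nodal positivity follows a segmented logistic model in the ELN
    count with a planted breakpoint ``n_star`` — the quantity the cutpoint
    pipeline is expected to recover.
``mechanistic``
    Each truly node-positive patient owns a nodal basin; examined positive
    nodes are a hypergeometric draw of the ELNs from that basin, so detection
    probability rises smoothly with the ELN count and saturates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "YEAR_GROUPS",
    "T_STAGES",
    "HISTOLOGIES",
    "N_STAGE_BINS",
    "PiecewiseParams",
    "MechanisticParams",
    "SurvivalParams",
    "GeneratorConfig",
    "default_config",
    "load_config",
    "save_config",
]

#: Diagnosis-year groups, oldest first.
YEAR_GROUPS = ("2001-2004", "2005-2008", "2009-2012", "2013-2016")

#: Pathological T-stage categories; "TX" is unknown, kept as its own category.
T_STAGES = ("T0", "T1", "T2", "T3", "T4", "TX")

#: Histology groups; "other" pools rarer subtypes (neuroendocrine, small cell,
#: large cell neuroendocrine, NOS).
HISTOLOGIES = ("AC", "SCC", "other")

#: AJCC 7th-edition N stage by count of positive nodes: N0 0, N1 1-2, N2 3-6,
#: N3 >=7.
N_STAGE_BINS = ((0, 0, "N0"), (1, 2, "N1"), (3, 6, "N2"), (7, None, "N3"))


def _check_probs(name: str, probs: Mapping[str, float], keys: tuple[str, ...]) -> None:
    if set(probs) != set(keys):
        raise ValueError(f"{name} must have keys {keys}, got {sorted(probs)}")
    vals = list(probs.values())
    if any(v < 0 for v in vals):
        raise ValueError(f"{name} has negative entries")
    if abs(sum(vals) - 1.0) > 1e-8:
        raise ValueError(f"{name} must sum to 1, sums to {sum(vals)!r}")


@dataclass
class PiecewiseParams:
    """Segmented-logit model for observed nodal positivity.

    logit P(observed N+ | n, T) = alpha + beta1*min(n, n_star)
                                  + beta2*max(0, n - n_star) + t_offsets[T]
    """

    alpha: float = -1.2
    beta1: float = 0.08
    beta2: float = 0.0
    n_star: int = 16
    t_offsets: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_star < 2:
            raise ValueError(f"n_star must be >= 2, got {self.n_star}")
        unknown = set(self.t_offsets) - set(T_STAGES)
        if unknown:
            raise ValueError(f"t_offsets has unknown T stages: {sorted(unknown)}")


@dataclass
class MechanisticParams:
    """Nodal-basin sampling model.

    The basin size (total regional nodes available to examine) is
    1 + NegBin(mean - 1, dispersion); a truly positive patient carries
    1 + NegBin(pos_mean - 1, pos_dispersion) positive nodes, truncated at the
    basin size. Examined positive nodes are hypergeometric.
    """

    basin_mean: float = 32.0
    basin_dispersion: float = 8.0
    pos_mean: float = 3.0
    pos_dispersion: float = 1.5

    def validate(self) -> None:
        if self.basin_mean <= 1 or self.pos_mean <= 1:
            raise ValueError("basin_mean and pos_mean must exceed 1")
        if self.basin_dispersion <= 0 or self.pos_dispersion <= 0:
            raise ValueError("dispersions must be positive")


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards survival model with right censoring.

    hazard = baseline_hazard * exp(log_hr_node_positive * 1{true N+}
             + log_hr_t_stage[T] + log_hr_residual_pos * undetected_pos)

    Death times compete with an independent exponential censoring time at
    ``random_censor_rate`` and an administrative cutoff at
    ``admin_censor_months``.
    """

    baseline_hazard: float = 0.0115  # per month; median ~60 mo for reference group
    log_hr_node_positive: float = 0.85
    log_hr_t_stage: dict[str, float] = field(
        default_factory=lambda: {
            "T0": -0.30,
            "T1": -0.25,
            "T2": -0.10,
            "T3": 0.0,
            "T4": 0.35,
            "TX": 0.05,
        }
    )
    log_hr_residual_pos: float = 0.08  # per undetected positive node
    admin_censor_months: float = 180.0
    random_censor_rate: float = 0.004  # per month

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be >= 0")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be > 0")
        missing = set(T_STAGES) - set(self.log_hr_t_stage)
        if missing:
            raise ValueError(f"log_hr_t_stage missing stages: {sorted(missing)}")


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort model.

    ``eln_dist`` maps each year group to a (mean, dispersion) pair of the
    shifted negative-binomial ELN-count distribution 1 + NegBin(mean - 1, k);
    means drift upward across year groups to emulate rising nodal yields.
    ``true_node_pos_prev`` is either a single prevalence or a per-T-stage map.
    """

    n_patients: int = 10_000
    seed: int = 0
    mode: str = "mechanistic"
    eln_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "2001-2004": (10.5, 1.9),
            "2005-2008": (12.5, 1.9),
            "2009-2012": (14.5, 2.1),
            "2013-2016": (18.0, 2.6),
        }
    )
    year_group_weights: dict[str, float] = field(
        default_factory=lambda: {
            "2001-2004": 0.152,
            "2005-2008": 0.218,
            "2009-2012": 0.274,
            "2013-2016": 0.356,
        }
    )
    t_stage_probs: dict[str, float] = field(
        default_factory=lambda: {
            "T0": 0.0004,
            "T1": 0.1000,
            "T2": 0.1333,
            "T3": 0.4975,
            "T4": 0.0499,
            "TX": 0.2189,
        }
    )
    histology_probs: dict[str, float] = field(
        default_factory=lambda: {"AC": 0.778, "SCC": 0.200, "other": 0.022}
    )
    true_node_pos_prev: float | dict[str, float] = 0.45
    piecewise: PiecewiseParams = field(default_factory=PiecewiseParams)
    mechanistic: MechanisticParams = field(default_factory=MechanisticParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        if isinstance(self.piecewise, dict):
            self.piecewise = PiecewiseParams(**self.piecewise)
        if isinstance(self.mechanistic, dict):
            self.mechanistic = MechanisticParams(**self.mechanistic)
        if isinstance(self.survival, dict):
            self.survival = SurvivalParams(**self.survival)
        self.eln_dist = {k: tuple(v) for k, v in self.eln_dist.items()}

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.mode not in ("piecewise", "mechanistic"):
            raise ValueError(f"mode must be 'piecewise' or 'mechanistic', got {self.mode!r}")
        _check_probs("year_group_weights", self.year_group_weights, YEAR_GROUPS)
        _check_probs("t_stage_probs", self.t_stage_probs, T_STAGES)
        _check_probs("histology_probs", self.histology_probs, HISTOLOGIES)
        if set(self.eln_dist) != set(YEAR_GROUPS):
            raise ValueError("eln_dist must have one (mean, dispersion) per year group")
        for yg, (mean, disp) in self.eln_dist.items():
            if mean <= 1 or disp <= 0:
                raise ValueError(f"eln_dist[{yg}] must have mean > 1 and dispersion > 0")
        prev = self.true_node_pos_prev
        if isinstance(prev, dict):
            missing = set(T_STAGES) - set(prev)
            if missing:
                raise ValueError(f"true_node_pos_prev missing T stages: {sorted(missing)}")
            vals = prev.values()
        else:
            vals = [prev]
        if any(not (0.0 <= p <= 1.0) for p in vals):
            raise ValueError("true_node_pos_prev must lie in [0, 1]")
        self.piecewise.validate()
        self.mechanistic.validate()
        self.survival.validate()
        # planted break must sit inside the bulk of the ELN support
        if self.mode == "piecewise":
            max_mean = max(m for m, _ in self.eln_dist.values())
            if self.piecewise.n_star > 6 * max_mean:
                raise ValueError("n_star far exceeds the ELN-count support")

    def prev_for(self, t_stage: str) -> float:
        prev = self.true_node_pos_prev
        return prev[t_stage] if isinstance(prev, dict) else prev

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config(**overrides) -> GeneratorConfig:
    """The frozen default configuration; keyword overrides replace fields."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def load_config(path: str) -> GeneratorConfig:
    """Read a GeneratorConfig from YAML or JSON."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    cfg = GeneratorConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: GeneratorConfig, path: str) -> None:
    """Write a GeneratorConfig as YAML (or JSON when the path ends in .json)."""
    data = cfg.to_dict()
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
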