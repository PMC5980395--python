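"""Simulation parameter sets, validation, and flat-config serialization.

A :class:`SimulationParams` instance fully determines one replicate of either
model given a seed. Parameters can round-trip through a flat ``key: value``
YAML config file; command-line flags override file values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "AllocationRule",
    "ModelKind",
    "ParameterError",
    "ConfigError",
    "SimulationParams",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """A simulation parameter violated its invariant. Names the offending field."""


class ConfigError(ValueError):
    """A config file could not be parsed into valid parameters."""


class AllocationRule(str, enum.Enum):
    """How the replenished resource is split among foragers each step.

    ``group_competition`` gives group k the share s_k = R * n_k^2 / sum_j n_j^2
    (larger groups outcompete smaller ones), divided equally within the group.
    ``equal_allocation`` ignores group size: every group member receives
    R / (total number of group members).
    """

    GROUP_COMPETITION = "group_competition"
    EQUAL_ALLOCATION = "equal_allocation"


class ModelKind(str, enum.Enum):
    BASELINE = "baseline"
    REPRODUCTIVE = "reproductive"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulation run.

    Parameters
    ----------
    n : int
        Initial population size (>= 2).
    r : int
        Resource patch size, in resource units replenished each step (>= 2).
        Also the optimal group size: a sole group of exactly ``r`` members
        receives a per-capita share of 1.
    t_prob : float
        Probability that each ordered pair of individuals carries an initial
        directed foraging tie.
    n_steps : int or None
        Number of time steps. ``None`` means the model default: ``5 * n`` for
        the baseline model, 1000 for the reproductive model.
    allocation_rule : AllocationRule
    injection_prob : float
        Per-step probability of one random directed tie being added from a
        group member to any other individual (default 1e-4, i.e. 0.01%).
    seed : int
        Seed for the single numpy Generator that drives every stochastic
        element of the run.
    model : ModelKind
    n_perm : int
        Number of draws of the group-membership permutation null used for the
        chance-relatedness baseline (reproductive model only).
    relatedness_every : int
        Cadence (in steps) of the relatedness metrics l_m, l_r, L_t; the final
        step is always evaluated. 0 disables all but the final step.
    randomize_founder_ages : bool
        If True, founders start with ages drawn uniformly on [0, 100) instead
        of all 0.
    """

    n: int
    r: int
    t_prob: float = 0.2
    n_steps: int | None = None
    allocation_rule: AllocationRule = AllocationRule.GROUP_COMPETITION
    injection_prob: float = 1e-4
    seed: int = 0
    model: ModelKind = ModelKind.BASELINE
    n_perm: int = 100
    relatedness_every: int = 10
    randomize_founder_ages: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 2:
            raise ParameterError(f"n must be an integer >= 2, got {self.n!r}")
        if not isinstance(self.r, int) or self.r < 2:
            raise ParameterError(f"r must be an integer >= 2, got {self.r!r}")
        if not (0.0 <= self.t_prob <= 1.0) or math.isnan(self.t_prob):
            raise ParameterError(f"t_prob must lie in [0, 1], got {self.t_prob!r}")
        if self.n_steps is not None and (not isinstance(self.n_steps, int) or self.n_steps < 1):
            raise ParameterError(f"n_steps must be an integer >= 1 or None, got {self.n_steps!r}")
        if not (0.0 <= self.injection_prob <= 1.0):
            raise ParameterError(
                f"injection_prob must lie in [0, 1], got {self.injection_prob!r}"
            )
        if self.n_perm < 1:
            raise ParameterError(f"n_perm must be >= 1, got {self.n_perm!r}")
        if self.relatedness_every < 0:
            raise ParameterError(
                f"relatedness_every must be >= 0, got {self.relatedness_every!r}"
            )
        # coerce plain strings from config files into enums
        object.__setattr__(self, "allocation_rule", AllocationRule(self.allocation_rule))
        object.__setattr__(self, "model", ModelKind(self.model))

    @property
    def steps(self) -> int:
        """Effective number of steps (applies the per-model default)."""
        if self.n_steps is not None:
            return self.n_steps
        return 5 * self.n if self.model is ModelKind.BASELINE else 1000

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.value if isinstance(v, enum.Enum) else v
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except ParameterError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path, **overrides: Any) -> SimulationParams:
    """Load parameters from a flat YAML file, with keyword overrides.

    Overrides (typically CLI flags) take precedence over file values. ``None``
    overrides are ignored so that unset CLI flags fall through to the file.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key: value mapping")
    for key, value in overrides.items():
        if value is not None:
            raw[key] = value
    return SimulationParams.from_dict(raw)


def save_config(params: SimulationParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
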