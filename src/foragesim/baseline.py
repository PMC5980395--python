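"""Closed-population simulation loop: allocate, update ties by payoff, repeat.

Each step: (1) detect reciprocity groups, (2) allocate the replenished R
resource units, (3) let every forager update its ties from its own payoff —
r_i < 1 removes one random outgoing tie, r_i > 1 adds one random new outgoing
tie, r_i = 1 leaves ties unchanged — then (4) with small probability inject
one random tie from a group member, modeling random new-group formation.

Tie updates are synchronous: every decision is evaluated against the
pre-update network and all changes are applied atomically, so outcomes do not
depend on any within-step ordering of individuals.

Random-stream protocol (relied on by the trajectory-equality oracle tests):
draws occur in ascending forager-id order; a removal draws one integer index
into the sorted out-neighbor list; an addition draws one integer index into
the sorted candidate list (skipped entirely when the candidate set is empty);
injection draws one uniform, then — only when it fires — one index into the
sorted member list and one into the sorted list of other individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AllocationResult,
    GroupPartition,
    TieMatrix,
    allocate,
    find_groups,
    init_network,
)
from .metrics import MetricsRecord, StabilityAccumulator, summarize_step
from .params import ModelKind, SimulationParams

__all__ = [
    "StepOutcome",
    "InternalConsistencyError",
    "update_ties",
    "inject_random_tie",
    "step_baseline",
    "run_baseline",
    "BaselineResult",
]


class InternalConsistencyError(RuntimeError):
    """The state violated an invariant the dynamics rely on."""


@dataclass(frozen=True)
class StepOutcome:
    """Bookkeeping for one simulation step (state before demography)."""

    partition: GroupPartition
    allocation: AllocationResult
    ties_after: TieMatrix
    injected: bool = False


def update_ties(
    ties: TieMatrix,
    allocation: AllocationResult,
    partition: GroupPartition,
    rng: np.random.Generator,
) -> TieMatrix:
    """Synchronous payoff-driven tie update for every forager.

    Only group members act (lone individuals have r_i = 0 and no patch
    experience). A forager with r_i < 1 removes one uniformly random existing
    outgoing tie; with r_i > 1 it adds an outgoing tie to a uniformly random
    individual it is not already out-tied to (self excluded; no-op when no
    such individual exists); with r_i exactly 1 it changes nothing. All
    choices are made against the pre-update network and applied together.
    """
    removals: list[tuple[int, int]] = []
    additions: list[tuple[int, int]] = []
    members = partition.members
    for i in sorted(ties.ids):
        if i not in members:
            continue
        sign = allocation.payoff_sign(i)
        if sign == 0:
            continue
        if sign < 0:
            outs = ties.out_neighbors(i)
            if not outs:
                raise InternalConsistencyError(
                    f"group member {i} has r_i < 1 but no outgoing ties"
                )
            removals.append((i, outs[int(rng.integers(len(outs)))]))
        else:
            tied = set(ties.out_neighbors(i))
            candidates = [j for j in sorted(ties.ids) if j != i and j not in tied]
            if candidates:
                additions.append((i, candidates[int(rng.integers(len(candidates)))]))
    out = ties.copy()
    for i, j in removals:
        out.remove_tie(i, j)
    for i, j in additions:
        out.add_tie(i, j)
    return out


def inject_random_tie(
    ties: TieMatrix,
    partition: GroupPartition,
    p: float,
    rng: np.random.Generator,
) -> tuple[TieMatrix, bool]:
    """With probability p, add one random group-member -> anyone tie.

    One Bernoulli(p) event per time step for the whole population. The source
    is a uniformly random current group member, the target a uniformly random
    other individual (group membership irrelevant); adding an existing tie is
    a no-op. No groups means no injection (and no random draws).
    """
    if not partition.groups:
        return ties, False
    if rng.random() >= p:
        return ties, False
    members = sorted(partition.members)
    src = members[int(rng.integers(len(members)))]
    others = [j for j in sorted(ties.ids) if j != src]
    if not others:
        return ties, False
    dst = others[int(rng.integers(len(others)))]
    out = ties.copy()
    out.add_tie(src, dst)
    return out, True


def step_baseline(
    ties: TieMatrix, params: SimulationParams, rng: np.random.Generator
) -> StepOutcome:
    """One full step: detect groups -> allocate -> update ties -> inject.

    The resource repletes every step; injection acts last, so an injected tie
    first takes effect at the next step's group detection.
    """
    partition = find_groups(ties)
    allocation = allocate(partition, params.r, params.allocation_rule)
    updated = update_ties(ties, allocation, partition, rng)
    updated, injected = inject_random_tie(updated, partition, params.injection_prob, rng)
    return StepOutcome(
        partition=partition,
        allocation=allocation,
        ties_after=updated,
        injected=injected,
    )


@dataclass
class BaselineResult:
    """Trajectory of one baseline replicate."""

    params: SimulationParams
    metrics: list[MetricsRecord]
    stability: StabilityAccumulator
    final_ties: TieMatrix
    trajectory: list[StepOutcome] = field(default_factory=list)

    @property
    def final(self) -> MetricsRecord:
        return self.metrics[-1]


def run_baseline(
    params: SimulationParams,
    record_trajectory: bool = False,
) -> BaselineResult:
    """Run one baseline replicate for ``params.steps`` steps.

    Fully reproducible: the single Generator seeded with ``params.seed``
    drives initialization, tie updates, and injection. The stability network
    accumulates the ties each step *forages on* (the pre-update network), and
    the per-step metrics describe that same foraging state.
    """
    if params.model is not ModelKind.BASELINE:
        raise ValueError("params.model must be 'baseline'")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    ties = init_network(params, rng)
    acc = StabilityAccumulator()
    metrics: list[MetricsRecord] = []
    trajectory: list[StepOutcome] = []
    for step in range(1, params.steps + 1):
        acc.update(ties)
        outcome = step_baseline(ties, params, rng)
        metrics.append(
            summarize_step(
                outcome.partition,
                outcome.allocation,
                step=step,
                acc=acc,
                resource=params.r,
            )
        )
        if record_trajectory:
            trajectory.append(outcome)
        ties = outcome.ties_after
    return BaselineResult(
        params=params,
        metrics=metrics,
        stability=acc,
        final_ties=ties,
        trajectory=trajectory,
    )
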