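"""Baseline loop plus age-dependent birth/death, tie inheritance, pedigree.

Each individual of age a (time steps alive) reproduces in a step with
probability Pr(a) = 1e-3 * 1 / (1 + exp(-0.1 a + 5)) — a logistic ramp with
midpoint at age 50 and ceiling 1e-3 — and dies with the identical probability
P_d(a) = Pr(a), so the population stays roughly stationary while fluctuating
stochastically. An offspring inherits all of its parent's ties (incoming and
outgoing) and adds one unreciprocated tie to the parent, so it joins the
parent's group without founding a new one. A death removes every tie incident
to the deceased; the pedigree keeps everyone ever born.

Within-step order: detect groups -> allocate -> update ties -> inject ->
birth draws -> death draws -> age increments. Birth and death draws cover the
individuals alive at the start of the step, in ascending id order; newborns
are exempt in their birth step and get their first age increment at its end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline import StepOutcome, inject_random_tie, update_ties
from .core import TieMatrix, allocate, find_groups, init_network
from .metrics import (
    MetricsRecord,
    RelatednessReport,
    StabilityAccumulator,
    relatedness_report,
    summarize_step,
)
from .params import ModelKind, ParameterError, SimulationParams
from .pedigree import Pedigree

__all__ = [
    "DemographicEvent",
    "ReproductiveState",
    "reproduction_prob",
    "death_prob",
    "give_birth",
    "kill",
    "init_reproductive",
    "step_reproductive",
    "run_reproductive",
    "pedigree_from_events",
    "ReproductiveResult",
]


def reproduction_prob(a):
    """Pr(a) = 1e-3 / (1 + exp(-0.1 a + 5)) for age a in time steps.

    Strictly increasing, ~6.69e-6 at age 0, 5e-4 at the midpoint age 50,
    asymptote 1e-3. Accepts scalars or arrays.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0):
        raise ParameterError(f"age must be >= 0, got {a!r}")
    out = 1e-3 / (1.0 + np.exp(-0.1 * arr + 5.0))
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def death_prob(a):
    """P_d(a) = Pr(a): identical schedule, keeping the population stationary."""
    return reproduction_prob(a)


@dataclass(frozen=True)
class DemographicEvent:
    """One birth or death, sufficient to replay the pedigree."""

    step: int
    kind: str  # "birth" | "death"
    subject: int
    parent: int | None = None


@dataclass
class ReproductiveState:
    """Mutable state of one reproductive replicate."""

    ties: TieMatrix
    ages: dict[int, int]
    pedigree: Pedigree
    next_id: int
    events: list[DemographicEvent] = field(default_factory=list)

    @property
    def alive(self) -> list[int]:
        return sorted(self.ties.ids)

    @property
    def n_alive(self) -> int:
        return len(self.ties)


def init_reproductive(
    params: SimulationParams, rng: np.random.Generator
) -> ReproductiveState:
    """Founders: a random tie network, no pedigree edges (all unrelated)."""
    ties = init_network(params, rng)
    if params.randomize_founder_ages:
        drawn = rng.integers(0, 100, size=params.n)
        ages = {i: int(drawn[k]) for k, i in enumerate(ties.ids)}
    else:
        ages = {i: 0 for i in ties.ids}
    ped = Pedigree()
    for i in ties.ids:
        ped.add_founder(i, step=0)
    return ReproductiveState(ties=ties, ages=ages, pedigree=ped, next_id=params.n)


def give_birth(
    state: ReproductiveState, parent: int, step: int
) -> DemographicEvent:
    """Create one offspring of ``parent`` with inherited ties.

    The offspring (age 0) copies every outgoing and incoming tie of the
    parent as they stand at this moment, plus one unreciprocated
    offspring -> parent tie; the parent gains no tie to the offspring. If the
    parent is in a group, the offspring therefore enters the same group
    immediately.
    """
    child = state.next_id
    state.next_id += 1
    outs = state.ties.out_neighbors(parent)
    ins = state.ties.in_neighbors(parent)
    state.ties.add_individual(child, out_to=outs, in_from=ins)
    state.ties.add_tie(child, parent)
    state.ages[child] = 0
    state.pedigree.add_birth(parent, child, step)
    event = DemographicEvent(step=step, kind="birth", subject=child, parent=parent)
    state.events.append(event)
    return event


def kill(state: ReproductiveState, victim: int, step: int) -> DemographicEvent:
    """Remove ``victim`` from the living network; keep it in the pedigree."""
    state.ties.remove_individual(victim)
    state.pedigree.mark_death(victim, step)
    del state.ages[victim]
    event = DemographicEvent(step=step, kind="death", subject=victim)
    state.events.append(event)
    return event


def step_reproductive(
    state: ReproductiveState,
    params: SimulationParams,
    rng: np.random.Generator,
    step: int,
) -> StepOutcome:
    """One reproductive-model step: baseline step, then demography.

    Births come before deaths, so a newborn can lose its parent within its
    birth step. Each individual alive at the start of the step draws one
    birth Bernoulli (at most one offspring per step) and one death Bernoulli,
    independently; no compensation holds N constant. Ages of all survivors,
    newborns included, increment at the end.
    """
    partition = find_groups(state.ties)
    allocation = allocate(partition, params.r, params.allocation_rule)
    updated = update_ties(state.ties, allocation, partition, rng)
    updated, injected = inject_random_tie(
        updated, partition, params.injection_prob, rng
    )
    state.ties = updated

    at_start = sorted(state.ages)
    for i in at_start:
        if rng.random() < reproduction_prob(state.ages[i]):
            give_birth(state, i, step)
    victims = [i for i in at_start if rng.random() < death_prob(state.ages[i])]
    for i in victims:
        kill(state, i, step)
    for i in state.ages:
        state.ages[i] += 1
    return StepOutcome(
        partition=partition,
        allocation=allocation,
        ties_after=state.ties,
        injected=injected,
    )


@dataclass
class ReproductiveResult:
    """Trajectory of one reproductive replicate."""

    params: SimulationParams
    metrics: list[MetricsRecord]
    stability: StabilityAccumulator
    pedigree: Pedigree
    events: list[DemographicEvent]
    final_state: ReproductiveState
    extinct: bool = False
    steps_run: int = 0

    @property
    def final(self) -> MetricsRecord:
        return self.metrics[-1]


def run_reproductive(params: SimulationParams) -> ReproductiveResult:
    """Run one reproductive replicate for ``params.steps`` steps.

    Two child streams are split off the master seed: one drives the dynamics
    (network init, tie updates, injection, demography), the other the
    permutation-null draws — so the trajectory is invariant to the metrics
    cadence while the whole pipeline stays single-seed reproducible.
    Extinction truncates the run cleanly and flags the result.

    Relatedness metrics (l_m, l_r, L_t) are evaluated every
    ``params.relatedness_every`` steps and always at the final step; other
    metrics are recorded every step.
    """
    if params.model is not ModelKind.REPRODUCTIVE:
        raise ValueError("params.model must be 'reproductive'")
    dyn_ss, perm_ss = np.random.SeedSequence(params.seed).spawn(2)
    rng = np.random.default_rng(dyn_ss)
    perm_rng = np.random.default_rng(perm_ss)
    state = init_reproductive(params, rng)
    acc = StabilityAccumulator()
    metrics: list[MetricsRecord] = []
    extinct = False
    steps_run = 0
    every = params.relatedness_every
    for step in range(1, params.steps + 1):
        acc.update(state.ties)
        alive_at_start = state.alive
        outcome = step_reproductive(state, params, rng, step)
        want_rel = step == params.steps or (every > 0 and step % every == 0)
        report: RelatednessReport | None = None
        if want_rel and outcome.partition.groups:
            report = relatedness_report(
                state.pedigree,
                outcome.partition,
                alive_at_start,
                n_perm=params.n_perm,
                rng=perm_rng,
            )
        metrics.append(
            summarize_step(
                outcome.partition,
                outcome.allocation,
                step=step,
                acc=acc,
                resource=params.r,
                relatedness=report,
            )
        )
        steps_run = step
        if state.n_alive == 0:
            extinct = True
            break
    return ReproductiveResult(
        params=params,
        metrics=metrics,
        stability=acc,
        pedigree=state.pedigree,
        events=list(state.events),
        final_state=state,
        extinct=extinct,
        steps_run=steps_run,
    )


def pedigree_from_events(
    events: list[DemographicEvent], n_founders: int
) -> Pedigree:
    """Rebuild the pedigree purely from the demographic event log."""
    ped = Pedigree()
    for i in range(n_founders):
        ped.add_founder(i, step=0)
    for ev in events:
        if ev.kind == "birth":
            assert ev.parent is not None
            ped.add_birth(ev.parent, ev.subject, ev.step)
        elif ev.kind == "death":
            ped.mark_death(ev.subject, ev.step)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return ped
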