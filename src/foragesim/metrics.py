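"""Observables: stability network, exclusivity, pedigree relatedness, nulls.

The per-step observables are (a) number of groups, (b) mean group size
(groups only — lone individuals are excluded), (c) mean payoff among
individuals actually foraging (r_i > 0), (d) the social-stability network
s_ij(t) = (steps with a mutual i-j tie) / t, (e) exclusivity E — the share of
total stability weight held among the R highest weighted-degree individuals —
and, when a pedigree exists, (f)-(i): pedigree, pairwise relatedness
l_ij = 1 / 2^d_ij (d = undirected shortest pedigree path; 0 if disconnected),
mean within-group relatedness l_m, the chance expectation l_r from a
group-membership permutation null, and the log-ratio L_t = ln(l_m / l_r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core import AllocationResult, GroupPartition, TieMatrix
from .params import ParameterError
from .pedigree import Pedigree

__all__ = [
    "StabilityAccumulator",
    "MetricsRecord",
    "RelatednessReport",
    "update_stability",
    "exclusivity",
    "relatedness",
    "relatedness_matrix",
    "member_relatedness",
    "permutation_null",
    "log_ratio",
    "relatedness_report",
    "pedigree_diameter",
    "summarize_step",
    "group_tie_resilience",
]

LT_OK = "ok"
LT_UNDEFINED = "undefined"  # l_r = 0 (or no groups): ratio has no value
LT_NEG_INF = "neg_inf"  # l_m = 0 with l_r > 0: ln(0) = -inf


class StabilityAccumulator:
    """Running per-dyad count of steps with a mutual tie.

    The weight s_ij(t) divides the mutual-tie count by the *total* elapsed
    steps t, so dyads accrue weight only while both members are alive but are
    diluted by the full run length — dyads never co-alive simply stay at 0.
    """

    __slots__ = ("counts", "t", "seen")

    def __init__(self) -> None:
        self.counts: dict[tuple[int, int], int] = {}
        self.t: int = 0
        self.seen: set[int] = set()

    def update(self, ties: TieMatrix) -> "StabilityAccumulator":
        """Record one step: count every currently reciprocated dyad."""
        self.t += 1
        self.seen.update(ties.ids)
        recip = ties.reciprocal()
        ii, jj = np.nonzero(np.triu(recip, k=1))
        for a, b in zip(ii, jj):
            i, j = ties.ids[a], ties.ids[b]
            key = (i, j) if i < j else (j, i)
            self.counts[key] = self.counts.get(key, 0) + 1
        return self

    def weights(self) -> dict[tuple[int, int], float]:
        """The stability network s_ij(t) as a dict over nonzero dyads."""
        if self.t == 0:
            return {}
        return {k: c / self.t for k, c in self.counts.items()}

    def weighted_degree(self, restrict: set[int] | None = None) -> dict[int, float]:
        ids = self.seen if restrict is None else (self.seen & restrict)
        deg = {i: 0.0 for i in ids}
        for (i, j), w in self.weights().items():
            if i in deg and j in deg:
                deg[i] += w
                deg[j] += w
        return deg


def update_stability(acc: StabilityAccumulator, ties: TieMatrix) -> StabilityAccumulator:
    """Functional alias for :meth:`StabilityAccumulator.update`."""
    return acc.update(ties)


def exclusivity(
    acc: StabilityAccumulator,
    r: int,
    restrict: Iterable[int] | None = None,
) -> float | None:
    """Share of total stability weight held within the top-R individuals.

    Individuals are ranked by weighted degree in the stability network (ties
    broken by ascending id); E is the sum of s_ij over dyads with *both*
    endpoints in the top-R set divided by the sum over all dyads. E ~ 1 means
    a single optimally sized group monopolized the patch for most of the run.
    Returns None when the network carries no weight (E is then undefined).

    By default every individual ever observed enters the ranking; pass
    ``restrict`` (e.g. the final survivors) to confine both the ranking and
    the weight sums to a subset.
    """
    restrict_set = set(restrict) if restrict is not None else None
    deg = acc.weighted_degree(restrict_set)
    weights = acc.weights()
    if restrict_set is not None:
        weights = {
            (i, j): w for (i, j), w in weights.items()
            if i in restrict_set and j in restrict_set
        }
    total = sum(weights.values())
    if total == 0:
        return None
    ranked = sorted(deg, key=lambda i: (-deg[i], i))
    top = set(ranked[:r])
    inside = sum(w for (i, j), w in weights.items() if i in top and j in top)
    return inside / total


def relatedness(ped: Pedigree, i: int, j: int) -> float:
    """Pairwise pedigree relatedness l_ij = 1 / 2^d_ij.

    d_ij is the shortest path length between i and j in the undirected
    pedigree (dead individuals included); disconnected pairs have l = 0.
    Parent-offspring pairs (d = 1) score 0.5, grandparent-grandoffspring and
    same-mother sibs (d = 2) score 0.25.
    """
    if i == j:
        raise ParameterError("self-relatedness is undefined")
    if i not in ped or j not in ped:
        raise ParameterError(f"ids {i}, {j} must both be in the pedigree")
    g = ped.to_undirected()
    try:
        d = nx.shortest_path_length(g, i, j)
    except nx.NetworkXNoPath:
        return 0.0
    return 0.5**d


def relatedness_matrix(ped: Pedigree, ids: Sequence[int]) -> dict[tuple[int, int], float]:
    """Pairwise relatedness over ``ids``, keyed by ordered (min, max) pairs.

    One BFS per source in the undirected pedigree; only nonzero entries are
    stored.
    """
    g = ped.to_undirected()
    ids = sorted(set(ids))
    idset = set(ids)
    out: dict[tuple[int, int], float] = {}
    for i in ids:
        for j, d in nx.single_source_shortest_path_length(g, i).items():
            if j in idset and i < j:
                out[(i, j)] = 0.5**d
    return out


def _group_mean_rel(
    group: Iterable[int], rel: dict[tuple[int, int], float]
) -> float:
    members = sorted(group)
    n = len(members)
    pairs = n * (n - 1) // 2
    if pairs == 0:
        return 0.0
    s = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            s += rel.get((members[a], members[b]), 0.0)
    return s / pairs


def member_relatedness(
    ped: Pedigree,
    partition: GroupPartition,
    rel: dict[tuple[int, int], float] | None = None,
) -> float | None:
    """Mean within-group relatedness l_m.

    First the relatedness is averaged over all unordered member pairs within
    each group, then the per-group means are averaged with equal weight.
    Returns None when there are no groups.
    """
    if not partition.groups:
        return None
    if rel is None:
        rel = relatedness_matrix(ped, sorted(partition.members))
    per_group = [_group_mean_rel(g, rel) for g in partition.groups]
    return float(np.mean(per_group))


def permutation_null(
    ped: Pedigree,
    partition: GroupPartition,
    alive_ids: Sequence[int],
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    rel: dict[tuple[int, int], float] | None = None,
) -> float | None:
    """Chance-level within-group relatedness l_r.

    For each of ``n_perm`` draws, groups of the observed number and sizes are
    refilled by sampling the living individuals uniformly without
    replacement; the member relatedness of each randomized grouping is
    computed exactly as l_m, and l_r is the mean over draws.
    """
    if not partition.groups:
        return None
    alive = sorted(set(alive_ids))
    sizes = list(partition.sizes)
    if sum(sizes) > len(alive):
        raise ValueError(
            f"group sizes {sizes} exceed the living population ({len(alive)})"
        )
    if rng is None:
        rng = np.random.default_rng()
    if rel is None:
        rel = relatedness_matrix(ped, alive)
    alive_arr = np.asarray(alive)
    means = np.empty(n_perm)
    for p in range(n_perm):
        perm = alive_arr[rng.permutation(len(alive_arr))]
        pos = 0
        per_group = []
        for nk in sizes:
            per_group.append(_group_mean_rel(perm[pos : pos + nk], rel))
            pos += nk
        means[p] = np.mean(per_group)
    return float(means.mean())


def log_ratio(l_m: float | None, l_r: float | None) -> tuple[float | None, str]:
    """L_t = ln(l_m / l_r), with distinct missing-value flags.

    Returns ``(value, flag)``: flag ``"undefined"`` when l_r = 0 or either
    input is missing (the ratio has no value), ``"neg_inf"`` when l_m = 0
    with l_r > 0 (ln 0 = -inf), else ``"ok"`` with the finite value.
    """
    if l_m is None or l_r is None or l_r == 0:
        return None, LT_UNDEFINED
    if l_m == 0:
        return None, LT_NEG_INF
    return float(np.log(l_m / l_r)), LT_OK


@dataclass(frozen=True)
class RelatednessReport:
    """l_m, l_r and L_t for one step, plus the per-group means behind l_m."""

    l_m: float | None
    l_r: float | None
    log_ratio: float | None
    flag: str
    per_group: tuple[float, ...] = ()


def relatedness_report(
    ped: Pedigree,
    partition: GroupPartition,
    alive_ids: Sequence[int],
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> RelatednessReport:
    """Compute l_m, l_r and L_t for the current state in one pass."""
    if not partition.groups:
        return RelatednessReport(None, None, None, LT_UNDEFINED)
    rel = relatedness_matrix(ped, sorted(alive_ids))
    per_group = tuple(_group_mean_rel(g, rel) for g in partition.groups)
    l_m = float(np.mean(per_group))
    l_r = permutation_null(ped, partition, alive_ids, n_perm, rng, rel=rel)
    lt, flag = log_ratio(l_m, l_r)
    return RelatednessReport(l_m, l_r, lt, flag, per_group)


def pedigree_diameter(ped: Pedigree) -> int:
    """Diameter of the largest component of the full undirected pedigree.

    Dead individuals are included. An edgeless pedigree (all components are
    singletons) has diameter 0. Serves as a generations-elapsed statistic:
    the longest kinship chain realized by the run.
    """
    if len(ped) == 0:
        raise ParameterError("pedigree is empty")
    g = ped.to_undirected()
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    top_size = len(comps[0])
    if top_size == 1:
        return 0
    return max(
        nx.diameter(g.subgraph(c)) for c in comps if len(c) == top_size
    )


@dataclass(frozen=True)
class MetricsRecord:
    """Per-step observables. Missing values are None, never 0."""

    step: int
    n_alive: int
    n_groups: int
    mean_group_size: float | None
    mean_payoff: float | None
    exclusivity: float | None = None
    l_m: float | None = None
    l_r: float | None = None
    log_ratio: float | None = None
    lt_flag: str | None = None


def summarize_step(
    partition: GroupPartition,
    allocation: AllocationResult,
    step: int = 0,
    acc: StabilityAccumulator | None = None,
    resource: int | None = None,
    relatedness: RelatednessReport | None = None,
) -> MetricsRecord:
    """Collapse one step's state into a :class:`MetricsRecord`.

    Mean group size is over groups only (size >= 2); mean payoff is over
    individuals with r_i > 0, i.e. those actually on the patch. Both are
    missing (None) when no group exists.
    """
    n_groups = len(partition.groups)
    if n_groups:
        mean_size = float(np.mean(partition.sizes))
        payoffs = [v for v in allocation.per_capita.values() if v > 0]
        mean_payoff = float(np.mean(payoffs)) if payoffs else None
    else:
        mean_size = None
        mean_payoff = None
    e = None
    if acc is not None and resource is not None:
        e = exclusivity(acc, resource)
    rr = relatedness
    return MetricsRecord(
        step=step,
        n_alive=len(partition.members) + len(partition.lone),
        n_groups=n_groups,
        mean_group_size=mean_size,
        mean_payoff=mean_payoff,
        exclusivity=e,
        l_m=rr.l_m if rr else None,
        l_r=rr.l_r if rr else None,
        log_ratio=rr.log_ratio if rr else None,
        lt_flag=rr.flag if rr else None,
    )


def group_tie_resilience(n: int) -> tuple[float, float]:
    """Worst-case one-step tie loss for a group of size n.

    A group of n members holds up to n*(n-1) directed ties and sheds at most
    one outgoing tie per member per step (n ties). Returns
    ``(max_loss_fraction, min_retained_fraction)`` = (1/(n-1), (n-2)/(n-1)):
    a size-3 group can lose half its ties in one bad step, a size-11 group at
    most 10% — large groups ride out negative payoffs far more easily.
    """
    if n < 2:
        raise ParameterError(f"group size must be >= 2, got {n!r}")
    possible = n * (n - 1)
    max_removed = n
    loss = max_removed / possible
    return loss, 1.0 - loss
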