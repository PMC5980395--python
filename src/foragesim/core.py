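"""Core social-network state: directed ties, reciprocity groups, allocation.

The social state is a directed binary network of "foraging ties" over the
living individuals: a tie i -> j expresses i's willingness to forage with j.
Only *reciprocated* ties (i -> j and j -> i) create co-foraging. Groups are
the connected components of the reciprocity graph with at least two members
(the chain rule: A~B and B~C puts A, B, C in one group whether or not A~C).

The resource patch holds R units, replenished every step, and is contested by
groups; lone individuals cannot access it. Under the group-competition rule a
group of size n_k takes s_k = R * n_k^2 / sum_j n_j^2, split evenly among its
members; under the equal-allocation variant every group member receives
R / (total foragers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .params import ParameterError, SimulationParams, AllocationRule

__all__ = [
    "TieMatrix",
    "GroupPartition",
    "AllocationResult",
    "init_network",
    "find_groups",
    "allocate",
]


class TieMatrix:
    """Directed binary adjacency over the living individuals.

    Individuals are addressed by stable integer ids that are never reused;
    internally a dense boolean matrix is kept over the current live set with
    an id <-> row-index mapping. Self-ties are structurally impossible.
    """

    __slots__ = ("ids", "index", "a")

    def __init__(self, ids: Sequence[int], a: np.ndarray | None = None):
        self.ids: list[int] = list(ids)
        self.index: dict[int, int] = {v: k for k, v in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate ids")
        n = len(self.ids)
        if a is None:
            a = np.zeros((n, n), dtype=bool)
        else:
            a = np.asarray(a, dtype=bool).copy()
            if a.shape != (n, n):
                raise ValueError(f"adjacency shape {a.shape} does not match {n} ids")
            np.fill_diagonal(a, False)
        self.a = a

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def has_tie(self, i: int, j: int) -> bool:
        return bool(self.a[self.index[i], self.index[j]])

    def out_neighbors(self, i: int) -> list[int]:
        """Targets of i's outgoing ties, in ascending id order."""
        row = self.a[self.index[i]]
        return sorted(self.ids[k] for k in np.flatnonzero(row))

    def in_neighbors(self, j: int) -> list[int]:
        col = self.a[:, self.index[j]]
        return sorted(self.ids[k] for k in np.flatnonzero(col))

    def n_ties(self) -> int:
        return int(self.a.sum())

    def reciprocal(self) -> np.ndarray:
        """Boolean matrix of mutual ties (the co-foraging graph)."""
        return self.a & self.a.T

    def edges(self) -> list[tuple[int, int]]:
        """All directed ties as (source, target) id pairs, sorted."""
        src, dst = np.nonzero(self.a)
        return sorted((self.ids[s], self.ids[d]) for s, d in zip(src, dst))

    def copy(self) -> "TieMatrix":
        return TieMatrix(self.ids, self.a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TieMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.a, other.a)

    # -- mutation --------------------------------------------------------
    def add_tie(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-ties are not allowed")
        self.a[self.index[i], self.index[j]] = True

    def remove_tie(self, i: int, j: int) -> None:
        self.a[self.index[i], self.index[j]] = False

    def add_individual(
        self,
        new_id: int,
        out_to: Iterable[int] = (),
        in_from: Iterable[int] = (),
    ) -> None:
        """Append a new individual with the given initial ties."""
        if new_id in self.index:
            raise ValueError(f"id {new_id} already present")
        n = len(self.ids)
        grown = np.zeros((n + 1, n + 1), dtype=bool)
        grown[:n, :n] = self.a
        self.ids.append(new_id)
        self.index[new_id] = n
        self.a = grown
        for j in out_to:
            self.add_tie(new_id, j)
        for j in in_from:
            self.add_tie(j, new_id)

    def remove_individual(self, dead_id: int) -> None:
        """Drop an individual and every tie incident to it."""
        k = self.index.pop(dead_id)
        self.ids.pop(k)
        self.a = np.delete(np.delete(self.a, k, axis=0), k, axis=1)
        for v, pos in self.index.items():
            if pos > k:
                self.index[v] = pos - 1

    # -- plain-text IO ---------------------------------------------------
    def to_edge_list(self, path: str | Path) -> None:
        """Write one ``source<TAB>target`` line per directed tie.

        Isolated individuals are preserved via a ``# node`` comment header so
        the round trip is lossless.
        """
        lines = [f"# nodes: {' '.join(str(i) for i in sorted(self.ids))}"]
        lines += [f"{s}\t{t}" for s, t in self.edges()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edge_list(cls, path: str | Path) -> "TieMatrix":
        ids: list[int] = []
        pairs: list[tuple[int, int]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# nodes:"):
                ids = [int(tok) for tok in line.split(":", 1)[1].split()]
            elif line.startswith("#"):
                continue
            else:
                s, t = line.split("\t")
                pairs.append((int(s), int(t)))
        if not ids:
            ids = sorted({v for pair in pairs for v in pair})
        tm = cls(ids)
        for s, t in pairs:
            tm.add_tie(s, t)
        return tm

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(self.edges())
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "TieMatrix":
        g = nx.read_graphml(str(path))
        ids = sorted(int(v) for v in g.nodes)
        tm = cls(ids)
        for s, t in g.edges:
            tm.add_tie(int(s), int(t))
        return tm


@dataclass(frozen=True)
class GroupPartition:
    """Reciprocity groups (components of size >= 2) plus the lone set."""

    groups: tuple[frozenset[int], ...]
    lone: frozenset[int]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    @property
    def members(self) -> frozenset[int]:
        return frozenset().union(*self.groups) if self.groups else frozenset()

    def group_of(self, i: int) -> int | None:
        for k, g in enumerate(self.groups):
            if i in g:
                return k
        return None


@dataclass(frozen=True)
class AllocationResult:
    """Resource shares for one step.

    ``group_shares[k]`` is s_k for ``partition.groups[k]``; ``per_capita``
    maps every living id to its r_i (0 for lone individuals). ``payoff_sign``
    gives the exact comparison of r_i against 1 (-1, 0, +1) computed in
    integer arithmetic, so the "ties remain unchanged" branch at r_i = 1 is
    never lost to float noise.
    """

    group_shares: tuple[float, ...]
    per_capita: dict[int, float]
    signs: dict[int, int]

    def payoff_sign(self, i: int) -> int:
        return self.signs[i]


def init_network(params: SimulationParams, rng: np.random.Generator) -> TieMatrix:
    """Random initial network: each ordered pair tied with probability t_prob.

    Draws one uniform per entry of the N x N matrix (diagonal included, then
    discarded) so the consumption of the random stream is independent of
    t_prob.
    """
    n = params.n
    u = rng.random((n, n))
    a = u < params.t_prob
    np.fill_diagonal(a, False)
    return TieMatrix(range(n), a)


def find_groups(ties: TieMatrix) -> GroupPartition:
    """Partition the living ids into reciprocity groups and lone individuals.

    A group is a connected component of the mutual-tie graph with >= 2
    members; everyone else is lone. Components never need an explicit
    "contains a reciprocated dyad" check: any component of size >= 2 of the
    reciprocity graph contains one by construction.
    """
    n = len(ties)
    if n == 0:
        return GroupPartition(groups=(), lone=frozenset())
    recip = ties.reciprocal()
    n_comp, labels = connected_components(
        csr_array(recip), directed=False, return_labels=True
    )
    buckets: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        buckets.setdefault(int(lab), []).append(ties.ids[idx])
    groups = []
    lone: set[int] = set()
    for members in buckets.values():
        if len(members) >= 2:
            groups.append(frozenset(members))
        else:
            lone.update(members)
    groups.sort(key=min)
    return GroupPartition(groups=tuple(groups), lone=frozenset(lone))


def allocate(
    partition: GroupPartition,
    r: int,
    rule: AllocationRule = AllocationRule.GROUP_COMPETITION,
) -> AllocationResult:
    """Split the R resource units among the groups for one step.

    Under ``group_competition``, s_k = R * n_k^2 / sum_j n_j^2 and each member
    of group k receives r_i = s_k / n_k; the whole patch is consumed
    (sum_k s_k = R) whenever at least one group exists. Under
    ``equal_allocation``, r_i = R / (total number of group members) for every
    member. Lone individuals always receive 0: they cannot access the patch.
    """
    if r < 2:
        raise ParameterError(f"r must be >= 2, got {r!r}")
    rule = AllocationRule(rule)
    per_capita: dict[int, float] = {i: 0.0 for i in partition.lone}
    signs: dict[int, int] = {i: 0 for i in partition.lone}
    sizes = partition.sizes
    if not sizes:
        return AllocationResult(group_shares=(), per_capita=per_capita, signs=signs)

    shares: list[float] = []
    if rule is AllocationRule.GROUP_COMPETITION:
        denom = sum(nk * nk for nk in sizes)
        for g, nk in zip(partition.groups, sizes):
            s_k = r * nk * nk / denom
            r_i = s_k / nk
            sign = (r * nk > denom) - (r * nk < denom)  # r_i <=> 1 exactly
            shares.append(s_k)
            for i in g:
                per_capita[i] = r_i
                signs[i] = sign
    else:
        total = sum(sizes)
        r_i = r / total
        sign = (r > total) - (r < total)
        for g, nk in zip(partition.groups, sizes):
            shares.append(r_i * nk)
            for i in g:
                per_capita[i] = r_i
                signs[i] = sign
    return AllocationResult(
        group_shares=tuple(shares), per_capita=per_capita, signs=signs
    )
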