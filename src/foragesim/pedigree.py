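"""Append-only pedigree: parent -> offspring links over everyone ever born.

The model population is single-sex (females; males are uncounted and always
disperse), so every non-founder has exactly one recorded parent. Dead
individuals are never removed — kinship paths routinely pass through dead
ancestors.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["Pedigree"]


class Pedigree:
    """Parent -> offspring graph over all individuals ever born.

    Acyclicity and the single-parent property hold by construction: offspring
    ids are assigned in birth order, a parent must already exist when a birth
    is recorded, and a node's parent is recorded exactly once.
    """

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.children: dict[int, list[int]] = {}
        self.birth_step: dict[int, int] = {}
        self.death_step: dict[int, int | None] = {}

    # -- construction ----------------------------------------------------
    def add_founder(self, i: int, step: int = 0) -> None:
        if i in self.death_step:
            raise ValueError(f"id {i} already in pedigree")
        self.birth_step[i] = step
        self.death_step[i] = None

    def add_birth(self, parent: int, child: int, step: int) -> None:
        if parent not in self.death_step:
            raise ValueError(f"parent {parent} not in pedigree")
        if child in self.death_step:
            raise ValueError(f"id {child} already in pedigree")
        self.parent[child] = parent
        self.children.setdefault(parent, []).append(child)
        self.birth_step[child] = step
        self.death_step[child] = None

    def mark_death(self, i: int, step: int) -> None:
        if self.death_step.get(i, -1) is not None:
            raise ValueError(f"id {i} not alive in pedigree")
        self.death_step[i] = step

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.death_step)

    def __contains__(self, i: int) -> bool:
        return i in self.death_step

    @property
    def ids(self) -> list[int]:
        return sorted(self.death_step)

    @property
    def founders(self) -> list[int]:
        return sorted(i for i in self.death_step if i not in self.parent)

    def founder_lineage(self, i: int) -> int:
        """The founder at the root of i's maternal line."""
        while i in self.parent:
            i = self.parent[i]
        return i

    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.parent.items(), key=lambda kv: kv[0])  # (child, parent)

    def to_undirected(self) -> nx.Graph:
        """The pedigree as an undirected kinship graph (all ids, dead included)."""
        g = nx.Graph()
        g.add_nodes_from(self.death_step)
        g.add_edges_from((p, c) for c, p in self.parent.items())
        return g

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.death_step)
        g.add_edges_from((p, c) for c, p in self.parent.items())
        return g
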