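"""Independent reference implementations used as test oracles.

These are deliberately naive, literal transcriptions of the model rules —
dict-of-sets state, union-find grouping, Fraction arithmetic — kept free of
the package's own data structures so that agreement is informative.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# union-find grouping oracle


def union_find_groups(ids, reciprocated_pairs):
    """Groups (components >= 2 of the mutual-tie graph) via union-find."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in reciprocated_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in ids:
        comps.setdefault(find(i), set()).add(i)
    groups = sorted(
        (frozenset(c) for c in comps.values() if len(c) >= 2), key=min
    )
    lone = frozenset(i for c in comps.values() if len(c) == 1 for i in c)
    return tuple(groups), lone


# ---------------------------------------------------------------------------
# straight-line baseline-trajectory oracle


class NaiveBaseline:
    """Literal transcription of the baseline loop on dict-of-sets state.

    Mirrors the package's documented random-stream protocol exactly (one
    uniform per ordered pair at init in row-major order; per-step draws in
    ascending forager-id order; injection draws only when groups exist).
    """

    def __init__(self, n, r, t_prob, seed, rule="group_competition", injection_prob=1e-4):
        self.n, self.r, self.rule, self.p_inject = n, r, rule, injection_prob
        self.rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.out = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(n):
                u = self.rng.random()
                if i != j and u < t_prob:
                    self.out[i].add(j)

    def edges(self):
        return sorted((i, j) for i in self.out for j in self.out[i])

    def _groups(self):
        pairs = [
            (i, j)
            for i in self.out
            for j in self.out[i]
            if i < j and i in self.out[j]
        ]
        groups, lone = union_find_groups(list(self.out), pairs)
        return groups

    def step(self):
        groups = self._groups()
        sizes = [len(g) for g in groups]
        payoff = {}
        if groups:
            if self.rule == "group_competition":
                denom = sum(s * s for s in sizes)
                for g, s in zip(groups, sizes):
                    r_i = Fraction(self.r * s, denom)
                    for i in g:
                        payoff[i] = r_i
            else:
                total = sum(sizes)
                for g in groups:
                    for i in g:
                        payoff[i] = Fraction(self.r, total)
        removals, additions = [], []
        for i in sorted(self.out):
            if i not in payoff:
                continue
            r_i = payoff[i]
            if r_i < 1:
                outs = sorted(self.out[i])
                removals.append((i, outs[int(self.rng.integers(len(outs)))]))
            elif r_i > 1:
                cands = [
                    j for j in sorted(self.out) if j != i and j not in self.out[i]
                ]
                if cands:
                    additions.append((i, cands[int(self.rng.integers(len(cands)))]))
        for i, j in removals:
            self.out[i].discard(j)
        for i, j in additions:
            self.out[i].add(j)
        if groups:
            if self.rng.random() < self.p_inject:
                members = sorted(set().union(*groups))
                src = members[int(self.rng.integers(len(members)))]
                others = [j for j in sorted(self.out) if j != src]
                if others:
                    dst = others[int(self.rng.integers(len(others)))]
                    self.out[src].add(dst)


# ---------------------------------------------------------------------------
# exhaustive permutation-null expectation


def exhaustive_pair_null(pair_relatedness, ids, group_size):
    """Exact expected mean relatedness of one random group of ``group_size``.

    Enumerates every subset of the given size (tiny instances only) and
    averages the mean pairwise relatedness; the permutation null converges to
    this as the number of draws grows.
    """
    from itertools import combinations

    ids = sorted(ids)
    vals = []
    for combo in combinations(ids, group_size):
        pairs = list(combinations(combo, 2))
        vals.append(
            sum(
                pair_relatedness.get((min(a, b), max(a, b)), 0.0)
                for a, b in pairs
            )
            / len(pairs)
        )
    return sum(vals) / len(vals)
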