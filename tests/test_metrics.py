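import math

import numpy as np
import pytest

from foragesim import (
    GroupPartition,
    ParameterError,
    Pedigree,
    StabilityAccumulator,
    allocate,
    chain_pedigree,
    exclusivity,
    find_groups,
    group_tie_resilience,
    log_ratio,
    member_relatedness,
    pedigree_diameter,
    permutation_null,
    relatedness,
    relatedness_matrix,
    summarize_step,
)
from foragesim.metrics import LT_NEG_INF, LT_OK, LT_UNDEFINED
from oracles import exhaustive_pair_null
from test_core import tm_from_pairs


def mother_daughter_pedigree(n_founders=5):
    """Founders 0..n-1, plus one daughter (id n) of founder 0."""
    ped = Pedigree()
    for i in range(n_founders):
        ped.add_founder(i)
    ped.add_birth(0, n_founders, step=1)
    return ped


class TestStability:
    def test_weights_count_reciprocated_fraction(self):
        acc = StabilityAccumulator()
        always = tm_from_pairs([0, 1, 2], mutual=[(0, 1)])
        once = tm_from_pairs([0, 1, 2], mutual=[(0, 1), (1, 2)])
        for tm in [once, always, always, always]:
            acc.update(tm)
        w = acc.weights()
        assert w[(0, 1)] == 1.0
        assert w[(1, 2)] == 0.25
        assert (0, 2) not in w

    def test_weight_decays_once_dyad_stops_reciprocating(self):
        acc = StabilityAccumulator()
        tied = tm_from_pairs([0, 1], mutual=[(0, 1)])
        untied = tm_from_pairs([0, 1], directed=[(0, 1)])
        acc.update(tied)
        w1 = acc.weights()[(0, 1)]
        acc.update(untied)
        w2 = acc.weights()[(0, 1)]
        acc.update(untied)
        assert w1 > w2 > acc.weights()[(0, 1)]


class TestExclusivity:
    @staticmethod
    def make_acc(weighted_edges, t=10, extra_ids=()):
        acc = StabilityAccumulator()
        acc.t = t
        acc.counts = {
            (min(i, j), max(i, j)): int(round(w * t))
            for (i, j), w in weighted_edges.items()
        }
        for i, j in acc.counts:
            acc.seen.update((i, j))
        acc.seen.update(extra_ids)
        return acc

    def test_single_persistent_clique_is_fully_exclusive(self):
        edges = {(i, j): 1.0 for i in range(5) for j in range(i + 1, 5)}
        acc = self.make_acc(edges, extra_ids=range(10))
        assert exclusivity(acc, 5) == pytest.approx(1.0)

    def test_uniform_complete_graph_gives_combinatorial_ratio(self):
        edges = {(i, j): 0.5 for i in range(10) for j in range(i + 1, 10)}
        acc = self.make_acc(edges)
        assert exclusivity(acc, 5) == pytest.approx(10 / 45)

    def test_heavier_clique_wins_top_slots(self):
        edges = {(i, j): 1.0 for i in range(5) for j in range(i + 1, 5)}
        edges |= {(i, j): 0.5 for i in range(5, 10) for j in range(i + 1, 10)}
        acc = self.make_acc(edges)
        assert exclusivity(acc, 5) == pytest.approx(10 / 15)

    def test_zero_weight_is_missing_not_zero(self):
        acc = StabilityAccumulator()
        acc.t = 5
        acc.seen = {0, 1, 2}
        assert exclusivity(acc, 2) is None

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        t = 8
        acc = StabilityAccumulator()
        acc.t = t
        acc.seen = set(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                c = int(rng.integers(0, t + 1))
                if c and rng.random() < 0.7:
                    acc.counts[(i, j)] = c
        r = int(rng.integers(2, n + 1))
        e = exclusivity(acc, r)
        # brute force: recompute degrees and both sums from scratch
        w = {k: c / t for k, c in acc.counts.items()}
        deg = {i: 0.0 for i in range(n)}
        for (i, j), v in w.items():
            deg[i] += v
            deg[j] += v
        top = set(sorted(range(n), key=lambda i: (-deg[i], i))[:r])
        total = sum(w.values())
        if total == 0:
            assert e is None
        else:
            inside = sum(v for (i, j), v in w.items() if i in top and j in top)
            assert e == pytest.approx(inside / total)


class TestRelatedness:
    def test_halves_with_each_pedigree_step(self):
        ped = chain_pedigree()
        assert relatedness(ped, 0, 1) == 0.5
        assert relatedness(ped, 0, 2) == 0.25
        assert relatedness(ped, 0, 3) == 0.125
        assert relatedness(ped, 1, 3) == 0.25
        for d in range(1, 3):
            assert relatedness(ped, 0, d + 1) == relatedness(ped, 0, d) / 2

    def test_symmetric_and_zero_when_disconnected(self):
        ped = chain_pedigree()
        assert relatedness(ped, 3, 0) == relatedness(ped, 0, 3)
        assert relatedness(ped, 0, 10) == 0.0

    def test_self_relatedness_rejected(self):
        with pytest.raises(ParameterError):
            relatedness(chain_pedigree(), 2, 2)

    def test_matrix_agrees_with_pairwise(self):
        ped = chain_pedigree()
        rel = relatedness_matrix(ped, ped.ids)
        for (i, j), v in rel.items():
            assert v == relatedness(ped, i, j)
        assert (0, 10) not in rel  # zeros are not stored


class TestMemberRelatedness:
    def test_single_mother_daughter_group(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(groups=(frozenset({0, 5}),), lone=frozenset({1, 2, 3, 4}))
        assert member_relatedness(ped, part) == 0.5

    def test_average_over_groups_is_unweighted(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(
            groups=(frozenset({1, 2}), frozenset({0, 5})), lone=frozenset({3, 4})
        )
        assert member_relatedness(ped, part) == pytest.approx(0.25)

    def test_all_founder_groups_have_zero_relatedness(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(groups=(frozenset({1, 2, 3}),), lone=frozenset({0, 4, 5}))
        assert member_relatedness(ped, part) == 0.0

    def test_no_groups_is_missing(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(groups=(), lone=frozenset(range(6)))
        assert member_relatedness(ped, part) is None


class TestPermutationNull:
    def test_edgeless_pedigree_has_zero_null(self):
        ped = Pedigree()
        for i in range(6):
            ped.add_founder(i)
        part = GroupPartition(groups=(frozenset({0, 1, 2}),), lone=frozenset({3, 4, 5}))
        assert permutation_null(ped, part, range(6), rng=np.random.default_rng(0)) == 0.0

    def test_whole_population_group_is_permutation_invariant(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(groups=(frozenset(range(6)),), lone=frozenset())
        l_m = member_relatedness(ped, part)
        l_r = permutation_null(ped, part, range(6), n_perm=13, rng=np.random.default_rng(1))
        assert l_r == pytest.approx(l_m)

    def test_oversized_groups_rejected(self):
        ped = mother_daughter_pedigree()
        part = GroupPartition(groups=(frozenset(range(6)),), lone=frozenset())
        with pytest.raises(ValueError):
            permutation_null(ped, part, [0, 1, 2], rng=np.random.default_rng(0))

    def test_converges_to_exhaustive_enumeration(self):
        # 6 individuals: one mother-daughter pair among 4 unrelated founders;
        # one random group of 2 contains the related pair 1/15 of the time.
        ped = mother_daughter_pedigree(n_founders=5)
        alive = list(range(6))
        part = GroupPartition(groups=(frozenset({1, 2}),), lone=frozenset({0, 3, 4, 5}))
        rel = relatedness_matrix(ped, alive)
        exact = exhaustive_pair_null(rel, alive, 2)
        assert exact == pytest.approx(0.5 / 15)
        big = permutation_null(
            ped, part, alive, n_perm=20_000, rng=np.random.default_rng(7)
        )
        assert big == pytest.approx(exact, abs=3 * 0.5 * math.sqrt((1 / 15) * (14 / 15) / 20_000))

    def test_hundred_draw_estimate_within_binomial_band(self):
        ped = mother_daughter_pedigree(n_founders=5)
        alive = list(range(6))
        part = GroupPartition(groups=(frozenset({1, 2}),), lone=frozenset({0, 3, 4, 5}))
        from scipy import stats

        lo, hi = stats.binom.ppf([0.005, 0.995], 100, 1 / 15)
        l_r = permutation_null(ped, part, alive, n_perm=100, rng=np.random.default_rng(3))
        assert 0.5 * lo / 100 <= l_r <= 0.5 * hi / 100


class TestLogRatio:
    def test_equal_rates_give_zero(self):
        value, flag = log_ratio(0.3, 0.3)
        assert value == pytest.approx(0.0) and flag == LT_OK

    def test_worked_value(self):
        value, flag = log_ratio(0.25, 1 / 30)
        assert value == pytest.approx(math.log(7.5)) and flag == LT_OK
        assert value == pytest.approx(2.015, abs=5e-3)

    def test_zero_null_is_undefined(self):
        value, flag = log_ratio(0.25, 0.0)
        assert value is None and flag == LT_UNDEFINED

    def test_zero_member_relatedness_is_negative_infinity_flag(self):
        value, flag = log_ratio(0.0, 0.1)
        assert value is None and flag == LT_NEG_INF

    def test_missing_inputs_are_undefined(self):
        assert log_ratio(None, 0.1) == (None, LT_UNDEFINED)


class TestPedigreeDiameter:
    def test_edgeless_pedigree_has_zero_diameter(self):
        ped = Pedigree()
        for i in range(4):
            ped.add_founder(i)
        assert pedigree_diameter(ped) == 0

    def test_four_generation_chain_has_diameter_three(self):
        assert pedigree_diameter(chain_pedigree()) == 3

    def test_star_of_five_offspring_has_diameter_two(self):
        ped = Pedigree()
        ped.add_founder(0)
        for k in range(1, 6):
            ped.add_birth(0, k, step=k)
        assert pedigree_diameter(ped) == 2

    def test_empty_pedigree_rejected(self):
        with pytest.raises(ParameterError):
            pedigree_diameter(Pedigree())


class TestSummarizeStep:
    def test_single_optimal_group(self):
        tm = tm_from_pairs(range(5), mutual=[(i, (i + 1) % 5) for i in range(5)])
        part = find_groups(tm)
        m = summarize_step(part, allocate(part, 5), step=1)
        assert (m.n_groups, m.mean_group_size, m.mean_payoff) == (1, 5.0, 1.0)

    def test_no_groups_yields_missing_values(self):
        tm = tm_from_pairs([0, 1], directed=[(0, 1)])
        part = find_groups(tm)
        m = summarize_step(part, allocate(part, 5), step=1)
        assert m.n_groups == 0
        assert m.mean_group_size is None and m.mean_payoff is None

    def test_weighted_mean_payoff_over_foragers(self):
        tm = tm_from_pairs(range(6), mutual=[(0, 1), (1, 2), (3, 4)])
        part = find_groups(tm)
        m = summarize_step(part, allocate(part, 5), step=1)
        assert m.mean_group_size == 2.5
        # (3 * 15/13 + 2 * 10/13) / 5 = 1: lone individual 5 excluded
        assert m.mean_payoff == pytest.approx(1.0)


class TestTieResilience:
    def test_large_groups_lose_at_most_a_tenth(self):
        loss, retained = group_tie_resilience(11)
        assert loss == pytest.approx(0.10)

    def test_small_groups_can_lose_half(self):
        loss, retained = group_tie_resilience(3)
        assert retained == pytest.approx(0.50)

    def test_dyads_can_lose_everything(self):
        loss, retained = group_tie_resilience(2)
        assert loss == 1.0 and retained == 0.0
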