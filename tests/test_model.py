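"""Unit and property tests for the ring-lattice payoff model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringpgg import (
    LocalityStats,
    ModelParams,
    Strategy,
    locality_stats,
    neighbor_indices,
    payoff_components,
    payoff_vector,
    pi_fine,
    pi_game,
    pi_punish_cost,
    population_from_string,
)

ATOL = 1e-12


def test_strategy_flags_are_a_bijection():
    combos = {(s.cooperates, s.punishes) for s in Strategy}
    assert len(Strategy) == 4
    assert combos == {(True, True), (True, False), (False, True), (False, False)}
    assert Strategy.CP.cooperates and Strategy.CP.punishes
    assert Strategy.CN.cooperates and not Strategy.CN.punishes
    assert not Strategy.DP.cooperates and Strategy.DP.punishes
    assert not Strategy.DN.cooperates and not Strategy.DN.punishes


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n": 3},              # odd neighborhood
        {"n": 100, "N": 100},  # n must be < N
        {"n": 0},
        {"g": 1.5},
        {"mu": -0.1},
        {"b": -1.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)


@pytest.mark.parametrize(
    "i, N, n, expected",
    [
        (0, 100, 4, [98, 99, 1, 2]),
        (99, 100, 4, [97, 98, 0, 1]),
        (5, 10, 2, [4, 6]),
    ],
)
def test_neighbor_indices_wrap_around_the_ring(i, N, n, expected):
    params = ModelParams(N=N, n=n)
    assert neighbor_indices(i, params).tolist() == expected


def test_neighbor_relation_is_symmetric():
    params = ModelParams(N=30, n=6)
    nbrs = [set(neighbor_indices(i, params).tolist()) for i in range(params.N)]
    for i in range(params.N):
        assert i not in nbrs[i]
        assert len(nbrs[i]) == params.n
        for j in nbrs[i]:
            assert i in nbrs[j]


def test_neighbor_indices_rejects_out_of_range():
    with pytest.raises(ValueError):
        neighbor_indices(100, ModelParams())


def test_locality_stats_homogeneous_population():
    params = ModelParams(N=20, n=4)
    pop = np.full(20, Strategy.CP, dtype=np.int8)
    st_ = locality_stats(pop, 7, params)
    assert (st_.nC_local, st_.nP_local, st_.NC_global, st_.NP_global) == (1, 1, 1, 1)


def test_locality_stats_worked_configuration():
    # "C C C C D D D" on a 7-ring with n=4: player 2 sees CCCD, player 4 CCDD
    pop = population_from_string("C C C C D D D")
    params = ModelParams(N=7, n=4)
    assert locality_stats(pop, 2, params).nC_local == pytest.approx(3 / 4)
    assert locality_stats(pop, 4, params).nC_local == pytest.approx(2 / 4)


def test_local_counts_sum_to_n_times_global_count(random_population, params):
    # ring regularity: every player appears in exactly n neighborhoods
    total_local = sum(
        locality_stats(random_population, i, params).nC_local * params.n
        for i in range(params.N)
    )
    n_coop = sum(Strategy(s).cooperates for s in random_population)
    assert total_local == pytest.approx(params.n * n_coop)


class TestPayoffComponents:
    def test_worked_example_cooperator(self):
        # neighbors CCCD, fully local game: 4b/5 - c
        params = ModelParams(N=7, n=4, g=0.0)
        stats = LocalityStats(3 / 4, 0.0, 0.5, 0.0)
        assert pi_game(stats, params, True) == pytest.approx(
            4 * params.b / 5 - params.c
        )
        assert pi_game(stats, params, True) == pytest.approx(0.6)

    def test_worked_example_defector(self):
        # neighbors CCDD, fully local game: 2b/5
        params = ModelParams(N=7, n=4, g=0.0)
        stats = LocalityStats(2 / 4, 0.0, 2 / 3, 0.0)
        assert pi_game(stats, params, False) == pytest.approx(2 * params.b / 5)
        assert pi_game(stats, params, False) == pytest.approx(0.8)

    @pytest.mark.parametrize("g", [0.0, 0.3, 1.0])
    def test_all_cooperator_limit(self, g):
        params = ModelParams(g=g)
        stats = LocalityStats(1.0, 0.5, 1.0, 0.5)
        assert pi_game(stats, params, True) == pytest.approx(params.b - params.c)

    def test_punish_cost_examples(self):
        assert pi_punish_cost(
            LocalityStats(1, 1, 1, 1), ModelParams(p=0.7)
        ) == pytest.approx(0.0)
        assert pi_punish_cost(
            LocalityStats(0.2, 0, 0.5, 0), ModelParams(p=1.0, s=3)
        ) == pytest.approx(1.5)
        assert pi_punish_cost(
            LocalityStats(0.0, 0, 1.0, 0), ModelParams(p=0.5, s=3)
        ) == pytest.approx(1.5)

    def test_fine_examples(self):
        assert pi_fine(LocalityStats(1, 0, 1, 0), ModelParams(p=0.3)) == 0.0
        assert pi_fine(
            LocalityStats(0, 0.5, 0, 0.1), ModelParams(p=0.0, f=6)
        ) == pytest.approx(3.0)
        assert pi_fine(
            LocalityStats(0, 0.2, 0, 1.0), ModelParams(p=1.0, f=6)
        ) == pytest.approx(6.0)

    def test_totals_assemble_per_strategy(self):
        params = ModelParams(g=0.4, p=0.6)
        stats = LocalityStats(0.5, 0.25, 0.6, 0.3)
        game_c = pi_game(stats, params, True)
        game_d = pi_game(stats, params, False)
        cost = pi_punish_cost(stats, params)
        fine = pi_fine(stats, params)
        assert payoff_components(Strategy.CP, stats, params).total == pytest.approx(
            game_c - cost
        )
        assert payoff_components(Strategy.CN, stats, params).total == pytest.approx(
            game_c
        )
        assert payoff_components(Strategy.DP, stats, params).total == pytest.approx(
            game_d - cost - fine
        )
        assert payoff_components(Strategy.DN, stats, params).total == pytest.approx(
            game_d - fine
        )


def test_payoff_vector_homogeneous_limits():
    params = ModelParams(N=50)
    all_cn = np.full(50, Strategy.CN, dtype=np.int8)
    all_dn = np.full(50, Strategy.DN, dtype=np.int8)
    assert payoff_vector(all_cn, params) == pytest.approx(
        np.full(50, params.b - params.c)
    )
    assert payoff_vector(all_dn, params) == pytest.approx(np.zeros(50))


def test_payoff_vector_matches_per_player_components(random_population, params):
    pay = payoff_vector(random_population, params.replace(g=0.3, p=0.8))
    p2 = params.replace(g=0.3, p=0.8)
    for i in range(params.N):
        expected = payoff_components(
            Strategy(random_population[i]), locality_stats(random_population, i, p2), p2
        ).total
        assert pay[i] == pytest.approx(expected, abs=ATOL)


stats_st = st.builds(
    LocalityStats,
    nC_local=st.sampled_from([k / 4 for k in range(5)]),
    nP_local=st.sampled_from([k / 4 for k in range(5)]),
    NC_global=st.floats(0, 1),
    NP_global=st.floats(0, 1),
)
params_st = st.builds(
    ModelParams,
    g=st.floats(0, 1),
    p=st.floats(0, 1),
    b=st.floats(0, 5),
    c=st.floats(0, 3),
    f=st.floats(0, 8),
    s=st.floats(0, 5),
)


@settings(deadline=None, max_examples=200)
@given(stats=stats_st, params=params_st)
def test_cooperator_defector_gap_is_constant(stats, params):
    # pi_C - pi_D = b/(n+1) - c for any locality stats and any g
    gap = pi_game(stats, params, True) - pi_game(stats, params, False)
    assert gap == pytest.approx(params.b / (params.n + 1) - params.c, abs=1e-9)


@settings(deadline=None, max_examples=200)
@given(stats=stats_st, params=params_st)
def test_component_bounds(stats, params):
    assert -params.c - ATOL <= pi_game(stats, params, True) <= params.b - params.c + 1e-9
    assert -ATOL <= pi_game(stats, params, False) <= params.b * params.n / (params.n + 1) + 1e-9
    assert -ATOL <= pi_punish_cost(stats, params) <= params.s + 1e-9
    assert -ATOL <= pi_fine(stats, params) <= params.f + 1e-9


@settings(deadline=None, max_examples=100)
@given(stats=stats_st, params=params_st)
def test_punishment_never_directly_pays(stats, params):
    # CN >= CP and DN >= DP at identical stats, equal iff the sanction cost is 0
    cp = payoff_components(Strategy.CP, stats, params).total
    cn = payoff_components(Strategy.CN, stats, params).total
    dp = payoff_components(Strategy.DP, stats, params).total
    dn = payoff_components(Strategy.DN, stats, params).total
    cost = pi_punish_cost(stats, params)
    assert cn - cp == pytest.approx(cost, abs=1e-9)
    assert dn - dp == pytest.approx(cost, abs=1e-9)
    assert cost >= -ATOL


@settings(deadline=None, max_examples=100)
@given(
    g=st.floats(0.01, 0.99),
    lo=st.floats(0, 0.49),
    hi=st.floats(0.51, 1.0),
)
def test_payoffs_monotone_in_cooperator_and_punisher_ratios(g, lo, hi):
    params = ModelParams(g=g, p=0.5)
    for coop in (True, False):
        assert pi_game(LocalityStats(hi, 0, 0.5, 0), params, coop) > pi_game(
            LocalityStats(lo, 0, 0.5, 0), params, coop
        )
        assert pi_game(LocalityStats(0.5, 0, hi, 0), params, coop) > pi_game(
            LocalityStats(0.5, 0, lo, 0), params, coop
        )
    assert pi_fine(LocalityStats(0, hi, 0, 0.5), params) > pi_fine(
        LocalityStats(0, lo, 0, 0.5), params
    )
    assert pi_punish_cost(LocalityStats(hi, 0, 0.5, 0), params) < pi_punish_cost(
        LocalityStats(lo, 0, 0.5, 0), params
    )


@settings(deadline=None, max_examples=50)
@given(k=st.integers(1, 99), seed=st.integers(0, 2**31 - 1))
def test_payoff_vector_translation_invariance(k, seed):
    params = ModelParams(g=0.3, p=0.7)
    pop = np.random.default_rng(seed).integers(0, 4, 100).astype(np.int8)
    rotated = np.roll(pop, k)
    assert payoff_vector(rotated, params) == pytest.approx(
        np.roll(payoff_vector(pop, params), k), abs=ATOL
    )


def test_global_limit_payoffs_depend_only_on_type(random_population):
    # g = p = 1: arrangement on the ring is irrelevant
    params = ModelParams(g=1.0, p=1.0)
    pay = payoff_vector(random_population, params)
    for s in Strategy:
        vals = pay[random_population == s]
        if vals.size:
            assert np.ptp(vals) < ATOL
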