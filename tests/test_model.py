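"""Unit tests for the lattice game core: payoffs, resource sharing, replacement."""

import numpy as np
import pytest

from limres import (
    GameParams,
    LatticeState,
    PayoffField,
    death_birth_step,
    distribute_resource,
    init_lattice,
    mcs_step,
    pair_payoff,
    payoff_field,
    select_parent,
)
from conftest import homogeneous_state, random_state


def payoff_oracle(cp: np.ndarray, params: GameParams) -> np.ndarray:
    """Naive double loop over sites and neighbours, written from the payoff matrix."""
    L = cp.shape[0]
    out = np.zeros_like(cp)
    for i in range(L):
        for j in range(L):
            pi = cp[i, j]
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                pj = cp[(i + di) % L, (j + dj) % L]
                out[i, j] += (
                    pi * pj * params.reward
                    + (1 - pi) * pj * params.b
                    + pi * (1 - pj) * params.sucker
                    + (1 - pi) * (1 - pj) * params.punishment
                )
    return out


class TestGameParams:
    @pytest.mark.parametrize("kwargs", [{"L": 1}, {"L": 0}, {"L": 2, "c": 0.0},
                                        {"L": 2, "c": -1.0}, {"L": 2.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            GameParams(**{"b": 1.5, "c": 1.1, **kwargs})

    def test_budget_is_c_times_sites(self):
        p = GameParams(L=10, c=1.3)
        assert p.total_resource == pytest.approx(1.3 * 100)


class TestInitLattice:
    def test_entries_in_unit_interval(self, rng):
        state = init_lattice(GameParams(L=100), rng)
        assert state.cp.shape == (100, 100)
        assert np.all((state.cp >= 0) & (state.cp <= 1))

    def test_mean_matches_uniform_law(self, rng):
        # sample mean of L^2 Uniform(0,1) draws within 4 sigma of 0.5
        state = init_lattice(GameParams(L=50), rng)
        bound = 4 * np.sqrt(1 / 12) / 50
        assert abs(state.cp.mean() - 0.5) < bound

    def test_deterministic_under_fixed_seed(self):
        a = init_lattice(GameParams(L=30), np.random.default_rng(5))
        b = init_lattice(GameParams(L=30), np.random.default_rng(5))
        assert np.array_equal(a.cp, b.cp)


class TestPairPayoff:
    @pytest.mark.parametrize(
        "pi, pj, b, expected",
        [
            (1.0, 1.0, 1.5, 1.0),       # mutual full cooperation pays R
            (0.7, 0.0, 1.5, 0.0),       # any strategy vs full defector earns 0
            (0.0, 1.0, 1.5, 1.5),       # full defector vs full cooperator earns T=b
            (0.5, 0.5, 1.9, 0.725),     # 0.25*1 + 0.25*1.9
        ],
    )
    def test_known_values(self, pi, pj, b, expected):
        assert pair_payoff(pi, pj, GameParams(L=2, b=b)) == pytest.approx(expected)

    def test_asymmetric_in_arguments(self):
        params = GameParams(L=2, b=1.5)
        assert pair_payoff(0.2, 0.9, params) != pytest.approx(pair_payoff(0.9, 0.2, params))

    @pytest.mark.parametrize("pi, pj", [(-0.1, 0.5), (0.5, 1.1), (2.0, 2.0)])
    def test_out_of_range_strategy_rejected(self, pi, pj):
        with pytest.raises(ValueError):
            pair_payoff(pi, pj, GameParams(L=2))


class TestPayoffField:
    def test_homogeneous_lattice_closed_form(self):
        field = payoff_field(homogeneous_state(5, 0.5), GameParams(L=5, b=1.1))
        assert np.allclose(field.payoff, 4 * (0.25 + 0.25 * 1.1))

    def test_full_cooperation_pays_four(self):
        field = payoff_field(homogeneous_state(4, 1.0), GameParams(L=4, b=1.7))
        assert np.allclose(field.payoff, 4.0)

    @pytest.mark.parametrize("L", [2, 3, 4, 6])
    def test_matches_naive_double_loop(self, L):
        state = random_state(L, seed=L * 11)
        params = GameParams(L=L, b=1.9)
        field = payoff_field(state, params)
        expected = payoff_oracle(state.cp, params)
        np.testing.assert_allclose(field.payoff, expected, rtol=1e-12)
        assert field.total == pytest.approx(expected.sum(), rel=1e-12)

    def test_general_payoff_matrix_matches_oracle(self):
        state = random_state(5, seed=77)
        params = GameParams(L=5, b=1.4, reward=0.8, sucker=0.1, punishment=0.3)
        np.testing.assert_allclose(
            payoff_field(state, params).payoff, payoff_oracle(state.cp, params), rtol=1e-12
        )


class TestDistributeResource:
    def test_homogeneous_shares_are_equal(self):
        params = GameParams(L=6, b=1.3, c=1.4)
        field = payoff_field(homogeneous_state(6, 0.8), params)
        res = distribute_resource(field, params)
        assert np.allclose(res.allocated, 1.4)
        assert np.allclose(res.net, 0.4)

    def test_two_by_two_hand_example(self):
        # payoffs (4,3,2,1), c=1.25: G_sys=5, shares (2,1.5,1,0.5), H=(1,.5,0,-.5)
        params = GameParams(L=2, c=1.25)
        field = PayoffField(payoff=np.array([[4.0, 3.0], [2.0, 1.0]]), total=10.0)
        res = distribute_resource(field, params)
        np.testing.assert_allclose(res.allocated, [[2.0, 1.5], [1.0, 0.5]])
        np.testing.assert_allclose(res.net, [[1.0, 0.5], [0.0, -0.5]])
        assert int((res.net < 0).sum()) == 1

    def test_zero_payoff_lattice_splits_equally(self):
        # all-defector lattice earns zero payoff everywhere; budget split equally
        params = GameParams(L=4, c=1.9)
        field = payoff_field(homogeneous_state(4, 0.0), params)
        assert field.total == 0.0
        res = distribute_resource(field, params)
        assert np.allclose(res.allocated, 1.9)
        assert np.allclose(res.net, 0.9)
        assert res.allocated.sum() == pytest.approx(params.total_resource)

    def test_conservation_on_random_lattice(self):
        params = GameParams(L=8, b=1.8, c=1.05)
        field = payoff_field(random_state(8, seed=3), params)
        res = distribute_resource(field, params)
        assert res.allocated.sum() == pytest.approx(params.total_resource, rel=1e-12)
        assert res.net.sum() == pytest.approx((params.c - 1) * 64, rel=1e-9, abs=1e-9)


def _resources_from_net(net: np.ndarray, c: float = 1.0):
    from limres import ResourceField

    net = np.asarray(net, dtype=float)
    return ResourceField(allocated=net + 1.0, net=net, total_budget=c * net.size)


class TestSelectParent:
    def test_single_survivor_is_certain(self, rng):
        # only the north neighbour of (1,1) survives
        net = np.full((3, 3), -0.5)
        net[0, 1] = 0.7
        state = random_state(3, seed=9)
        params = GameParams(L=3)
        for _ in range(5):
            cp = select_parent((1, 1), state, _resources_from_net(net), params, rng)
            assert cp == state.cp[0, 1]

    def test_alive_site_rejected(self, rng):
        net = np.full((3, 3), 0.2)
        with pytest.raises(ValueError):
            select_parent((1, 1), random_state(3, 1), _resources_from_net(net),
                          GameParams(L=3), rng)

    def test_equal_weights_split_evenly(self, rng):
        # two survivors with H=0.5 each: empirical 50/50 within 3 binomial SE
        net = np.full((3, 3), -0.5)
        net[0, 1] = 0.5
        net[2, 1] = 0.5
        state = LatticeState(cp=np.arange(9).reshape(3, 3) / 10.0)
        params = GameParams(L=3)
        n = 10_000
        hits = sum(
            select_parent((1, 1), state, _resources_from_net(net), params, rng)
            == state.cp[0, 1]
            for _ in range(n)
        )
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_proportional_to_net_resource(self, rng):
        # survivors with H = 1 and 3 should be picked 1:3
        net = np.full((3, 3), -0.5)
        net[0, 1] = 1.0
        net[1, 0] = 3.0
        state = LatticeState(cp=np.arange(9).reshape(3, 3) / 10.0)
        params = GameParams(L=3)
        n = 10_000
        hits = sum(
            select_parent((1, 1), state, _resources_from_net(net), params, rng)
            == state.cp[0, 1]
            for _ in range(n)
        )
        assert abs(hits / n - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_zero_weight_survivors_fall_back_to_uniform(self, rng):
        # both survivors sit exactly at H=0: uniform among them
        net = np.full((3, 3), -0.5)
        net[0, 1] = 0.0
        net[1, 0] = 0.0
        state = LatticeState(cp=np.arange(9).reshape(3, 3) / 10.0)
        params = GameParams(L=3)
        n = 4_000
        hits = sum(
            select_parent((1, 1), state, _resources_from_net(net), params, rng)
            == state.cp[0, 1]
            for _ in range(n)
        )
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_all_neighbors_dead_draws_fresh_uniform(self, rng):
        net = np.full((3, 3), -0.2)
        state = LatticeState(cp=np.zeros((3, 3)))  # every neighbour CP is 0
        params = GameParams(L=3)
        draws = np.array(
            [select_parent((1, 1), state, _resources_from_net(net), params, rng)
             for _ in range(2_000)]
        )
        assert np.all((draws >= 0) & (draws <= 1))
        assert np.all(draws > 0)  # not copied from any (all-zero) neighbour
        assert abs(draws.mean() - 0.5) < 4 * np.sqrt(1 / 12 / len(draws))

    def test_gross_weighting_uses_allocated_resource(self, rng):
        # with parent_weight="gross", weights are G = H + 1: here 1 vs 3
        from limres import ResourceField

        net = np.full((3, 3), -0.5)
        net[0, 1] = 0.0
        net[1, 0] = 2.0
        res = ResourceField(allocated=net + 1.0, net=net, total_budget=9.0)
        state = LatticeState(cp=np.arange(9).reshape(3, 3) / 10.0)
        params = GameParams(L=3, parent_weight="gross")
        n = 10_000
        hits = sum(
            select_parent((1, 1), state, res, params, rng) == state.cp[0, 1]
            for _ in range(n)
        )
        assert abs(hits / n - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


class TestDeathBirthStep:
    def test_no_deaths_is_identity(self, rng):
        state = random_state(5, seed=2)
        res = _resources_from_net(np.full((5, 5), 0.3))
        result = death_birth_step(state, res, GameParams(L=5), rng)
        assert result.deaths == 0 and result.reseeded == 0
        assert np.array_equal(result.new_state.cp, state.cp)

    def test_two_by_two_example_replaces_single_site(self, rng):
        # continuation of the hand example: only (1,1) dies; its sole
        # positive-weight surviving neighbour is (0,1), so the outcome is certain
        params = GameParams(L=2, c=1.25)
        field = PayoffField(payoff=np.array([[4.0, 3.0], [2.0, 1.0]]), total=10.0)
        res = distribute_resource(field, params)
        state = LatticeState(cp=np.array([[0.9, 0.7], [0.4, 0.1]]))
        result = death_birth_step(state, res, params, rng)
        assert result.deaths == 1 and result.reseeded == 0
        expected = state.cp.copy()
        expected[1, 1] = state.cp[0, 1]
        assert np.array_equal(result.new_state.cp, expected)

    @pytest.mark.parametrize("replacement", ["synchronous", "sequential"])
    def test_homogeneous_scarcity_kills_everyone(self, rng, replacement):
        # c < 1 on a homogeneous lattice: every H = c-1 < 0, full re-randomization
        params = GameParams(L=6, b=1.5, c=0.9, replacement=replacement)
        state = homogeneous_state(6, 0.4)
        field = payoff_field(state, params)
        res = distribute_resource(field, params)
        result = death_birth_step(state, res, params, rng)
        assert result.deaths == 36
        if replacement == "synchronous":
            # every neighbour is dead in the same snapshot: all sites reseeded
            assert result.reseeded == 36
        else:
            # sequentially refilled sites rejoin the parent pool, so only the
            # earliest-processed sites need fresh draws
            assert 1 <= result.reseeded < 36
        assert np.all((result.new_state.cp >= 0) & (result.new_state.cp <= 1))
        assert not np.allclose(result.new_state.cp, 0.4)

    def test_step_selection_law_matches_resource_weights(self):
        # the vectorised step must obey the same proportional-selection law as
        # the scalar reference: survivors H=1 and H=3 picked 1:3
        net = np.full((3, 3), -0.5)
        net[0, 1] = 1.0
        net[1, 0] = 3.0
        res = _resources_from_net(net)
        state = LatticeState(cp=np.arange(9).reshape(3, 3) / 10.0)
        params = GameParams(L=3)
        n = 10_000
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(n):
            out = death_birth_step(state, res, params, rng)
            hits += out.new_state.cp[1, 1] == state.cp[0, 1]
        assert abs(hits / n - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_sequential_mode_lets_refilled_sites_parent(self):
        # 1-D-like chain of dead sites flanked by one survivor: in sequential
        # mode the survivor's CP can propagate through refilled neighbours,
        # so no site needs a fresh random draw unless isolated
        params = GameParams(L=4, replacement="sequential")
        net = np.full((4, 4), -0.5)
        net[0, 0] = 1.0
        res = _resources_from_net(net)
        state = LatticeState(cp=np.full((4, 4), 0.25))
        result = death_birth_step(state, res, params, np.random.default_rng(0))
        assert result.deaths == 15
        assert 0 <= result.reseeded <= result.deaths


class TestMcsStep:
    def test_homogeneous_abundant_lattice_is_fixed_point(self, rng):
        state = homogeneous_state(8, 0.7)
        new_state, stats = mcs_step(state, GameParams(L=8, b=1.4, c=1.5), rng)
        assert stats.deaths == 0
        assert stats.mean_cp == pytest.approx(0.7)
        assert stats.std_cp == pytest.approx(0.0)
        assert np.array_equal(new_state.cp, state.cp)
        assert new_state.mcs == state.mcs + 1

    def test_homogeneous_scarce_lattice_all_die(self, rng):
        _, stats = mcs_step(homogeneous_state(10, 0.6), GameParams(L=10, c=0.8), rng)
        assert stats.deaths == 100

    def test_cp_stays_in_unit_interval(self, rng):
        state = random_state(12, seed=4)
        params = GameParams(L=12, b=1.9, c=1.01)
        for _ in range(20):
            state, _ = mcs_step(state, params, rng)
            assert np.all((state.cp >= 0) & (state.cp <= 1))
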