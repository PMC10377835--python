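"""Competitive search operators and the full optimization loop."""

import numpy as np
import pytest

from oraldx.optimizer import (
    AmendmentDraws,
    CSOConfig,
    SearchSpace,
    UpdateDraws,
    draw_update,
    initialize,
    opposition_jump,
    optimize,
    rank_and_split,
    reference_update,
    sine_cosine_worst_update,
    update_excellent,
    update_general,
    withdraw_replace,
)

SPACE2 = SearchSpace.cube(2, 0.0, 10.0)


def make_draws(**kw):
    base = dict(rho=1, alpha=0.5, q=1.0, l2=np.ones(2), o=0.5, p=1.0, rand1=1.0)
    base.update(kw)
    return UpdateDraws(**base)


class TestConfig:
    def test_defaults_resolved(self):
        cfg = CSOConfig(n=60)
        assert cfg.ec == 30 and cfg.rc == 6

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError):
            CSOConfig(n=1)

    def test_bad_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            CSOConfig(n=10, ec=10)
        with pytest.raises(ValueError):
            CSOConfig(n=10, rc=10)

    def test_space_requires_lb_below_ub(self):
        with pytest.raises(ValueError):
            SearchSpace(lb=np.array([0.0, 1.0]), ub=np.array([1.0, 1.0]))


class TestInitialize:
    def test_same_seed_identical(self):
        cfg = CSOConfig(n=8)
        p1, a1 = initialize(SPACE2, cfg, np.random.default_rng(5))
        p2, a2 = initialize(SPACE2, cfg, np.random.default_rng(5))
        assert np.array_equal(p1, p2) and np.array_equal(a1, a2)

    def test_positions_within_bounds(self):
        p, a = initialize(SPACE2, CSOConfig(n=50), np.random.default_rng(0))
        assert np.all(p >= SPACE2.lb) and np.all(p <= SPACE2.ub)
        assert np.all((a >= 0) & (a <= 1))

    def test_empirical_mean_matches_uniform(self):
        space = SearchSpace.cube(2, -4.0, 10.0)
        p, _ = initialize(space, CSOConfig(n=10_000), np.random.default_rng(7))
        se = (space.ub[0] - space.lb[0]) / np.sqrt(12) / np.sqrt(10_000)
        for j in range(2):
            assert abs(p[:, j].mean() - 3.0) < 3 * se


class TestRankAndSplit:
    def test_lowest_cost_is_excellent(self):
        exc, gen = rank_and_split(np.array([3.0, 1.0, 2.0]), 1)
        assert list(exc) == [1] and list(gen) == [2, 0]

    def test_stable_tie_break_by_index(self):
        exc, gen = rank_and_split(np.array([1.0, 1.0, 1.0]), 2)
        assert list(exc) == [0, 1] and list(gen) == [2]

    def test_partition_covers_population(self):
        costs = np.arange(10.0)
        exc, gen = rank_and_split(costs, 4)
        assert len(exc) + len(gen) == 10

    def test_unevaluated_rejected(self):
        with pytest.raises(RuntimeError):
            rank_and_split(np.array([1.0, np.nan]), 1)


class TestGroupUpdates:
    CFG = CSOConfig(n=10)  # ub_pct=20, lb_pct=5, l1=0.5

    def test_zero_direction_keeps_position(self):
        pos = np.array([3.0, 4.0])
        out = update_excellent(pos, 0.9, SPACE2, self.CFG, make_draws(rho=0))
        assert np.array_equal(out, pos)

    def test_strong_learner_step_hand_value(self):
        # rand1=1 -> S1 = (5 + 15)/100 = 0.2; A=1, rho=1, range 10 -> +2
        out = update_excellent(
            np.array([1.0, 2.0]), 1.0, SPACE2, self.CFG, make_draws(rand1=1.0, rho=1)
        )
        np.testing.assert_allclose(out, [3.0, 4.0])

    def test_normal_learner_step_bounded_by_lb_pct(self, rng):
        for _ in range(20):
            d = draw_update(rng, 2)
            pos = np.array([5.0, 5.0])
            out = update_excellent(pos, 0.4, SPACE2, self.CFG, d)
            assert np.all(np.abs(out - pos) <= 0.05 * 10.0 + 1e-12)

    def test_general_zero_alpha_keeps_position(self):
        pos = np.array([2.0, 3.0])
        out = update_general(pos, 0.9, SPACE2, self.CFG, make_draws(alpha=0.0))
        assert np.array_equal(out, pos)

    def test_general_zero_ability_annihilates(self):
        out = update_general(
            np.array([2.0, 3.0]), 0.0, SPACE2, self.CFG, make_draws()
        )
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_general_elementwise_rescale(self):
        # normal learner (A <= L1): Y' = Y * L2 * F * A with F = P*o
        space = SearchSpace.cube(2, -1.0, 1.0)
        out = update_general(
            np.array([1.0, 1.0]),
            0.4,
            space,
            self.CFG,
            make_draws(l2=np.array([1.0, -1.0]), p=2.5, o=0.5),  # F = 1.25
        )
        np.testing.assert_allclose(out, [0.5, -0.5])


class TestReferenceUpdate:
    def test_full_ability_jumps_to_best(self):
        out = reference_update(np.array([1.0, 2.0]), 1.0, np.array([7.0, 8.0]), 0.7, SPACE2)
        np.testing.assert_allclose(out, [7.0, 8.0])

    def test_low_ability_gated(self):
        pos = np.array([1.0, 2.0])
        out = reference_update(pos, 0.7, np.array([7.0, 8.0]), 0.7, SPACE2)
        assert np.array_equal(out, pos)

    def test_midpoint_for_half_ability(self):
        out = reference_update(np.zeros(2), 0.5, np.array([2.0, 2.0]), 0.3, SPACE2)
        np.testing.assert_allclose(out, [1.0, 1.0])


class TestWithdrawReplace:
    def test_rc_zero_is_identity(self, rng):
        pos = rng.uniform(0, 10, size=(5, 2))
        ab = rng.random(5)
        costs = rng.random(5)
        snap = (pos.copy(), ab.copy(), costs.copy())
        withdraw_replace(pos, ab, costs, 0, SPACE2, rng)
        assert np.array_equal(pos, snap[0]) and np.array_equal(costs, snap[2])

    def test_best_contestant_survives(self, rng):
        pos = np.arange(6.0).reshape(3, 2)
        ab = np.array([0.1, 0.2, 0.3])
        costs = np.array([5.0, 1.0, 9.0])
        withdraw_replace(pos, ab, costs, 2, SPACE2, rng, objective=lambda x: 100.0)
        np.testing.assert_allclose(pos[1], [2.0, 3.0])
        assert costs[1] == 1.0

    def test_population_size_conserved(self, rng):
        pos = rng.uniform(0, 10, size=(7, 2))
        ab = rng.random(7)
        costs = rng.random(7)
        withdraw_replace(pos, ab, costs, 3, SPACE2, rng, objective=lambda x: 0.5)
        assert pos.shape == (7, 2) and len(costs) == 7


class TestAmendmentOperators:
    def test_decayed_amplitude_keeps_position(self):
        worst = np.array([3.0, 3.0])
        d = AmendmentDraws(a1=0.0, a2=1.0, a3=1.5, a4=0.2)
        assert np.array_equal(
            sine_cosine_worst_update(worst, np.array([9.0, 9.0]), SPACE2, d), worst
        )

    def test_worst_at_best_with_unit_a3_fixed(self):
        g = np.array([4.0, 4.0])
        d = AmendmentDraws(a1=2.0, a2=0.3, a3=1.0, a4=0.9)
        np.testing.assert_allclose(sine_cosine_worst_update(g.copy(), g, SPACE2, d), g)

    def test_hand_computed_sine_step(self):
        d = AmendmentDraws(a1=2.0, a2=np.pi / 2, a3=1.0, a4=0.2)
        out = sine_cosine_worst_update(
            np.zeros(1), np.ones(1), SearchSpace.cube(1, -5.0, 5.0), d
        )
        np.testing.assert_allclose(out, [2.0])

    def test_a1_decays_linearly_to_zero(self):
        first = AmendmentDraws.draw(np.random.default_rng(0), 1, 100, 2.0)
        last = AmendmentDraws.draw(np.random.default_rng(0), 100, 100, 2.0)
        assert first.a1 == pytest.approx(2.0 - 0.02)
        assert last.a1 == pytest.approx(0.0)

    def test_opposition_midpoint_fixed_point(self):
        pos = np.array([5.0, 5.0])
        out, cost, n = opposition_jump(pos, 1.0, lambda x: 1.0, SPACE2, 1.0, 0.0)
        np.testing.assert_allclose(out, pos)

    def test_opposition_reflects_lb_to_ub(self):
        np.testing.assert_allclose(SPACE2.opposite(SPACE2.lb), SPACE2.ub)
        # from lb with a worse cost than the reflected ub, the jump lands on ub
        out, cost, _ = opposition_jump(
            SPACE2.lb.copy(), 100.0, lambda x: float(x.sum()), SPACE2, 1.0, 0.0
        )
        np.testing.assert_allclose(out, SPACE2.ub)
        assert cost == 20.0

    def test_opposition_greedy_never_worse(self, rng):
        obj = lambda x: float(np.sum((x - 2.0) ** 2))
        for _ in range(10):
            pos = rng.uniform(0, 10, size=2)
            c0 = obj(pos)
            _, c1, spent = opposition_jump(pos, c0, obj, SPACE2, 1.0, 0.0)
            assert spent == 1 and c1 <= c0

    def test_no_jump_above_rate(self):
        pos = np.array([1.0, 1.0])
        out, cost, spent = opposition_jump(pos, 3.0, lambda x: 0.0, SPACE2, 0.3, 0.9)
        assert spent == 0 and cost == 3.0 and np.array_equal(out, pos)


class TestOptimize:
    def test_improves_over_initial_best(self):
        res = optimize(
            lambda x: float(np.sum(x**2)),
            SearchSpace.cube(2, -5.0, 5.0),
            CSOConfig(n=20, iterations=50),
            seed=0,
        )
        assert res.best_cost < res.cost_history[0] or res.best_cost == 0.0
        assert res.best_cost == res.cost_history[-1]

    @pytest.mark.parametrize("mode", ["CSO", "ACSO"])
    def test_history_non_increasing(self, mode):
        res = optimize(
            lambda x: float(np.sum((x - 1.0) ** 2)),
            SearchSpace.cube(3, -5.0, 5.0),
            CSOConfig(n=15, iterations=40),
            mode=mode,
            seed=3,
        )
        assert np.all(np.diff(res.cost_history) <= 0)
        assert res.best_cost == res.cost_history.min()

    def test_quadratic_optimum_recovery(self):
        errs = []
        for seed in range(20):
            res = optimize(
                lambda x: (x[0] - 3.0) ** 2,
                SearchSpace.cube(1, 0.0, 10.0),
                CSOConfig(n=30, iterations=100),
                seed=seed,
            )
            errs.append(abs(res.best_position[0] - 3.0))
        assert np.median(errs) < 0.05

    def test_deterministic_replay(self):
        obj = lambda x: float(np.sum(np.abs(x)))
        kw = dict(
            space=SearchSpace.cube(4, -2.0, 2.0),
            cfg=CSOConfig(n=12, iterations=25),
            mode="ACSO",
            seed=11,
        )
        r1 = optimize(obj, **kw)
        r2 = optimize(obj, **kw)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.cost_history, r2.cost_history)
        assert r1.evaluations == r2.evaluations

    @pytest.mark.parametrize("mode", ["CSO", "ACSO"])
    def test_evaluation_count_exact(self, mode):
        calls = [0]

        def obj(x):
            calls[0] += 1
            return float(np.sum(x**2))

        res = optimize(
            obj, SearchSpace.cube(2, -1.0, 1.0), CSOConfig(n=10, iterations=15),
            mode=mode, seed=2,
        )
        assert res.evaluations == calls[0]

    def test_every_evaluated_position_in_bounds(self):
        space = SearchSpace.cube(3, -1.5, 2.5)

        def obj(x):
            assert np.all(x >= space.lb - 1e-12) and np.all(x <= space.ub + 1e-12)
            return float(np.sum(x**2))

        optimize(obj, space, CSOConfig(n=10, iterations=20), seed=4)

    def test_non_finite_objective_flagged_as_inf(self, caplog):
        def obj(x):
            return np.nan if x[0] > 0 else float(x[0] ** 2)

        res = optimize(
            obj, SearchSpace.cube(1, -1.0, 1.0), CSOConfig(n=8, iterations=10), seed=0
        )
        assert np.isfinite(res.best_cost)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0, SPACE2, CSOConfig(n=5, iterations=2), mode="XYZ")
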