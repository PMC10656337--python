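"""ML1 identification: L1 profile, weighted-median LAD solver, condition
checks, and the equivalence-class transform."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import difml1 as dm


def grid_argmin(gamma, a, step=1e-4):
    """Independent oracle: brute-force minimization of h(c) on a fine grid."""
    r = gamma / a
    lo, hi = r.min() - 1.0, r.max() + 1.0
    grid = np.arange(lo, hi + step, step)
    h = np.abs(gamma[None, :] - np.outer(grid, a)).sum(axis=1)
    return grid[np.argmin(h)], h.min()


class TestL1Profile:
    def test_toy_example_value(self, fig_toy):
        gamma, a = fig_toy
        assert dm.l1_profile(gamma, a, 0.0) == pytest.approx(2.0)
        assert dm.l1_profile(np.zeros(6), np.arange(1.0, 7.0), 0.0) == 0.0

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(0)
        g, a, c = rng.normal(size=8), rng.normal(size=8), 0.37
        assert dm.l1_profile(g, a, c) == pytest.approx(np.abs(g - a * c).sum())

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            dm.l1_profile(np.zeros(3), np.ones(4), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 1.0))
    def test_convexity(self, seed, lam):
        rng = np.random.default_rng(seed)
        g, a = rng.normal(size=7), rng.normal(size=7)
        c1, c2 = rng.uniform(-3, 3, 2)
        mid = lam * c1 + (1 - lam) * c2
        assert dm.l1_profile(g, a, mid) <= (
            lam * dm.l1_profile(g, a, c1)
            + (1 - lam) * dm.l1_profile(g, a, c2) + 1e-9)


class TestMl1Shift:
    def test_toy_minimizer_is_zero(self, fig_toy):
        assert dm.ml1_shift(*fig_toy) == 0.0

    def test_single_item_exact_fit(self):
        assert dm.ml1_shift(np.array([3.0]), np.array([2.0])) == \
            pytest.approx(1.5)

    def test_lower_weighted_median_tie_break(self):
        # total weight splits exactly in half: [0, 1] all minimize; lower end
        assert dm.weighted_median(np.array([0.0, 1.0]),
                                  np.array([1.0, 1.0])) == 0.0

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            J = rng.integers(2, 13)
            a = rng.uniform(0.5, 2.0, J) * rng.choice([-1, 1], J)
            g = rng.uniform(-1.5, 1.5, J)
            c_wm = dm.ml1_shift(g, a)
            c_grid, h_grid = grid_argmin(g, a)
            assert dm.l1_profile(g, a, c_wm) <= h_grid + 1e-9
            assert abs(c_wm - c_grid) <= 1.1e-4

    def test_local_minimality(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(0.3, 2.0, 9) * rng.choice([-1, 1], 9)
            g = rng.normal(size=9)
            c = dm.ml1_shift(g, a)
            for eps in (1e-3, 1e-2, 1e-1):
                assert dm.l1_profile(g, a, c) <= dm.l1_profile(g, a, c + eps) + 1e-12
                assert dm.l1_profile(g, a, c) <= dm.l1_profile(g, a, c - eps) + 1e-12

    def test_zero_slopes_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            c = dm.ml1_shift(np.array([5.0, 1.0, 1.0]),
                             np.array([0.0, 1.0, 1.0]))
        assert c == pytest.approx(1.0)
        with pytest.raises(ValueError, match="degenerate"):
            dm.ml1_shift(np.array([1.0, 2.0]), np.zeros(2))


class TestConditionChecks:
    def test_toy_counts_and_verdict(self, fig_toy):
        v = dm.check_prop1(*fig_toy)
        assert v.holds
        assert v.indicator_counts == (10, 0, 8, 2)
        assert v.ineq7_lhs < 0 < v.ineq8_lhs

    def test_zero_dif_always_holds(self):
        a = np.array([1.0, 2.0, 0.5, 1.5])
        assert dm.check_prop1(np.zeros(4), a).holds
        v = dm.check_cor1(np.zeros(4), a)
        assert v.holds
        assert v.rho_star == pytest.approx(4.0)

    def test_one_sided_dif_fails_when_half_items_affected(self):
        g, a = np.array([1.0, 1.0, 1.0, 0.0]), np.ones(4)
        v = dm.check_prop1(g, a)
        assert not v.holds
        c_grid, _ = grid_argmin(g, a)
        assert abs(c_grid) > 0.5  # grid confirms the minimizer is away from 0

    def test_cor1_direct_inequality_evaluation(self):
        # 7 null, 1 positive-ratio, 1 negative-ratio item, rho* = 2
        a = np.array([1.0] * 7 + [2.0, 1.0])
        g = np.array([0.0] * 7 + [0.8, -0.4])
        v = dm.check_cor1(g, a)
        n_ge, n_lt, n_le, n_gt = v.indicator_counts
        assert (n_le > 2.0 * n_gt) and (n_ge > 2.0 * n_lt)
        assert v.holds

    def test_cor1_sufficient_not_necessary(self):
        # balanced +/- DIF with a large slope spread: sign condition holds
        # while the count condition fails
        a = np.array([4.0, 1.0, 1.0])
        g = np.array([0.0, 1.0, -1.0])
        assert dm.check_prop1(g, a).holds
        assert not dm.check_cor1(g, a).holds

    def test_cor1_implies_prop1_randomized(self):
        """Sufficiency on 10,000 random instances (never the converse)."""
        rng = np.random.default_rng(123)
        n_checked = 0
        for _ in range(10_000):
            J = rng.integers(3, 12)
            a = rng.uniform(0.3, 3.0, J) * rng.choice([-1, 1], J)
            n_dif = rng.integers(0, J)
            g = np.zeros(J)
            g[:n_dif] = rng.uniform(-1.5, 1.5, n_dif)
            if dm.check_cor1(g, a).holds:
                n_checked += 1
                assert dm.check_prop1(g, a).holds
        assert n_checked > 100  # the implication was actually exercised

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            dm.check_prop1(np.zeros(3), np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            dm.check_cor1(np.zeros(3), np.array([1.0, 0.0, 1.0]))


class TestMl1Transform:
    def _random_params(self, rng, J=8):
        return dm.ModelParams(
            beta=rng.normal(), sigma2=rng.uniform(0.2, 2.0),
            a=rng.uniform(0.5, 2.0, J), d=rng.normal(size=J),
            gamma=np.concatenate([np.zeros(J - 3),
                                  rng.uniform(-1, 1, 3)]))

    def test_identified_params_are_fixed_point(self, fig_toy):
        gamma, a = fig_toy
        params = dm.ModelParams(0.0, 1.0, a, np.zeros(10), gamma)
        out, shift = dm.ml1_transform(params)
        assert shift == 0.0
        np.testing.assert_array_equal(out.gamma, gamma)

    def test_invariance_over_equivalence_class(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            params = self._random_params(rng)
            c = rng.uniform(-2, 2)
            shifted = dm.ModelParams(params.beta + c, params.sigma2, params.a,
                                     params.d, params.gamma - params.a * c)
            out1, _ = dm.ml1_transform(params)
            out2, _ = dm.ml1_transform(shifted)
            np.testing.assert_allclose(out1.gamma, out2.gamma, atol=1e-10)
            np.testing.assert_allclose(out1.beta, out2.beta, atol=1e-10)

    def test_l1_never_increases_and_idempotent(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            params = self._random_params(rng)
            c = rng.uniform(-2, 2)
            shifted = dm.ModelParams(params.beta + c, params.sigma2, params.a,
                                     params.d, params.gamma - params.a * c)
            out, _ = dm.ml1_transform(shifted)
            assert np.abs(out.gamma).sum() <= np.abs(shifted.gamma).sum() + 1e-12
            again, shift2 = dm.ml1_transform(out)
            assert shift2 == 0.0
            np.testing.assert_array_equal(again.gamma, out.gamma)

    def test_preserves_marginal_loglik(self):
        rng = np.random.default_rng(13)
        params = self._random_params(rng, J=5)
        data = dm.ResponseData(rng.integers(0, 2, (30, 5)),
                               rng.integers(0, 2, 30))
        out, _ = dm.ml1_transform(params)
        quad = dm.QuadratureSpec(41)
        assert dm.marginal_loglik(out, data, quad) == pytest.approx(
            dm.marginal_loglik(params, data, quad), abs=1e-6)

    def test_all_table_designs_satisfy_ml1_condition(self):
        """Every resolved study design passes the sign condition."""
        for mag in ("small", "large"):
            for prop in ("high", "medium", "low"):
                g = dm.DIF_GAMMA[(mag, prop)]
                assert dm.check_prop1(g, dm.DISCRIMINATION).holds
                assert dm.ml1_shift(g, dm.DISCRIMINATION) == 0.0
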