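"""Mode/variance parameterization of the beta family and its inversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import beta as beta_dist

from pdffnet.beta_math import (
    BetaParams,
    CredibleInterval,
    ModeVarianceSpec,
    beta_credible_interval,
    beta_mode,
    beta_variance,
    max_feasible_variance,
    solve_beta_from_mode_variance,
)


def grid_argmax_mode(alpha: float, beta: float, n: int = 200_001) -> float:
    """Independent oracle: argmax of the log-density on a dense grid."""
    x = np.linspace(1e-6, 1 - 1e-6, n)
    logpdf = (alpha - 1) * np.log(x) + (beta - 1) * np.log1p(-x)
    return float(x[np.argmax(logpdf)])


def grid_search_concentration(mode: float, variance: float, s_max: float = 500.0, n: int = 2_000_001) -> tuple[float, float]:
    """Independent oracle: scan total concentration s for the target variance."""
    s = np.linspace(2.0 + 1e-6, s_max, n)
    a = 1 + mode * (s - 2)
    b = 1 + (1 - mode) * (s - 2)
    var = a * b / (s**2 * (s + 1))
    k = int(np.argmin(np.abs(var - variance)))
    return float(a[k]), float(b[k])


class TestMode:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(2.0, 2.0, 0.5), (3.0, 2.0, 2.0 / 3.0)],
    )
    def test_closed_form(self, alpha, beta, expected):
        assert beta_mode(BetaParams(alpha, beta)) == pytest.approx(expected, abs=1e-12)

    def test_matches_density_argmax(self):
        assert beta_mode(BetaParams(2.33, 26.3)) == pytest.approx(grid_argmax_mode(2.33, 26.3), abs=1e-4)

    def test_matches_density_argmax_random_shapes(self, rng):
        for _ in range(50):
            a = 1.0 + rng.uniform(0.05, 30)
            b = 1.0 + rng.uniform(0.05, 30)
            assert beta_mode(BetaParams(a, b)) == pytest.approx(grid_argmax_mode(a, b), abs=1e-4)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 2.0), (0.5, 3.0), (2.0, 1.0), (np.inf, 2.0)])
    def test_rejects_invalid_shapes(self, alpha, beta):
        with pytest.raises(ValueError):
            BetaParams(alpha, beta)


class TestVariance:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(2.0, 2.0, 0.05), (1.5, 1.5, 0.0625), (2.0, 5.0, 10.0 / 392.0)],
    )
    def test_closed_form(self, alpha, beta, expected):
        assert beta_variance(BetaParams(alpha, beta)) == pytest.approx(expected, rel=1e-12)


class TestMaxFeasibleVariance:
    def test_symmetric_floor_is_beta22(self):
        assert max_feasible_variance(0.5, 4.0) == pytest.approx(0.05, abs=1e-14)

    def test_uniform_limit(self):
        for mode in (0.1, 0.5, 0.9):
            assert max_feasible_variance(mode, 2.0 + 1e-9) == pytest.approx(1.0 / 12.0, abs=1e-6)

    def test_matches_direct_evaluation(self):
        # floor 10, mode 0.1 puts the line at Beta(1.8, 8.2)
        assert max_feasible_variance(0.1, 10.0) == pytest.approx(beta_variance(BetaParams(1.8, 8.2)), rel=1e-12)

    def test_rejects_floor_at_or_below_two(self):
        with pytest.raises(ValueError):
            max_feasible_variance(0.3, 2.0)


class TestInversion:
    def test_symmetric_case(self):
        p = solve_beta_from_mode_variance(ModeVarianceSpec(0.5, 0.05))
        assert p.alpha == pytest.approx(2.0, abs=1e-9)
        assert p.beta == pytest.approx(2.0, abs=1e-9)

    def test_low_fat_auxiliary_variance_matches_grid_oracle(self):
        p = solve_beta_from_mode_variance(ModeVarianceSpec(0.05, 0.0025))
        a_ref, b_ref = grid_search_concentration(0.05, 0.0025)
        assert p.alpha == pytest.approx(a_ref, abs=1e-3)
        assert p.beta == pytest.approx(b_ref, abs=1e-3)
        assert beta_mode(p) == pytest.approx(0.05, abs=1e-12)
        assert beta_variance(p) == pytest.approx(0.0025, abs=1e-10)

    def test_infeasible_variance_raises_with_maximum_named(self):
        # between the numerically attainable maximum and the 1/12 supremum
        near_sup = 1.0 / 12.0 - 1e-9
        with pytest.raises(ValueError, match="maximum"):
            solve_beta_from_mode_variance(ModeVarianceSpec(0.5, near_sup))

    def test_above_supremum_rejected_by_spec_type(self):
        with pytest.raises(ValueError):
            ModeVarianceSpec(0.5, 0.2)

    def test_clamp_policy_returns_feasible_params(self):
        near_sup = 1.0 / 12.0 - 1e-9
        p = solve_beta_from_mode_variance(ModeVarianceSpec(0.5, near_sup), on_infeasible="clamp")
        assert beta_mode(p) == pytest.approx(0.5, abs=1e-12)
        assert beta_variance(p) < 1.0 / 12.0

    @pytest.mark.parametrize("mode", [0.01, 0.02, 0.05, 0.1, 0.3, 0.5, 0.9])
    @pytest.mark.parametrize("variance", [1e-4, 2.5e-3, 1e-2, 5e-2])
    def test_round_trip_grid(self, mode, variance):
        if variance >= max_feasible_variance(mode, 2.0 + 1e-6):
            pytest.skip("infeasible combination by construction")
        p = solve_beta_from_mode_variance(ModeVarianceSpec(mode, variance))
        assert beta_mode(p) == pytest.approx(mode, abs=1e-12)
        assert abs(beta_variance(p) - variance) <= 1e-10

    def test_variance_strictly_decreasing_in_concentration(self):
        # the premise that makes one-dimensional root-finding valid
        s = np.linspace(2.0 + 1e-6, 1000.0, 20000)
        for mode in (0.01, 0.1, 0.5, 0.9, 0.99):
            a = 1 + mode * (s - 2)
            b = 1 + (1 - mode) * (s - 2)
            var = a * b / (s**2 * (s + 1))
            assert (np.diff(var) < 0).all()

    @given(
        mode=st.floats(0.005, 0.995),
        variance=st.floats(1e-6, 0.05),
    )
    def test_round_trip_property(self, mode, variance):
        if variance >= 0.99 * max_feasible_variance(mode, 2.0 + 1e-6):
            return
        p = solve_beta_from_mode_variance(ModeVarianceSpec(mode, variance))
        assert beta_mode(p) == pytest.approx(mode, abs=1e-9)
        assert abs(beta_variance(p) - variance) <= 1e-10


class TestCredibleInterval:
    def test_beta22_against_polynomial_cdf_roots(self):
        # CDF of Beta(2,2) is 3x^2 - 2x^3; solve for the 2.5% / 97.5% quantiles
        def cdf_root(q):
            roots = np.roots([-2.0, 3.0, 0.0, -q])
            real = roots[np.isreal(roots)].real
            return float(real[(real >= 0) & (real <= 1)][0])

        ci = beta_credible_interval(BetaParams(2.0, 2.0), 0.95)
        assert ci.lower == pytest.approx(cdf_root(0.025), abs=1e-9)
        assert ci.upper == pytest.approx(cdf_root(0.975), abs=1e-9)
        assert ci.lower == pytest.approx(0.0943, abs=5e-4)
        assert ci.upper == pytest.approx(0.9057, abs=5e-4)

    @pytest.mark.parametrize("shape", [1.5, 2.0, 5.0, 20.0])
    @pytest.mark.parametrize("level", [0.5, 0.9, 0.99])
    def test_symmetric_shapes_give_symmetric_intervals(self, shape, level):
        ci = beta_credible_interval(BetaParams(shape, shape), level)
        assert ci.lower + ci.upper == pytest.approx(1.0, abs=1e-9)

    def test_level_to_one_limit(self):
        ci = beta_credible_interval(BetaParams(2.0, 2.0), 1 - 1e-12)
        assert ci.lower == pytest.approx(0.0, abs=1e-4)
        assert ci.upper == pytest.approx(1.0, abs=1e-4)

    def test_equal_tail_property_on_grid(self):
        for a in (1.2, 2.0, 5.0, 40.0):
            for b in (1.2, 3.0, 25.0, 200.0):
                ci = beta_credible_interval(BetaParams(a, b), 0.95)
                assert beta_dist.cdf(ci.lower, a, b) == pytest.approx(0.025, abs=1e-8)
                assert 1 - beta_dist.cdf(ci.upper, a, b) == pytest.approx(0.025, abs=1e-8)

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            beta_credible_interval(BetaParams(2, 2), 1.0)

    def test_interval_type_invariants(self):
        with pytest.raises(ValueError):
            CredibleInterval(0.5, 0.4, 0.95)
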