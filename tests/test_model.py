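import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import wienerdm as w
from oracles import choice_probability_oracle, series_density_oracle

finite_params = {
    "a": st.floats(0.2, 4.0),
    "z_rel": st.floats(0.08, 0.92),
    "nu": st.floats(-4.0, 4.0),
    "s2": st.floats(0.3, 3.0),
}


class TestChoiceProbability:
    def test_default_set_matches_closed_form(self, defaults):
        # at z_rel = 0.5 the ruin probability reduces to 1 / (1 + exp(nu a / s2))
        p = w.lower_choice_probability(defaults)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(0.2)), abs=1e-12)
        assert p == pytest.approx(0.4502, abs=5e-5)

    def test_driftless_limit_is_complement_of_start_point(self):
        assert w.lower_choice_probability(w.DMParameters(z_rel=0.3, nu=0.0)) == 0.7
        assert w.lower_choice_probability(w.DMParameters(a=2.5, nu=0.0, s2=0.6)) == 0.5

    def test_continuity_at_zero_drift(self):
        for z in (0.2, 0.5, 0.8):
            p_eps = w.lower_choice_probability(w.DMParameters(z_rel=z, nu=1e-6))
            assert abs(p_eps - (1.0 - z)) < 1e-5

    @given(**finite_params)
    def test_matches_naive_formula_and_stays_in_unit_interval(self, a, z_rel, nu, s2):
        p = w.lower_choice_probability(w.DMParameters(a=a, z_rel=z_rel, nu=nu, s2=s2))
        assert 0.0 <= p <= 1.0
        if 1e-6 < abs(2 * nu * a / s2) < 500:  # naive formula unstable outside this
            assert p == pytest.approx(choice_probability_oracle(a, z_rel, nu, s2), abs=1e-10)

    @given(**finite_params)
    def test_boundary_probabilities_are_complementary(self, a, z_rel, nu, s2):
        p_lo = w.lower_choice_probability(w.DMParameters(a=a, z_rel=z_rel, nu=nu, s2=s2))
        p_up_mirror = w.lower_choice_probability(
            w.DMParameters(a=a, z_rel=1.0 - z_rel, nu=-nu, s2=s2)
        )
        assert p_lo + p_up_mirror == pytest.approx(1.0, abs=1e-12)

    def test_extreme_drift_does_not_overflow(self):
        assert w.lower_choice_probability(w.DMParameters(nu=500.0)) == pytest.approx(0.0, abs=1e-12)
        assert w.lower_choice_probability(w.DMParameters(nu=-500.0)) == pytest.approx(1.0, abs=1e-12)


class TestSeries:
    def test_matches_exhaustive_summation_at_default_point(self):
        # frozen from the exhaustive plain-python oracle
        val = w.evaluate_series(0.5, 1.0, 0.5, 0.2, 1.0, 100)
        assert val == pytest.approx(0.2386705279047044, abs=1e-12)
        assert val == pytest.approx(series_density_oracle(0.5, 1.0, 0.5, 0.2), abs=1e-12)

    @pytest.mark.parametrize(
        "t, a, z_abs, nu, s2",
        [
            (0.3, 1.0, 0.5, 0.2, 1.0),
            (0.08, 1.2, 0.4, -1.0, 1.0),
            (1.5, 2.0, 1.3, 0.7, 0.8),
            (0.6, 0.6, 0.12, 2.5, 1.0),
        ],
    )
    def test_matches_exhaustive_summation(self, t, a, z_abs, nu, s2):
        got = w.evaluate_series(t, a, z_abs, nu, s2, 100)
        want = series_density_oracle(t, a, z_abs, nu, s2)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_truncation_at_one_term_already_converged_at_moderate_time(self):
        # at t = 0.5 s only the k = 1 term survives to ~2e-9
        d1 = w.evaluate_series(0.5, 1.0, 0.5, 0.2, 1.0, 1)
        d100 = w.evaluate_series(0.5, 1.0, 0.5, 0.2, 1.0, 100)
        assert abs(d1 - d100) < 2e-9

    def test_underflow_limit_is_exact_zero(self):
        assert w.evaluate_series(200.0, 1.0, 0.5, 0.2, 1.0, 100) == 0.0

    def test_nonpositive_decision_time_rejected(self):
        with pytest.raises(w.ParameterError, match="t_dec_s"):
            w.evaluate_series(0.0, 1.0, 0.5, 0.2, 1.0, 100)
        with pytest.raises(w.ParameterError, match="t_dec_s"):
            w.evaluate_series(-0.1, 1.0, 0.5, 0.2, 1.0, 100)

    def test_negative_partial_sum_is_clamped_with_warning(self):
        # small kmax near t0 produces the known spike artifact (raw sum < 0)
        with pytest.warns(w.TruncationArtifactWarning):
            val = w.evaluate_series(0.01, 1.0, 0.8, 0.2, 1.0, 10)
        assert val == 0.0


class TestPointDensities:
    def test_zero_before_and_at_nondecision_time(self, defaults, default_numerics):
        assert w.fpt_density_lower(300.0, defaults, default_numerics) == 0.0
        assert w.fpt_density_lower(100.0, defaults, default_numerics) == 0.0
        assert w.fpt_density_upper(0.0, defaults, default_numerics) == 0.0

    def test_lower_density_at_800ms_is_series_at_half_second(self, defaults, default_numerics):
        got = w.fpt_density_lower(800.0, defaults, default_numerics)
        assert got == pytest.approx(0.2386705279047044, abs=1e-12)

    def test_upper_density_is_reflected_lower_density(self, default_numerics):
        p = w.DMParameters(z_rel=0.3, nu=0.5)
        mirror = w.DMParameters(z_rel=0.7, nu=-0.5)
        for t in (350.0, 500.0, 900.0, 1800.0):
            assert w.fpt_density_upper(t, p, default_numerics) == w.fpt_density_lower(
                t, mirror, default_numerics
            )

    def test_symmetric_parameters_give_identical_densities(self, default_numerics):
        p = w.DMParameters(z_rel=0.5, nu=0.0)
        for t in (400.0, 700.0, 1200.0):
            assert w.fpt_density_upper(t, p, default_numerics) == w.fpt_density_lower(
                t, p, default_numerics
            )


class TestDensityCurve:
    def test_default_curve_shape_and_probabilities(self, defaults, default_numerics):
        c = w.density_curve(defaults, default_numerics)
        assert len(c.times_ms) == default_numerics.n_points
        assert c.times_ms[0] == 0.0 and c.times_ms[-1] == default_numerics.t_max_ms
        assert np.all(np.diff(c.times_ms) > 0)
        assert np.all(c.g_upper >= 0) and np.all(c.g_lower >= 0)
        assert c.p_lower == pytest.approx(0.4502, abs=5e-5)
        assert c.p_upper == pytest.approx(1 - c.p_lower)
        assert np.all(c.g_upper[c.times_ms <= 300.0] == 0.0)
        assert np.all(c.g_lower[c.times_ms <= 300.0] == 0.0)

    def test_upper_mass_complements_lower_probability(self, defaults):
        num = w.NumericsConfig(t_max_ms=5000.0, n_points=5000)
        c = w.density_curve(defaults, num)
        assert c.mass_upper() == pytest.approx(1 - w.lower_choice_probability(defaults), abs=1e-4)
        assert c.mass_upper() == pytest.approx(0.5498, abs=1e-3)

    def test_grid_must_extend_past_nondecision_time(self, defaults):
        with pytest.raises(w.ParameterError, match="t_max_ms"):
            w.density_curve(defaults, w.NumericsConfig(t_max_ms=250.0))

    def test_shifting_t0_translates_curves_exactly(self):
        # 2 ms grid step, 100 ms shift: translated values are bit-identical
        num = w.NumericsConfig(t_max_ms=2000.0, n_points=1001)
        base = w.density_curve(w.DMParameters(t0_ms=300.0), num)
        shifted = w.density_curve(w.DMParameters(t0_ms=400.0), num)
        k = 50  # 100 ms / 2 ms
        assert np.array_equal(shifted.g_upper[k:], base.g_upper[:-k])
        assert np.array_equal(shifted.g_lower[k:], base.g_lower[:-k])
        assert shifted.p_lower == base.p_lower

    @given(c=st.floats(0.2, 5.0), **finite_params)
    def test_scale_invariance_of_the_whole_curve(self, c, a, z_rel, nu, s2):
        # (a, nu, s) -> (c a, c nu, c s) changes nothing observable.  Restrict
        # to well-conditioned sets: for a |nu| / s2 >> 1 the series suffers
        # catastrophic cancellation near t0 and carries no reliable digits,
        # so bit-level agreement is not meaningful there.
        assume(a * abs(nu) / s2 <= 6.0)
        num = w.NumericsConfig(t_max_ms=1500.0, n_points=200)
        base = w.density_curve(w.DMParameters(a=a, z_rel=z_rel, nu=nu, s2=s2), num)
        scaled = w.density_curve(
            w.DMParameters(a=c * a, z_rel=z_rel, nu=c * nu, s2=c * c * s2), num
        )
        assert scaled.p_lower == pytest.approx(base.p_lower, abs=1e-12)
        # absolute floor scales with the curve's magnitude (series terms are
        # accumulated relative to the largest density value on the grid)
        atol = 1e-12 * (1.0 + max(base.g_upper.max(), base.g_lower.max()))
        np.testing.assert_allclose(scaled.g_upper, base.g_upper, rtol=1e-12, atol=atol)
        np.testing.assert_allclose(scaled.g_lower, base.g_lower, rtol=1e-12, atol=atol)

    @given(**finite_params)
    def test_reflection_exchanges_the_two_densities_exactly(self, a, z_rel, nu, s2):
        num = w.NumericsConfig(t_max_ms=1500.0, n_points=200)
        base = w.density_curve(w.DMParameters(a=a, z_rel=z_rel, nu=nu, s2=s2), num)
        mirror = w.density_curve(w.DMParameters(a=a, z_rel=1 - z_rel, nu=-nu, s2=s2), num)
        # one direction is computed from bit-identical inputs; the other goes
        # through 1 - (1 - z_rel), which may differ by one ulp
        assert np.array_equal(mirror.g_lower, base.g_upper)
        np.testing.assert_allclose(mirror.g_upper, base.g_lower, rtol=1e-12, atol=1e-12)
        assert mirror.p_lower + base.p_lower == pytest.approx(1.0, abs=1e-12)
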