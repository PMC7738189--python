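"""TF-driven chromatin accessibility: opening chain, Erlang limit, and the
accessible-equilibrium composition."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import erlang

from hbaccess.inputs import default_input_field
from hbaccess.tfdriven import (
    TFDrivenModel,
    TFDrivenParams,
    fraction_active,
    mean_loading_rate,
    opening_probability,
    pbound_accessible,
    pi_rate,
)
from hbaccess.thermo import ThermoParams


class TestPiRate:
    def test_additive_form(self):
        assert pi_rate(0.1, 0.2, 3.0, 4.0) == pytest.approx(1.1)

    def test_no_catalysis_without_rate_constants(self):
        assert pi_rate(0.0, 0.0, 10.0, 10.0) == 0.0

    def test_zelda_null_leaves_bicoid_term(self):
        b = np.linspace(0, 5, 11)
        np.testing.assert_allclose(pi_rate(0.3, 2.0, b, np.zeros_like(b)), 0.3 * b)


class TestOpeningProbability:
    def test_no_rate_never_opens(self):
        t = np.linspace(0, 20, 41)
        assert np.all(opening_probability(3, np.zeros_like(t), t) == 0.0)

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_constant_rate_matches_erlang_cdf(self, m):
        t = np.linspace(0, 15, 31)
        pi = 0.8
        p = opening_probability(m, np.full_like(t, pi), t)
        np.testing.assert_allclose(p, erlang.cdf(t, m, scale=1 / pi), atol=1e-8)

    def test_single_step_is_exponential(self):
        t = np.linspace(0, 10, 21)
        p = opening_probability(1, np.full_like(t, 0.5), t)
        np.testing.assert_allclose(p, 1 - np.exp(-0.5 * t), atol=1e-10)

    def test_matches_ode_chain_for_time_varying_rate(self):
        # independent oracle: integrate dP_k/dt = pi(t)(P_{k-1}-P_k) directly
        m = 3
        pi_f = lambda t: 0.5 * (1 - np.exp(-t))  # noqa: E731
        t = np.linspace(0, 17, 2001)

        def rhs(tt, y):
            p = pi_f(tt)
            d = np.empty_like(y)
            d[0] = -p * y[0]
            d[1:m] = p * (y[: m - 1] - y[1:m])
            d[m] = p * y[m - 1]
            return d

        y0 = np.zeros(m + 1)
        y0[0] = 1.0
        sol = solve_ivp(rhs, (0, 17), y0, t_eval=t, rtol=1e-10, atol=1e-12)
        ours = opening_probability(m, pi_f(t), t)
        np.testing.assert_allclose(ours, sol.y[m], atol=1e-6)

    def test_monotone_nondecreasing(self, rng):
        t = np.linspace(0, 17, 69)
        pi = np.abs(rng.normal(0.5, 0.4, t.size))
        p = opening_probability(4, pi, t)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_mean_opening_time_is_m_over_pi(self):
        # first-passage mean of the m-step chain at constant rate
        m, pi = 4, 0.9
        t = np.linspace(0, 400, 40001)
        p = opening_probability(m, np.full_like(t, pi), t)
        mean = np.trapezoid(1 - p, t)
        assert mean == pytest.approx(m / pi, rel=1e-4)

    def test_rejects_bad_arguments(self):
        t = np.linspace(0, 5, 6)
        with pytest.raises(ValueError):
            opening_probability(0, np.ones_like(t), t)
        with pytest.raises(ValueError):
            opening_probability(2, -np.ones_like(t), t)


class TestAccessibleEquilibrium:
    def test_zelda_independence(self):
        eq = ThermoParams(n_b=6, n_z=10, K_z=0.3)
        vals = [pbound_accessible(eq, 0.4, z) for z in (0.0, 5.0, 50.0)]
        assert max(vals) - min(vals) < 1e-14

    def test_full_opening_recovers_thermo_accessible_rate(self, field):
        # c_z huge: P_open == 1 almost immediately -> rate = R * p_bound_acc
        params = TFDrivenParams(m=1, c_b=0.0, c_z=1e4)
        t = field.time_grid
        rate = mean_loading_rate(params, field.bicoid[0], field.zelda, t)
        expected = params.equilibrium.R * pbound_accessible(
            params.equilibrium, field.bicoid[0], field.zelda
        )
        np.testing.assert_allclose(rate[5:], expected[5:], rtol=1e-3)

    def test_erlang_factorization_at_constant_inputs(self):
        t = np.linspace(0, 17, 35)
        params = TFDrivenParams(m=3, c_b=0.5, c_z=0.0)
        b = np.full_like(t, 2.0)
        z = np.zeros_like(t)
        rate = mean_loading_rate(params, b, z, t)
        pb = pbound_accessible(params.equilibrium, 2.0)
        expected = erlang.cdf(t, 3, scale=1 / 1.0) * params.equilibrium.R * pb
        np.testing.assert_allclose(rate, expected, atol=1e-8)


class TestFractionActive:
    def test_erlang_value_at_cycle_end(self):
        t = np.linspace(0, 15, 301)
        params = TFDrivenParams(m=3, c_b=0.2, c_z=0.0, nc_duration=15.0)
        val = fraction_active(params, np.ones_like(t), np.zeros_like(t), t)
        assert val == pytest.approx(0.5768, abs=1e-4)

    def test_zero_rate_never_active(self):
        t = np.linspace(0, 17, 35)
        params = TFDrivenParams(c_b=0.0, c_z=0.0)
        assert fraction_active(params, np.ones_like(t), np.ones_like(t) * 0, t) == 0.0

    def test_requires_cycle_coverage(self):
        t = np.linspace(0, 10, 21)  # shorter than nc_duration
        params = TFDrivenParams(nc_duration=17.0)
        with pytest.raises(ValueError):
            fraction_active(params, np.ones_like(t), np.zeros_like(t), t)


class TestSpatialPhenotypes:
    def test_zelda_null_onset_delayed_posteriorly(self, field):
        model = TFDrivenModel()
        frac = model.fraction_active_profile(field.zelda_nulled())
        assert np.all(np.diff(frac) <= 1e-12)  # activity lost posteriorly

    def test_wild_type_fully_active(self, field):
        model = TFDrivenModel()
        frac = model.fraction_active_profile(field)
        assert np.all(frac > 0.99)

    def test_chain_probabilities_conserved(self):
        # P_open plus the survival probabilities of the silent states sum to 1
        from scipy.stats import poisson

        t = np.linspace(0, 17, 35)
        pi = 0.4 * (1 - np.exp(-t))
        m = 4
        from scipy.integrate import cumulative_trapezoid

        hazard = cumulative_trapezoid(pi, t, initial=0.0)
        states = np.array([poisson.pmf(k, hazard) for k in range(m)])
        total = states.sum(axis=0) + opening_probability(m, pi, t)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
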