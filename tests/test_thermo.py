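"""Thermodynamic MWC and generalized equilibrium models.

The closed-form RNAP-bound probability is checked against brute-force state
enumeration, the generalized model against its exact MWC embedding, plus the
analytic limits (no RNAP, accessible limit, Zelda cancellation) and
monotonicity properties.
"""

import numpy as np
import pytest

from hbaccess.thermo import (
    GeneralizedThermoParams,
    ThermoParams,
    enumerate_states,
    loading_rate,
    mwc_to_generalized,
    pbound_enumerated,
    pbound_generalized,
    pbound_mwc,
)


def random_params(rng):
    return ThermoParams(
        n_b=int(rng.integers(0, 7)),
        n_z=int(rng.integers(0, 11)),
        K_b=float(10 ** rng.uniform(-2, 2)),
        K_z=float(10 ** rng.uniform(-2, 2)),
        omega_b=float(10 ** rng.uniform(-2, 3)),
        omega_bp=float(10 ** rng.uniform(-2, 3)),
        delta_eps_chrom=float(rng.uniform(-10, 10)),
        rnap_level=float(10 ** rng.uniform(-2, 1)),
    )


class TestEnumerateStates:
    @pytest.mark.parametrize(
        "n_b,n_z,expected",
        [(0, 0, 3), (2, 1, 13), (1, 0, 5), (6, 10, 1 + 7 * 11 * 2)],
    )
    def test_state_count(self, n_b, n_z, expected):
        assert len(enumerate_states(n_b, n_z)) == expected

    def test_accessible_partition_sum_without_inputs(self):
        # b = z = 0 leaves only the empty accessible states: 1 + p
        p = ThermoParams(n_b=6, n_z=10, rnap_level=0.4)
        acc = [s for s in enumerate_states(6, 10) if s.accessible]
        total = sum(s.weight(p, 0.0, 0.0) for s in acc)
        assert total == pytest.approx(1.4)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            enumerate_states(-1, 0)


class TestPboundMWC:
    def test_matches_enumeration_randomized(self, rng):
        for _ in range(300):
            params = random_params(rng)
            b = float(10 ** rng.uniform(-2, 2))
            z = float(10 ** rng.uniform(-2, 2))
            assert pbound_mwc(params, b, z) == pytest.approx(
                pbound_enumerated(params, b, z), abs=1e-10
            )

    def test_no_rnap_means_no_bound_states(self):
        p = ThermoParams(rnap_level=0.0)
        assert pbound_mwc(p, 5.0, 5.0) == 0.0

    def test_accessible_limit_is_simple_occupancy(self):
        # delta_eps -> -inf, no activators, p = 1: p_bound -> p/(1+p) = 1/2
        p = ThermoParams(delta_eps_chrom=-720.0, rnap_level=1.0)
        assert pbound_mwc(p, 0.0, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(100):
            params = random_params(rng)
            vals = pbound_mwc(params, 10 ** rng.uniform(-3, 3, 5), 10 ** rng.uniform(-3, 3, 5))
            assert np.all((vals >= 0) & (vals <= 1))

    def test_monotone_in_bicoid_with_cooperative_interactions(self, rng):
        b = np.linspace(0, 50, 200)
        for _ in range(20):
            params = random_params(rng)
            params.omega_b = max(params.omega_b, 1.0)
            params.omega_bp = max(params.omega_bp, 1.0)
            vals = pbound_mwc(params, b, 1.0)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_monotone_in_zelda(self, rng):
        z = np.linspace(0, 50, 200)
        for _ in range(20):
            params = random_params(rng)
            vals = pbound_mwc(params, 1.0, z)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_zelda_cancels_in_accessible_limit(self):
        p = ThermoParams(delta_eps_chrom=-720.0)
        vals = pbound_mwc(p, 0.7, np.array([0.0, 5.0, 50.0]))
        assert np.ptp(vals) < 1e-14

    def test_overflow_safe_at_extreme_concentrations(self):
        p = ThermoParams(n_b=6, n_z=10, K_b=1e-2, K_z=1e-2, omega_b=1e3, omega_bp=1e3)
        val = pbound_mwc(p, 1e6, 1e6)
        assert 0.0 <= val <= 1.0 and np.isfinite(val)

    def test_rejects_negative_concentrations(self):
        with pytest.raises(ValueError):
            pbound_mwc(ThermoParams(), -1.0, 0.0)


class TestGeneralizedModel:
    def test_embedding_reproduces_mwc(self, rng):
        for _ in range(50):
            params = random_params(rng)
            z = float(10 ** rng.uniform(-2, 2))
            gen = mwc_to_generalized(params, z)
            for b in 10 ** rng.uniform(-2, 2, 20):
                assert pbound_generalized(gen, float(b)) == pytest.approx(
                    pbound_mwc(params, float(b), z), abs=1e-12
                )

    def test_embedding_with_zero_zelda_ignores_site_count(self):
        p6 = ThermoParams(n_z=10)
        p0 = ThermoParams(n_z=0)
        g6 = mwc_to_generalized(p6, 0.0)
        g0 = mwc_to_generalized(p0, 0.0)
        np.testing.assert_allclose(g6.weights, g0.weights)

    def test_empty_weight_row_gives_zero(self):
        w = np.zeros((2, 3))
        w[0] = [1.0, 2.0, 1.0]
        gen = GeneralizedThermoParams(n_b=2, weights=w, p_inacc=1.0)
        assert pbound_generalized(gen, 3.0) == 0.0

    def test_huge_inaccessible_weight_silences(self):
        w = np.ones((2, 2))
        gen = GeneralizedThermoParams(n_b=1, weights=w, p_inacc=1e300)
        assert pbound_generalized(gen, 1.0) == pytest.approx(0.0, abs=1e-290)

    def test_all_zero_weights_is_degenerate(self):
        gen = GeneralizedThermoParams(n_b=1, weights=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            pbound_generalized(gen, 1.0)

    def test_bicoid_binding_to_inaccessible_state_reduces_pbound(self):
        w = np.ones((2, 3))
        plain = GeneralizedThermoParams(n_b=2, weights=w, p_inacc=1.0)
        poly = GeneralizedThermoParams(n_b=2, weights=w, p_inacc=np.array([1.0, 2.0]))
        assert pbound_generalized(poly, 3.0) < pbound_generalized(plain, 3.0)


class TestLoadingRate:
    def test_zero_during_mitotic_repression(self):
        assert loading_rate(0.9, 10.0, t=2.0, t_mitrep=3.0) == 0.0

    def test_occupancy_hypothesis_after_repression(self):
        assert loading_rate(0.5, 10.0, t=5.0, t_mitrep=3.0) == 5.0

    def test_no_repression_window(self):
        t = np.linspace(0, 10, 21)
        np.testing.assert_allclose(loading_rate(0.25, 8.0, t, 0.0), 2.0)
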