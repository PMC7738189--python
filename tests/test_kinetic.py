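"""Non-equilibrium MWC model: state graphs, master-equation propagation and
the detailed-balance equilibrium limit."""

import numpy as np
import pytest

from hbaccess.inputs import default_input_field
from hbaccess.kinetic import (
    NoneqMWCModel,
    NoneqParams,
    build_state_graph,
    detailed_balance_graph,
    equilibrium_weights,
    pbound_timecourse,
    propagate,
)
from hbaccess.thermo import ThermoParams, pbound_mwc


class TestBuildStateGraph:
    def test_minimal_graph(self):
        g = build_state_graph(0)
        assert g.n_states == 3
        assert len(g.rate_entries) == 4  # open/close + RNAP bind/unbind

    @pytest.mark.parametrize("n_b,mode,expected", [(2, "occupancy", 7), (2, "configuration", 9),
                                                   (3, "occupancy", 9), (3, "configuration", 17)])
    def test_state_counts(self, n_b, mode, expected):
        assert build_state_graph(n_b, mode).n_states == expected

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            build_state_graph(6)

    def test_concentration_dependence_only_on_binding_edges(self):
        g = build_state_graph(2, "occupancy")
        for (i, j), (rate, dep) in g.rate_entries.items():
            si, sj = g.states[i], g.states[j]
            if dep == "bicoid":
                assert sj[1] == si[1] + 1  # Bicoid binding raises occupancy
            elif dep == "rnap":
                assert (si[2], sj[2]) == (0, 1)
            else:
                # unbinding or chromatin opening/closing
                assert si[0] != sj[0] or si[1] is None or sj[1] is None \
                    or sj[1] < si[1] or sj[2] < si[2] or (si[1] == sj[1] and sj[2] != si[2])


class TestEdgeListSerialization:
    def test_rates_round_trip_through_edge_table(self, tmp_path):
        rng = np.random.default_rng(2)
        g = build_state_graph(2, "occupancy")
        g = g.with_rates(np.exp(rng.uniform(-2, 2, len(g.rate_entries))))
        path = tmp_path / "graph.csv"
        g.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = build_state_graph(2, "occupancy").with_rates_from_frame(pd.read_csv(path))
        for key, (rate, dep) in g.rate_entries.items():
            assert back.rate_entries[key][0] == pytest.approx(rate, abs=1e-12)
            assert back.rate_entries[key][1] == dep


class TestPropagate:
    def test_all_rates_zero_stays_inaccessible(self, field):
        g = build_state_graph(1, "occupancy").with_rates(
            np.zeros(len(build_state_graph(1, "occupancy").rate_entries))
        )
        params = NoneqParams(n_b=1, graph=g, t_mitrep=0)
        probs = propagate(params, field.bicoid[0], field.time_grid)
        assert np.allclose(probs[0], 1.0)

    def test_probability_conserved_and_nonnegative(self, field):
        rng = np.random.default_rng(3)
        g = build_state_graph(2, "configuration")
        g = g.with_rates(np.exp(rng.uniform(np.log(0.1), np.log(50), len(g.rate_entries))))
        params = NoneqParams(n_b=2, graph=g, t_mitrep=0)
        probs = propagate(params, field.bicoid[0], field.time_grid)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-8)

    def test_time_rescaling(self):
        # doubling all rates at constant input halves the time axis
        rng = np.random.default_rng(5)
        g = build_state_graph(1, "occupancy")
        rates = np.exp(rng.uniform(np.log(0.2), np.log(5), len(g.rate_entries)))
        t = np.linspace(0, 8, 33)
        b = np.full_like(t, 0.5)
        p1 = propagate(NoneqParams(n_b=1, graph=g.with_rates(rates), t_mitrep=0), b, t)
        p2 = propagate(NoneqParams(n_b=1, graph=g.with_rates(2 * rates), t_mitrep=0), b, t)
        # P_doubled(t) == P_original(2t): compare at matching indices
        np.testing.assert_allclose(p2[:, ::2][:, : p1[:, ::4].shape[1]], p1[:, ::4], atol=1e-6)

    def test_expm_matches_bdf(self, field):
        rng = np.random.default_rng(11)
        g = build_state_graph(3, "occupancy")
        g = g.with_rates(np.exp(rng.uniform(np.log(1e-2), np.log(1e2), len(g.rate_entries))))
        params = NoneqParams(n_b=3, graph=g, t_mitrep=0)
        a = propagate(params, field.bicoid[0], field.time_grid, method="bdf")
        b = propagate(params, field.bicoid[0], field.time_grid, method="expm")
        np.testing.assert_allclose(a, b, atol=5e-4)

    def test_frozen_variant_holds_state_until_mitrep(self, field):
        rng = np.random.default_rng(7)
        g = build_state_graph(1, "occupancy")
        g = g.with_rates(np.exp(rng.uniform(0, 2, len(g.rate_entries))))
        params = NoneqParams(n_b=1, graph=g, t_mitrep=3.0, mitrep_variant="frozen-evolution")
        probs = propagate(params, field.bicoid[0], field.time_grid)
        before = field.time_grid <= 3.0
        assert np.allclose(probs[0, before], 1.0)
        assert probs[0, -1] < 1.0


class TestEquilibriumLimit:
    def test_detailed_balance_converges_to_thermo(self):
        tp = ThermoParams(
            n_b=2, n_z=0, K_b=1.0, omega_b=2.0, omega_bp=5.0,
            delta_eps_chrom=1.0, rnap_level=0.3, t_mitrep=0.0,
        )
        t = np.linspace(0, 2, 21)  # short horizon so convergence is visible
        b = np.full_like(t, 0.7)
        target = pbound_mwc(tp, 0.7, 0.0)
        graph = build_state_graph(2, "occupancy")
        errors = []
        for scale in (1.0, 10.0, 100.0):
            g = detailed_balance_graph(tp, graph, 0.7, 0.0, scale=scale)
            probs = propagate(NoneqParams(n_b=2, graph=g, t_mitrep=0), b, t)
            errors.append(abs(pbound_timecourse(probs, g)[-1] - target))
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 1e-6

    def test_equilibrium_weights_normalize_to_mwc(self):
        tp = ThermoParams(n_b=3, n_z=0, K_b=0.5, omega_b=3.0, omega_bp=2.0,
                          delta_eps_chrom=2.0, rnap_level=0.2)
        g = build_state_graph(3, "occupancy")
        w = equilibrium_weights(tp, g, bicoid=0.8)
        bound = g.rnap_bound_mask()
        assert w[bound].sum() / w.sum() == pytest.approx(pbound_mwc(tp, 0.8, 0.0), abs=1e-12)


class TestPboundTimecourse:
    def test_starts_at_zero_from_inaccessible(self, field):
        g = build_state_graph(1, "occupancy").with_rates(
            np.ones(len(build_state_graph(1, "occupancy").rate_entries))
        )
        params = NoneqParams(n_b=1, graph=g, t_mitrep=0)
        probs = propagate(params, field.bicoid[0], field.time_grid)
        pb = pbound_timecourse(probs, g)
        assert pb[0] == 0.0
        assert np.all((pb >= 0) & (pb <= 1))

    def test_all_mass_on_bound_state(self):
        g = build_state_graph(0)
        vec = np.zeros((g.n_states, 1))
        vec[[i for i, s in enumerate(g.states) if s[2] == 1][0]] = 1.0
        assert pbound_timecourse(vec, g)[0] == 1.0

    def test_output_rate_zero_during_repression_in_both_variants(self, field):
        rng = np.random.default_rng(9)
        g = build_state_graph(1, "occupancy")
        g = g.with_rates(np.exp(rng.uniform(0, 2, len(g.rate_entries))))
        for variant in ("transcription-only", "frozen-evolution"):
            params = NoneqParams(n_b=1, graph=g, t_mitrep=4.0, mitrep_variant=variant)
            rates = NoneqMWCModel(params).loading_rates(field)
            assert np.all(rates[:, field.time_grid < 4.0] == 0.0)
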