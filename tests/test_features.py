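"""Feature extraction and onset metrics: exactness, noise behavior, and the
offset/delay signatures."""

import numpy as np
import pytest

from hbaccess.features import (
    FeatureConfig,
    PositionProfile,
    apply_activity_filter,
    avg_ton_delay,
    extract_features,
    signature_point,
    ton_offset,
)


def make_profile(positions, t_on, fraction=None, t_on_sem=None):
    positions = np.asarray(positions, dtype=float)
    t_on = np.asarray(t_on, dtype=float)
    return PositionProfile(
        positions=positions,
        init_rate=np.full_like(positions, 10.0),
        t_on=t_on,
        fraction_active=np.ones_like(positions) if fraction is None else np.asarray(fraction, float),
        t_on_sem=t_on_sem,
    )


GRID = np.arange(0.0, 20.0001, 0.5)


class TestExtractFeatures:
    def test_exact_on_piecewise_linear_trace(self):
        feats = extract_features(GRID, np.maximum(0.0, 2.0 * (GRID - 4.0)))
        assert feats.init_rate == pytest.approx(2.0, abs=1e-9)
        assert feats.t_on == pytest.approx(4.0, abs=1e-9)

    def test_exact_on_rise_plateau_trace(self):
        trace = np.minimum(np.maximum(0.0, 5.0 * (GRID - 6.0)), 30.0)
        feats = extract_features(GRID, trace)
        assert feats.init_rate == pytest.approx(5.0, abs=1e-9)
        assert feats.t_on == pytest.approx(6.0, abs=1e-9)

    def test_flat_trace_is_inactive(self):
        assert extract_features(GRID, np.zeros_like(GRID)) is None

    def test_below_min_signal_is_inactive(self):
        trace = np.maximum(0.0, 0.02 * (GRID - 4.0))  # peak 0.32 RNAP
        assert extract_features(GRID, trace, FeatureConfig(min_signal=1.0)) is None

    def test_unbiased_under_noise(self, rng):
        # Monte-Carlo recovery: slope 5, onset 6 min, sd 0.5, 100 replicates
        tons, rates = [], []
        for _ in range(100):
            trace = np.minimum(np.maximum(0.0, 5.0 * (GRID - 6.0)), 30.0)
            noisy = np.maximum(trace + rng.normal(0, 0.5, GRID.size), 0.0)
            feats = extract_features(GRID, noisy)
            tons.append(feats.t_on)
            rates.append(feats.init_rate)
        assert np.mean(tons) == pytest.approx(6.0, abs=0.1)
        assert np.mean(rates) == pytest.approx(5.0, rel=0.05)

    def test_sem_propagated_from_fit_covariance(self, rng):
        trace = np.minimum(np.maximum(0.0, 5.0 * (GRID - 6.0)), 30.0)
        noisy = np.maximum(trace + rng.normal(0, 0.5, GRID.size), 0.0)
        feats = extract_features(GRID, noisy)
        assert 0.0 < feats.t_on_sem < 1.0
        assert 0.0 < feats.init_rate_sem < 2.0


class TestOnsetMetrics:
    def test_offset_reads_anterior_bin(self):
        prof = make_profile([20, 22.5, 25], [4.0, 4.5, 5.0])
        assert ton_offset(prof) == 4.0

    def test_offset_of_linear_profile(self):
        x = np.arange(20, 40.1, 2.5)
        prof = make_profile(x, 3.0 + 0.1 * (x - 20.0))
        assert ton_offset(prof) == pytest.approx(3.0)

    def test_offset_requires_active_anterior_bin(self):
        prof = make_profile([20, 22.5], [np.nan, 4.0])
        prof.active_mask = np.array([False, True])
        with pytest.raises(ValueError):
            ton_offset(prof)

    def test_delay_of_constant_profile_is_zero(self):
        x = np.arange(20, 40.1, 2.5)
        assert avg_ton_delay(make_profile(x, np.full_like(x, 4.2))) == pytest.approx(0.0)

    @pytest.mark.parametrize("slope", [0.08, 0.2])
    def test_delay_of_linear_profile(self, slope):
        # analytic: mean of slope * (x - 20) over 17.5 %EL = slope * 17.5 / 2
        x = np.arange(20, 37.6, 2.5)
        prof = make_profile(x, 5.0 + slope * (x - 20.0))
        assert avg_ton_delay(prof) == pytest.approx(slope * 17.5 / 2, abs=1e-12)

    def test_delay_of_single_bump(self):
        # one interior bin raised by delta: trapezoid weight = bin width / span
        x = np.arange(20, 37.6, 2.5)
        t_on = np.full_like(x, 4.0)
        t_on[3] += 1.0
        assert avg_ton_delay(make_profile(x, t_on)) == pytest.approx(2.5 / 17.5, abs=1e-12)

    def test_delay_invariant_under_constant_shift(self, rng):
        x = np.arange(20, 37.6, 2.5)
        t_on = 4.0 + rng.uniform(0, 2, x.size)
        d0 = avg_ton_delay(make_profile(x, t_on))
        d1 = avg_ton_delay(make_profile(x, t_on + 11.3))
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_delay_normalizes_over_active_subinterval(self):
        # activity ends at 30 %EL: integrate and normalize over [20, 30] only
        x = np.arange(20, 37.6, 2.5)
        t_on = 4.0 + 0.2 * (x - 20.0)
        frac = np.where(x <= 30.0, 1.0, 0.1)
        prof = apply_activity_filter(make_profile(x, t_on, fraction=frac))
        assert avg_ton_delay(prof) == pytest.approx(0.2 * 10.0 / 2, abs=1e-12)

    def test_signature_point_carries_sems(self):
        x = np.arange(20, 37.6, 2.5)
        prof = make_profile(x, np.full_like(x, 4.0), t_on_sem=np.full_like(x, 0.3))
        pt = signature_point(prof)
        assert pt.offset == 4.0 and pt.avg_delay == pytest.approx(0.0)
        assert pt.sem_offset == pytest.approx(0.3)
        assert pt.sem_delay > 0


class TestActivityFilter:
    def test_fully_active_profile_unchanged(self):
        x = np.arange(20, 37.6, 2.5)
        prof = apply_activity_filter(make_profile(x, np.full_like(x, 4.0)))
        assert prof.active_mask.all()

    def test_strict_threshold(self):
        prof = make_profile([20, 22.5, 25], [4, 4, 4], fraction=[1.0, 0.29, 0.30])
        filtered = apply_activity_filter(prof)
        np.testing.assert_array_equal(filtered.active_mask, [True, False, True])
        assert np.isnan(filtered.t_on[1])
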