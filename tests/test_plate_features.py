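import numpy as np
import pytest

from imep.plate_features import (
    CHI2_95_2DF,
    bandpass,
    compute_features,
    cop_area_95,
    cop_path,
    rms,
    segment_window,
    total_force,
    total_moment,
)
from imep.types import PlateTrial


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        fs, f = 1000.0, 30.0
        t = np.arange(0, 10, 1 / fs)
        out = bandpass(np.sin(2 * np.pi * f * t), fs)
        core = out[2000:-2000]  # discard edge transients
        amplitude = (core.max() - core.min()) / 2
        assert 0.9 <= amplitude <= 1.1

    def test_dc_suppressed(self):
        out = bandpass(np.full(5000, 7.0), fs=1000.0)
        assert np.abs(out).max() < 0.01 * 7.0

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|band edge"):
            bandpass(np.zeros(1000), fs=80.0, high=50.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            bandpass(np.zeros(10), fs=1000.0)

    def test_idempotent_in_passband(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 30.0 * t)
        once = bandpass(x, fs)[2000:-2000]
        twice = bandpass(bandpass(x, fs), fs)[2000:-2000]
        a1 = (once.max() - once.min()) / 2
        a2 = (twice.max() - twice.min()) / 2
        assert abs(a2 - a1) <= 0.02 * a1


class TestSegmentWindow:
    def test_static_drops_three_seconds_each_end(self):
        assert segment_window("SLB", 16.0, 100.0, 1600) == (300, 1300)

    def test_ybt_keeps_first_four_seconds(self):
        assert segment_window("YBT", 5.0, 100.0, 500) == (0, 400)

    def test_short_static_trial_rejected(self):
        with pytest.raises(ValueError, match="empty|inconsistent"):
            segment_window("SLB", 6.0, 100.0, 600)

    @pytest.mark.parametrize("fs,duration", [(100.0, 16.0), (1000.0, 16.0), (250.0, 16.0)])
    def test_static_window_length_formula(self, fs, duration):
        n = int(round(duration * fs))
        start, stop = segment_window("TBT", duration, fs, n)
        assert abs((stop - start) - round((duration - 6.0) * fs)) <= 1


class TestRms:
    def test_constant(self):
        assert rms(np.full(100, 5.0)) == pytest.approx(5.0)

    def test_sinusoid_whole_periods(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        assert rms(2.0 * np.sin(2 * np.pi * 5 * t)) == pytest.approx(2 / np.sqrt(2), rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms(np.array([]))


class TestCopPath:
    def test_direct_ratio(self, static_trial):
        cop_x, cop_y, dropped = cop_path(static_trial, (0, static_trial.n_samples))
        # Fz = 500 N, My = -10 N·m, Mx = 25 N·m per sample
        np.testing.assert_allclose(cop_x, 2.0)
        np.testing.assert_allclose(cop_y, 5.0)
        assert dropped == 0

    def test_zero_moments_give_origin(self, static_trial):
        static_trial.mx[:] = 0.0
        static_trial.my[:] = 0.0
        cop_x, cop_y, _ = cop_path(static_trial, (0, static_trial.n_samples))
        assert np.all(cop_x == 0.0) and np.all(cop_y == 0.0)

    def test_unloaded_plate_rejected(self, static_trial):
        static_trial.fz[:] = 0.0
        with pytest.raises(ValueError, match="no loaded samples"):
            cop_path(static_trial, (0, static_trial.n_samples))

    def test_partially_unloaded_samples_dropped_and_counted(self, static_trial):
        static_trial.fz[:100] = 5.0
        _, _, dropped = cop_path(static_trial, (0, static_trial.n_samples))
        assert dropped == 100


class TestCopArea:
    def test_isotropic_gaussian_matches_analytic_area(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(0.0, 1.0, size=(2, 100_000))
        area = cop_area_95(pts[0], pts[1])
        expected = np.pi * CHI2_95_2DF  # σ=1 per axis → sqrt(det Σ)=1
        assert area == pytest.approx(expected, rel=0.02)

    def test_gaussian_coverage_is_95_percent(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 2.0, 100_000)
        y = rng.normal(1.0, 0.5, 100_000) + 0.3 * x
        cov = np.cov(np.vstack([x, y]))
        inv = np.linalg.inv(cov)
        d = np.vstack([x - x.mean(), y - y.mean()])
        mahal2 = np.einsum("ij,jk,ik->i", d.T, inv, d.T)
        inside = np.mean(mahal2 <= CHI2_95_2DF)
        assert inside == pytest.approx(0.95, abs=0.01)
        # and the reported area equals the ellipse of exactly that quantile
        assert cop_area_95(x, y) == pytest.approx(
            np.pi * CHI2_95_2DF * np.sqrt(np.linalg.det(cov)), rel=1e-9
        )

    def test_degenerate_cloud_has_zero_area(self):
        assert cop_area_95(np.full(10, 1.0), np.full(10, 2.0)) == 0.0

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            cop_area_95(np.array([1.0]), np.array([2.0]))

    def test_rotation_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.3, 5000)
        y = rng.normal(0, 0.6, 5000) + 0.4 * x
        base = cop_area_95(x, y)
        theta = 0.77
        xr = np.cos(theta) * x - np.sin(theta) * y
        yr = np.sin(theta) * x + np.cos(theta) * y
        assert cop_area_95(xr, yr) == pytest.approx(base, rel=1e-9)
        assert cop_area_95(3 * x, 3 * y) == pytest.approx(9 * base, rel=1e-9)


class TestTotals:
    def test_static_load_total_force(self, static_trial):
        assert total_force(static_trial, (0, 1600)) == pytest.approx(500.0)

    def test_all_zero_channels(self):
        n = 1600
        trial = PlateTrial("a", "SLB", "open", "right", 100.0,
                           *[np.zeros(n)] * 6)
        assert total_force(trial, (0, n)) == 0.0
        assert total_moment(trial, (0, n)) == 0.0

    def test_matches_per_sample_oracle(self):
        rng = np.random.default_rng(11)
        n = 800
        chans = [rng.normal(size=n) for _ in range(6)]
        trial = PlateTrial("a", "SLB", "open", "right", 100.0, *chans)
        window = (100, 700)
        # independent brute-force loop
        acc = 0.0
        for i in range(*window):
            acc += trial.fx[i] ** 2 + trial.fy[i] ** 2 + trial.fz[i] ** 2
        oracle = np.sqrt(acc / (window[1] - window[0]))
        assert total_force(trial, window) == pytest.approx(oracle, rel=1e-12)

    def test_rms_idempotent_on_duplicated_window(self, static_trial):
        half = total_force(static_trial, (0, 800))
        full = total_force(static_trial, (0, 1600))
        assert full == pytest.approx(half)

    def test_empty_window_rejected(self, static_trial):
        with pytest.raises(ValueError, match="empty"):
            total_force(static_trial, (100, 100))


def test_compute_features_full_chain(static_trial):
    feats = compute_features(static_trial)
    assert feats.window == (750, 3250)
    assert feats.tf == pytest.approx(500.0)
    assert feats.cop_a == 0.0  # constant COP point
    assert set(feats.rms_per_channel) == {"Fx", "Fy", "Fz", "Mx", "My", "Mz"}
    # the cleaned stream has no DC: constant channels filter to ~0
    assert feats.rms_per_channel["Fz"] < 1.0
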