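"""Multichannel propagation: windows, timing, slopes, asymmetry, bootstrap."""

import numpy as np
import pytest

from wavepipe import propagation as prop
from wavepipe import synthetic as syn


def _spec(va=0.01, vb=-0.01, **kw):
    kw.setdefault("name", "x")
    kw.setdefault("amplitude_space_constant_um", 60.0)
    return syn.GeneratorClassSpec(
        v_above_ms_per_um=va, v_below_ms_per_um=vb, **kw
    )


def _profiles(va, vb, n=20, noise=0.05, seed=0):
    """Planted-slope trough-time profiles (soma anchored at 0)."""
    rng = np.random.default_rng(seed)
    offsets = np.arange(-100.0, 101.0, 20.0)
    line = np.where(offsets >= 0, va * offsets, vb * offsets)
    profs = []
    for _ in range(n):
        t = line + rng.normal(0, noise, offsets.size)
        t[offsets == 0] = 0.0
        profs.append(
            prop.PropagationProfile(
                offsets_um=offsets.copy(),
                trough_times_ms=t,
                peak_times_ms=np.full(offsets.size, np.nan),
            )
        )
    return profs


class TestExtractWindow:
    def test_eleven_channels_span_plus_minus_100um(self):
        tpl = syn.make_template(_spec(), 500.0, n_channels=15)
        win = prop.extract_window(tpl)
        assert win.offsets_um.size == 11
        assert win.offsets_um.min() == -100.0 and win.offsets_um.max() == 100.0
        assert not win.truncated

    def test_probe_edge_truncates_and_flags(self):
        tpl = syn.make_template(_spec(), 500.0, n_channels=11)
        # keep only 2 channels above the soma
        sub = type(tpl)(tpl.voltages[:, 3:], tpl.fs_hz, tpl.channel_depths_um[3:])
        win = prop.extract_window(sub)
        assert win.truncated
        assert (win.offsets_um > 0).sum() == 2

    def test_center_channel_is_max_channel(self):
        tpl = syn.make_template(_spec(), 500.0)
        win = prop.extract_window(tpl)
        amps = np.ptp(win.voltages, axis=0)
        assert int(np.argmax(amps)) == win.soma_index
        assert win.offsets_um[win.soma_index] == 0.0


class TestTroughPeakTimes:
    def test_noiseless_trough_time_at_60um(self):
        tpl = syn.make_template(_spec(va=0.01, vb=-0.01), 500.0)
        profile = prop.trough_peak_times(prop.extract_window(tpl))
        j = int(np.flatnonzero(profile.offsets_um == 60.0)[0])
        assert profile.trough_times_ms[j] == pytest.approx(0.6, abs=1 / 30.0)

    def test_soma_channel_time_is_zero(self):
        tpl = syn.make_template(_spec(), 500.0)
        profile = prop.trough_peak_times(prop.extract_window(tpl))
        j = int(np.flatnonzero(profile.offsets_um == 0.0)[0])
        assert profile.trough_times_ms[j] == 0.0

    def test_low_amplitude_channel_is_missing(self):
        tpl = syn.make_template(
            _spec(amplitude_space_constant_um=25.0), 500.0
        )  # steep decay: +/-100 um < 15% of soma amplitude
        profile = prop.trough_peak_times(prop.extract_window(tpl))
        assert np.isnan(profile.trough_times_ms[profile.offsets_um == 100.0]).all()


class TestClusterTrajectory:
    def test_identical_profiles_have_zero_sem(self):
        profs = _profiles(0.01, -0.01, n=6, noise=0.0)
        traj = prop.cluster_trajectory(profs)
        np.testing.assert_allclose(traj.sem_ms[np.isfinite(traj.sem_ms)], 0.0,
                                   atol=1e-12)

    def test_planted_outlier_is_excluded(self):
        profs = _profiles(0.01, -0.01, n=20, noise=0.01)
        profs[0].trough_times_ms = profs[0].trough_times_ms + 5.0  # gross contaminant
        profs[0].trough_times_ms[profs[0].offsets_um == 0] = 0.0
        traj = prop.cluster_trajectory(profs)
        off0 = traj.offsets_um != 0
        assert np.all(traj.n_used[off0 & np.isfinite(traj.mean_ms)] == 19)

    def test_noiseless_mean_matches_generator_line(self):
        traj = prop.cluster_trajectory(_profiles(0.01, -0.01, n=8, noise=0.0))
        expected = 0.01 * np.abs(traj.offsets_um)
        np.testing.assert_allclose(traj.mean_ms, expected, atol=1 / 30.0)

    def test_low_n_flagged(self):
        traj = prop.cluster_trajectory(_profiles(0.01, -0.01, n=3, noise=0.0))
        assert traj.low_n


class TestSlopesAndAsymmetry:
    def test_exact_line_recovered_above(self):
        d = np.arange(-100.0, 101.0, 20.0)
        sa, sb = prop.propagation_slopes(d, np.where(d >= 0, 0.01 * d, 0.0))
        assert sa == pytest.approx(0.01)

    def test_symmetric_template_slopes(self):
        d = np.arange(-100.0, 101.0, 20.0)
        sa, sb = prop.propagation_slopes(d, 0.01 * np.abs(d))
        assert sa == pytest.approx(0.01) and sb == pytest.approx(-0.01)

    def test_unidirectional_template_slopes(self):
        d = np.arange(-100.0, 101.0, 20.0)
        sa, sb = prop.propagation_slopes(d, 0.01 * d)
        assert sa == pytest.approx(0.01) and sb == pytest.approx(0.01)

    def test_side_with_too_few_points_is_nan(self):
        d = np.array([-20.0, 0.0, 20.0, 40.0])
        sa, sb = prop.propagation_slopes(d, 0.01 * d)
        assert np.isfinite(sa) and np.isnan(sb)

    @pytest.mark.parametrize(
        "sa,sb,expected",
        [(0.01, -0.01, 0.0), (1.0, 1.0, np.sqrt(2.0)), (0.0, 0.0, 0.0)],
    )
    def test_asymmetry_is_point_line_distance(self, sa, sb, expected):
        assert prop.asymmetry_index(sa, sb) == pytest.approx(expected)

    def test_asymmetry_symmetric_under_side_exchange(self):
        # swapping above/below together with a sign flip of distances maps
        # (sa, sb) -> (-sb, -sa) and leaves the index unchanged
        assert prop.asymmetry_index(0.01, -0.003) == pytest.approx(
            prop.asymmetry_index(0.003, -0.01)
        )


class TestBootstrap:
    def test_zero_noise_cluster_has_zero_se(self):
        boot = prop.bootstrap_slope_tests(_profiles(0.01, -0.01, n=10, noise=0.0), seed=1)
        assert boot.se_above == pytest.approx(0.0, abs=1e-12)

    def test_planted_below_slope_detected(self):
        boot = prop.bootstrap_slope_tests(_profiles(0.01, 0.01, n=20, noise=0.05), seed=2)
        assert boot.ci_below_95[0] > 0.0

    def test_single_unit_cluster_degenerate(self):
        boot = prop.bootstrap_slope_tests(_profiles(0.01, -0.01, n=1), seed=3)
        assert boot.degenerate

    def test_pairwise_asymmetry_null_calibration(self):
        # equal asymmetry in both clusters: the 98% CI should exclude zero
        # in about 2% of replicates
        hits = 0
        n_rep = 60
        for i in range(n_rep):
            a = _profiles(0.01, -0.01, n=12, noise=0.05, seed=100 + i)
            b = _profiles(0.01, -0.01, n=12, noise=0.05, seed=500 + i)
            _, _, sig = prop.compare_asymmetry(a, b, n_boot=100, seed=i)
            hits += sig
        assert hits <= 6  # binomial(60, 0.02) rarely exceeds 6


class TestSlopeRecovery:
    @pytest.mark.parametrize("va,vb", [(0.01, 0.01), (0.01, -0.01)])
    def test_relative_error_below_10pct(self, va, vb):
        boot = prop.bootstrap_slope_tests(_profiles(va, vb, n=20, noise=0.05), seed=4)
        assert abs(boot.slope_above - va) / abs(va) < 0.10
        assert abs(boot.slope_below - vb) / abs(vb) < 0.10
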