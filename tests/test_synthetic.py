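"""Generator contracts: template geometry, renewal trains, tuning, coupling."""

import numpy as np
import pytest
from scipy import stats as sps

from wavepipe import connectivity as conn
from wavepipe import synthetic as syn


def _spec(**kw):
    kw.setdefault("name", "x")
    return syn.GeneratorClassSpec(**kw)


class TestMakeTemplate:
    def test_trough_shift_is_linear_in_distance(self):
        spec = _spec(v_above_ms_per_um=0.01, v_below_ms_per_um=-0.01,
                     amplitude_space_constant_um=60.0)
        tpl = syn.make_template(spec, 500.0, n_channels=11, pitch_um=20.0, noise_sd=0.0)
        troughs = np.argmin(tpl.voltages, axis=0)
        # channel 3 above the soma (index 2, 60 um): lag 0.6 ms = 18 samples
        assert troughs[2] - troughs[5] == 18

    def test_amplitude_decays_exponentially(self):
        spec = _spec(amplitude_uv=100.0, amplitude_space_constant_um=60.0)
        tpl = syn.make_template(spec, 500.0, noise_sd=0.0)
        amps = np.ptp(tpl.voltages, axis=0)
        assert amps[5] == pytest.approx(100.0)
        assert amps[2] == pytest.approx(100.0 / np.e)  # 60 um away

    def test_same_seed_bit_identical(self):
        a = syn.make_template(_spec(), 500.0, noise_sd=3.0, seed=42)
        b = syn.make_template(_spec(), 500.0, noise_sd=3.0, seed=42)
        assert np.array_equal(a.voltages, b.voltages)

    @pytest.mark.parametrize("kw", [dict(fs_hz=0.0), dict(pitch_um=-1.0)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            syn.make_template(_spec(), 500.0, **kw)

    def test_invalid_amplitude_rejected(self):
        with pytest.raises(ValueError):
            _spec(amplitude_uv=0.0)

    def test_noiseless_max_channel_is_soma_for_all_classes(self):
        for spec, _ in syn.default_config().classes:
            tpl = syn.make_template(spec, 600.0, noise_sd=0.0)
            amps = np.ptp(tpl.voltages, axis=0)
            assert int(np.argmax(amps)) == 5


class TestSpikeTrain:
    def test_nonbursty_isis_match_shifted_exponential(self):
        st_ = syn.simulate_spike_train(20.0, 0.0, 100.0, seed=1)
        isis = np.diff(st_) - 0.001  # remove the refractory shift
        scale = 1 / 20.0 - 0.001
        assert sps.kstest(isis, "expon", args=(0, scale)).pvalue > 0.01

    def test_bursty_train_has_more_short_isis(self):
        a = syn.simulate_spike_train(20.0, 0.0, 100.0, seed=2)
        b = syn.simulate_spike_train(20.0, 0.8, 100.0, seed=2)
        assert np.mean(np.diff(b) < 0.01) > np.mean(np.diff(a) < 0.01)

    def test_count_within_poisson_scale_bounds(self):
        st_ = syn.simulate_spike_train(20.0, 0.0, 100.0, seed=3)
        assert 1700 <= st_.size <= 2300

    @pytest.mark.parametrize("rate,burst", [(5.0, 0.0), (20.0, 0.5), (50.0, 0.8)])
    def test_rate_conserved_within_3_se(self, rate, burst):
        duration = 100.0
        st_ = syn.simulate_spike_train(rate, burst, duration, seed=4)
        se = np.sqrt(rate / duration)
        assert abs(st_.size / duration - rate) < 3 * se

    def test_refractory_period_respected(self):
        st_ = syn.simulate_spike_train(80.0, 0.8, 50.0, seed=5)
        assert np.diff(st_).min() >= 0.001

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_spike_train(10.0, 0.0, 0.0)


class TestTuning:
    def test_zero_dsi_gives_equal_pref_and_null_rates(self):
        spec = _spec(tuning=syn.TuningSpec(90.0, 0.5, 0.0, 5.0, 25.0))
        r = syn.tuned_rate(spec, [90.0, 270.0])
        assert r[0] == pytest.approx(r[1])

    def test_full_osi_zero_baseline_silences_orthogonal(self):
        spec = _spec(tuning=syn.TuningSpec(90.0, 1.0, 0.0, 0.0, 30.0))
        r = syn.tuned_rate(spec, [0.0, 180.0])
        assert np.all(r < 1e-6)

    @pytest.mark.parametrize("dsi,osi", [(0.0, 0.0), (0.3, 0.6), (0.8, 0.8), (0.5, 0.9)])
    def test_analytic_indices_hit_targets(self, dsi, osi):
        got_dsi, got_osi = syn.analytic_indices(dsi, osi)
        assert got_dsi == pytest.approx(dsi, abs=1e-6)
        assert got_osi == pytest.approx(osi, abs=1e-6)

    def test_unreachable_osi_target_names_the_bound(self):
        with pytest.raises(ValueError, match="floor"):
            syn.solve_kappas(0.9, 0.05)

    def test_trial_counts_follow_rate_model(self):
        spec = _spec(tuning=syn.TuningSpec(90.0, 0.6, 0.4, 5.0, 30.0))
        proto = syn.StimulusProtocol(trials_per_condition=50)
        df = syn.simulate_tuned_trials(spec, proto, seed=6)
        mean_pref = df[df.direction_deg == 90.0].stimulus_count.mean()
        mean_null = df[df.direction_deg == 270.0].stimulus_count.mean()
        assert mean_pref > mean_null


class TestCoupledPair:
    def test_zero_efficacy_uncorrelated(self):
        src = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=7)
        tgt = syn.simulate_coupled_pair(src, "directed", efficacy=0.0, seed=70,
                                        duration_s=600.0)
        rec = conn.jitter_correct(src, tgt, n_jitter=100, seed=7, duration_s=600.0)
        se = rec.noise_sd / np.sqrt(rec.ccg_corrected.size)
        assert abs(rec.ccg_corrected.mean()) < 3 * se

    def test_directed_peak_at_delay(self):
        src = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=8)
        tgt = syn.simulate_coupled_pair(src, "directed", delay_ms=2.0, efficacy=0.2,
                                        jitter_ms=0.3, seed=80, duration_s=600.0)
        lags, ccg = conn.compute_ccg(src, tgt, duration_s=600.0)
        assert lags[np.argmax(ccg)] == pytest.approx(2.0)

    def test_common_input_peak_near_zero(self):
        src = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=9)
        tgt = syn.simulate_coupled_pair(src, "common_input", efficacy=0.2,
                                        jitter_ms=0.3, seed=90, duration_s=600.0)
        lags, ccg = conn.compute_ccg(src, tgt, duration_s=600.0)
        assert abs(lags[np.argmax(ccg)]) < 1.0

    def test_nonpositive_delay_rejected_in_directed_mode(self):
        with pytest.raises(ValueError):
            syn.simulate_coupled_pair(np.arange(10.0), "directed", delay_ms=0.0)


class TestBuildPopulation:
    def test_unit_count_and_ground_truth(self, small_session):
        assert len(small_session.units) == 60
        assert set(small_session.ground_truth.class_name) == {
            "NS-1", "NS-3", "BS-1", "BS-4", "TP-1", "POS-1"
        }
        assert len(small_session.ground_truth) == 60

    def test_layer_probs_respected_when_degenerate(self):
        spec = _spec(layer_probs=(0.0, 0.0, 1.0, 0.0, 0.0))
        cfg = syn.PopulationConfig(
            classes=[(spec, 15)], train_duration_s=5.0,
            protocol=syn.StimulusProtocol(trials_per_condition=1),
        )
        ses = syn.build_population(cfg, seed=1)
        assert set(ses.ground_truth.layer) == {"L4c"}
        edges = cfg.layer_edges_um
        assert ses.ground_truth.depth_um.between(edges[2], edges[3]).all()

    def test_same_config_and_seed_identical_digest(self):
        cfg = syn.default_config(units_per_class=3, train_duration_s=10.0,
                                 trials_per_condition=1)
        a = syn.build_population(cfg, seed=2).digest()
        b = syn.build_population(cfg, seed=2).digest()
        assert a == b

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            syn.PopulationConfig(classes=[])
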