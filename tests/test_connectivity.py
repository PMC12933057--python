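"""Cross-correlograms: normalization, jitter correction, peaks, lead-lag."""

import numpy as np
import pytest

from wavepipe import connectivity as conn
from wavepipe import synthetic as syn


def _record(values, lags=None, noise_sd=1.0):
    values = np.asarray(values, dtype=float)
    if lags is None:
        n = values.size // 2
        lags = np.arange(-n, n + 1, dtype=float)
    return conn.CCGRecord(
        lags_ms=np.asarray(lags, dtype=float),
        ccg_corrected=values,
        noise_sd=noise_sd,
    )


class TestComputeCcg:
    def test_duplicate_unit_peaks_at_zero_lag(self):
        st = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=1)
        lags, ccg = conn.compute_ccg(st, st.copy(), duration_s=600.0)
        assert lags[np.argmax(ccg)] == 0.0

    def test_independent_poisson_has_unit_mean(self):
        a = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=2)
        b = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=3)
        _, ccg = conn.compute_ccg(a, b, duration_s=600.0)
        assert ccg.mean() == pytest.approx(1.0, abs=0.05)

    def test_shifted_copy_peaks_at_shift(self):
        st = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=4)
        lags, ccg = conn.compute_ccg(st, st + 0.003, duration_s=600.0)
        assert lags[np.argmax(ccg)] == pytest.approx(3.0)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError, match="spikes"):
            conn.compute_ccg(np.arange(10.0), np.arange(10.0) + 0.001)


class TestJitterCorrect:
    def test_independent_trains_correct_to_zero(self):
        a = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=5)
        b = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=6)
        rec = conn.jitter_correct(a, b, n_jitter=100, seed=7, duration_s=600.0)
        se = rec.noise_sd / np.sqrt(rec.ccg_corrected.size)
        assert abs(rec.ccg_corrected.mean()) < 3 * se

    def test_slow_comodulation_removed(self, rng):
        # shared 1 Hz rate envelope: inhomogeneous Poisson by thinning
        def modulated(seed):
            r = np.random.default_rng(seed)
            t = np.sort(r.uniform(0, 600.0, size=r.poisson(20.0 * 600)))
            keep = r.random(t.size) < 0.5 * (1 + 0.8 * np.sin(2 * np.pi * 1.0 * t))
            return t[keep]

        a, b = modulated(8), modulated(9)
        _, raw = conn.compute_ccg(a, b, duration_s=600.0)
        rec = conn.jitter_correct(a, b, n_jitter=100, seed=10, duration_s=600.0)
        # the broad co-modulation hump is large in the raw CCG and gone after
        assert raw.mean() > 1.05
        assert abs(rec.ccg_corrected.mean()) < 0.1 * (raw.mean() - 1.0)

    def test_fine_coupling_survives_correction(self):
        src = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=11)
        tgt = syn.simulate_coupled_pair(src, "directed", delay_ms=2.0, efficacy=0.15,
                                        seed=12, duration_s=600.0)
        rec = conn.jitter_correct(src, tgt, n_jitter=100, seed=13, duration_s=600.0)
        assert rec.ccg_corrected[rec.lags_ms == 2.0] > 7 * rec.noise_sd

    def test_jitter_window_smaller_than_bin_rejected(self):
        st = np.arange(0, 600, 0.1)
        with pytest.raises(ValueError):
            conn.jitter_correct(st, st, bin_ms=1.0, jitter_ms=0.5)


class TestSignificanceAndPeak:
    def test_eight_sd_peak_is_significant(self):
        v = np.zeros(101)
        v[60] = 8.0
        rec = conn.significance_and_peak(_record(v))
        assert rec.significant and rec.peak_lag_ms == 10.0

    def test_six_point_nine_sd_peak_is_not(self):
        v = np.zeros(101)
        v[60] = 6.9
        assert not conn.significance_and_peak(_record(v)).significant

    def test_triangular_peak_width_at_half_height(self):
        v = np.zeros(101)
        v[49:54] = [1.0, 3.0, 8.0, 3.0, 1.0]  # >= 4.0 only over 1 bin + peak
        rec = conn.significance_and_peak(_record(v))
        assert rec.peak_width_ms == 1.0
        v[49:54] = [1.0, 5.0, 8.0, 5.0, 1.0]  # half height spans 3 bins
        rec = conn.significance_and_peak(_record(v))
        assert rec.peak_width_ms == 3.0

    def test_flat_ccg_not_significant(self):
        rec = conn.significance_and_peak(_record(np.zeros(101)))
        assert not rec.significant and np.isnan(rec.peak_lag_ms)


class TestLeadLagIndex:
    def test_symmetric_ccg_is_zero(self):
        v = np.exp(-np.abs(np.arange(-50, 51)) / 5.0)
        assert conn.lead_lag_index(_record(v)) == pytest.approx(0.0, abs=1e-12)

    def test_all_positive_lag_mass_is_one(self):
        v = np.zeros(101)
        v[55:60] = 1.0
        assert conn.lead_lag_index(_record(v)) == 1.0

    def test_direct_arithmetic_example(self):
        rec = _record([1.0, 1.0, 0.0, 3.0, 1.0], lags=[-2, -1, 0, 1, 2])
        assert conn.lead_lag_index(rec) == pytest.approx(1 / 3)

    def test_lag_zero_bin_excluded(self):
        rec = _record([0.0, 0.0, 99.0, 1.0, 0.0], lags=[-2, -1, 0, 1, 2])
        assert conn.lead_lag_index(rec) == 1.0

    def test_bounded_for_arbitrary_ccgs(self, rng):
        for _ in range(100):
            rec = _record(rng.normal(size=51))
            lli = conn.lead_lag_index(rec)
            assert np.isnan(lli) or abs(lli) <= 1.0


class TestClassifyPair:
    def test_index_just_above_threshold_is_connection(self):
        rec = _record(np.zeros(5), lags=[-2, -1, 0, 1, 2])
        rec.lead_lag_index, rec.peak_lag_ms, rec.peak_width_ms = 0.31, 3.0, 2.0
        assert conn.classify_pair(rec)["kind"] == "connection"

    def test_small_index_near_zero_lag_is_common_input(self):
        rec = _record(np.zeros(5), lags=[-2, -1, 0, 1, 2])
        rec.lead_lag_index, rec.peak_lag_ms, rec.peak_width_ms = -0.1, 0.0, 5.0
        out = conn.classify_pair(rec)
        assert out["kind"] == "common_input"
        assert out["near_zero_lag"] and out["wide_peak"]

    def test_simulated_directed_pair_is_connection_with_positive_lag(self):
        src = syn.simulate_spike_train(10.0, 0.0, 600.0, seed=14)
        tgt = syn.simulate_coupled_pair(src, "directed", delay_ms=3.0, efficacy=0.15,
                                        seed=15, duration_s=600.0)
        rec = conn.analyze_pair(src, tgt, seed=16, duration_s=600.0)
        assert rec.significant
        assert conn.classify_pair(rec)["kind"] == "connection"
        assert rec.peak_lag_ms > 0


class TestPairwiseSummary:
    def _records(self, llis, ref="NS", tgt="BS"):
        out = []
        for x in llis:
            rec = _record(np.zeros(5), lags=[-2, -1, 0, 1, 2])
            rec.significant = True
            rec.lead_lag_index = x
            rec.reference_cluster, rec.target_cluster = ref, tgt
            out.append(rec)
        return out

    def test_symmetric_llis_not_significant(self, rng):
        recs = self._records(rng.uniform(-0.5, 0.5, size=40))
        _, pvals, _, edges = conn.pairwise_summary(recs)
        assert len(edges) == 0
        assert pvals.loc["NS", "BS"] > 0.001

    def test_planted_directed_edge_recovered(self, rng):
        recs = self._records(np.clip(rng.normal(0.6, 0.1, size=30), -1, 1))
        median, pvals, _, edges = conn.pairwise_summary(recs)
        assert pvals.loc["NS", "BS"] < 0.001
        assert list(edges.itertuples(index=False))[0][:2] == ("NS", "BS")

    def test_mirrored_pairs_antisymmetric_medians(self, rng):
        llis = rng.uniform(0.2, 0.8, size=20)
        recs = self._records(llis) + self._records(-llis, ref="BS", tgt="NS")
        median, _, _, _ = conn.pairwise_summary(recs)
        assert median.loc["NS", "BS"] == pytest.approx(-median.loc["BS", "NS"])

    def test_underfilled_cells_untested(self):
        recs = self._records([0.5, 0.6])
        _, pvals, counts, _ = conn.pairwise_summary(recs, min_n=5)
        assert counts.loc["NS", "BS"] == 2 and np.isnan(pvals.loc["NS", "BS"])
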