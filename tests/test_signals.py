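import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcgsleep import signals as sig, synthetic as syn


class TestCwt:
    def test_zero_signal(self):
        scales = sig.scales_for_frequencies(np.array([2.0, 5.0]), 100.0)
        c = sig.cwt_decompose(np.zeros(500), 100.0, scales)
        assert c.shape == (2, 500)
        assert np.all(c == 0)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            sig.cwt_decompose(np.array([]), 100.0, np.array([2.0]))

    def test_impulse_energy_finite(self):
        x = np.zeros(1000)
        x[500] = 1.0
        scales = sig.scales_for_frequencies(sig.DEFAULT_FREQ_GRID, 100.0)
        c = sig.cwt_decompose(x, 100.0, scales)
        assert np.all(np.isfinite(c))
        assert np.all(np.sum(c**2, axis=1) > 0)

    def test_energy_peaks_at_matching_pseudofrequency(self):
        """For a pure tone, the max-energy scale is the nearest grid frequency."""
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        grid = sig.DEFAULT_FREQ_GRID
        scales = sig.scales_for_frequencies(grid, fs)
        c = sig.cwt_decompose(x, fs, scales)
        best = grid[np.argmax(np.sum(c**2, axis=1))]
        nearest = grid[np.argmin(np.abs(grid - 1.0))]
        assert best == nearest


class TestSelectScale:
    def test_single_scale(self):
        assert sig.select_scale([sig.ScaleScore(3.0, 1.0, 1.0)]) == 3.0

    def test_dominant_scale_wins(self):
        scores = [sig.ScaleScore(2.0, 1.0, 1.0), sig.ScaleScore(4.0, 10.0, 10.0)]
        assert sig.select_scale(scores) == 4.0

    def test_tie_breaks_to_smaller_scale(self):
        # normalized scores are (1,0)+(0,1) -> 1.0 each: a tie
        scores = [sig.ScaleScore(2.0, 10.0, 0.0), sig.ScaleScore(4.0, 0.0, 10.0)]
        assert sig.select_scale(scores) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sig.select_scale([])


class TestJPeaks:
    def test_constant_signal_no_peaks(self):
        with pytest.warns(UserWarning):
            pk = sig.detect_j_peaks(np.zeros(1000), 100.0)
        assert len(pk) == 0

    def test_metronome_recording_exact(self, metronome_recording):
        rec = metronome_recording
        heart, _ = sig.extract_heart(rec.samples, rec.fs)
        pk = sig.detect_j_peaks(heart, rec.fs)
        assert len(pk) == len(rec.truth_j_times)
        off = np.abs(pk.times - rec.truth_j_times)
        assert off.max() <= 1.0 / rec.fs

    def test_close_pair_suppressed(self):
        """Two candidate peaks 0.2 s apart: only the higher one survives."""
        fs = 100.0
        x = np.zeros(500)
        x[200] = 1.0
        x[220] = 0.6
        pk = sig.detect_j_peaks(x, fs)
        assert list(pk.indices) == [200]

    def test_gap_report_flags_missed_beats(self):
        fs = 100.0
        x = np.zeros(1000)
        for i in (100, 200, 900):  # 7 s hole between 2 s and 9 s
            x[i] = 1.0
        pk = sig.detect_j_peaks(x, fs)
        assert any(hi - lo > 1.4 for lo, hi in pk.gaps)

    def test_min_spacing_invariant_on_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4000)
        pk = sig.detect_j_peaks(x, 100.0)
        if len(pk) > 1:
            assert np.diff(pk.indices).min() >= int(0.4 * 100)


class TestRespiration:
    def test_dc_gain_unity(self):
        out = sig.extract_respiration(np.full(2000, 3.7), 100.0)
        assert np.allclose(out, 3.7, atol=1e-6)

    def test_cutoff_attenuation_half_power_squared(self):
        """At 0.5 Hz, forward-backward order-4 Butterworth gives gain 1/2."""
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 0.5 * t)
        y = sig.extract_respiration(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = y[mid].std() / x[mid].std()
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_stopband_attenuation(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 5.0 * t)
        y = sig.extract_respiration(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # skip filtfilt edge transients
        assert y[mid].std() / x[mid].std() < 0.01

    def test_zero_phase(self):
        """A 0.1 Hz sinusoid keeps its peak positions exactly."""
        fs = 50.0
        t = np.arange(0, 100, 1 / fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = sig.extract_respiration(x, fs)
        mid = slice(250, len(t) - 250)
        from scipy.signal import find_peaks

        px, _ = find_peaks(x[mid])
        py, _ = find_peaks(y[mid])
        assert np.array_equal(px, py)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sig.extract_respiration(np.ones(10), 100.0)


class TestBreathPeaks:
    def test_sinusoid_count_and_spacing(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        pk = sig.detect_breath_peaks(np.sin(2 * np.pi * 0.25 * t), fs)
        assert len(pk) == 15
        assert np.allclose(np.diff(pk.times), 4.0, atol=0.02)

    def test_constant_no_peaks(self):
        assert len(sig.detect_breath_peaks(np.ones(500), 100.0)) == 0

    def test_fast_oscillation_respects_min_distance(self):
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        pk = sig.detect_breath_peaks(np.sin(2 * np.pi * 1.0 * t), fs)
        assert np.all(np.diff(pk.times) >= 2.0)


class TestEpochIntervals:
    def test_simple_arithmetic(self):
        pk = sig.PeakTrain(indices=np.array([50, 150, 250]), fs=100.0)
        out = sig.build_epoch_intervals(pk, "JJ", n_epochs=1)
        assert np.allclose(out[0].values, [1.0, 1.0])
        assert not out[0].empty_flag

    def test_empty_epoch_flagged(self):
        pk = sig.PeakTrain(indices=np.array([50, 150]), fs=100.0)
        out = sig.build_epoch_intervals(pk, "JJ", n_epochs=2)
        assert out[1].empty_flag and out[1].values.size == 0

    def test_boundary_interval_goes_to_earlier_epoch(self):
        # peaks at 29.5 s and 30.5 s: the interval belongs to epoch 0
        pk = sig.PeakTrain(indices=np.array([2950, 3050]), fs=100.0)
        out = sig.build_epoch_intervals(pk, "JJ", n_epochs=2)
        assert np.allclose(out[0].values, [1.0])
        assert out[1].empty_flag

    def test_matches_simulator_truth(self, metronome_recording):
        rec = metronome_recording
        pk = sig.PeakTrain(
            indices=np.round(rec.truth_j_times * rec.fs).astype(int), fs=rec.fs
        )
        out = sig.build_epoch_intervals(pk, "JJ", n_epochs=rec.n_epochs)
        rr = np.diff(rec.truth_j_times)
        got = np.concatenate([e.values for e in out])
        assert np.allclose(got, rr, atol=1.0 / rec.fs)


class TestCleanIntervals:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
            ((1.0, 1.0, 1.0, 4.0), (1.0, 1.0, 1.0, 1.75)),  # m=1.75, 4 > 1.5m
            ((1.0, 1.0, 0.2), (1.0, 1.0, 1.1 / 1.5)),  # m=0.7333, 0.2 < 0.3m
        ],
    )
    def test_hand_examples(self, values, expected):
        seq = sig.EpochIntervals(0, "JJ", np.array(values))
        out = sig.clean_intervals(seq)
        assert np.allclose(out.values, expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sig.clean_intervals(sig.EpochIntervals(0, "JJ", np.array([])))

    @given(
        st.lists(st.floats(min_value=0.05, max_value=3.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_output_within_band_of_raw_mean(self, values):
        v = np.array(values)
        m = v.mean()
        out = sig.clean_intervals(sig.EpochIntervals(0, "JJ", v))
        assert len(out.values) == len(v)
        assert np.all(out.values >= 0.3 * m - 1e-12)
        assert np.all(out.values <= 1.5 * m + 1e-12)


class TestEndToEnd:
    def test_noise_free_chain_exact(self, metronome_recording):
        rec = metronome_recording
        jj, _bb = sig.process_recording(rec)
        n_det = sum(len(e.values) for e in jj) + sum(1 for e in jj if not e.empty_flag)
        truth_rr = np.diff(rec.truth_j_times)
        got = np.concatenate([e.values for e in jj])
        assert abs(len(got) - len(truth_rr)) == 0
        assert np.mean(np.abs(got - truth_rr)) < 1.0 / rec.fs

    def test_snr10_precision_recall(self):
        """J-peak detection keeps precision/recall >= 0.95 at 10 dB SNR."""
        tp = fp = fn = 0
        for seed in range(3):
            hyp = syn.generate_hypnogram(4, seed=seed)
            ns = syn.snr_noise_sigma(10.0)
            rec = syn.generate_recording(None, hyp, seed=seed, noise_sigma=ns)
            heart, _ = sig.extract_heart(rec.samples, rec.fs)
            pk = sig.detect_j_peaks(heart, rec.fs)
            d = np.abs(pk.times[:, None] - rec.truth_j_times[None, :])
            tp += int(np.sum(d.min(axis=1) < 0.1))
            fp += int(np.sum(d.min(axis=1) >= 0.1))
            fn += int(np.sum(d.min(axis=0) >= 0.1))
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95
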