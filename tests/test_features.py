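import numpy as np
import pytest

from bcgsleep import features as ft
from bcgsleep.signals import EpochIntervals

RNG = np.random.default_rng(42)


class TestRegistry:
    def test_family_counts_and_total(self):
        counts = ft.family_counts()
        assert counts == {
            "time": 34, "frequency": 44, "poincare": 14, "asymmetry": 14,
            "complexity": 2, "multiscale": 124,
        }
        assert len(ft.REGISTRY) == 232

    def test_names_unique_and_frozen(self):
        assert len(set(ft.REGISTRY_NAMES)) == 232
        # any rename/reorder of the registry must be deliberate
        assert ft.registry_checksum() == (
            "8603328d3d83c8f112ed459c0e3e07411571c1854cd5a9ba28b7912a29130b46"
        )


class TestTimeDomain:
    def test_constant_sequence_zero_variability(self):
        out = ft.time_domain(np.ones(10))
        assert out["SDNN"] == 0 and out["RMSSD"] == 0 and out["PNN50"] == 0
        assert out["CVNN"] == 0 and out["Mean"] == 1.0 and out["Median"] == 1.0

    def test_two_interval_hand_arithmetic(self):
        out = ft.time_domain(np.array([0.8, 1.0]))
        assert out["RMSSD"] == pytest.approx(0.2)
        assert out["NN50"] == 1 and out["PNN50"] == 1.0
        assert out["NN20"] == 1 and out["PNN20"] == 1.0

    def test_matches_independent_definitions(self):
        """Cross-check against direct numpy formulas on random sequences."""
        for _ in range(5):
            v = RNG.normal(0.9, 0.05, 40)
            out = ft.time_domain(v)
            d = np.diff(v)
            assert out["SDNN"] == pytest.approx(np.std(v, ddof=1), rel=1e-9)
            assert out["RMSSD"] == pytest.approx(np.sqrt(np.mean(d**2)), rel=1e-9)
            assert out["SDSD"] == pytest.approx(np.std(d, ddof=1), rel=1e-9)
            assert out["CVNN"] == pytest.approx(out["SDNN"] / v.mean(), rel=1e-9)
            assert out["MAD"] == pytest.approx(
                np.median(np.abs(v - np.median(v))), rel=1e-9
            )
            assert out["RMSA"] == pytest.approx(np.sqrt(np.mean(v**2)), rel=1e-9)
            assert out["HR_Mean"] == pytest.approx(np.mean(60 / v), rel=1e-9)

    def test_short_input_flagged(self):
        out = ft.time_domain(np.array([1.0]))
        assert all(np.isnan(x) for x in out.values())

    def test_hti_definition(self):
        # 10 identical values -> single bin -> HTI = N / maxcount = 1
        out = ft.time_domain(np.ones(10))
        assert out["HTI"] == 1.0


class TestFrequencyDomain:
    def test_lf_tone_dominates(self):
        """RR(t)=1+0.1 sin(2pi 0.1 t): LF >> HF and LFf near 0.1 Hz."""
        t, rr = 0.0, []
        while t < 300:
            rr.append(1.0 + 0.1 * np.sin(2 * np.pi * 0.1 * t))
            t += rr[-1]
        out = ft.frequency_domain(np.array(rr))
        assert out["LF"] > 10 * out["HF"]
        assert out["LFHF"] > 10
        assert out["LFf"] == pytest.approx(0.1, abs=0.02)

    def test_constant_tachogram_zero_power(self):
        out = ft.frequency_domain(np.ones(100))
        assert out["TF"] == pytest.approx(0.0, abs=1e-20)
        assert np.isnan(out["LFHF"])  # ratio undefined at zero HF power

    def test_two_tone_normalized_powers_balance(self):
        t, rr = 0.0, []
        while t < 600:
            rr.append(
                1.0
                + 0.05 * np.sin(2 * np.pi * 0.1 * t)
                + 0.05 * np.sin(2 * np.pi * 0.3 * t)
            )
            t += rr[-1]
        out = ft.frequency_domain(np.array(rr))
        assert out["LFn"] == pytest.approx(out["HFn"], rel=0.10)

    def test_parseval_total_power(self):
        """Integrated PSD within 10% of tachogram variance for band-limited RR."""
        t, rr = 0.0, []
        while t < 600:
            rr.append(1.0 + 0.08 * np.sin(2 * np.pi * 0.25 * t))
            t += rr[-1]
        rr = np.array(rr)
        out = ft.frequency_domain(rr)
        grid_var = 0.08**2 / 2  # analytic tone variance
        assert out["Ttlpwr"] == pytest.approx(grid_var, rel=0.10)

    def test_short_window_low_bands_flagged(self):
        # a 30-s epoch cannot resolve ULF/VLF
        out = ft.frequency_domain(np.full(30, 1.0))
        assert np.isnan(out["ULF"]) and np.isnan(out["VL"])


class TestPoincare:
    def test_constant_degenerate(self):
        out = ft.poincare(np.ones(10))
        assert out["SD1"] == 0 and out["SD2"] == 0 and out["S"] == 0

    def test_alternating_short_term_dominates(self):
        v = np.tile([0.9, 1.1], 100)
        out = ft.poincare(v)
        assert out["SD1"] > out["SD2"]
        # SD2 -> 0 in the long alternating limit
        assert out["SD2"] < 0.02

    def test_sd1_sd2_sdnn_identity(self):
        for _ in range(5):
            v = RNG.normal(1.0, 0.1, 60)
            out = ft.poincare(v)
            lhs = out["SD1"] ** 2 + out["SD2"] ** 2
            assert lhs == pytest.approx(2 * np.var(v, ddof=1), rel=1e-9)


class TestAsymmetry:
    def test_alternating_is_symmetric(self):
        v = np.append(np.tile([0.9, 1.1], 50), 0.9)  # odd length: 50 up, 50 down
        out = ft.asymmetry(v)
        assert out["GI"] == pytest.approx(50.0, abs=1e-9)
        assert out["C1d"] == pytest.approx(0.5, abs=1e-9)

    def test_monotone_one_sided(self):
        out = ft.asymmetry(np.linspace(0.8, 1.2, 20))
        assert out["C1d"] == 1.0 and out["C1a"] == 0.0

    def test_partitions_sum_to_one(self):
        for _ in range(5):
            v = RNG.normal(1.0, 0.1, 50)
            out = ft.asymmetry(v)
            assert out["C1d"] + out["C1a"] == pytest.approx(1.0, abs=1e-12)
            assert out["Cd"] + out["Ca"] == pytest.approx(1.0, abs=1e-12)
            assert out["C2d"] + out["C2a"] == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_point_partition(self):
        """SD1d/SD1a agree with an explicit loop over Poincare points."""
        v = RNG.normal(1.0, 0.08, 40)
        out = ft.asymmetry(v)
        up = down = 0.0
        m = 0
        for i in range(len(v) - 1):
            d = (v[i + 1] - v[i]) / np.sqrt(2)
            m += 1
            if d > 0:
                up += d * d
            elif d < 0:
                down += d * d
        assert out["SD1d"] == pytest.approx(np.sqrt(up / m), rel=1e-12)
        assert out["SD1a"] == pytest.approx(np.sqrt(down / m), rel=1e-12)

    def test_reversal_flips_direction(self):
        v = RNG.normal(1.0, 0.08, 40)
        fwd, rev = ft.asymmetry(v), ft.asymmetry(v[::-1])
        assert fwd["GI"] == pytest.approx(100 - rev["GI"], abs=1e-9)
        assert fwd["C1d"] == pytest.approx(rev["C1a"], abs=1e-12)


class TestSampleEntropy:
    def test_constant_zero(self):
        assert ft.sample_entropy(np.ones(30)) == 0.0

    def test_matches_brute_force(self):
        """Vectorized count equals the O(n^2) double-loop definition."""
        v = RNG.normal(0, 1, 80)
        m, r = 2, 0.2 * v.std()

        def count(mm):
            c = 0
            for i in range(len(v) - mm):
                for j in range(i + 1, len(v) - mm):
                    if np.max(np.abs(v[i : i + mm] - v[j : j + mm])) <= r:
                        c += 1
            return c

        expected = -np.log(count(3) / count(2))
        assert ft.sample_entropy(v) == pytest.approx(expected, abs=1e-12)

    def test_iid_uniform_is_high(self):
        v = np.random.default_rng(0).uniform(size=300)
        assert ft.sample_entropy(v) > 1.5

    def test_too_short_flagged(self):
        assert np.isnan(ft.sample_entropy(np.ones(5)))


class TestMultiscaleWindows:
    def _epochs(self, n, m=30):
        return [
            EpochIntervals(i, "JJ", RNG.normal(1.0, 0.05, m)) for i in range(n)
        ]

    def test_concatenation_lengths(self):
        eps = self._epochs(25)
        wins = ft.multiscale_windows(eps, 0)
        assert sum(len(s) for s in wins[1][0]) == 60
        assert sum(len(s) for s in wins[10][0]) == 600
        assert not wins[10][1]

    def test_truncation_at_end(self):
        eps = self._epochs(5)
        wins = ft.multiscale_windows(eps, 4)
        segs, truncated = wins[10]
        assert truncated and len(segs) == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            ft.multiscale_windows(self._epochs(3), 3)

    def test_sdann_sdnni_brute_force(self):
        """SDANN/SDNNI equal explicit minute-by-minute recomputation."""
        eps = self._epochs(10)
        segs, _ = ft.multiscale_windows(eps, 0)[5]
        out = ft.window_time_domain(segs)
        minutes = [np.concatenate(segs[j : j + 2]) for j in range(0, len(segs) - 1, 2)]
        assert out["SDANN"] == pytest.approx(
            np.std([m.mean() for m in minutes], ddof=1), rel=1e-12
        )
        assert out["SDNNI"] == pytest.approx(
            np.mean([m.std(ddof=1) for m in minutes]), rel=1e-12
        )

    def test_two_minute_hand_example(self):
        # two 1-min halves with means 0.8 and 1.0 -> SDANN = SD({0.8, 1.0})
        segs = [np.full(30, 0.8), np.full(30, 0.8),
                np.full(30, 1.0), np.full(30, 1.0)]
        out = ft.window_time_domain(segs)
        assert out["SDANN"] == pytest.approx(np.std([0.8, 1.0], ddof=1), rel=1e-12)
        assert out["SDNNI"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_window(self):
        segs = [np.ones(30)] * 4
        out = ft.window_time_domain(segs)
        assert out["SDANN"] == 0 and out["SDNNI"] == 0 and out["Mode"] == pytest.approx(1.0, abs=1 / 128)


class TestAssemble:
    def test_shape_and_labels(self, small_feature_table):
        table, mask = small_feature_table
        assert table.shape[1] == 233  # 232 features + stage
        assert list(table.columns[:-1]) == ft.REGISTRY_NAMES
        assert mask.shape == (len(table), 232)

    def test_no_breaths_isolated_to_bb_columns(self, noisy_recording):
        from bcgsleep import signals as sig

        jj, bb = sig.process_recording(noisy_recording)
        empty_bb = [EpochIntervals(e.epoch_index, "BB", np.array([])) for e in bb]
        table, mask = ft.assemble(jj, empty_bb)
        bb_cols = [n for n in ft.REGISTRY_NAMES if n.startswith("BB_")]
        jj_cols = [n for n in ft.REGISTRY_NAMES if n.startswith(("JJ_", "HR_"))]
        assert mask[bb_cols].to_numpy().all()
        assert not mask[jj_cols].to_numpy().all()

    def test_time_translation_invariance(self, metronome_recording):
        """Shifting all peaks by a constant leaves every feature unchanged."""
        from bcgsleep import signals as sig

        rec = metronome_recording
        pk = sig.PeakTrain(
            indices=np.round(rec.truth_j_times * rec.fs).astype(int), fs=rec.fs
        )
        jj = sig.build_epoch_intervals(pk, "JJ", rec.n_epochs)
        row0 = ft.epoch_features(jj, jj, 0)
        shifted = sig.PeakTrain(indices=pk.indices + 7, fs=rec.fs)
        jj2 = sig.build_epoch_intervals(shifted, "JJ", rec.n_epochs)
        row1 = ft.epoch_features(jj2, jj2, 0)
        for k in row0:
            if not (np.isnan(row0[k]) and np.isnan(row1[k])):
                assert row0[k] == pytest.approx(row1[k], rel=1e-6), k

    def test_stage_separation_planted_direction(self):
        """Mean HR differs between N3 and REM epochs as the profiles dictate."""
        from bcgsleep import signals as sig, synthetic as syn

        hyp = ["N3"] * 4 + ["REM"] * 4
        rec = syn.generate_recording(None, hyp, seed=9, noise_sigma=0.05)
        jj, bb = sig.process_recording(rec)
        table, _ = ft.assemble(jj, bb, stages=rec.stages)
        hr = table.groupby("stage")["HR_Mean"].mean()
        # N3 profile has the longest rr_mean -> lowest heart rate
        assert hr["N3"] < hr["REM"]
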