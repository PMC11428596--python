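"""Generators: determinism, regime statistics, ECG ground truth, rhythm tracks."""

import dataclasses

import numpy as np
import pytest

from pafnet import synthetic
from pafnet.synthetic import RRGenConfig, generate_ecg, generate_rhythm_track, generate_rr


class TestGenerateRR:
    def test_zero_noise_nsr_is_constant(self):
        cfg = RRGenConfig(class_label="NSR", n_beats=100, mean_rr=0.8, rr_sd=0.0,
                          resp_mod_depth=0.0, premature_prob=0.0)
        rr = generate_rr(cfg)
        assert len(rr) == 100
        np.testing.assert_array_equal(rr.intervals, np.full(100, 0.8))

    def test_same_seed_bit_identical(self):
        cfg = synthetic.default_config("PAF_PRONE", n_beats=500, seed=7)
        a, b = generate_rr(cfg), generate_rr(cfg)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_different_seed_differs(self):
        a = generate_rr(synthetic.default_config("NSR", n_beats=500, seed=1))
        b = generate_rr(synthetic.default_config("NSR", n_beats=500, seed=2))
        assert not np.array_equal(a.intervals, b.intervals)

    def test_premature_fraction_matches_binomial(self):
        # with small Gaussian jitter, intervals below 0.8x mean are (almost)
        # exclusively premature beats; each premature draw consumes two
        # beats, so the expected short fraction is p/(1+p) ~ 0.0476, inside
        # the 99% binomial CI of p = 0.05 at n = 10,000
        cfg = synthetic.default_config("PAF_PRONE", n_beats=10_000, seed=3,
                                       rr_sd=0.02, premature_prob=0.05)
        rr = generate_rr(cfg)
        frac = float(np.mean(rr.intervals < 0.8 * cfg.mean_rr))
        p = 0.05
        half = 2.576 * np.sqrt(p * (1 - p) / cfg.n_beats)
        assert p - half <= frac <= p + half

    def test_intervals_clipped_to_physiological_band(self):
        cfg = synthetic.default_config("PAF_PRONE", n_beats=5000, seed=9, rr_sd=0.19)
        rr = generate_rr(cfg)
        assert rr.intervals.min() >= synthetic.CLIP_MIN_S
        assert rr.intervals.max() <= synthetic.CLIP_MAX_S

    def test_paf_prone_more_variable_than_nsr(self):
        nsr = generate_rr(synthetic.default_config("NSR", n_beats=1000, seed=4))
        paf = generate_rr(synthetic.default_config("PAF_PRONE", n_beats=1000, seed=4))
        assert np.std(paf.intervals) > np.std(nsr.intervals)

    @pytest.mark.parametrize("field, bad", [
        ("class_label", "AF"),
        ("n_beats", 0),
        ("mean_rr", 2.5),
        ("premature_prob", 0.5),
        ("premature_scale", 1.2),
        ("compensatory_scale", 0.9),
        ("resp_period", 0.0),
    ])
    def test_invalid_config_names_field(self, field, bad):
        with pytest.raises(ValueError, match=field):
            dataclasses.replace(RRGenConfig(), **{field: bad})


class TestGenerateECG:
    def test_exact_peak_placement_without_noise(self):
        rr = generate_rr(RRGenConfig(n_beats=2, mean_rr=1.0, rr_sd=0, resp_mod_depth=0))
        ecg = generate_ecg(rr, fs=128.0, noise_sd=0.0, wander_amp=0.0)
        r0 = ecg.true_rpeaks[0]
        np.testing.assert_array_equal(ecg.true_rpeaks, [r0, r0 + 128, r0 + 256])

    def test_clean_peaks_are_local_maxima(self, clean_ecg):
        x = clean_ecg.samples
        for p in clean_ecg.true_rpeaks:
            lo, hi = max(0, p - 10), min(len(x), p + 11)
            assert lo + np.argmax(x[lo:hi]) == p

    def test_truth_intervals_consistent_within_sample_quantum(self, clean_ecg):
        err = np.abs(np.diff(clean_ecg.true_rpeaks) / clean_ecg.fs - clean_ecg.rr_truth)
        assert err.max() <= 1.0 / clean_ecg.fs

    def test_deterministic_under_seed(self, nsr_rr):
        a = generate_ecg(nsr_rr, fs=128, noise_sd=0.05, wander_amp=0.1, seed=8)
        b = generate_ecg(nsr_rr, fs=128, noise_sd=0.05, wander_amp=0.1, seed=8)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_empty_sequence_rejected(self):
        from pafnet.containers import RRSequence
        with pytest.raises(ValueError, match="empty"):
            generate_ecg(RRSequence(intervals=np.empty(0)), fs=128)

    def test_low_sampling_rate_rejected(self, nsr_rr):
        with pytest.raises(ValueError, match="fs"):
            generate_ecg(nsr_rr, fs=50)


class TestGenerateRhythmTrack:
    def test_no_episodes_single_normal_interval(self):
        track = generate_rhythm_track(None, 1800.0)
        assert len(track.intervals) == 1
        iv = track.intervals[0]
        assert (iv.start, iv.end, iv.label) == (0.0, 1800.0, "N")

    def test_single_episode_three_intervals(self):
        track = generate_rhythm_track([(3600.0, 3900.0)], 7200.0)
        labels = [(iv.start, iv.end, iv.label) for iv in track.intervals]
        assert labels == [(0.0, 3600.0, "N"), (3600.0, 3900.0, "AFIB"), (3900.0, 7200.0, "N")]

    def test_short_af_span_identifiable(self):
        from pafnet.windows import MIN_EPISODE_S
        track = generate_rhythm_track([(1000.0, 1200.0)], 3600.0)
        af = track.spans("AFIB")[0]
        assert af.duration == 200.0 < MIN_EPISODE_S

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_rhythm_track([(100.0, 400.0), (300.0, 600.0)], 1000.0)

    def test_episode_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_rhythm_track([(100.0, 1200.0)], 1000.0)
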