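"""Synthetic benchmark generator: background, waveforms, insertion, corpora."""

import numpy as np
import pandas as pd
import pytest

from hfopipe.simulator import (
    EVENT_TYPES, SimConfig, balanced_flag_dataset, component_snr_db,
    event_type_flags, generate_training_corpus, insert_events,
    make_background, make_event_waveform, simulate_benchmark, simulate_channel,
)

FS = 2048.0


def band_energy(x, fs, lo, hi):
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    return spec[(freqs >= lo) & (freqs <= hi)].sum()


class TestBackground:
    def test_deterministic_and_normalized(self):
        a = make_background(10.0, FS, seed=5, rms=50.0)
        b = make_background(10.0, FS, seed=5, rms=50.0)
        np.testing.assert_array_equal(a, b)
        rms = np.sqrt(np.mean(a ** 2))
        assert abs(rms - 50.0) < 0.5
        assert abs(a.mean()) < 1.0

    def test_different_seeds_differ(self):
        a = make_background(2.0, FS, seed=1)
        b = make_background(2.0, FS, seed=2)
        assert not np.allclose(a, b)

    def test_pink_spectral_slope(self):
        from scipy.signal import welch
        x = make_background(60.0, FS, seed=11)
        f, p = welch(x, fs=FS, nperseg=int(8 * FS))
        sel = (f >= 1) & (f <= 400)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert abs(slope - (-1.0)) < 0.25


class TestEventWaveforms:
    def test_ripple_has_at_least_four_cycles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ev = make_event_waveform(5, FS, rng)
            p = ev["params"]
            assert p["r_freq"] * p["r_duration"] > 4.0

    def test_fast_ripple_cycles_and_band(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ev = make_event_waveform(6, FS, rng)
            p = ev["params"]
            assert p["fr_freq"] * p["fr_duration"] > 4.0
            assert 250 <= p["fr_freq"] <= 500
            assert p["fr_duration"] <= 0.030

    def test_spike_band_energy_fraction(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ev = make_event_waveform(1, FS, rng)
            _, w = ev["components"]["spike"]
            frac = band_energy(w, FS, 80, 500) / band_energy(w, FS, 0, 1024)
            assert frac < 0.20

    def test_composite_has_two_spectral_peaks(self):
        rng = np.random.default_rng(3)
        ev = make_event_waveform(7, FS, rng)
        (band_r, wr) = ev["components"]["ripple"]
        (band_f, wf) = ev["components"]["fast_ripple"]
        n = max(len(wr), len(wf))
        total = np.zeros(n)
        total[:len(wr)] += wr
        total[:len(wf)] += wf
        r_peak = band_energy(total, FS, *band_r)
        f_peak = band_energy(total, FS, *band_f)
        assert r_peak > 0 and f_peak > 0
        # each component dominates its own band
        assert band_energy(wr, FS, *band_r) > band_energy(wr, FS, *band_f)
        assert band_energy(wf, FS, *band_f) > band_energy(wf, FS, *band_r)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            make_event_waveform(8, FS, np.random.default_rng(0))

    def test_flags_per_type(self):
        assert event_type_flags("spike+R+FR") == {
            "artifact": False, "spike": True, "ripple": True,
            "fast_ripple": True}
        assert event_type_flags("emg_burst")["artifact"]
        assert not event_type_flags("FR")["ripple"]


class TestInsertion:
    def _event(self, type_id, center, rng):
        ev = make_event_waveform(type_id, FS, rng)
        ev["center"] = center
        return ev

    def test_realized_snr_within_1db(self):
        rng = np.random.default_rng(4)
        bg = make_background(8.0, FS, seed=21)
        for snr in (0.0, 10.0, 15.0):
            ev = self._event(5, 4.0, rng)  # pure ripple
            x, log = insert_events(bg, [ev], snr, FS)
            band, w = ev["components"]["ripple"]
            c = int(4.0 * FS)
            n_est = max(len(w), int(0.1 * FS))
            lo = c - n_est // 2
            seg_ev = (x - bg)[lo:lo + n_est]
            seg_bg = bg[lo:lo + n_est]
            got = component_snr_db(seg_ev, seg_bg, FS, band)
            assert abs(got - snr) < 1.0, (snr, got)

    def test_zero_scale_leaves_background(self):
        rng = np.random.default_rng(5)
        bg = make_background(4.0, FS, seed=3)
        ev = self._event(6, 2.0, rng)
        x, _ = insert_events(bg, [ev], -np.inf, FS, spike_visibility=0.0)
        np.testing.assert_allclose(x, bg)

    def test_all_events_logged(self):
        rng = np.random.default_rng(6)
        bg = make_background(30.0, FS, seed=8)
        events = [self._event(1 + i % 7, 1.0 + 0.6 * i, rng)
                  for i in range(42)]
        x, log = insert_events(bg, events, 10.0, FS)
        assert len(log) == 42

    def test_edge_event_skipped(self):
        rng = np.random.default_rng(7)
        bg = make_background(2.0, FS, seed=9)
        ev = self._event(5, 0.01, rng)
        _, log = insert_events(bg, [ev], 10.0, FS)
        assert len(log) == 0


class TestBenchmark:
    def test_shapes_counts_and_spacing(self):
        cfg = SimConfig(n_channels=4, duration=30.0, snr_levels=(15.0,),
                        events_per_channel=14, seed=3)
        rec, truth = simulate_benchmark(cfg)
        assert rec.n_channels == 4
        assert rec.n_samples == int(30 * FS)
        assert len(truth) == 4 * 14
        for ch, grp in truth.groupby("channel"):
            centers = np.sort(grp["center_s"].to_numpy())
            assert (np.diff(centers) >= 0.5 - 1e-9).all()
            # 14 events, 2 per type: 12 contain an HFO
            assert (grp["type_id"] != 1).sum() == 12

    def test_bit_identical_under_seed(self):
        cfg = SimConfig(n_channels=2, duration=20.0, snr_levels=(10.0,),
                        events_per_channel=7, seed=12)
        rec1, t1 = simulate_benchmark(cfg)
        rec2, t2 = simulate_benchmark(cfg)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_events_per_channel_must_divide_by_7(self):
        with pytest.raises(ValueError):
            SimConfig(events_per_channel=40)

    def test_sensitivity_monotone_in_snr(self):
        # parameter-recovery property at reduced scale
        from hfopipe.detector import detect_candidates
        from hfopipe.evaluation import score_detections
        medians = []
        for snr in (0.0, 15.0):
            sens = []
            for k in range(3):
                x, log = simulate_channel(
                    SimConfig(duration=60.0, events_per_channel=21, seed=0),
                    snr, seed=50 + k)
                peaks = np.array([ev.t_peak
                                  for ev in detect_candidates(x, FS)])
                sens.append(score_detections(peaks, log).sensitivity)
            medians.append(np.median(sens))
        assert medians[1] > medians[0]


class TestTrainingCorpus:
    def test_counts_images_and_balance(self):
        sgs, images, flags = generate_training_corpus(
            n_per_class=3, snr_db=15.0, seed=31, raster=(32, 32))
        assert len(images) == 3 * 9
        assert len(sgs) == len(images)
        for img in images:
            assert np.isfinite(img.pixels).all()
            assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0
        X, y = balanced_flag_dataset(images, flags, "ripple", 3, seed=0)
        assert X.shape == (6, 32, 32)
        assert y.sum() == 3

    def test_balance_insufficient_raises(self):
        _, images, flags = generate_training_corpus(
            n_per_class=2, snr_db=15.0, seed=32, raster=(16, 16))
        with pytest.raises(ValueError, match="balance"):
            balanced_flag_dataset(images, flags, "artifact", 50)

    def test_artifact_images_are_broadband(self):
        from hfopipe.classifier import (BlobClassifierConfig,
                                        _activation_profile,
                                        _longest_contiguous_hz)
        sgs, _, flags = generate_training_corpus(
            n_per_class=4, snr_db=15.0, seed=33)
        cfg = BlobClassifierConfig()
        idx = np.flatnonzero((flags["class"] == "emg_burst").to_numpy())
        extents = []
        for i in idx:
            m = _activation_profile(sgs[i], cfg)
            extents.append(_longest_contiguous_hz(m > 0.5, sgs[i].freqs))
        assert np.median(extents) > 350.0
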