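"""Spike-wave detector: screening, variance profile, rules, end-to-end."""
import numpy as np
import pytest

from lfpsync.detect import (
    DetectorParams,
    VarianceProfile,
    detect_swd,
    merge_and_filter,
    periodicity_filter,
    prevalence,
    screen_saturation,
    threshold_segments,
    variance_profile,
)
from lfpsync.errors import ConfigError, DataError, DegenerateSignalError
from lfpsync.signals import Signal
from lfpsync.synth import GenConfig, SWDSpec, gen_background, gen_session, gen_swd_train

FS = 2000.0


class TestSaturationScreening:
    def test_clean_signal_passes(self):
        rng = np.random.default_rng(0)
        sig = Signal(50 * rng.standard_normal(int(10 * FS)), FS)
        excluded, ok = screen_saturation(sig, rail=500.0)
        assert ok and not excluded.any()

    def test_brief_run_tolerated(self):
        x = np.zeros(int(10 * FS))
        x[1000 : 1000 + int(0.030 * FS)] = 600.0  # 30 ms at rail
        excluded, ok = screen_saturation(Signal(x, FS), rail=500.0)
        assert ok and not excluded.any()

    def test_long_runs_exclude_channel(self):
        # oracle: direct run-length accounting - 10% of time in 200-ms runs
        x = np.zeros(int(10 * FS))
        for k in range(5):
            i = int(k * 2 * FS)
            x[i : i + int(0.2 * FS)] = 600.0
        excluded, ok = screen_saturation(Signal(x, FS), rail=500.0)
        assert excluded.mean() == pytest.approx(0.10, rel=0.01)
        assert not ok

    def test_invalid_rail(self):
        with pytest.raises(ConfigError):
            screen_saturation(Signal(np.zeros(100), FS), rail=-1.0)


class TestVarianceProfile:
    def test_constant_signal_zero_profile(self):
        prof = variance_profile(Signal(np.full(int(5 * FS), 3.0), FS))
        assert np.nanmax(prof.values) == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_scaling_quadratic(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(10 * FS))
        p1 = variance_profile(Signal(x, FS)).values
        p2 = variance_profile(Signal(2 * x, FS)).values
        mask = p1 > p1.max() * 1e-3
        assert np.allclose(p2[mask] / p1[mask], 4.0, rtol=1e-6)

    def test_maxima_near_ground_truth_spikes(self):
        from scipy.signal import find_peaks

        cfg = GenConfig(fs=FS, duration_s=4, seed=2)
        spec = SWDSpec(cycle_freq=6.0, n_cycles=12, spike_amp=800.0, jitter_ms=0.0)
        train, truth = gen_swd_train(cfg, spec)
        noise = gen_background(GenConfig(fs=FS, duration_s=4, seed=3, background_rms=20.0))
        x = noise.data.copy()
        x[: train.n_samples] += train.data
        prof = variance_profile(Signal(x, FS))
        thr = np.nanmax(prof.values) * 0.2
        peaks, _ = find_peaks(prof.values, height=thr)
        peak_t = peaks / FS
        for st_ in truth.spike_times_s[0]:
            assert np.min(np.abs(peak_t - st_)) < 0.025


class TestThresholding:
    def _boxcar_profile(self):
        vals = np.ones(int(10 * FS))
        vals[int(3 * FS) : int(5 * FS)] = 100.0
        return VarianceProfile(values=vals, fs=FS)

    def test_all_below_threshold_no_intervals(self):
        prof = VarianceProfile(values=np.ones(int(5 * FS)), fs=FS)
        assert threshold_segments(prof) == []

    def test_boxcar_recovered(self):
        segs = threshold_segments(self._boxcar_profile())
        assert len(segs) == 1
        s, e = segs[0]
        assert s == pytest.approx(3.0, abs=1 / FS)
        assert e == pytest.approx(5.0, abs=1 / FS)

    def test_noise_only_candidate_fraction_small(self):
        # empirical null: on event-free 1/f sessions candidates cover <1% of time
        fracs = []
        for seed in range(5):
            sig = gen_background(GenConfig(fs=FS, duration_s=60, seed=seed))
            prof = variance_profile(sig)
            segs = threshold_segments(prof)
            fracs.append(sum(e - s for s, e in segs) / 60.0)
        assert np.mean(fracs) < 0.01


class TestMergeAndFilter:
    def test_gap_below_threshold_merged(self):
        assert merge_and_filter([(0.0, 0.6), (1.1, 1.7)]) == [(0.0, 1.7)]

    def test_short_segment_removed(self):
        assert merge_and_filter([(0.0, 0.8)]) == []

    def test_gap_above_threshold_kept_separate(self):
        out = merge_and_filter([(0.0, 1.2), (2.5, 4.0)])
        assert out == [(0.0, 1.2), (2.5, 4.0)]

    def test_idempotent_on_own_output(self):
        out = merge_and_filter([(0.0, 0.6), (1.1, 1.7), (3.0, 3.4), (5.0, 6.5)])
        assert merge_and_filter(out) == out

    def test_unsorted_rejected(self):
        with pytest.raises(DataError):
            merge_and_filter([(2.0, 3.0), (0.0, 1.0)])


def _profile_with_peaks(peak_times, duration=4.0, width_s=0.02):
    """Hand-constructed smooth profile with maxima at prescribed times."""
    t = np.arange(0, duration, 1 / FS)
    vals = np.zeros_like(t)
    for pt in peak_times:
        vals += np.exp(-0.5 * ((t - pt) / width_s) ** 2)
    return VarianceProfile(values=vals, fs=FS)


class TestPeriodicityFilter:
    def test_six_hz_train_kept(self):
        times = 0.5 + np.arange(12) / 6.0
        prof = _profile_with_peaks(times)
        events = periodicity_filter(prof, [(0.3, 2.7)])
        assert len(events) == 1
        assert np.allclose(np.diff(events[0].spike_times_s), 1 / 6, atol=0.01)

    def test_twenty_hz_burst_rejected(self):
        times = 0.5 + np.arange(20) / 20.0
        prof = _profile_with_peaks(times, width_s=0.008)
        assert periodicity_filter(prof, [(0.3, 1.7)]) == []

    def test_half_in_range_boundary_kept(self):
        # oracle: hand-constructed maxima with exactly 50% of ISIs at 6 Hz
        times = [0.5]
        for k in range(4):
            times.append(times[-1] + (1 / 6 if k % 2 == 0 else 1 / 20))
        prof = _profile_with_peaks(times, width_s=0.008)
        events = periodicity_filter(prof, [(0.3, 1.6)])
        assert len(events) == 1

    def test_too_few_maxima_rejected(self):
        prof = _profile_with_peaks([0.5, 1.0])
        assert periodicity_filter(prof, [(0.3, 1.3)]) == []


class TestDetectEndToEnd:
    def test_scheduled_trains_recovered(self, swd_session):
        from lfpsync.detect import _jaccard

        rec, truth = swd_session
        events = detect_swd(rec.get("EEG_FL"))
        for iv in truth.event_intervals:
            assert any(_jaccard(iv, (ev.start_s, ev.end_s)) >= 0.5 for ev in events)

    def test_nearby_trains_merge_into_one(self):
        cfg = GenConfig(fs=FS, duration_s=60, seed=11)
        spec = SWDSpec(cycle_freq=6.0, spike_amp=700.0, jitter_ms=3.0)
        rec, _ = gen_session(cfg, swd_spec=spec, swd_schedule=[(20.0, 2.0), (22.5, 2.0)])
        events = detect_swd(rec.get("EEG_FL"))
        covering = [ev for ev in events if ev.start_s < 23 and ev.end_s > 21.5]
        assert len(covering) == 1

    def test_dc_offset_invariance(self, swd_session):
        rec, _ = swd_session
        sig = rec.get("EEG_FL")
        base = detect_swd(sig)
        shifted = detect_swd(Signal(sig.data + 500.0, FS, channel=sig.channel))
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert a.start_s == pytest.approx(b.start_s, abs=2 / FS)
            assert a.end_s == pytest.approx(b.end_s, abs=2 / FS)

    def test_detection_times_follow_schedule_shift(self):
        spec = SWDSpec(cycle_freq=6.0, spike_amp=700.0, jitter_ms=0.0)
        starts = {}
        for shift in (0.0, 5.0):
            cfg = GenConfig(fs=FS, duration_s=60, seed=17)
            rec, _ = gen_session(cfg, swd_spec=spec, swd_schedule=[(20.0 + shift, 2.0)])
            events = detect_swd(rec.get("EEG_FL"))
            assert len(events) == 1
            starts[shift] = events[0].start_s
        assert starts[5.0] - starts[0.0] == pytest.approx(5.0, abs=0.1)

    def test_saturated_channel_raises(self):
        x = np.zeros(int(30 * FS))
        x[: int(6 * FS)] = 600.0
        with pytest.raises(DegenerateSignalError):
            detect_swd(Signal(x, FS), rail=500.0)


class TestPrevalence:
    def _ev(self, s, e):
        from lfpsync.detect import SWDEvent

        return SWDEvent(start_s=s, end_s=e, spike_times_s=np.array([]))

    def test_no_events_zero(self):
        assert prevalence([], 100.0) == 0.0

    def test_simple_fraction(self):
        evs = [self._ev(0, 2), self._ev(10, 14)]
        assert prevalence(evs, 100.0) == pytest.approx(0.06)

    def test_excluded_overlap_not_counted(self):
        # oracle: interval-intersection arithmetic
        evs = [self._ev(0.0, 4.0)]
        assert prevalence(evs, 96.0, excluded_intervals=[(3.0, 7.0)]) == pytest.approx(3.0 / 96.0)

    def test_zero_analyzed_time(self):
        with pytest.raises(DataError):
            prevalence([], 0.0)
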