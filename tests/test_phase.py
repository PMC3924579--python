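"""Narrow-band phase extraction, PLV exactness, band averaging, sync vectors."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpsync.errors import ConfigError, DataError, IncompleteMontageError
from lfpsync.phase import (
    PhaseSeries,
    SyncVector,
    band_plv,
    narrowband_phase,
    plv,
    session_sync_vector,
    subbands,
)
from lfpsync.signals import Recording, Signal
from lfpsync.spectral import CANONICAL_BANDS
from lfpsync.synth import expected_plv

FS = 2000.0
THETA = next(b for b in CANONICAL_BANDS if b.name == "theta")
BETA = next(b for b in CANONICAL_BANDS if b.name == "beta")


def _tone(freq, duration=20.0, phase=0.0):
    t = np.arange(0, duration, 1 / FS)
    return Signal(np.cos(2 * np.pi * freq * t + phase), FS)


def _ps(theta_vals):
    """Raw PhaseSeries (no edge margin) for hand-constructed phase arrays."""
    return PhaseSeries(phase=np.asarray(theta_vals, dtype=float), band=(5, 10), fs=FS)


class TestNarrowbandPhase:
    def test_sinusoid_phase_slope(self):
        ps = narrowband_phase(_tone(7.0), 5, 10)
        sl = slice(ps.edge, -ps.edge)
        slope = np.polyfit(np.arange(ps.phase.size)[sl] / FS, np.unwrap(ps.phase[sl]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 7.0, rel=0.01)

    def test_quadrature_constant_difference(self):
        t = np.arange(0, 20, 1 / FS)
        pc = narrowband_phase(Signal(np.cos(2 * np.pi * 7 * t), FS), 5, 10)
        psn = narrowband_phase(Signal(np.sin(2 * np.pi * 7 * t), FS), 5, 10)
        sl = slice(pc.edge, -pc.edge)
        diff = np.angle(np.exp(1j * (pc.phase[sl] - psn.phase[sl])))
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_chirp_phase_bounded_and_matches_fft_hilbert(self):
        # oracle: analytic signal by direct FFT construction on the filtered trace
        from scipy import signal as sps

        t = np.arange(0, 20, 1 / FS)
        chirp = Signal(sps.chirp(t, f0=4, f1=12, t1=20), FS)
        ps = narrowband_phase(chirp, 5, 10)
        assert np.all(np.abs(ps.phase) <= np.pi + 1e-12)
        assert np.all(np.isfinite(ps.phase))
        taps = sps.firwin(ps.edge, [5, 10], pass_zero=False, window="hamming", fs=FS)
        filtered = sps.filtfilt(taps, [1.0], chirp.data)
        spec = np.fft.fft(filtered)
        h = np.zeros(spec.size)
        h[0] = 1
        h[1 : spec.size // 2] = 2
        oracle = np.angle(np.fft.ifft(spec * h))
        sl = slice(ps.edge, -ps.edge)
        # the package pads the analytic transform to a fast FFT length, the
        # oracle does not, so agreement is close but not bitwise
        assert np.allclose(np.angle(np.exp(1j * (ps.phase - oracle)))[sl], 0, atol=0.02)

    def test_wrong_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            narrowband_phase(_tone(7.0), 5, 12)

    def test_band_above_100hz_rejected(self):
        with pytest.raises(ConfigError):
            narrowband_phase(_tone(7.0), 100, 105)

    def test_subband_tilings(self):
        assert subbands(THETA) == [(5, 10), (10, 15)]
        assert subbands(BETA) == [(20, 25), (25, 30)]
        sg = next(b for b in CANONICAL_BANDS if b.name == "slow_gamma")
        fg = next(b for b in CANONICAL_BANDS if b.name == "fast_gamma")
        assert len(subbands(sg)) == 5 and subbands(sg)[0] == (30, 35)
        assert len(subbands(fg)) == 7 and subbands(fg)[-1] == (95, 100)


class TestPlv:
    def test_identical_phases_exactly_one(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 500)
        assert plv(_ps(phase), _ps(phase)) == 1.0

    def test_four_point_cancellation(self):
        p1 = _ps([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        p2 = _ps([0, 0, 0, 0])
        assert plv(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_null_magnitude(self):
        # oracle: modulus of a 2-D random walk, E|sum|/N ~ sqrt(pi)/2/sqrt(N)
        rng = np.random.default_rng(1)
        n = 10**4
        vals = [plv(_ps(rng.uniform(-np.pi, np.pi, n)), _ps(np.zeros(n))) for _ in range(20)]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert expected / 3 < np.mean(vals) < expected * 3

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            plv(_ps(np.zeros(10)), _ps(np.zeros(11)))

    def test_band_mismatch(self):
        a = PhaseSeries(np.zeros(10), band=(5, 10), fs=FS)
        b = PhaseSeries(np.zeros(10), band=(10, 15), fs=FS)
        with pytest.raises(DataError):
            plv(a, b)

    def test_sample_mask_restricts_sum(self):
        rng = np.random.default_rng(4)
        locked = np.zeros(500)
        scrambled = rng.uniform(-np.pi, np.pi, 500)
        phase = np.concatenate([locked, scrambled])
        ref = _ps(np.zeros(1000))
        mask = np.arange(1000) < 500
        assert plv(_ps(phase), ref, mask=mask) == 1.0
        assert plv(_ps(phase), ref) < 0.7
        with pytest.raises(DataError):
            plv(_ps(phase), ref, mask=np.zeros(1000, dtype=bool))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=4, max_size=64),
        st.lists(st.floats(-np.pi, np.pi), min_size=4, max_size=64),
        st.floats(-np.pi, np.pi),
    )
    def test_symmetry_shift_invariance_bounds(self, a, b, c):
        n = min(len(a), len(b))
        pa, pb = np.array(a[:n]), np.array(b[:n])
        v = plv(_ps(pa), _ps(pb))
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(plv(_ps(pb), _ps(pa)), abs=1e-12)
        assert v == pytest.approx(plv(_ps(pa + c), _ps(pb + c)), abs=1e-9)


class TestBandPlv:
    def test_identical_signals_unity(self):
        rng = np.random.default_rng(2)
        sig = Signal(rng.standard_normal(int(30 * FS)), FS)
        for band in CANONICAL_BANDS:
            assert band_plv(sig, sig, band) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_floor(self):
        rng = np.random.default_rng(3)
        s1 = Signal(rng.standard_normal(int(60 * FS)), FS)
        s2 = Signal(rng.standard_normal(int(60 * FS)), FS)
        for band in CANONICAL_BANDS:
            assert band_plv(s1, s2, band) < 0.1

    def test_von_mises_coupling_recovery(self):
        from lfpsync.synth import CouplingSpec, GenConfig, gen_coupled_pair

        cfg = GenConfig(fs=FS, duration_s=60, seed=21)
        s1, s2, truth = gen_coupled_pair(
            cfg, CouplingSpec(band_center=10.0, band_width=10.0, kappa=2.0)
        )
        assert band_plv(s1, s2, THETA) == pytest.approx(truth.expected_plv["pair"], abs=0.05)
        assert band_plv(s1, s2, BETA) < 0.1  # no coupling injected there

    def test_plv_monotone_in_kappa(self):
        from lfpsync.synth import CouplingSpec, GenConfig, gen_coupled_pair

        est = []
        for kappa in (0.5, 1.0, 2.0, 4.0):
            cfg = GenConfig(fs=FS, duration_s=30, seed=31)
            s1, s2, _ = gen_coupled_pair(
                cfg, CouplingSpec(band_center=10.0, band_width=10.0, kappa=kappa)
            )
            est.append(band_plv(s1, s2, THETA))
        assert np.all(np.diff(est) > 0)


class TestSessionSyncVector:
    def test_shared_signal_all_unity(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(int(30 * FS))
        from lfpsync.signals import Montage

        montage = Montage()
        rec = Recording(
            channels={r: Signal(base.copy(), FS, channel=r) for r in montage.roles},
            fs=FS,
        )
        sv = session_sync_vector(rec)
        assert np.all(sv.to_array() > 0.999)

    def test_single_coupling_recovered(self, theta_session):
        rec, truth = theta_session
        sv = session_sync_vector(rec)
        got = sv.values[("LHC-RHC", "theta")]
        assert got == pytest.approx(expected_plv(4.0), abs=0.05)
        others = [v for k, v in sv.values.items() if k != ("LHC-RHC", "theta")]
        assert max(others) < 0.15

    def test_missing_channel_named(self, theta_session):
        rec, _ = theta_session
        channels = {k: v for k, v in rec.channels.items() if k != "RmPFC"}
        partial = Recording(channels=channels, fs=rec.fs)
        with pytest.raises(IncompleteMontageError, match="RmPFC"):
            session_sync_vector(partial)

    def test_vector_roundtrip_and_validation(self):
        arr = np.linspace(0, 1, 32)
        sv = SyncVector.from_array(arr, meta={"group": "g"})
        assert np.allclose(sv.to_array(), arr)
        with pytest.raises(DataError):
            SyncVector.from_array(np.full(32, 1.5))
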