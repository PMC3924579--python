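"""Band-limited phase extraction and phase-locking values (PLV).

The instantaneous phase of a channel in a narrow band is obtained by
forward-backward (zero net phase shift) FIR band-pass filtering followed by
the Hilbert transform. The PLV between two channels is the modulus of the
mean unit phasor of their phase difference,

    PLV = (1/N) | sum_n exp(i * [phi1(n) - phi2(n)]) |,

which is 1 for perfectly locked phases and tends to 0 for independent ones.
Phases are extracted in a filter bank of fixed 5-Hz-wide bands covering
0-100 Hz; for an analysis band spanning several 5-Hz sub-bands the PLVs of
the tiling sub-bands are averaged. A session is summarised by the 32-vector
of PLVs over 8 montage pairs x 4 bands (theta, beta, slow gamma, fast gamma).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .errors import ConfigError, DataError, IncompleteMontageError, InsufficientDataError
from .signals import Montage, Recording, Signal
from .spectral import CANONICAL_BANDS, Band

__all__ = [
    "PhaseSeries",
    "SyncVector",
    "SUBBAND_WIDTH_HZ",
    "subbands",
    "narrowband_phase",
    "plv",
    "band_plv",
    "session_sync_vector",
]

#: Granularity of the narrow-band filter bank in Hz.
SUBBAND_WIDTH_HZ = 5.0
#: Upper edge of the filter bank.
MAX_BAND_HZ = 100.0


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) in one sub-band.

    ``edge`` is the number of samples at each end that the band-pass /
    analytic-signal pipeline cannot estimate reliably; PLV sums exclude them.
    """

    phase: np.ndarray
    band: tuple[float, float]
    fs: float
    edge: int = 0

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if self.edge < 0 or 2 * self.edge >= self.phase.size:
            if self.phase.size == 0:
                raise DataError("empty phase series")
            if self.edge > 0:
                raise DataError("edge margin swallows the whole series")


def subbands(band: Band) -> list[tuple[float, float]]:
    """5-Hz sub-bands tiling [band.lo, band.hi), e.g. theta -> [(5,10), (10,15)]."""
    lo = band.lo
    edges = np.arange(lo, band.hi, SUBBAND_WIDTH_HZ)
    return [(float(e), float(e + SUBBAND_WIDTH_HZ)) for e in edges]


def _fir_taps(fs: float, lo: float, n_samples: int) -> int:
    """Windowed-sinc length: order 3*fs/lo rounded to even, capped at n/3."""
    order = int(round(3.0 * fs / lo))
    order += order % 2  # even order -> odd tap count -> type-I linear phase
    max_order = max(2, (n_samples // 3) - 1)
    order = min(order, max_order - max_order % 2)
    return order + 1


def narrowband_phase(signal: Signal, lo: float, hi: float) -> PhaseSeries:
    """Instantaneous phase in the 5-Hz band [lo, hi].

    Zero-phase FIR band-pass (Hamming windowed-sinc, applied forward and
    backward) followed by the analytic-signal angle. Only bands of the
    0-100 Hz filter bank are supported.
    """
    if not np.isclose(hi - lo, SUBBAND_WIDTH_HZ):
        raise ConfigError(f"filter bank uses {SUBBAND_WIDTH_HZ}-Hz bands, got [{lo}, {hi}]")
    if lo <= 0 or hi > MAX_BAND_HZ:
        raise ConfigError(f"band [{lo}, {hi}] outside the supported 0-{MAX_BAND_HZ:.0f} Hz range")
    if hi >= signal.fs / 2:
        raise ConfigError(f"band [{lo}, {hi}] exceeds Nyquist ({signal.fs / 2} Hz)")
    n = signal.n_samples
    numtaps = _fir_taps(signal.fs, lo, n)
    if numtaps < 9 or n < 3 * numtaps:
        raise InsufficientDataError("signal too short for the narrow-band filter")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=signal.fs)
    filtered = sps.filtfilt(taps, [1.0], signal.data)
    analytic = sps.hilbert(filtered, N=next_fast_len(n))[:n]
    phase = np.angle(analytic)
    return PhaseSeries(phase=phase, band=(lo, hi), fs=signal.fs, edge=numtaps)


def plv(
    phase1: PhaseSeries, phase2: PhaseSeries, mask: np.ndarray | None = None
) -> float:
    """Phase-locking value: modulus of the mean phase-difference phasor.

    Symmetric in its arguments, invariant to adding a common constant to both
    series, and bounded in [0, 1]. The larger of the two edge margins is
    discarded from each end before the sum. An optional boolean `mask` (same
    length as the series) restricts the sum to selected samples, e.g. to
    stillness epochs; the default uses all samples.
    """
    if phase1.phase.shape != phase2.phase.shape:
        raise DataError(
            f"phase series lengths differ: {phase1.phase.size} vs {phase2.phase.size}"
        )
    if phase1.band != phase2.band:
        raise DataError(f"phase series from different bands: {phase1.band} vs {phase2.band}")
    edge = max(phase1.edge, phase2.edge)
    n = phase1.phase.size
    if n == 0 or n - 2 * edge <= 0:
        raise DataError("no samples left for the PLV sum")
    keep = np.zeros(n, dtype=bool)
    keep[edge : n - edge] = True
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != phase1.phase.shape:
            raise DataError("mask must match the phase series length")
        keep &= mask
        if not keep.any():
            raise DataError("mask leaves no samples for the PLV sum")
    theta = phase1.phase[keep] - phase2.phase[keep]
    return float(np.abs(np.exp(1j * theta).mean()))


def band_plv(
    sig1: Signal,
    sig2: Signal,
    band: Band,
    mask: np.ndarray | None = None,
    _phase_cache: dict | None = None,
) -> float:
    """Mean PLV over the 5-Hz sub-bands tiling an analysis band."""
    if band.attenuated:
        raise ConfigError(f"band {band.name!r} is hardware-attenuated and excluded from PLV")
    values = []
    for lo, hi in subbands(band):
        p1 = _cached_phase(sig1, lo, hi, _phase_cache)
        p2 = _cached_phase(sig2, lo, hi, _phase_cache)
        values.append(plv(p1, p2, mask=mask))
    return float(np.mean(values))


def _cached_phase(sig: Signal, lo: float, hi: float, cache: dict | None) -> PhaseSeries:
    if cache is None:
        return narrowband_phase(sig, lo, hi)
    key = (id(sig), lo, hi)
    if key not in cache:
        cache[key] = narrowband_phase(sig, lo, hi)
    return cache[key]


@dataclass
class SyncVector:
    """The 32 phase-locking values (8 pairs x 4 bands) of one session."""

    values: dict[tuple[str, str], float]
    meta: dict = field(default_factory=dict)

    PAIR_ORDER = tuple(f"{a}-{b}" for a, b in Montage().pairs)
    BAND_ORDER = tuple(b.name for b in CANONICAL_BANDS)

    def __post_init__(self):
        expected = {(p, b) for p in self.PAIR_ORDER for b in self.BAND_ORDER}
        if set(self.values) != expected:
            missing = expected - set(self.values)
            raise DataError(f"incomplete sync vector, missing keys such as {sorted(missing)[:3]}")
        for k, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise DataError(f"PLV out of [0,1] at {k}: {v}")

    def to_array(self) -> np.ndarray:
        """Flatten to shape (32,), pairs-major, band order theta..fast gamma."""
        return np.array(
            [self.values[(p, b)] for p in self.PAIR_ORDER for b in self.BAND_ORDER]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, meta: dict | None = None) -> "SyncVector":
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size != 32:
            raise DataError(f"sync vector needs 32 entries, got {arr.size}")
        keys = [(p, b) for p in cls.PAIR_ORDER for b in cls.BAND_ORDER]
        return cls(values=dict(zip(keys, arr)), meta=meta or {})


def session_sync_vector(
    rec: Recording,
    montage: Montage | None = None,
    bands: tuple[Band, ...] = CANONICAL_BANDS,
) -> SyncVector:
    """Compute the 32-D synchrony vector of a session.

    Phases are extracted once per (channel, sub-band) and reused across the
    8 montage pairs. Raises IncompleteMontageError naming the first missing
    channel.
    """
    montage = montage or Montage()
    for role in montage.roles:
        if role not in rec.channels:
            raise IncompleteMontageError(role)
    excluded = rec.meta.get("excluded_channels", ())
    for role in montage.roles:
        if role in excluded:
            raise IncompleteMontageError(role, reason="excluded by saturation screening")
    cache: dict = {}
    values: dict[tuple[str, str], float] = {}
    for a, b in montage.pairs:
        for band in bands:
            values[(f"{a}-{b}", band.name)] = band_plv(
                rec.get(a), rec.get(b), band, _phase_cache=cache
            )
    return SyncVector(values=values, meta=dict(rec.meta))
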