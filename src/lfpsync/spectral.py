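"""Power spectral density with the pipeline's normalization conventions.

LFP channels are first divided by their RMS value (removes electrode-specific
gain/impedance differences), the PSD is averaged over 5-s non-overlapping
Hamming-tapered windows, the 60-Hz line region is replaced by linear
interpolation between 58 and 62 Hz, and the spectrum is divided by its sum so
total power is 1. Frequency bands shared by the whole package are defined
here: theta 5-15 Hz, beta 20-30 Hz (chosen to exclude the strong second theta
harmonic), slow gamma 30-55 Hz, fast gamma 65-100 Hz (avoiding the 60-Hz
region). The delta band (0-3 Hz) is computed but flagged attenuated — the
acquisition hardware's DC-removal filter suppresses it — and it never enters
synchrony vectors.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DegenerateSignalError, InsufficientDataError
from .signals import Signal

__all__ = [
    "PSD",
    "Band",
    "CANONICAL_BANDS",
    "DELTA_BAND",
    "rms_normalize",
    "compute_psd",
    "interpolate_line_region",
    "normalize_psd",
    "band_fraction",
]


@dataclass(frozen=True)
class Band:
    """A half-open frequency interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float
    attenuated: bool = False  # hardware-attenuated bands are excluded from PLV

    def __post_init__(self):
        if not (0 <= self.lo < self.hi):
            raise ConfigError(f"band {self.name}: need 0 <= lo < hi, got [{self.lo}, {self.hi})")


#: Canonical analysis bands. Half-open edges [lo, hi) prevent double counting
#: at shared boundaries (30 Hz belongs to slow gamma, not beta).
CANONICAL_BANDS: tuple[Band, ...] = (
    Band("theta", 5.0, 15.0),
    Band("beta", 20.0, 30.0),
    Band("slow_gamma", 30.0, 55.0),
    Band("fast_gamma", 65.0, 100.0),
)

#: Delta is reported for completeness but flagged: the hardware DC-removal
#: filter attenuates it, so it is never used for synchrony.
DELTA_BAND = Band("delta", 0.0, 3.0, attenuated=True)


@dataclass
class PSD:
    """Averaged power spectrum on a regular frequency grid.

    ``power`` is a spectral density until :func:`normalize_psd` converts it to
    unit-sum fractions (``normalized`` flips to True).
    """

    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    normalized: bool = False

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ConfigError("freqs and power must have equal shape")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def total_power(self) -> float:
        """Integrated power: sum(power)*df for a density, sum(power) if normalized."""
        if self.normalized:
            return float(self.power.sum())
        return float(self.power.sum() * self.df)


def rms_normalize(signal: Signal) -> Signal:
    """Divide a signal by its RMS value so the output has RMS exactly 1."""
    rms = float(np.sqrt(np.mean(signal.data**2)))
    if rms == 0.0 or not np.isfinite(rms):
        raise DegenerateSignalError("cannot RMS-normalize an all-zero or non-finite signal")
    out = signal.copy()
    out.data = out.data / rms
    out.units = "rms"
    return out


def compute_psd(signal: Signal, window_s: float = 5.0) -> PSD:
    """Average periodograms over non-overlapping `window_s`-long windows.

    Each window is Hamming-tapered and mean-detrended; a trailing partial
    window is discarded. Scaling is one-sided density, so for a unit-RMS
    signal ``sum(power) * df`` is close to 1 (Parseval).
    """
    if window_s <= 0:
        raise ConfigError("window_s must be positive")
    nper = int(round(window_s * signal.fs))
    if signal.n_samples < nper:
        raise InsufficientDataError(
            f"signal of {signal.duration_s:.2f} s shorter than one {window_s} s window"
        )
    freqs, power = sps.welch(
        signal.data,
        fs=signal.fs,
        window="hamming",
        nperseg=nper,
        noverlap=0,
        detrend="constant",
        scaling="density",
    )
    return PSD(freqs=freqs, power=power, window_s=window_s)


def interpolate_line_region(psd: PSD, lo: float = 58.0, hi: float = 62.0) -> PSD:
    """Replace bins strictly inside (lo, hi) by a line between the boundary values.

    Removes the 60-Hz line-noise peak. Bins at or outside the boundaries are
    untouched. Anchors are the last bin at or below `lo` and the first bin at
    or above `hi`.
    """
    if lo >= hi:
        raise ConfigError(f"need lo < hi, got [{lo}, {hi}]")
    f = psd.freqs
    if lo < f[0] or hi > f[-1]:
        raise ConfigError(f"interpolation range [{lo}, {hi}] outside PSD grid")
    inner = (f > lo) & (f < hi)
    if not inner.any():
        return replace(psd, power=psd.power.copy())
    i_lo = int(np.searchsorted(f, lo, side="right")) - 1
    i_hi = int(np.searchsorted(f, hi, side="left"))
    power = psd.power.copy()
    power[inner] = np.interp(f[inner], [f[i_lo], f[i_hi]], [power[i_lo], power[i_hi]])
    return replace(psd, power=power)


def normalize_psd(psd: PSD) -> PSD:
    """Divide the spectrum by its sum so total power equals 1."""
    total = psd.power.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateSignalError("PSD has zero or non-finite total power")
    return replace(psd, power=psd.power / total, normalized=True)


def band_fraction(psd: PSD, band: Band) -> float:
    """Fraction of total power in [band.lo, band.hi)."""
    total = psd.power.sum()
    if total <= 0:
        raise DegenerateSignalError("PSD has zero total power")
    sel = (psd.freqs >= band.lo) & (psd.freqs < band.hi)
    return float(psd.power[sel].sum() / total)
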