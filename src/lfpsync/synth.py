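"""Synthetic LFP/EEG generator with known ground truth.

Everything the analysis pipeline consumes can be generated here with the
answer known in advance: 1/f-background field potentials, pairs of channels
whose band-limited oscillations are phase-coupled with a controllable von
Mises phase-difference distribution (so the expected phase-locking value has
the closed form I1(kappa)/I0(kappa)), ~6-Hz spike-wave trains with separately
parameterized spike and wave components, full 8-channel sessions with
scheduled events, 60-Hz line contamination and amplifier saturations,
group-structured 32-D synchrony vectors, and rotating-arena trajectories.

All generators are deterministic given (config, seed): the same seed yields
bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .behavior import PositionSeries, ZoneSpec, _angular_offset_deg
from .errors import ConfigError, ScheduleError
from .signals import Montage, Recording, Signal

__all__ = [
    "GenConfig",
    "CouplingSpec",
    "SWDSpec",
    "GroundTruth",
    "expected_plv",
    "gen_background",
    "gen_coupled_pair",
    "gen_swd_train",
    "gen_session",
    "gen_sync_vectors",
    "gen_trajectory",
]

#: kappa at or above this is treated as a point mass (perfect locking).
KAPPA_INF = 1e6


@dataclass
class GenConfig:
    """Acquisition-level parameters of a synthetic recording.

    Defaults mirror the emulated acquisition chain: 2000 Hz sampling after
    1-500 Hz band-pass. The background is pink-ish (1/f) noise; amplitude
    scales are free parameters of the generator (the recordings being
    emulated published no amplitude calibration), chosen at values typical of
    rodent LFP: ~50 uV RMS background.
    """

    fs: float = 2000.0
    duration_s: float = 60.0
    seed: int = 0
    background_exponent: float = 1.0
    background_rms: float = 50.0
    line_amp: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be positive, got {self.duration_s}")
        if self.background_rms < 0 or self.line_amp < 0:
            raise ConfigError("amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class CouplingSpec:
    """Phase coupling between one channel pair in one narrow band.

    The inter-channel phase difference in the band is von Mises distributed
    with mean ``mean_lag`` and concentration ``kappa``; the population
    phase-locking value is then I1(kappa)/I0(kappa).
    """

    band_center: float
    band_width: float = 5.0
    kappa: float = 2.0
    mean_lag: float = 0.0
    amp: float = 200.0  # oscillation amplitude, uV

    def __post_init__(self):
        if self.kappa < 0:
            raise ConfigError(f"kappa must be >= 0, got {self.kappa}")
        if self.band_center <= 0 or self.band_width <= 0:
            raise ConfigError("band_center and band_width must be positive")
        if self.amp < 0:
            raise ConfigError("amp must be non-negative")


@dataclass
class SWDSpec:
    """Morphology of one spike-wave train.

    Each ~`1/cycle_freq`-long cycle is a sharp positive spike (raised cosine
    of height ``spike_amp`` and base width ``spike_width_ms``) flanked by two
    narrow negative valleys — the one following the spike reaching
    ``-wave_amp``, the preceding one shallower by ``pre_valley_frac`` — with a
    slow positive half-sine wave filling the remainder of the cycle. The
    spike-to-valley voltage is therefore spike_amp + wave_amp.
    """

    cycle_freq: float = 6.0
    n_cycles: int = 12
    spike_amp: float = 800.0
    spike_width_ms: float = 60.0
    wave_amp: float = 100.0
    jitter_ms: float = 0.0
    valley_width_ms: float = 20.0
    pre_valley_frac: float = 0.6
    wave_hump_frac: float = 0.5

    def __post_init__(self):
        if self.cycle_freq <= 0 or self.n_cycles < 1:
            raise ConfigError("cycle_freq and n_cycles must be positive")
        period_ms = 1000.0 / self.cycle_freq
        if self.spike_width_ms >= period_ms:
            raise ConfigError(
                f"spike width {self.spike_width_ms} ms >= cycle period {period_ms:.1f} ms"
            )
        if self.spike_width_ms + 2 * self.valley_width_ms >= period_ms:
            raise ConfigError("spike plus flanking valleys do not fit in one cycle")
        if not (0 < self.pre_valley_frac <= 1):
            raise ConfigError("pre_valley_frac must be in (0, 1]")
        if min(self.spike_amp, self.wave_amp) < 0 or self.jitter_ms < 0:
            raise ConfigError("amplitudes and jitter must be non-negative")

    @property
    def period_s(self) -> float:
        return 1.0 / self.cycle_freq


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic dataset."""

    event_intervals: list[tuple[float, float]] = field(default_factory=list)
    spike_times_s: list[np.ndarray] = field(default_factory=list)
    cycle_features: list[dict] = field(default_factory=list)
    expected_plv: dict = field(default_factory=dict)
    entrance_count: int | None = None
    extras: dict = field(default_factory=dict)


def expected_plv(kappa: float) -> float:
    """Population PLV of a von Mises phase difference: I1(kappa)/I0(kappa).

    Uses exponentially scaled Bessel functions, stable for large kappa.
    """
    if kappa < 0:
        raise ConfigError("kappa must be >= 0")
    if kappa >= KAPPA_INF:
        return 1.0
    if kappa == 0.0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


# --------------------------------------------------------------------------
# background


def gen_background(cfg: GenConfig, rng: np.random.Generator | None = None) -> Signal:
    """Zero-mean 1/f^exponent noise with RMS equal to cfg.background_rms.

    White Gaussian noise is shaped in the frequency domain (amplitude
    proportional to f^(-exponent/2), flattened below 1 Hz to emulate the
    hardware DC-removal corner) and rescaled to the exact target RMS.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    white = rng.standard_normal(n)
    if cfg.background_exponent == 0.0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
        shape = np.ones_like(freqs)
        pos = freqs > 0
        f_eff = np.maximum(freqs[pos], 1.0)  # flatten below the 1-Hz corner
        shape[pos] = f_eff ** (-cfg.background_exponent / 2.0)
        shape[0] = 0.0  # zero mean
        x = np.fft.irfft(spec * shape, n=n)
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0 and cfg.background_rms > 0:
        x *= cfg.background_rms / rms
    elif cfg.background_rms == 0:
        x = np.zeros(n)
    return Signal(data=x, fs=cfg.fs, channel="background")


# --------------------------------------------------------------------------
# coupled oscillation pairs


def _vonmises_block_values(
    n_blocks: int, kappa: float, mean_lag: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified von Mises draws: exact marginal, near-zero sampling error.

    One quantile is drawn per equal-probability stratum and the values are
    permuted in time, so the empirical mean phasor converges to the
    population value at O(1/n_blocks^2) instead of O(1/sqrt(n_blocks)).
    """
    u = (np.arange(n_blocks) + rng.uniform(size=n_blocks)) / n_blocks
    if kappa >= KAPPA_INF:
        theta = np.full(n_blocks, mean_lag)
    elif kappa < 1e-12:
        theta = -np.pi + 2 * np.pi * u + mean_lag
    else:
        theta = stats.vonmises.ppf(u, kappa, loc=mean_lag)
    theta = np.angle(np.exp(1j * theta))  # wrap to (-pi, pi]
    return rng.permutation(theta)


def _block_phase_offset(
    n: int, fs: float, block_s: float, ramp_s: float, values: np.ndarray
) -> np.ndarray:
    """Piecewise-constant phase offset with raised-cosine ramps between blocks."""
    block_len = int(round(block_s * fs))
    theta = np.repeat(values, block_len)[:n]
    if theta.size < n:
        theta = np.pad(theta, (0, n - theta.size), mode="edge")
    half_ramp = int(round(ramp_s * fs / 2))
    if half_ramp > 0:
        for b in range(1, len(values)):
            j = b * block_len
            lo, hi = max(j - half_ramp, 0), min(j + half_ramp, n)
            if hi <= lo:
                continue
            delta = np.angle(np.exp(1j * (values[b] - values[b - 1])))
            u = (np.arange(lo, hi) - (j - half_ramp)) / (2 * half_ramp)
            theta[lo:hi] = values[b - 1] + delta * 0.5 * (1 - np.cos(np.pi * u))
    return theta


#: Phase-offset block length and crossfade, seconds. Blocks must be long
#: relative to the ~0.2-s response of the 5-Hz analysis filters (shorter
#: blocks let the filter average the offsets, inflating the measured PLV) yet
#: numerous enough for the stratified draws to pin the time-average phasor.
COUPLING_BLOCK_S = 2.0
COUPLING_RAMP_S = 0.2


def _carrier_centers(spec: CouplingSpec) -> list[float]:
    """Carrier frequencies: one per 5-Hz sub-band tiling the coupling band."""
    n_sub = max(int(round(spec.band_width / 5.0)), 1)
    lo = spec.band_center - spec.band_width / 2.0
    if n_sub == 1:
        return [spec.band_center]
    return [lo + 5.0 * k + 2.5 for k in range(n_sub)]


def _coupled_components(
    spec: CouplingSpec,
    n: int,
    fs: float,
    duration_s: float,
    rng: np.random.Generator,
    block_s: float,
    ramp_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed coupled carriers for the two channels of one pair."""
    t = np.arange(n) / fs
    x1 = np.zeros(n)
    x2 = np.zeros(n)
    n_blocks = max(int(np.ceil(duration_s / block_s)), 1)
    for f0 in _carrier_centers(spec):
        values = _vonmises_block_values(n_blocks, spec.kappa, spec.mean_lag, rng)
        theta = _block_phase_offset(n, fs, block_s, ramp_s, values)
        carrier = 2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
        x1 += spec.amp * np.cos(carrier)
        x2 += spec.amp * np.cos(carrier - theta)
    return x1, x2


def gen_coupled_pair(
    cfg: GenConfig,
    spec: CouplingSpec,
    block_s: float = COUPLING_BLOCK_S,
    ramp_s: float = COUPLING_RAMP_S,
) -> tuple[Signal, Signal, GroundTruth]:
    """Two channels sharing band-limited oscillations with von Mises coupling.

    One carrier is placed at the center of every 5-Hz sub-band tiling
    [band_center - band_width/2, band_center + band_width/2), so each
    analysis sub-band sees a locked oscillation. Channel 1 carries
    cos(phi(t)); channel 2 carries cos(phi(t) - theta(t)) where theta(t) is a
    slowly varying (block-resampled, stratified) von Mises(mean_lag, kappa)
    process: the band-limited phase difference has the requested distribution
    and expected PLV I1(kappa)/I0(kappa). 1/f background noise is added
    independently to each channel.
    """
    f_lo = spec.band_center - spec.band_width / 2.0
    f_hi = spec.band_center + spec.band_width / 2.0
    if not (0 < spec.band_center < cfg.fs / 2) or f_lo <= 0 or f_hi >= cfg.fs / 2:
        raise ConfigError(
            f"coupling band [{f_lo}, {f_hi}] Hz outside (0, {cfg.fs / 2}) Hz"
        )
    seq = np.random.SeedSequence(cfg.seed).spawn(3)
    s1, s2 = _coupled_components(
        spec, cfg.n_samples, cfg.fs, cfg.duration_s,
        np.random.default_rng(seq[0]), block_s, ramp_s,
    )
    if cfg.background_rms > 0:
        s1 = s1 + gen_background(cfg, np.random.default_rng(seq[1])).data
        s2 = s2 + gen_background(cfg, np.random.default_rng(seq[2])).data

    truth = GroundTruth(
        expected_plv={"pair": expected_plv(spec.kappa)},
        extras={"kappa": spec.kappa, "mean_lag": spec.mean_lag,
                "band_center": spec.band_center},
    )
    return (
        Signal(s1, cfg.fs, channel="ch1"),
        Signal(s2, cfg.fs, channel="ch2"),
        truth,
    )


# --------------------------------------------------------------------------
# spike-wave trains


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height raised-cosine pulse, zero outside [center +/- width/2]."""
    u = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1 + np.cos(2 * np.pi * u[m]))
    return out


def _spike_wave_waveform(
    spec: SWDSpec, fs: float, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    """Clean spike-wave train and its spike peak times (s)."""
    p = spec.period_s
    w = spec.spike_width_ms / 1000.0
    vw = spec.valley_width_ms / 1000.0
    dur = spec.n_cycles * p
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    base_peaks = np.arange(spec.n_cycles) * p + w / 2 + vw
    if spec.jitter_ms > 0 and rng is not None:
        jitter = rng.normal(0.0, spec.jitter_ms / 1000.0, size=spec.n_cycles)
        peaks = base_peaks + jitter
        peaks = np.clip(peaks, w / 2 + vw, dur - w / 2 - vw)
        peaks.sort()
    else:
        peaks = base_peaks

    x = np.zeros(n)
    for k, pk in enumerate(peaks):
        x += spec.spike_amp * _raised_cosine(t, pk, w)
        x -= spec.pre_valley_frac * spec.wave_amp * _raised_cosine(t, pk - w / 2 - vw / 2, vw)
        x -= spec.wave_amp * _raised_cosine(t, pk + w / 2 + vw / 2, vw)
        hump_start = pk + w / 2 + vw
        hump_end = peaks[k + 1] - w / 2 - vw if k + 1 < len(peaks) else dur
        if hump_end - hump_start > 2.0 / fs:
            m = (t >= hump_start) & (t < hump_end)
            u = (t[m] - hump_start) / (hump_end - hump_start)
            x[m] += spec.wave_hump_frac * spec.wave_amp * np.sin(np.pi * u)
    return x, peaks


def _train_ground_truth(spec: SWDSpec, peaks: np.ndarray, x: np.ndarray, fs: float) -> list[dict]:
    """Per-cycle morphology implied by the construction.

    Valley positions and depths follow the layout analytically; the wave
    energy is read off the clean waveform between the flanking valleys.
    """
    w = spec.spike_width_ms / 1000.0
    vw = spec.valley_width_ms / 1000.0
    level = -spec.pre_valley_frac * spec.wave_amp  # higher-voltage flanking min
    # width at that level: full spike base, plus the descent into the following
    # valley down to `level`, plus the climb from the preceding valley bottom.
    frac = np.arccos(1 + 2 * level / spec.wave_amp) / (2 * np.pi) if spec.wave_amp > 0 else 0.0
    spike_duration_s = w + vw / 2 + frac * vw if spec.wave_amp > 0 else w
    out = []
    for k, pk in enumerate(peaks):
        post_min_t = pk + w / 2 + vw / 2
        feat = {
            "spike_time_s": float(pk),
            "spike_to_valley_uV": spec.spike_amp + spec.wave_amp,
            "spike_duration_ms": spike_duration_s * 1000.0,
            "inter_spike_ms": float((peaks[k + 1] - pk) * 1000.0) if k + 1 < len(peaks) else None,
        }
        if k + 1 < len(peaks):
            next_pre_min_t = peaks[k + 1] - w / 2 - vw / 2
            feat["wave_duration_ms"] = (next_pre_min_t - post_min_t) * 1000.0
            i0, i1 = int(round(post_min_t * fs)), int(round(next_pre_min_t * fs))
            feat["wave_energy"] = float(np.sum(x[i0:i1] ** 2))
        else:
            feat["wave_duration_ms"] = None
            feat["wave_energy"] = None
        out.append(feat)
    return out


def gen_swd_train(cfg: GenConfig, spec: SWDSpec) -> tuple[Signal, GroundTruth]:
    """A clean spike-wave train segment plus its per-cycle ground truth."""
    rng = np.random.default_rng(cfg.seed)
    x, peaks = _spike_wave_waveform(spec, cfg.fs, rng)
    truth = GroundTruth(
        event_intervals=[(0.0, len(x) / cfg.fs)],
        spike_times_s=[peaks],
        cycle_features=_train_ground_truth(spec, peaks, x, cfg.fs),
        extras={"spec": spec},
    )
    return Signal(x, cfg.fs, channel="swd"), truth


# --------------------------------------------------------------------------
# full sessions


def _check_schedule(schedule: list[tuple[float, float]], duration_s: float) -> None:
    iv = sorted((float(s), float(s) + float(d)) for s, d in schedule)
    for s, e in iv:
        if s < 0 or e > duration_s:
            raise ScheduleError(f"event [{s}, {e}] outside session [0, {duration_s}]")
    for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
        if s1 < e0:
            raise ScheduleError(f"events [{s0},{e0}] and [{s1},{e1}] overlap")


def gen_session(
    cfg: GenConfig,
    montage: Montage | None = None,
    couplings: dict[tuple[str, str], CouplingSpec] | None = None,
    swd_spec: SWDSpec | None = None,
    swd_schedule: list[tuple[float, float]] | None = None,
    swd_channels: tuple[str, ...] = ("EEG_FL", "EEG_FR", "EEG_PL", "EEG_PR"),
    rail_uV: float | None = None,
    saturation_schedule: list[tuple[float, float]] | None = None,
    meta: dict | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate a full 8-channel session.

    Per channel: 1/f background, plus any coupled oscillations the channel
    participates in, plus spike-wave trains at the scheduled (start_s,
    duration_s) intervals on `swd_channels`, plus optional 60-Hz line noise
    and hard-clipped saturation intervals at `rail_uV`.
    """
    montage = montage or Montage()
    couplings = couplings or {}
    swd_schedule = sorted(swd_schedule or [], key=lambda iv: iv[0])
    _check_schedule(swd_schedule, cfg.duration_s)
    if swd_schedule and swd_spec is None:
        raise ConfigError("swd_schedule given without an SWDSpec")
    for a, b in couplings:
        if a not in montage.roles or b not in montage.roles:
            raise ConfigError(f"coupling pair ({a}, {b}) not in montage")
    for ch in swd_channels:
        if ch not in montage.roles:
            raise ConfigError(f"swd channel {ch} not in montage")

    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    seq = np.random.SeedSequence(cfg.seed)
    # fixed spawn order => determinism: backgrounds, couplings, trains, line
    children = iter(seq.spawn(len(montage.roles) + len(couplings) + len(swd_schedule) + 1))

    data = {}
    for role in montage.roles:
        data[role] = gen_background(cfg, np.random.default_rng(next(children))).data

    truth = GroundTruth(extras={"schedule": list(swd_schedule)})
    for (a, b), cspec in couplings.items():
        rng_c = np.random.default_rng(next(children))
        x1, x2 = _coupled_components(
            cspec, n, cfg.fs, cfg.duration_s, rng_c, COUPLING_BLOCK_S, COUPLING_RAMP_S
        )
        data[a] = data[a] + x1
        data[b] = data[b] + x2
        truth.expected_plv[(a, b)] = expected_plv(cspec.kappa)

    for start_s, dur_s in swd_schedule:
        rng_e = np.random.default_rng(next(children))
        n_cycles = max(int(round(dur_s * swd_spec.cycle_freq)), 1)
        from dataclasses import replace as _dc_replace

        espec = _dc_replace(swd_spec, n_cycles=n_cycles)
        x, peaks = _spike_wave_waveform(espec, cfg.fs, rng_e)
        i0 = int(round(start_s * cfg.fs))
        i1 = min(i0 + x.size, n)
        for ch in swd_channels:
            data[ch][i0:i1] += x[: i1 - i0]
        truth.event_intervals.append((start_s, start_s + x.size / cfg.fs))
        truth.spike_times_s.append(peaks + start_s)
        truth.cycle_features.append(_train_ground_truth(espec, peaks, x, cfg.fs))

    if cfg.line_amp > 0:
        rng_l = np.random.default_rng(next(children))
        line_phase = rng_l.uniform(0, 2 * np.pi)
        line = cfg.line_amp * np.sin(2 * np.pi * 60.0 * t + line_phase)
        for role in montage.roles:
            data[role] = data[role] + line

    if saturation_schedule:
        if rail_uV is None or rail_uV <= 0:
            raise ConfigError("saturation_schedule requires a positive rail_uV")
        _check_schedule(saturation_schedule, cfg.duration_s)
        for start_s, dur_s in saturation_schedule:
            i0 = int(round(start_s * cfg.fs))
            i1 = min(int(round((start_s + dur_s) * cfg.fs)), n)
            for role in montage.roles:
                data[role][i0:i1] = 10 * rail_uV
        truth.extras["saturation_schedule"] = list(saturation_schedule)
    if rail_uV is not None:
        for role in montage.roles:
            np.clip(data[role], -rail_uV, rail_uV, out=data[role])

    channels = {
        role: Signal(data[role], cfg.fs, channel=role) for role in montage.roles
    }
    rec = Recording(channels=channels, fs=cfg.fs, meta=dict(meta or {}))
    truth.extras["prevalence"] = (
        sum(e - s for s, e in truth.event_intervals) / cfg.duration_s
    )
    return rec, truth


def gen_detection_benchmark(
    seed: int,
    duration_s: float = 300.0,
    with_trains: bool = True,
    spike_amp: float = 600.0,
    fs: float = 2000.0,
) -> tuple[Signal, list[tuple[float, float]]]:
    """One benchmark channel for detector evaluation.

    A `duration_s`-long epidural-screw channel over 1/f background, with
    (when `with_trains`) 3-6 scheduled 6-Hz spike-wave trains of 1.5-3 s at
    `spike_amp`. Returns the channel and the scheduled intervals (the ground
    truth the detector is scored against).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
    cfg = GenConfig(fs=fs, duration_s=duration_s, seed=seed, background_rms=50.0)
    schedule: list[tuple[float, float]] = []
    if with_trains:
        n_trains = int(rng.integers(3, 7))
        starts = np.sort(rng.uniform(5.0, duration_s - 10.0, n_trains))
        prev_end = -np.inf
        for s in starts:
            d = float(rng.uniform(1.5, 3.0))
            if s > prev_end + 2.0 and s + d < duration_s - 2.0:
                schedule.append((float(s), d))
                prev_end = s + d
    spec = SWDSpec(cycle_freq=6.0, spike_amp=spike_amp, wave_amp=100.0, jitter_ms=3.0)
    rec, truth = gen_session(
        cfg, swd_spec=spec if schedule else None, swd_schedule=schedule
    )
    return rec.get("EEG_FL"), truth.event_intervals


# --------------------------------------------------------------------------
# synchrony-vector clouds and trajectories


def gen_sync_vectors(
    group_centroids: dict[str, np.ndarray],
    noise_sd: float,
    n_per_group: int = 8,
    seed: int = 0,
):
    """Per-group isotropic Gaussian clouds of 32-D synchrony vectors.

    Values are clipped to the valid PLV range [0, 1]. Returns a list of
    :class:`~lfpsync.phase.SyncVector` with ``meta['group']`` set.
    """
    from .phase import SyncVector

    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for group in sorted(group_centroids):
        c = np.asarray(group_centroids[group], dtype=float).ravel()
        if c.size != 32:
            raise ConfigError(f"centroid for {group!r} must have 32 entries, got {c.size}")
        if c.min() < 0 or c.max() > 1:
            raise ConfigError(f"centroid entries for {group!r} must lie in [0, 1]")
        cloud = c[None, :] + noise_sd * rng.standard_normal((n_per_group, 32))
        np.clip(cloud, 0.0, 1.0, out=cloud)
        for i in range(n_per_group):
            out.append(
                SyncVector.from_array(cloud[i], meta={"group": group, "session": i})
            )
    return out


def gen_trajectory(
    arena_radius_cm: float = 41.0,
    rotation_period_s: float = 60.0,
    policy: str = "random-walk",
    duration_s: float = 600.0,
    seed: int = 0,
    zone: ZoneSpec | None = None,
    sample_hz: float = 30.0,
    speed_cm_s: float = 8.0,
) -> tuple[PositionSeries, GroundTruth]:
    """Simulate an animal's room-frame path on the rotating arena.

    Policies: ``random-walk`` (correlated random walk reflected at the wall),
    ``avoider`` (random walk that never enters the room-frame `zone` sector),
    ``stationary`` (sits still; the arena still rotates under it — the room-
    frame path is then a circle, which is why a passive animal fails the
    room-frame avoidance task... here it simply sits at a fixed room point).
    """
    if policy not in ("random-walk", "avoider", "stationary"):
        raise ConfigError(f"unknown policy {policy!r}")
    if policy == "avoider" and zone is None:
        raise ConfigError("avoider policy requires a ZoneSpec")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_hz))
    dt = 1.0 / sample_hz
    t = np.arange(n) * dt
    arena_angle = (360.0 * t / rotation_period_s) % 360.0

    x = np.empty(n)
    y = np.empty(n)
    if policy == "stationary":
        x[:] = arena_radius_cm / 2
        y[:] = 0.0
    else:
        start_ang = 0.0
        if zone is not None:
            start_ang = np.radians(zone.center_angle_deg + 180.0)  # opposite the zone
        pos = (arena_radius_cm / 2) * np.array([np.cos(start_ang), np.sin(start_ang)])
        heading = rng.uniform(0, 2 * np.pi)
        for i in range(n):
            x[i], y[i] = pos
            heading += rng.normal(0.0, 0.6) * np.sqrt(dt) * np.pi
            step = speed_cm_s * dt * np.array([np.cos(heading), np.sin(heading)])
            nxt = pos + step
            r = np.hypot(*nxt)
            if r > arena_radius_cm * 0.98:
                # reflect back toward the center
                heading = np.arctan2(-nxt[1], -nxt[0]) + rng.normal(0.0, 0.3)
                nxt = pos + speed_cm_s * dt * np.array([np.cos(heading), np.sin(heading)])
            if policy == "avoider":
                ang = np.degrees(np.arctan2(nxt[1], nxt[0]))
                off = _angular_offset_deg(ang, zone.center_angle_deg)
                margin = zone.width_deg / 2 + 5.0
                if abs(off) < margin:
                    # rotate the position out of the sector, preserving radius
                    push = margin if off >= 0 else -margin
                    new_ang = np.radians(zone.center_angle_deg + push)
                    rr = np.hypot(*nxt)
                    nxt = rr * np.array([np.cos(new_ang), np.sin(new_ang)])
                    heading = rng.uniform(0, 2 * np.pi)
            pos = nxt

    series = PositionSeries(
        t=t, x=x, y=y, valid=np.ones(n, dtype=bool), arena_angle_deg=arena_angle
    )
    truth = GroundTruth(
        entrance_count=0 if policy in ("avoider",) else None,
        extras={"policy": policy, "arena_radius_cm": arena_radius_cm},
    )
    return series, truth
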