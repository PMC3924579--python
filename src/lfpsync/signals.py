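"""Core containers: single-channel signals, multi-channel recordings, montage.

A :class:`Signal` is one electrode's sample series with its sampling rate and
physical units (microvolts throughout the package). A :class:`Recording` is an
aligned set of channels keyed by montage role, carrying session metadata
(group, treatment, trial index). The :class:`Montage` names the 8 recording
sites — left/right dorsal hippocampus (LHC/RHC), left/right medial prefrontal
cortex (LmPFC/RmPFC), and 4 epidural screws (frontal and parietal, each
hemisphere) — and the 8 canonical electrode pairs used for phase-locking.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, IncompleteMontageError

__all__ = ["Signal", "Recording", "Montage", "DEFAULT_MONTAGE"]


@dataclass
class Signal:
    """One channel's sample series.

    Parameters
    ----------
    data : ndarray
        Sample values in `units` (float).
    fs : float
        Sampling rate in Hz.
    units : str
        Physical units, default microvolts.
    channel : str or None
        Montage role or electrode label.
    """

    data: np.ndarray
    fs: float
    units: str = "uV"
    channel: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 1:
            raise ConfigError("Signal data must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Signal":
        return Signal(self.data.copy(), self.fs, self.units, self.channel)


# Montage roles: hippocampal and mPFC depth wires plus epidural screws in the
# frontal (F) and parietal (P) bones of each hemisphere (L/R).
_ROLES = ("LHC", "RHC", "LmPFC", "RmPFC", "EEG_FL", "EEG_FR", "EEG_PL", "EEG_PR")

# The 8 canonical electrode pairs: inter-hippocampal, inter-mPFC, the two
# ipsilateral hippocampus-mPFC pairs, and the inter-hemispheric (frontal L-R,
# parietal L-R) and associational (frontal-parietal within hemisphere) screw
# pairs.
_PAIRS = (
    ("LHC", "RHC"),
    ("LmPFC", "RmPFC"),
    ("LHC", "LmPFC"),
    ("RHC", "RmPFC"),
    ("EEG_FL", "EEG_FR"),
    ("EEG_PL", "EEG_PR"),
    ("EEG_FL", "EEG_PL"),
    ("EEG_FR", "EEG_PR"),
)


@dataclass(frozen=True)
class Montage:
    """Channel roles and the electrode pairs entering synchrony analysis."""

    roles: tuple[str, ...] = _ROLES
    pairs: tuple[tuple[str, str], ...] = _PAIRS

    def __post_init__(self):
        for a, b in self.pairs:
            if a not in self.roles or b not in self.roles:
                raise ConfigError(f"pair ({a}, {b}) references unknown channel role")
        if len(self.pairs) != len(set(self.pairs)):
            raise ConfigError("duplicate montage pairs")

    def pair_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


DEFAULT_MONTAGE = Montage()


@dataclass
class Recording:
    """Aligned multi-channel signal set with session metadata."""

    channels: dict[str, Signal]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {s.n_samples for s in self.channels.values()}
        if len(lengths) > 1:
            raise ConfigError("all channels in a Recording must share one length")
        for name, sig in self.channels.items():
            if sig.fs != self.fs:
                raise ConfigError(f"channel {name} fs {sig.fs} != recording fs {self.fs}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n_samples if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def get(self, role: str) -> Signal:
        try:
            return self.channels[role]
        except KeyError:
            raise IncompleteMontageError(role) from None
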