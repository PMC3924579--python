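"""Two-frame active place avoidance scoring.

The task puts an animal on a slowly rotating circular arena (82 cm diameter)
with a 60-degree shock sector fixed in stationary *room* coordinates, so
avoiding it requires using room-frame cues and ignoring the rotating
arena-frame cues. Performance is scored by counting entrances into the
sector over a 10-min trial; locomotor activity is summarised as average
speed. Scoring is done in the room frame only; an arena-frame view of the
path is available for plotting via the rotation-angle column.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, DegenerateSignalError

__all__ = [
    "PositionSeries",
    "ZoneSpec",
    "TrialScore",
    "count_entrances",
    "avg_speed",
    "score_trial",
    "correlate_sync_behavior",
]


def _angular_offset_deg(angle_deg, center_deg):
    """Signed angular distance in degrees, wrapped to (-180, 180]."""
    return (np.asarray(angle_deg) - center_deg + 180.0) % 360.0 - 180.0


@dataclass
class PositionSeries:
    """Tracked positions (cm, room frame) with per-sample validity flags."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None
    arena_angle_deg: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.t, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise DataError("t, x, y, valid must share one shape")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise DataError("timestamps must be non-decreasing")

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y,
                           "valid": self.valid.astype(int)})
        if self.arena_angle_deg is not None:
            df["arena_angle_deg"] = self.arena_angle_deg
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionSeries":
        return cls(
            t=df["t_s"].to_numpy(),
            x=df["x_cm"].to_numpy(),
            y=df["y_cm"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool) if "valid" in df else None,
            arena_angle_deg=df["arena_angle_deg"].to_numpy()
            if "arena_angle_deg" in df
            else None,
        )


@dataclass(frozen=True)
class ZoneSpec:
    """Angular shock sector fixed in room coordinates."""

    center_angle_deg: float = 0.0
    width_deg: float = 60.0
    frame: str = "room"

    def __post_init__(self):
        if not (0 < self.width_deg <= 360):
            raise ConfigError(f"zone width must be in (0, 360], got {self.width_deg}")
        if self.frame != "room":
            raise ConfigError("scoring is defined in the room frame only")

    def contains(self, x, y) -> np.ndarray:
        ang = np.degrees(np.arctan2(np.asarray(y), np.asarray(x)))
        return np.abs(_angular_offset_deg(ang, self.center_angle_deg)) <= self.width_deg / 2


@dataclass
class TrialScore:
    """Per-trial summary of one avoidance session."""

    entrances: int
    avg_speed_cm_s: float
    trial_duration_s: float = 600.0
    meta: dict = field(default_factory=dict)


def count_entrances(pos: PositionSeries, zone: ZoneSpec, debounce_s: float = 0.5) -> int:
    """Number of outside-to-inside transitions into the shock sector.

    Tracker jitter at the sector edge would otherwise split one visit into
    several, so an entrance episode only closes after the animal has been
    continuously outside for at least `debounce_s`; re-entering sooner does
    not count again.
    """
    if pos.n == 0:
        raise DataError("empty position series")
    if debounce_s < 0:
        raise ConfigError("debounce_s must be >= 0")
    inside = zone.contains(pos.x, pos.y) & pos.valid
    entrances = 0
    in_episode = False
    outside_since: float | None = None
    for i in range(pos.n):
        if not pos.valid[i]:
            continue
        if inside[i]:
            if not in_episode:
                entrances += 1
                in_episode = True
            outside_since = None
        elif in_episode:
            if outside_since is None:
                outside_since = pos.t[i]
            elif pos.t[i] - outside_since >= debounce_s:
                in_episode = False
                outside_since = None
    return entrances


def avg_speed(pos: PositionSeries) -> float:
    """Path length divided by elapsed valid time (cm/s).

    Segments with a duplicated timestamp or an invalid endpoint are skipped.
    """
    v = pos.valid
    if int(v.sum()) < 2:
        raise DataError("need at least 2 valid samples for speed")
    t, x, y = pos.t[v], pos.x[v], pos.y[v]
    dt = np.diff(t)
    keep = dt > 0
    if not keep.any():
        raise DataError("no positive time steps among valid samples")
    path = np.hypot(np.diff(x), np.diff(y))[keep]
    return float(path.sum() / dt[keep].sum())


def score_trial(pos: PositionSeries, zone: ZoneSpec, debounce_s: float = 0.5) -> TrialScore:
    """Entrance count and average speed for one trial."""
    duration = float(pos.t[-1] - pos.t[0]) if pos.n else 0.0
    return TrialScore(
        entrances=count_entrances(pos, zone, debounce_s),
        avg_speed_cm_s=avg_speed(pos),
        trial_duration_s=duration,
    )


def correlate_sync_behavior(plvs, entrances) -> tuple[float, float]:
    """Pearson correlation between per-animal synchrony and avoidance scores.

    Returns (r, two-sided p). Raises on zero variance in either vector.
    """
    a = np.asarray(plvs, dtype=float)
    b = np.asarray(entrances, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired 1-D vectors required")
    if a.size < 3:
        raise DataError("need at least 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateSignalError("zero variance in one of the vectors")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
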