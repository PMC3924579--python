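"""Reading and writing the pipeline's plain-text interchange formats.

Recordings travel as long-form CSV (t_s, channel, value_uV); ground truth as
JSON; trajectories as CSV (t_s, x_cm, y_cm, valid, arena_angle_deg); sync
vectors, detected events, per-cycle features, PSDs and distance tables as
CSV. EDF recordings can be *read* through mne when it is installed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import PositionSeries
from .detect import SWDEvent
from .errors import DataError
from .phase import SyncVector
from .signals import Recording, Signal
from .spectral import PSD
from .synth import GroundTruth

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_edf",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_events_csv",
    "write_events_json",
    "write_sync_vectors_csv",
    "write_psd_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_intervals_csv",
    "read_intervals_csv",
    "write_features_csv",
    "write_distribution_csv",
    "write_embedding_csv",
    "write_distance_table_csv",
]


def write_recording_csv(rec: Recording, path) -> None:
    """Long-form CSV: one row per (t, channel) sample, values in uV."""
    frames = []
    t = np.arange(rec.n_samples) / rec.fs
    for name, sig in rec.channels.items():
        frames.append(pd.DataFrame({"t_s": t, "channel": name, "value_uV": sig.data}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recording_csv(path, meta: dict | None = None) -> Recording:
    df = pd.read_csv(path)
    required = {"t_s", "channel", "value_uV"}
    if not required.issubset(df.columns):
        raise DataError(f"recording CSV needs columns {sorted(required)}")
    channels = {}
    fs = None
    for name, grp in df.groupby("channel", sort=False):
        t = grp["t_s"].to_numpy()
        if t.size < 2:
            raise DataError(f"channel {name} has fewer than 2 samples")
        fs_ch = 1.0 / float(np.median(np.diff(t)))
        fs = fs or round(fs_ch, 6)
        channels[str(name)] = Signal(grp["value_uV"].to_numpy(), fs, channel=str(name))
    return Recording(channels=channels, fs=fs, meta=meta or {})


def read_recording_edf(path, meta: dict | None = None) -> Recording:
    """Read a multi-channel EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the 'mne' package (lfpsync[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = {
        name: Signal(data[i], fs, channel=name) for i, name in enumerate(raw.ch_names)
    }
    return Recording(channels=channels, fs=fs, meta=meta or {})


def _intervals(obj):
    return [(float(s), float(e)) for s, e in obj]


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "event_intervals": _intervals(truth.event_intervals),
        "spike_times_s": [np.asarray(st).tolist() for st in truth.spike_times_s],
        "cycle_features": _jsonable(truth.cycle_features),
        "expected_plv": {str(k): v for k, v in truth.expected_plv.items()},
        "entrance_count": truth.entrance_count,
        "extras": _jsonable({k: v for k, v in truth.extras.items() if k != "spec"}),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        event_intervals=_intervals(payload.get("event_intervals", [])),
        spike_times_s=[np.asarray(st, dtype=float) for st in payload.get("spike_times_s", [])],
        cycle_features=payload.get("cycle_features", []),
        expected_plv=payload.get("expected_plv", {}),
        entrance_count=payload.get("entrance_count"),
        extras=payload.get("extras", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def write_events_csv(events: list[SWDEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "channel": ev.channel,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "n_spikes": ev.n_spikes,
            }
            for ev in events
        ]
    ).to_csv(path, index=False)


def write_events_json(events: list[SWDEvent], path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "channel": ev.channel,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "spike_times_s": ev.spike_times_s.tolist(),
                }
                for ev in events
            ],
            indent=1,
        )
    )


def write_sync_vectors_csv(vectors: list[SyncVector], path) -> None:
    rows = []
    for i, vec in enumerate(vectors):
        for (pair, band), value in vec.values.items():
            rows.append(
                {
                    "session_id": vec.meta.get("session", i),
                    "group": vec.meta.get("group"),
                    "treatment": vec.meta.get("treatment"),
                    "pair": pair,
                    "band": band,
                    "plv": value,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_psd_csv(psd: PSD, path) -> None:
    pd.DataFrame({"freq_hz": psd.freqs, "power_fraction": psd.power}).to_csv(
        path, index=False
    )


def write_trajectory_csv(pos: PositionSeries, path) -> None:
    pos.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> PositionSeries:
    return PositionSeries.from_frame(pd.read_csv(path))


def write_intervals_csv(intervals, path) -> None:
    """Marked-segment file: (channel, start_s, end_s, source).

    `intervals` is an iterable of (channel, start_s, end_s) or
    (channel, start_s, end_s, source) tuples; source defaults to "manual"
    and is one of {"manual", "auto", "truth"}.
    """
    rows = []
    for iv in intervals:
        ch, s, e = iv[0], float(iv[1]), float(iv[2])
        source = iv[3] if len(iv) > 3 else "manual"
        if source not in ("manual", "auto", "truth"):
            raise DataError(f"unknown interval source {source!r}")
        rows.append({"channel": ch, "start_s": s, "end_s": e, "source": source})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_intervals_csv(path) -> list[tuple[str, float, float, str]]:
    df = pd.read_csv(path)
    required = {"channel", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise DataError(f"interval CSV needs columns {sorted(required)}")
    if "source" not in df:
        df["source"] = "manual"
    return [
        (str(r.channel), float(r.start_s), float(r.end_s), str(r.source))
        for r in df.itertuples()
    ]


def write_features_csv(cycle_features, path) -> None:
    """Per-cycle morphology features, one row per spike-wave cycle."""
    pd.DataFrame(
        [
            {
                "spike_duration_ms": f.spike_duration_ms,
                "spike_to_valley_uV": f.spike_to_valley_uV,
                "inter_spike_ms": f.inter_spike_ms,
                "wave_duration_ms": f.wave_duration_ms,
                "wave_energy": f.wave_energy,
                "in_sequence": f.in_sequence,
            }
            for f in cycle_features
        ]
    ).to_csv(path, index=False)


def write_distribution_csv(dist, path) -> None:
    """Feature histogram as (bin_left, bin_right, probability)."""
    pd.DataFrame(
        {
            "bin_left": dist.bin_edges[:-1],
            "bin_right": dist.bin_edges[1:],
            "probability": dist.probabilities,
        }
    ).to_csv(path, index=False)


def write_embedding_csv(embedding, prefix) -> None:
    """PCA outputs as three CSVs: <prefix>_loadings/scores/variance.csv."""
    prefix = str(prefix)
    pd.DataFrame(embedding.loadings).to_csv(prefix + "_loadings.csv", index=False)
    scores = pd.DataFrame(embedding.scores)
    scores.insert(0, "group", embedding.labels)
    scores.to_csv(prefix + "_scores.csv", index=False)
    pd.DataFrame({"variance_fraction": embedding.variance_fractions}).to_csv(
        prefix + "_variance.csv", index=False
    )


def write_distance_table_csv(report, path) -> None:
    """The per-(group, reference) distance/t table of a DistanceReport."""
    report.table.to_csv(path, index=False)
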