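"""End-to-end orchestration: configuration, session reports, study reports.

`run_session` takes one recording (loaded or generated) through screening,
spectral analysis, spike-wave detection, optional feature extraction on
marked intervals, and the 32-D synchrony vector. `run_study` aggregates
session reports across treatment groups into the study-level statistics:
per-feature distribution comparisons (Kolmogorov-Smirnov), the PCA/distance
pattern analysis, and synchrony-behavior correlations. Every report carries a
hash of the configuration that produced it; identical config + seed gives
identical output.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import behavior as bhv
from .detect import DetectorParams, detect_swd, prevalence, screen_saturation
from .errors import ConfigError, DataError
from .features import FeatureParams, extract_features, find_spikes, ks_compare, preprocess
from .patterns import PatternDataset, fit_pca, group_distances, project
from .phase import SyncVector, session_sync_vector
from .signals import Montage, Recording, Signal
from .spectral import compute_psd, interpolate_line_region, normalize_psd, rms_normalize

__all__ = ["RunConfig", "SessionReport", "StudyReport", "run_session", "run_study"]


@dataclass
class RunConfig:
    """Fully serializable description of one session analysis."""

    seed: int = 0
    window_s: float = 5.0
    pca_k: int = 6
    detector: DetectorParams = field(default_factory=DetectorParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    rail_uV: float | None = None
    swd_channels: tuple[str, ...] = ("EEG_FL", "EEG_FR", "EEG_PL", "EEG_PR")
    group: str | None = None
    treatment: str | None = None
    session_id: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["swd_channels"] = list(self.swd_channels)
        d["detector"]["scales"] = list(self.detector.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "detector" in d and isinstance(d["detector"], dict):
            det = dict(d["detector"])
            det["scales"] = tuple(det.get("scales", DetectorParams().scales))
            d["detector"] = DetectorParams(**det)
        if "features" in d and isinstance(d["features"], dict):
            d["features"] = FeatureParams(**d["features"])
        if "swd_channels" in d:
            d["swd_channels"] = tuple(d["swd_channels"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SessionReport:
    """Per-session outputs: spectra, synchrony vector, detections, features."""

    config_hash: str
    meta: dict
    psd: dict                       # channel -> normalized PSD
    sync_vector: SyncVector
    events: dict                    # channel -> list[SWDEvent]
    prevalence: dict                # channel -> fraction
    cycle_features: list = field(default_factory=list)
    excluded_channels: tuple = ()


def run_session(
    cfg: RunConfig,
    rec: Recording,
    montage: Montage | None = None,
    feature_intervals: list[tuple[str, float, float]] | None = None,
) -> SessionReport:
    """Analyze one recording session.

    `feature_intervals` are (channel, start_s, end_s) marked segments —
    manual, auto, or ground-truth — on which morphology features are
    extracted; the detector's output is deliberately not auto-fed to the
    feature stage.
    """
    montage = montage or Montage()
    for role in montage.roles:
        if role not in rec.channels:
            from .errors import IncompleteMontageError

            raise IncompleteMontageError(role)

    excluded = []
    if cfg.rail_uV is not None:
        for role in montage.roles:
            _, ok = screen_saturation(rec.get(role), cfg.rail_uV, cfg.detector)
            if not ok:
                excluded.append(role)
    rec = Recording(
        channels=rec.channels,
        fs=rec.fs,
        meta={**rec.meta, "excluded_channels": tuple(excluded)},
    )

    psds = {}
    for role in montage.roles:
        if role in excluded:
            continue
        psd = compute_psd(rms_normalize(rec.get(role)), window_s=cfg.window_s)
        psds[role] = normalize_psd(interpolate_line_region(psd))

    sync = session_sync_vector(rec, montage)
    sync.meta.update(
        {k: v for k, v in (("group", cfg.group), ("treatment", cfg.treatment),
                           ("session", cfg.session_id)) if v is not None}
    )

    events, prev = {}, {}
    for ch in cfg.swd_channels:
        if ch in excluded:
            continue
        evs = detect_swd(rec.get(ch), cfg.detector, rail=cfg.rail_uV)
        events[ch] = evs
        prev[ch] = prevalence(evs, rec.duration_s)

    cycle_feats = []
    for ch, start_s, end_s in feature_intervals or []:
        sig = rec.get(ch)
        i0, i1 = int(round(start_s * rec.fs)), int(round(end_s * rec.fs))
        seg = Signal(sig.data[i0:i1], rec.fs, channel=ch)
        seg = preprocess(seg, cfg.features)
        spikes = find_spikes(seg, cfg.features)
        cycle_feats.extend(extract_features(seg, spikes, cfg.features))

    meta = {
        "group": cfg.group,
        "treatment": cfg.treatment,
        "session_id": cfg.session_id,
        **rec.meta,
    }
    return SessionReport(
        config_hash=cfg.config_hash(),
        meta=meta,
        psd=psds,
        sync_vector=sync,
        events=events,
        prevalence=prev,
        cycle_features=cycle_feats,
        excluded_channels=tuple(excluded),
    )


@dataclass
class StudyReport:
    """Study-level aggregation across groups."""

    feature_ks: dict                 # feature -> {(gA, gB): (D, p)}
    distance_report: object
    embedding: object
    behavior_correlations: dict      # band -> (r, p)
    group_prevalence: dict           # group -> mean prevalence


def run_study(
    session_reports: dict[str, list[SessionReport]],
    reference_group: str,
    pca_k: int = 6,
    behavior_scores: dict[str, list] | None = None,
    feature_subsample_n: int | None = None,
    seed: int = 0,
) -> StudyReport:
    """Aggregate per-session reports into group-level comparisons.

    `session_reports` maps group name -> session reports (>= 2 groups with
    >= 2 sessions each). `behavior_scores` optionally maps group -> per-
    session entrance counts aligned with the reports, enabling the
    synchrony-behavior correlation.
    """
    groups = sorted(session_reports)
    if len(groups) < 2:
        raise ConfigError("a study needs at least 2 groups")
    for g, reps in session_reports.items():
        if len(reps) < 2:
            raise DataError(f"group {g!r} has fewer than 2 sessions")
    if reference_group not in groups:
        raise ConfigError(f"reference group {reference_group!r} not in study")

    # ---- feature distributions + KS
    feature_names = (
        "spike_duration_ms",
        "spike_to_valley_uV",
        "inter_spike_ms",
        "wave_duration_ms",
        "wave_energy",
    )
    feature_ks: dict = {}
    pooled = {
        g: {
            name: np.array(
                [
                    getattr(cf, name)
                    for rep in reps
                    for cf in rep.cycle_features
                    if getattr(cf, name) is not None
                ]
            )
            for name in feature_names
        }
        for g, reps in session_reports.items()
    }
    for name in feature_names:
        for ga, gb in [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]:
            a, b = pooled[ga][name], pooled[gb][name]
            if a.size and b.size:
                feature_ks.setdefault(name, {})[(ga, gb)] = ks_compare(a, b)

    # ---- synchrony pattern analysis
    vectors = [rep.sync_vector for g in groups for rep in session_reports[g]]
    for g in groups:
        for rep in session_reports[g]:
            rep.sync_vector.meta.setdefault("group", g)
    dataset = PatternDataset.from_sync_vectors(vectors)
    embedding = fit_pca(dataset)
    k = min(pca_k, embedding.n_components)
    pts = project(embedding, k)
    distance_report = group_distances(pts, dataset.labels, reference_group, seed=seed)

    # ---- behavior correlations (per band, using inter-hippocampal PLV)
    correlations: dict = {}
    if behavior_scores:
        for band in SyncVector.BAND_ORDER:
            plvs, ent = [], []
            for g in groups:
                scores = behavior_scores.get(g)
                if scores is None:
                    continue
                for rep, score in zip(session_reports[g], scores):
                    plvs.append(rep.sync_vector.values[("LHC-RHC", band)])
                    ent.append(score)
            if len(plvs) >= 3 and np.std(plvs) > 0 and np.std(ent) > 0:
                correlations[band] = bhv.correlate_sync_behavior(plvs, ent)

    group_prev = {
        g: float(
            np.mean([v for rep in reps for v in rep.prevalence.values()] or [0.0])
        )
        for g, reps in session_reports.items()
    }
    return StudyReport(
        feature_ks=feature_ks,
        distance_report=distance_report,
        embedding=embedding,
        behavior_correlations=correlations,
        group_prevalence=group_prev,
    )
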