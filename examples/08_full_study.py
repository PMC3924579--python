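"""End-to-end study: generate two treatment groups, analyze, compare.

Each group's sessions run through screening, spectra, spike-wave detection,
feature extraction on ground-truth intervals, and the 32-D synchrony vector;
the study report aggregates KS feature comparisons, the PCA distance table,
and synchrony-behavior correlations.
"""
from lfpsync.pipeline import RunConfig, run_session, run_study
from lfpsync.synth import CouplingSpec, GenConfig, SWDSpec, gen_session


def make_group(name, kappa, swd_amp, seeds):
    reports = []
    for s in seeds:
        cfg = GenConfig(fs=2000.0, duration_s=30.0, seed=s)
        rec, truth = gen_session(
            cfg,
            couplings={("LHC", "RHC"): CouplingSpec(10.0, 10.0, kappa=kappa)},
            swd_spec=SWDSpec(cycle_freq=6.0, spike_amp=swd_amp),
            swd_schedule=[(5.0, 2.0), (20.0, 2.0)],
        )
        rc = RunConfig(seed=s, group=name, session_id=f"{name}-{s}")
        intervals = [("EEG_FL", a, b) for a, b in truth.event_intervals]
        reports.append(run_session(rc, rec, feature_intervals=intervals))
    return reports


# control: strong theta coupling, modest spike-wave events
# lesion: weak coupling, larger events, worse avoidance
reports = {
    "control": make_group("control", kappa=4.0, swd_amp=600.0, seeds=[1, 2, 3, 4]),
    "lesion": make_group("lesion", kappa=0.5, swd_amp=900.0, seeds=[11, 12, 13, 14]),
}
behavior = {"control": [3, 5, 4, 6], "lesion": [15, 12, 18, 14]}

study = run_study(reports, reference_group="control", behavior_scores=behavior)

print(f"mean SWD prevalence by group: "
      f"{ {g: round(v, 3) for g, v in study.group_prevalence.items()} }")
for feat, table in study.feature_ks.items():
    (d, p) = table[("control", "lesion")]
    print(f"KS {feat:<22s} D = {d:.2f}  p = {p:.3g}")
r, p = study.behavior_correlations["theta"]
print(f"theta PLV vs entrances: r = {r:.2f}, p = {p:.4f}")
print(study.distance_report.table[["group", "cross_mean", "p", "significant"]]
      .to_string(index=False))
# spike-to-valley distributions separate (amplitudes differ), the synchrony
# pattern of the lesion group sits away from control, and low theta locking
# predicts many entrances
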