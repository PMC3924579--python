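"""Generate a full 8-channel synthetic session and inspect its ground truth.

The session carries 1/f background on every electrode, an inter-hippocampal
theta coupling, two scheduled 6-Hz spike-wave trains on the epidural screws,
and 60-Hz line contamination.
"""
from lfpsync.io import write_ground_truth_json, write_recording_csv
from lfpsync.synth import CouplingSpec, GenConfig, SWDSpec, gen_session

cfg = GenConfig(fs=2000.0, duration_s=60.0, seed=1, background_rms=50.0, line_amp=15.0)
rec, truth = gen_session(
    cfg,
    couplings={("LHC", "RHC"): CouplingSpec(band_center=10.0, band_width=10.0, kappa=2.0)},
    swd_spec=SWDSpec(cycle_freq=6.0, spike_amp=700.0, wave_amp=100.0),
    swd_schedule=[(15.0, 2.0), (40.0, 2.5)],
    meta={"group": "demo", "session_id": "demo-0"},
)

print(f"channels: {sorted(rec.channels)}")
print(f"duration: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print(f"scheduled spike-wave intervals: {truth.event_intervals}")
print(f"expected inter-hippocampal theta PLV: {truth.expected_plv[('LHC', 'RHC')]:.3f}")
print(f"ground-truth prevalence: {truth.extras['prevalence']:.3f}")
# the two trains occupy 4.5 s of the 60-s session, hence prevalence 0.075

write_recording_csv(rec, "scratch_session.csv")
write_ground_truth_json(truth, "scratch_session_truth.json")
print("wrote scratch_session.csv and scratch_session_truth.json")
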