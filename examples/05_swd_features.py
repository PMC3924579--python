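"""Morphology of spike-wave cycles and a two-group feature comparison.

Features per cycle: spike duration, spike-to-valley voltage, inter-spike
time, wave duration, wave energy. Group distributions are built from an
equal subsample per animal and compared with the two-sample KS test.
"""
import numpy as np

from lfpsync.features import (
    build_distribution,
    extract_features,
    find_spikes,
    ks_compare,
    preprocess,
)
from lfpsync.synth import GenConfig, SWDSpec, gen_swd_train


def cycle_features(spike_amp, seed):
    cfg = GenConfig(fs=2000.0, seed=seed)
    spec = SWDSpec(cycle_freq=6.0, n_cycles=20, spike_amp=spike_amp,
                   wave_amp=100.0, jitter_ms=2.0)
    sig, _ = gen_swd_train(cfg, spec)
    seg = preprocess(sig)
    return extract_features(seg, find_spikes(seg))


feats = cycle_features(800.0, seed=5)
isis = [f.inter_spike_ms for f in feats if f.inter_spike_ms is not None]
print(f"6-Hz train: mean inter-spike time {np.mean(isis):.1f} ms (1000/6 = 166.7)")
print(f"mean spike-to-valley {np.mean([f.spike_to_valley_uV for f in feats]):.0f} uV")

# two synthetic 'groups' differing in spike amplitude, 3 animals each
group_a = {f"a{k}": [f.spike_to_valley_uV for f in cycle_features(700.0, seed=10 + k)]
           for k in range(3)}
group_b = {f"b{k}": [f.spike_to_valley_uV for f in cycle_features(1000.0, seed=20 + k)]
           for k in range(3)}
da = build_distribution(group_a, subsample_n=10, seed=0)
db = build_distribution(group_b, subsample_n=10, seed=0)
d, p = ks_compare(da.samples, db.samples)
print(f"KS comparison of spike-to-valley distributions: D = {d:.2f}, p = {p:.2e}")
# the 300-uV amplitude difference separates the distributions decisively
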