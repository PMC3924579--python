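# lfpsync

Neural-synchrony analysis of rodent LFP/EEG recordings: automatic spike-wave
discharge (SWD) detection and morphology profiling, band-wise phase locking
between brain regions, multidimensional synchrony-pattern comparison across
treatment groups, and active place-avoidance scoring — together with a
synthetic-data generator that emulates the statistical structure of such
recordings with known ground truth.

## The problem

In rodent models of neurodevelopmental disorders, cognitive impairment is
hypothesized to arise from *discoordination*: individually normal neural
activities that are abnormally synchronized between regions. Testing that
hypothesis requires quantifying synchrony from multi-site field-potential
recordings (dorsal hippocampus, medial prefrontal cortex, epidural screws;
1–500 Hz band-passed, 2000 Hz sampling), detecting episodes of pathological
hypersynchrony (SWD-like events during stillness), and relating both to
behavior on the rotating-arena place-avoidance task. This package implements
that analysis chain as a tested library, driven either by recorded data
(long-form CSV, or EDF via `mne`) or by its own generator.

## The core quantities

**Phase-locking value.** For two channels with instantaneous phases
φ₁(n), φ₂(n) extracted by zero-phase FIR band-pass filtering (fixed 5-Hz
bands tiling 0–100 Hz) followed by the Hilbert transform,

    PLV = (1/N) | Σₙ exp(i·[φ₁(n) − φ₂(n)]) |

is 1 for perfect locking and tends to 0 for independent phases. Band values
(theta 5–15, beta 20–30, slow gamma 30–55, fast gamma 65–100 Hz) average the
5-Hz sub-bands tiling the band. A session is summarized by the 32-vector of
PLVs over 8 electrode pairs × 4 bands; groups of sessions are compared by
PCA, 6-D Euclidean distances, and permutation-calibrated t statistics with
Bonferroni adjustment.

The synthetic coupled pairs draw their phase difference from a von Mises(μ, κ)
distribution, so the population PLV has the closed form **I₁(κ)/I₀(κ)**
(ratio of modified Bessel functions) — an exact target for validation.

**SWD detection.** Continuous wavelet transform (Morlet, scales 5–50 step 5,
pseudo-frequencies ≈16–160 Hz), 50-ms sliding variance per scale summed into
one profile, robust threshold (median + k·MAD), gap filling (<0.75 s),
minimum duration (1 s), and a periodicity test (≥50% of inter-spike intervals
at 2–10 Hz). Prevalence is detected event time over analyzed time.

**Morphology.** Per spike-wave cycle: spike duration (width at the
higher-voltage flanking minimum), spike-to-valley voltage, inter-spike time
(within 5–13 Hz spike sequences), wave duration, and wave energy; group
distributions use an equal-size subsample per animal and are compared by the
two-sample Kolmogorov–Smirnov test.

**Behavior.** Entrances into a 60° shock sector fixed in room coordinates
(debounced against tracker jitter) and average speed; Pearson correlation of
per-animal synchrony against entrance counts.

## Worked example

```python
from lfpsync.phase import band_plv
from lfpsync.spectral import CANONICAL_BANDS
from lfpsync.synth import CouplingSpec, GenConfig, expected_plv, gen_coupled_pair

theta = next(b for b in CANONICAL_BANDS if b.name == "theta")
cfg = GenConfig(fs=2000.0, duration_s=60.0, seed=3)
s1, s2, _ = gen_coupled_pair(cfg, CouplingSpec(band_center=10.0, band_width=10.0, kappa=2.0))
print(expected_plv(2.0), band_plv(s1, s2, theta))
```

prints `0.6977746579640082 0.7095...`: the measured theta-band PLV of a 60-s
pair coupled at κ = 2 lands on the Bessel-ratio target 0.698 to within the
estimator's sampling error. Detection, run on a 120-s session with three
scheduled 6-Hz trains (`examples/04_swd_detection.py`), prints

```
scheduled trains: [(20.0, 2.0), (55.0, 2.5), (90.0, 1.8)]
detected events:
  [  19.96,   21.98] s  with 12 spikes
  [  54.95,   57.48] s  with 15 spikes
  [  89.96,   91.83] s  with 11 spikes
prevalence: 0.0535 of analyzed time (ground truth 0.0528)
```

— every scheduled train recovered with tight boundaries and ~12 spikes per
2-s train, as a 6-Hz rhythm implies. The `examples/` directory has one short
script per capability (sessions, spectra, phase locking, detection, features,
patterns, behavior, full study).

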