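# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `lfpsync`, in the order data flows through the package.

## Synthetic recordings

The generator produces every input the analysis consumes, with ground truth
attached. It emulates an 8-site rodent montage (left/right dorsal
hippocampus, left/right mPFC, four epidural screws) digitized at 2000 Hz
after a 1–500 Hz band-pass.

**Background.** White Gaussian noise shaped in the frequency domain
(amplitude ∝ f^(−exponent/2), flattened below 1 Hz to mimic the hardware
DC-removal corner) and rescaled to an exact target RMS. Defaults: exponent 1,
RMS 50 µV. The emulated recordings published no amplitude calibration, so
these are free parameters set once at values typical of rodent LFP; nothing
downstream assumes them.

**Coupled oscillations.** A pair of channels shares one carrier per 5-Hz
sub-band tiling the coupling band; channel 2's carrier is offset by a phase
process θ(t) drawn from von Mises(μ, κ), so the band-limited phase difference
has a known distribution and the population PLV is I₁(κ)/I₀(κ). Two details
matter for accuracy:

- θ(t) is *block-resampled*: constant over 2-s blocks with 0.2-s
  raised-cosine crossfades. Blocks must be long relative to the ≈0.2-s
  response of the 5-Hz analysis filters — with short blocks the filter
  averages neighboring offsets and inflates the measured PLV (at 0.5-s blocks
  the κ=2 estimate rises from 0.70 to 0.74).
- block values are *stratified* draws (one quantile per equal-probability
  stratum, permuted in time): the marginal stays von Mises while the
  time-averaged phasor converges far faster than i.i.d. sampling, so a
  single 60-s realization estimates the population PLV to ±0.01 instead of
  ±0.07. Without stratification the PLV-recovery contract would need
  many-minute realizations.

**Spike-wave trains.** Each cycle of a train at `cycle_freq` (default 6 Hz)
is: a raised-cosine spike (height `spike_amp`, base width `spike_width_ms`),
flanked by two narrow raised-cosine valleys (the one after the spike reaching
−`wave_amp`, the one before it shallower by a fixed fraction 0.6), with a
positive half-sine wave hump filling the rest of the cycle. The asymmetric
valleys make the "width at the higher flanking minimum" measurement
transversal rather than tangent, which keeps the spike-duration feature
stable under the 100-Hz low-pass. Spike-to-valley voltage is exactly
`spike_amp + wave_amp` by construction. Per-cycle ground-truth features are
derived analytically from the layout; wave energy is read off the clean
waveform between the flanking valleys.

**Sessions** add scheduled trains (non-overlapping intervals validated), the
configured couplings, optional 60-Hz line noise, and optional hard-clipped
saturation intervals at a configurable rail, to all or selected channels. All
generators are deterministic given (config, seed); sub-streams are spawned
in a fixed order so adding one component never perturbs another.

**Trajectories.** Correlated random walk at 8 cm/s reflected inside the
41-cm arena radius; the `avoider` policy deterministically steers around the
room-frame shock sector (entrance count 0 by construction); `stationary`
sits still. The arena rotation period defaults to 60 s and is a free
parameter.

What the generator does *not* emulate: biophysical neuron or network
dynamics, state transitions (sleep/wake, movement artifacts beyond hard
clipping), drug effects on waveforms, electrode drift, or realistic
cross-frequency structure. Passing tests therefore demonstrate that the
*analysis* recovers what it claims from data with the stated statistical
structure — not that the generator reproduces in-vivo biology.

## Spectra

Signals are divided by their RMS (removing electrode-specific gain), then
Welch-averaged over 5-s non-overlapping Hamming windows with per-window mean
removal (overlap and detrending are conventions; the windowing scheme itself
is fixed). A trailing partial window is discarded. The 58–62 Hz region is
replaced by linear interpolation between the boundary bins before the
spectrum is normalized to unit sum. Band edges are half-open [lo, hi) so
shared edges are never double-counted; delta (0–3 Hz) is computed but flagged
attenuated (hardware DC-removal) and never enters synchrony vectors.

## Phase locking

FIR band-pass design: Hamming windowed-sinc, order 3·fs/lo rounded to even
and capped at a third of the signal, applied forward-backward (zero net
phase), followed by the analytic-signal angle. One filter length at each end
is excluded from every PLV sum — forward-backward filtering and the Hilbert
transform are unreliable there. The filter bank has fixed 5-Hz bands up to
100 Hz; analysis bands average the PLVs of their tiling sub-bands (theta:
5–10, 10–15; beta: 20–25, 25–30; slow gamma: five bands from 30; fast gamma:
seven bands from 65). The PLV is computed over the whole trial in a single
sum, not windowed-and-averaged. An optional sample mask can restrict the sum
(e.g., to stillness epochs); the default uses all samples.

## Spike-wave detection

The classifier decimates the channel to a 1000-Hz working rate, where the
Morlet wavelet (center frequency 0.8125 Hz·fs) maps scales 5–50 (step 5) to
pseudo-frequencies 162.5 down to 16.25 Hz — the 16–160 Hz range that
brackets spike components while excluding the theta band itself. Per scale, a
50-ms sliding variance; summed across scales; 50-ms moving-average smoothing;
then the profile is interpolated back to the source timebase.

Candidates are maximal runs above T = median + k·MAD over analyzed (non-
excluded) time. The threshold multiplier is the classifier's one genuinely
free parameter; `tune_threshold` sweeps it against synthetic ground truth
(score: event sensitivity minus false-detection time fraction). On the
benchmark conditions (300-s sessions, ≥600-µV trains over 50-µV 1/f
background) sensitivity is 1.0 for every k in 6–12 while the false-alarm
prevalence on event-free sessions falls from 0.0035 (k=6) to 0.0004 (k=8);
the default is k=8. Robust statistics are used precisely so the events
themselves do not drag the threshold.

Rules follow in order: gaps < 0.75 s filled, segments < 1 s removed, then the
periodicity test — local maxima of the smoothed profile (prominence > 5% of
T, preventing ISI fragmentation) define spike times, and a segment survives
iff ≥50% of inter-spike intervals correspond to 2–10 Hz (boundary
inclusive); segments with fewer than three maxima cannot form ISI statistics
and are rejected. Saturation screening runs first when a rail is given: runs
at |x| ≥ rail shorter than 50 ms are tolerated (large spikes may clip
briefly), longer runs are excluded from analyzed time, and a channel whose
excluded fraction exceeds 5% (configurable) is dropped.

## Morphology features

Marked segments (manual, ground-truth, or — deliberately not by default —
detector output) are low-pass filtered at 100 Hz (zero-phase Butterworth).
Local extrema use strict one-sample inequalities (plateaus take the center
sample); where no interior minimum precedes the first spike the segment
endpoint stands in. A spike must exceed the *higher*-voltage flanking minimum
by ≥400 µV and be ≥50 ms wide at that minimum's level. The printed 50-ms
rule is a *minimum*; because an upper bound is the more common convention for
sharp transients, a `width_max_ms` knob exists but defaults to unbounded so
the stated rule is what runs. Wave energy is the raw sum of squares over the
wave-duration samples (per-sample, not per-second — documented because the
convention is ambiguous). Inter-spike times are only reported inside 5–13 Hz
spike sequences. Group distributions subsample an equal number of events per
animal (without replacement, seeded; an animal with too few events raises an
error rather than silently down-weighting) and are compared with the
two-sample KS test.

## Synchrony patterns

PCA is computed on the covariance of the raw 32-D PLV vectors (no column
standardization — all features share the [0,1] PLV scale), centered, with a
deterministic sign convention (largest-magnitude loading positive). Sessions
are projected onto the first six components (which explain >90% of variance
for group-structured data of the kind analyzed here) and group structure is
quantified by mean pairwise 6-D Euclidean distances: within each group, and
from each group to a reference group.

The distance comparison uses the two-sample t statistic on the pair
distances, but its p-value is calibrated by permutation of the *point*
labels (999 draws, seeded). The naive t-test treats the n(n−1)/2 pair
distances as independent; they share points, and at 8 points per group the
test is anti-conservative by roughly a factor of two, which measurably
inflates false group-separation flags (12–24% of identical-group studies at
nominal α=0.05). The permutation null respects the dependence exactly. The
naive t-test p is still reported alongside (`p_ttest`), with pair counts, as
is the alternative contrast against the group's own within-distances; the
Bonferroni divisor is the number of (group, reference) comparisons in the
emitted table, and significance flags come from the permutation p.

## Behavior

Entrances are outside→inside transitions of the position's room-frame angle
into the sector; an entrance episode only closes after 0.5 s (configurable)
of continuous time outside, so tracker jitter at the sector edge cannot
split one visit into several. A trial that *starts* inside the sector counts
that as an entrance. Average speed is path length over elapsed valid time,
skipping invalid samples and duplicated timestamps. Scoring is room-frame
only; the arena-frame angle column exists for plotting. Synchrony–behavior
association is the Pearson correlation of per-animal band PLV against total
entrances.

## Pipeline and I/O

`run_session` chains screening → spectra → synchrony vector → detection →
(optional) features on supplied intervals; `run_study` aggregates sessions
into per-feature KS comparisons, the PCA/distance table, and behavior
correlations. Reports carry a SHA-256 hash of their configuration, and all
randomness flows from config seeds, so identical config + seed reproduces a
report exactly. Recordings travel as long-form CSV (t, channel, value µV);
EDF files can be read through `mne` when installed, but no EDF writer ships —
plain-text formats keep every artifact diffable and dependency-light.
Trajectories, events, features, sync vectors, PSDs, and distance tables are
CSV; ground truth is JSON.

## Problem sizes used in the shipped checks

PLV-recovery checks use single 60-s pairs per κ (estimator error ±0.01 with
stratified blocks); the detector benchmark uses 50 sessions of 300 s with
3–6 scheduled trains each plus 10 event-free sessions; the morphology grid
spans cycle frequency 4–8 Hz × spike width 50–80 ms × amplitude 500–1200 µV
with 15 cycles per cell; type-I control uses 50 replicates of two-group,
8-sessions-per-group studies. These sizes make the whole validation run in
about a minute on one CPU while keeping every estimate's sampling error well
inside the asserted tolerance.

## Known limitations

- The generator's amplitude scales and arena rotation speed are conventions,
  not calibrated to any particular laboratory's recordings.
- The detector's scale set assumes spike energy in the 16–160 Hz range;
  much slower or faster discharge morphologies would need a different scale
  set (configurable).
- PLV is an undirected, within-band measure: no cross-frequency coupling,
  spectral coherence, or directed (Granger-type) inference.
- The pairwise-distance report quantifies separation, not classification;
  no clustering or classifiers are built on the embedding.
- Feature extraction presumes the classic spike-wave morphology; events
  without a clear wave component yield sequence-level features flagged
  absent rather than imputed.
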