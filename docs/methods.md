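# Methods

This note records the models, conventions and numerical choices behind
`neodev`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## ΔF/F normalization

Two baselining conventions are implemented because they serve different
recording regimes.  `dff_mean_baseline` computes (F − F̄)/F̄ with F̄ the
per-cell mean over a configurable window; it is appropriate for sensor
traces and adult recordings where resting fluorescence is stationary.
`dff_percentile` uses the per-cell first percentile of the whole recording,
which tracks the floor of the fluorescence distribution and is robust to
developmental drift in resting calcium.  Percentiles use linear
interpolation between order statistics (the numpy default), recorded in the
output provenance; at 36,000-frame recordings the convention makes no
practical difference but it is pinned for reproducibility.  Both variants
are invariant under positive rescaling of raw fluorescence and map constant
traces to zero, which the test suite asserts as properties.

Savitzky–Golay smoothing uses mirror padding at the trace edges.  The
filter is a local least-squares polynomial fit; mirror padding avoids the
boundary transients that zero- or constant-padding produce on short sensor
traces.  Ratiometric correction defaults to subtracting the control
channel's ΔF/F (appropriate for removing hemodynamic fractional changes
from an activity-independent co-expressed fluorophore); a division mode of
the (1 + ΔF/F) ratios is exposed for pipelines that prefer raw ratios.  The
16×16 subregion grid assigns remainder pixels to the last tile in each
direction when the image size is not divisible.

## Population event detection

Detection operates on the unweighted population-mean ΔF/F trace.  The
threshold is the mean of that trace over the entire recording.  The
reference mean could also be read per 6 s bin; both are implemented
(`reference="recording"` default, `"bin"` optional) and the recording-wide
reading is the default because a per-bin mean makes the threshold depend on
the event itself in mostly-quiet bins.  Within each 6 s bin the maximum
above threshold seeds a candidate peak; the peak then migrates to the
largest maximum in a three-bin window centred on its current bin until
stable.  The migration strictly increases the peak value, so it terminates;
candidate peaks from different seed bins that resolve to the same
super-threshold interval are merged, keeping the largest amplitude.  Event
extent is the maximal contiguous interval around the peak where the
population mean stays strictly above threshold, reported half-open in
frames (0-based throughout the package).

Event amplitude is defined as the population-mean ΔF/F at the peak frame.
A per-participant mean would be an alternative reading; the population-mean
value was chosen because it is the quantity the detector thresholds, so
amplitude and detectability are on one scale.  Participation uses strict
`>` (a constant cell never participates), and the L-class bounds are
inclusive on both sides: participation > 0.80 → H, 0.20 ≤ p ≤ 0.80 → L,
p < 0.20 → unclassified.  Both strictness conventions are configuration
parameters so the opposite reading is testable.  Events whose extent
touches a recording edge are flagged truncated and excluded from duration
summaries (their duration is censored) but retained in counts and
amplitude summaries.

An exhaustive pure-Python reference detector (loop-based enumeration of
every super-threshold interval) lives in the test suite and in
`scripts/acceptance.py`; the vectorised implementation must agree with it
exactly on randomized small recordings.

## Responsiveness testing

For each cell and stimulus type, the paired samples are per-trial means of
the 1 s windows before and after onset.  Pairing is per-trial (not
trial-averaged) because the paired tests require paired observations; this
is the stricter reading of the procedure.  Shapiro–Wilk on the paired
differences at the analysis alpha selects a paired t-test (normal) or
Wilcoxon signed-rank test.  Benjamini–Hochberg correction is applied across
all cells within one recording and stimulus type — the natural family for a
per-recording recruitment fraction.  Cells with exactly constant
differences (possible in noiseless synthetic data) are assigned p = 1 when
the difference is zero, since neither test is defined there.

## Sleep scoring

The wake / quiet-sleep / active-sleep criteria are qualitative in origin
(continuous movement, immobility, isolated sharp twitches); the package
makes them operational with explicit thresholds, all configuration-exposed
and reported in output metadata: displacement is median-filtered over
0.2 s, thresholded at `move_threshold` (default 1.0 displacement units per
frame), suprathreshold runs longer than `max_twitch_s` = 0.5 s count as
movement and shorter ones as twitches, movement runs separated by less than
`min_still_s` = 2 s merge into one wake bout, twitches within
`min_gap_s` = 1 s of a wake bout are treated as movement continuation, and
sleep frames within `as_halo_s` = 5 s of a surviving twitch are labelled
active sleep.  The halo converts point-like twitches into contiguous AS
bouts; 5 s was chosen so that twitch trains at a fraction of a hertz —
typical of neonatal active sleep — fuse into one bout while isolated
twitches during otherwise long immobility do not relabel whole quiet-sleep
periods.  Scoring is invariant to uniform spatial rescaling of the
coordinates when the threshold is rescaled identically.  Missing or
low-confidence pose points are linearly interpolated; gaps longer than
0.5 s are interpolated too but logged, leaving the unscorable-interval
decision to the experimenter.

## Decoding and permutation calibration

Condition decoding uses scikit-learn logistic regression with an L2
penalty.  The phrase "regularisation strength 0.001" is read in the
scikit-learn convention, i.e. `C = 0.001` (strong regularisation); a
configuration flag switches to the penalty-weight reading (`C = 1000`) for
pipelines that meant the opposite.  The solver is lbfgs with tolerance
1e−6 and 5,000 iterations: unlike liblinear it does not penalise the
intercept, which matters at strong regularisation (a penalised intercept
pulls the decision boundary toward the origin and breaks even perfectly
separated problems).  Multi-class problems use an explicit one-vs-rest
wrapper.

The train/test split assigns whole animals, stratified by class, with 60%
of each class's animals in training (at least one on each side); an
assertion verifies on every run that no animal contributes trials to both
sides.  Permutation significance shuffles the animal→condition assignment
(all trials of an animal move together), redraws the split, refits every
per-bin classifier, and takes the max-over-bins test accuracy; the
threshold is the 95th percentile of the null by default (the level is a
parameter).  Shuffling at the animal level preserves within-animal trial
correlations, matching the subject-wise split.

A granularity property of this design is worth knowing: the null
distribution is supported on test accuracies achievable by relabelling
whole animals, so with `t` test animals the probability that a permutation
agrees with the true labels on all of them is on the order of 2⁻ᵗ (times a
combinatorial factor).  With 8 animals and a 60/40 split, t = 4 and that
mass is ≈6% > 5%, so when a planted effect saturates accuracy the 95%
threshold saturates too and the accuracy-minus-threshold margin cannot be
positive.  The validation therefore checks null calibration at 8 animals
(where it is exact by construction) and margin positivity at 16 animals
(t = 6, alignment mass ≈3%), comparable to the per-comparison group sizes
such experiments use in practice.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the imaging physics.  Traces follow
`raw = F0 · (1 + drive + shared + noise)` with per-cell baselines F0 ~
N(100, 20) clipped at 20 (arbitrary units), a difference-of-exponentials
indicator kernel (rise 0.18 s, decay 1.6 s — slow-indicator-like), white
per-cell noise (SD 0.05 in fractional units) and a shared Gaussian field
with exponential spatial covariance (SD 0.03, length 100 µm).  The shared
field is generated by an exact Cholesky factorisation of the covariance
over cell positions; at the cell counts of these recordings (hundreds) this
is cheap and gives exactly the monotone distance–correlation decay the
tests assert, which a low-rank approximation only approaches.

Planted population events occupy a jittered lattice at 1.5 events/min
(10-min recordings → ~15 events, within the range reported for neonatal
cortex), with participation drawn from 0.85–1.0 for H-events and 0.30–0.70
for L-events (half each), amplitude 0.8–1.2 peak ΔF/F, and drive duration
1–4 s, which after kernel convolution yields events of roughly 3–10 s —
inside the 2–20 s range such events span in vivo.  Each planted drive is
normalised so its convolved peak equals the configured amplitude,
independent of duration.  Ground-truth event class uses the same
thresholds as the detector applied to the planted participant fraction, so
recovery tests are well-posed.  Movement simulation produces suprathreshold
random-walk steps in wake, subthreshold jitter in sleep, and 0.3 s twitches
at 0.3 Hz on a jittered lattice during active sleep (isolated by ≥2 s by
construction).  Each sub-generator (placement, events, noise, stimuli, red
channel, movement, serotonin) draws from its own stream derived from the
master seed, so enlarging one component does not perturb the others.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: motion artefacts and registration error,
neuropil contamination, indicator nonlinearity and saturation, sensor
bleaching, non-stationary baselines within a session, cell-density effects
on segmentation, and temporally structured (oscillatory) shared noise.
Validation here shows the *algorithms* are correct and calibrated under
the stated statistical model, not that the model captures every failure
mode of real recordings.

## PSC feature extraction

Onset is the first sample in the 0–50 ms detection window whose absolute
deviation from the baseline mean exceeds 3 baseline SDs sustained for
0.5 ms; sweeps without such a crossing are failures.  Charge integrates the
baseline-subtracted current from onset until the deviation stays within
1 SD for 5 ms, capped at 200 ms.  Under white noise the sustained-return
condition essentially never triggers before the signal has genuinely
decayed (0.68¹⁰⁰ per window), so integration runs to the cap and the charge
estimate is unbiased; on noiseless data it stops exactly at the return to
baseline.  Stopping at the *first* unsmoothed sample within 1 SD would
instead truncate the decay tail and bias charge low by roughly 1/SNR.
Polarity (inward/outward) is reported as a sign flag alongside magnitude
features so IPSCs recorded at the glutamate reversal and EPSCs near resting
potential are handled uniformly.

## Pipeline determinism

All stages are deterministic given the master seed; per-stage seeds are
derived as the low 31 bits of SHA-256 of `"{seed}:{stage}"`.  HDF5 outputs
are written with object-time tracking disabled so reruns are byte-identical
and the manifest's SHA-256 hashes can assert bit-level reproducibility.

## Problem sizes in the validation suite

The acceptance checks run at desk scale: 100 randomized small recordings
for oracle equivalence; 50 ten-minute 200-cell recordings for event
recovery; 200 (tests) / 120 (acceptance script) null recordings of 100
cells × 10 trials for responsiveness calibration plus 10 recordings with
planted responders at a 3×noise effect; 200 / 120 replicate decoding
experiments with 500-permutation thresholds (scaled from the 7000 used on
real data, which would be numerically identical but slower) plus 20 seeds
with a planted effect; 50 seeded movement simulations; and a 100-cell
two-minute pipeline run for determinism.  These sizes were chosen so the
whole suite completes in minutes while leaving the binomial confidence
intervals of the calibration checks meaningful.
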