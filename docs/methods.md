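# Methods

`premacc` simulates and analyses two-alternative perceptual decisions in
which the informative sensory change (a contrast step between overlaid
gratings, or coherent-motion onset in a dot field) arrives only after an
unpredictable foreperiod of 800, 1200 or 1600 ms. Its purpose is to make
the idea of *premature evidence accumulation* — integration that starts at
an endogenous time calibrated to recently experienced foreperiods, often
before any informative evidence exists — concrete, testable and
recoverable by a standard EEG analysis pipeline.

## Task model

`TaskConfig` holds the stimulus constants: 100 frames/s presentation,
foreperiods {800, 1200, 1600} ms balanced within blocks of three and
pseudorandomised, a 2000 ms evidence period and response deadline, and a
150 ms premature-response cutoff. The gratings task flickers the
left-tilted grating at 20 Hz and the right-tilted one at 25 Hz, both at
50% contrast during the foreperiod; at the change the target steps up by
the per-subject contrast delta (default 0.055, the titrated group mean)
while the other steps down by the same amount, so the contrasts always sum
to 1. The dot task shows 100 dots in a 4° aperture; during the foreperiod
every dot is repositioned uniformly at random each frame, and after onset
each dot is independently a signal dot with probability equal to the
coherence (default 0.0742, the titrated group mean), displaced at the dot
speed (default 5 °/s — a conventional value, not a task constant) with
chord-wrapping at the aperture edge. Correct responses earn 40 points plus
a speed bonus falling linearly from 40 at 150 ms to 0 at the deadline;
everything else earns 0, so 80 points is the per-trial maximum.

The gratings aperture is recorded in config as a 6° disc; the source task
description gives mutually inconsistent inner/outer radii, and since the
gratings are never rasterised here the value is bookkeeping only.
Flicker is modelled as on–off luminance modulation; whether the original
stimulus was on–off or counterphase is not documented, and the choice does
not affect contrast energy. The per-trial counterbalanced phase-reversal
flag is carried through to the forward EEG model (it flips SSVEP polarity),
so phase-locked flicker components cancel in trial averages exactly as the
counterbalanced design intends.

## Motion energy

Dot frames are rasterised to a space–time luminance volume (default
0.05 °/px; analyses in this repository typically use 0.1 °/px, which
preserves every qualitative property at a quarter of the cost) and passed
through the classical opponent-energy construction: quadrature fourth-order
Cauchy profiles along the motion axis (σ_c = 0.35°), a Gaussian across it
(σ_g = 0.05°), and two causal temporal impulse responses
(k t)^n e^{−kt}[1/n! − (kt)²/(n+2)!] with n = 3 (fast) and n = 5 (slow),
k = 60 s⁻¹. These constants are the conventions of the widely used
reference implementations; the source description delegates to them and
states none itself. Writing A, B, C, D for the four separable filter
responses (even/odd × fast/slow), the rightward-minus-leftward energy
collapses to 4(AD − BC), which is what the code evaluates (sign fixed
against the 100%-coherence stimulus; a brute-force convolution oracle in
the tests pins the algebra). Energy units are arbitrary and scale with the
raster resolution.

The pre-evidence motion integral is the cumulative sum of momentary energy
from 100 ms after stimulus onset to the earlier of the foreperiod end and
the response, expressed either in the stimulus frame (+ = rightward) or
the choice frame (+ = favouring the chosen response); its slope is an OLS
line fit to the cumulative trace. Median splits on |slope| break ties by
trial index, with the steep set taking the extra trial at odd counts.

## Generative model

The accumulator is a single signed decision variable (DV) with absorbing
bounds at ±bound — not a race — because the analyses it feeds
(lateralisation, difference signals) are framed in terms of one signed
quantity, and a scalar DV keeps closed-form checks available.
Accumulation starts at

    t_on = onset_base + onset_prev_fp_gain · (prev_FP − 1200 ms) + jitter,

measured from stimulus onset. Sequential calibration acts on the onset
only — not on drift or bound — implementing the interpretation that recent
foreperiods shift *when* accumulation starts rather than how fast it runs.
From t_on the DV integrates drift_gain · evidence(t) dt plus Gaussian
increments of SD noise_sd·√dt; evidence is 0 during the foreperiod
(gratings) or the normalised opponent motion-energy trace of the rendered
frames (dot task, so choices couple to pre-evidence stimulus
fluctuations), and ±1 after the change. First bound crossing (linearly
interpolated between 512 Hz steps, with the first step integrating only
the partial interval after t_on, so noise-free crossing times are exact)
fixes the choice; RT = crossing + motor_delay. No crossing within the
deadline is a miss; a crossing within 150 ms of the change is premature.
An Exp-1-style choice bias is available as a starting-point offset
(start_bias, default 0).

Defaults: onset_base 800 ms, onset_prev_fp_gain 1.0, onset_jitter_sd
50 ms, drift_gain 0.0011 (a.u.·ms)⁻¹, noise_sd 0.025 a.u./√ms, bound 1,
motor_delay 100 ms. With these, accumulation begins roughly 400 ms after
the previous trial's foreperiod would have ended, and the qualitative
behavioural signatures emerge rather than being scripted: premature
responding rises steeply with foreperiod (noise has longer to wander to a
bound), misses concentrate on short-foreperiod trials following long
foreperiods (accumulation starts after the evidence), fast responses on
long foreperiods are at chance, and congruent foreperiod repetitions beat
maximally incongruent transitions on the percentage of trials answered
correctly. The jitter default is deliberately modest: the
threshold-crossing onset estimator (below) carries an intrinsic early bias
of roughly one jitter SD, and 50 ms keeps estimator bias comfortably
inside the ±100 ms recovery band that the package promises.

## Forward EEG model

Each trial yields 128-channel reference-free EEG at 512 Hz on the grid
[−1200, foreperiod + 2600] ms, as a sum of:

- a centro-parietal build-up following |DV| (the centro-parietal
  positivity is positive-going whichever alternative wins; a signed
  component would cancel in trial averages and make pre-evidence build-up
  invisible by construction) on a Gaussian scalp map centred at Pz
  (σ = 4 cm), gain cpp_gain = 8 μV per unit DV, held through the motor
  delay and decaying with τ = 200 ms after the trial;
- 20/25 Hz oscillations on an Oz-centred map whose amplitude tracks each
  grating's momentary contrast (ssvep_gain = 4 μV per unit contrast),
  polarity flipped by the counterbalanced phase flag; absent in dot-task
  mode (nothing flickers);
- 10–30 Hz band-limited noise carriers on C3/C4-centred maps whose
  envelopes shrink as the chosen-signed DV grows
  (mubeta_base − mubeta_dv_gain·DV_chosen, ipsilateral at half the
  DV-driven gain), strongest contralateral to the response hand;
- a bilateral occipito-temporal negative transient 200–300 ms after the
  sensory change on P7/P8 maps (n2_gain = 5 μV);
- 1/f-amplitude-shaped sensor noise (8 μV SD per channel) plus injected
  artifacts: ~350 μV blinks (bipolar EOG and a frontal scalp copy,
  Poisson rate 0.1/trial) and rare single-channel step artifacts.

Channel geometry comes from MNE's built-in BioSemi-128 montage; named
10-20 sites are located via the standard 10-05 montage and mapped onto the
BioSemi grid by distance. Scalp maps are spherical Gaussians — no
biophysical head model is intended — and EEG is generated reference-free
so no current-source-density step is needed for synthetic runs.

What the generator does *not* emulate: stimulus-onset evoked potentials,
eye-movement (as opposed to blink) artifacts, alpha rhythms, inter-subject
topography variation, non-stationary noise, or any learning across the
session. Passing recovery tests on this data demonstrates that the
pipeline measures what the model puts in — not that the model is a
complete account of real recordings.

## Preprocessing

Trial records are band-limited to 0.05–35 Hz and average-referenced. The
low-pass is a zero-phase windowed-sinc FIR (5 Hz transition, ~339 taps);
the high-pass is a zero-phase 2nd-order Butterworth that only engages on
records substantially longer than its time constant — on trial-length
records a 0.05 Hz filter is unobservable and the drift correction is the
detrend. Detrending is linear on continuous input but constant (mean
removal) on trial-wise records: a line fitted within a few seconds of data
tips over slow event-related ramps (it visibly distorted the CPP here),
which cannot happen when the fit spans a whole recording.

Epochs are stimulus-aligned [0, foreperiod + 2000] ms (0–2800/3200/3600 ms
by condition) or response-aligned [−1000, +600] ms, and every epoch —
response-aligned ones included — subtracts its own 500–550 ms
post-stimulus mean, computed in the stimulus frame. Trials are rejected if
the bipolar vertical EOG exceeds 200 μV or any scalp channel exceeds
100 μV anywhere in the stimulus-aligned epoch (the rule is defined on the
stimulus epoch only, following the source's wording); a channel whose own
artifact count exceeds 10% of trials is interpolated from its nearest
neighbours by inverse-distance weighting (spline interpolation is out of
scope), capped at 10% of channels; a recording losing more than 40% of
trials after all this is flagged for exclusion. The pass is idempotent:
re-running it on cleaned epochs changes nothing.

## Spectral analysis

The STFT uses 400 ms rectangular segments every 50 ms. At 512 Hz that is
204.8 samples; segments take 205 samples and the DFT is evaluated directly
at the nominal 2.5 Hz bin grid, preserving the stated resolution and the
integer-cycle property (8 cycles of 20 Hz and 10 of 25 Hz per segment, so
the tags do not leak into each other; residual leakage from the fractional
sample is <0.1%). Magnitude is divided by half the window length in
samples, so a sinusoid of amplitude a measures a. Segments are labelled by
their median time.

SSVEP SNR divides the tag-bin amplitude by the mean of the two bins on
each side, excluding the other tag frequency (and harmonics) from that
set; the d-SSVEP is target minus non-target SNR and is exactly
antisymmetric under swapping roles. Note the ratio estimator's null level
on featureless noise sits near 1.2, not 1.0 (Jensen inflation of
1/mean). Mu/Beta is the 10–30 Hz band average excluding the 20 and 25 Hz
bins (keeping motor and sensory activity unmixed), baseline-corrected
against the segment labelled 550 ms post stimulus, with lateralisation =
contralateral − ipsilateral relative to the response hand.

## Decision-signal measurement

Electrode clusters are selected per subject from broad candidate sets (the
12 montage channels nearest each named site): the 4 most positive
grand-average pre-response channels for the CPP and SSVEP clusters, the 4
largest-|lateralisation| for Mu/Beta, the 3 most negative per hemisphere
for the N2, ties broken by label. Windowed measures are means (amplitude)
or OLS slopes: pre-evidence amplitude ±50 ms around the change,
pre-response amplitude −150..−50 ms, pre-evidence slope −250..+50 ms,
pre-response slope −500..−200 ms (the source's Methods window; its Results
prose once says −450..−150 ms, available as an argument), N2 amplitude
200–300 ms post change. Trials beyond ±3 SD of the within-subject mean of
the pre-response measure are flagged in a single pass (no cascade), and
each signal's rejection is computed independently. RT bins are
equal-count within each foreperiod (6 for gratings analyses, 3 for the
dot task, 8/6 for conditional accuracy functions), ties broken by trial
order.

The accumulation-onset estimator is the first time the trial-averaged
cluster waveform exceeds its baseline mean by twice the baseline SD and
stays there for 100 ms. The baseline SD comes from the 100–550 ms
post-stimulus window — long enough for a stable estimate of the
low-frequency noise wander, ending before any plausible onset — and the
sustained-run requirement suppresses false crossings by that wander
without delaying true detections (once real build-up crosses, it stays
up). For fixed-onset datasets the estimate pools all trials; with the
sequential gain active, onset differs by previous foreperiod and the
estimator is applied per group at a corresponding cost in trials.

## Behavioural summaries

Outcome classes partition trials: premature (response at or before 150 ms
after the change, negative RTs included), miss (no response by the
deadline), else correct/error. Two accuracy conventions are reported side
by side: `accuracy` = correct/(correct+error), the usual
resolved-trials-only rate, and `correct_rate` = correct/all trials, the
percentage of trials answered correctly. Per-foreperiod summaries use the
former; the sequential FPn × FPn−1 grid uses the latter, because the
congruency question — does repeating a foreperiod help? — must count
anticipations and misses as calibration failures, and under the
resolved-only denominator survivor selection (heavily premature-filtered
cells retain only their luckiest trials) masks the effect entirely.
Similarly, the per-foreperiod mean RT pools corrects and errors only,
while the sequential RT grid pools every recorded response, anticipations
included, since it is a measure of response timing. Conditional accuracy
functions use equal-count RT bins over all trials with a recorded choice.

The staircase is 2-down 1-up with configurable symmetric steps (the source
states none): difficulty falls after two consecutive corrects, rises after
every error, converging to ~70.7% accuracy (√½), which a 10,000-trial
Monte-Carlo oracle in the tests confirms.

## Statistics

`rm_anova` wraps pingouin's repeated-measures ANOVA (one or two within
factors, complete balanced designs only — no imputation): Mauchly's test
is run per effect where defined, and whenever it rejects at p < 0.05 the
Greenhouse–Geisser-corrected p-value is reported, with corrected df =
ε × uncorrected df; two-level effects have ε ≡ 1. Linear and quadratic
contrasts over ordered factors are one-sample t-tests on per-subject
contrast scores. `t_test_suite` runs one-sample/paired t-tests and reports
the Bonferroni-corrected alpha (0.05/family; 0.017 for the three pairwise
foreperiod comparisons); zero-variance inputs yield flagged NaN results.
The test suite checks the F statistic against an explicit sums-of-squares
oracle and calibrates the type-I error rate on 2000 null simulations.

## Problem sizes and numerical choices

Analyses in the repository run at sizes chosen to make their statistical
properties stable: 300 trials for EEG parameter recovery, 1500
behaviour-only trials for rate comparisons, 2000 simulations for type-I
calibration, 0.1 °/px rasters for motion-energy property checks. Seeds
propagate from a single generator; identical seeds give byte-identical
trial tables. Degenerate inputs are handled explicitly: onset beyond the
trial end yields a flagged always-miss trial; zero-variance inputs yield
no outlier flags and NaN t statistics; empty sequential cells are reported
as missing, never zero.

## Known limitations

Single-subject scope (no group-level hierarchy); no CSD transform, ICA or
ocular regression; the forward model's scalp maps are geometric, not
biophysical; motion-energy units are resolution-relative; the generative
equations are this package's own formalisation of a verbal hypothesis and
should not be read as fitted to any real dataset.
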