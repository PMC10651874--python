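# Methods

This note documents the models, conventions and free parameters behind the
`selfsound` analyses, and what the synthetic generator does and does not
emulate.

## Evoked responses and the modulation index

Event-aligned PSTHs use half-open 5 ms bins; a spike at time *t* counts
toward the bin containing *t − t_event*. The evoked amplitude of a trial
is the rate in the 10–50 ms response window minus the rate in the trial's
own 0–200 ms baseline (the per-trial baseline matches the per-presentation
response definition used for the rank-sum comparison; the choice matters
little for the mean amplitude, which is what the modulation index uses).

Responsiveness divides the mean amplitude by the SD of the 5 ms-binned,
trial-averaged baseline rate, pooling baseline windows over both sound
classes, and requires z ≥ 2 for either class ("at least two times" is read
as inclusive). A completely silent baseline (SD = 0) would leave z
undefined; such a unit counts as responsive iff its amplitude is positive
and at least 25 % of trials carry a response spike. This is an artifact
convention that preserves obvious responders without dividing by zero.

`MI = (S − R)/(S + R)` on mean amplitudes. Units with S + R = 0 have no
defined MI and are dropped from MI summaries (flagged). Units with
negative amplitudes (suppression below baseline) can push MI outside
[−1, 1]; they are retained but flagged, and the report counts them.
Population MI summaries use auditory-responsive neurons only.

Per-unit significance classes (attenuated / enhanced / ns) come from a
two-sided Mann–Whitney test on per-trial amplitudes at α = 0.05, with the
direction taken from the median shift (mean shift on median ties).

## Event selection

The refractory rule (default 1 s, onset-to-onset) is evaluated against
the full physical sound history, including sounds that other rules later
discard, because adaptation depends on what the animal heard, not on
analysis choices. A sound with no predecessor passes the refractory test
vacuously; a random sound with no predecessor fails the
`preceded_by_self` rule (the condition cannot be verified). The
alternative random-sound rules are `pre_press_window` (default 1 s before
a press; the window is a free parameter, documented not prescribed) and
`lever_held` (between a press and its next release).

Blocks are defined on the ordinal sequence of all self-generated sounds:
the first 300 are the early block, the next 300 (or the remainder) the
late block. Random sounds belong to the block whose time span — first to
last self sound, half-open on the right — contains them. Within-block
retention uses a 0.5 s refractory so that fewer sessions fall below the
20-retained-sounds-per-class floor; sessions with fewer than 400 self
sounds in total are excluded. Preparatory-activity presses require ≥ 2 s
since the last sound of either type.

## Preparatory activity and paired pulses

Pre-press activity is binned at 100 ms over the second before the press
(the bin width matches the −1000/−900 ms reference and the 0–200 ms
summary interval arithmetic) and referenced to the −1000 to −900 ms bin,
which is therefore identically zero. The summary is the mean delta over
the last 200 ms.

The paired-pulse ratio divides the mean response to the second sound of a
pair by the mean response to the first (both 10–50 ms rates minus the
pair's pre-first baseline). 100 ms intervals are excluded from summaries
because first-sound responses can extend past 100 ms; a non-positive
first-sound response makes the ratio undefined (NaN) for that interval.

## Cell typing

Features: half-width = trough width at half the baseline-referenced
trough amplitude (baseline = mean of the first five samples; linear
interpolation between samples), and trough-to-peak = time from the trough
to the subsequent maximum. A two-component full-covariance Gaussian
mixture is fit on the pooled features with deterministic k-means
initialisation (10 restarts, fixed seed), making assignments independent
of unit order. The narrower component (smaller mean trough-to-peak) is
labelled pIN. Units with maximum posterior < 0.95 are unclassified — the
same gate as "other-class probability > 0.05". Singular fits are retried
with covariance regularisation stepped up to 0.1.

## Optogenetic response mapping

ΔFR per 5 ms bin over 0–100 ms after light onset is referenced to the
−100–0 ms baseline. The chance distribution resamples 200 ms segments
from all baseline time (anything not overlapping a 100 ms post-light
epoch), one segment per light presentation, 1000 surrogates; the first
100 ms of each segment is treated as baseline and the second as response,
and all 20 surrogate bins are pooled into a single 20 000-value null.
Surrogate segments are drawn with replacement and aligned to the 5 ms
grid (a numerical convenience; segment starts are otherwise
unconstrained). The p-value of an observed bin is the fraction of null
values at least as extreme on the side matching its sign, ties counted as
extreme. Note the calibration consequence: because the tail is chosen by
the observed sign, ~2α of null bins fall below α — the classification
criteria are single-tail, so they are unaffected.

Excitatory: latency is the end time of the first bin with positive ΔFR
and p < 0.001 (bin [0,5) → 5 ms), so the ≤ 10 ms terminal cutoff admits
exactly the first two bins; ≥ 10 spikes are required in that bin across
presentations. Soma stimulation extends the cutoff to 15 ms. Inhibitory:
≥ 3 consecutive bins with negative ΔFR and p < 0.05 inside 0–50 ms, plus
≥ 20 baseline spikes. Excitation takes precedence when both hold. Layer
fractions split at 600 µm.

## Hierarchical bootstrap

Each replicate resamples animals with replacement (same count), then
within every drawn animal that animal's own number of values with
replacement, and takes the pooled-neuron mean. Replicate *i* of one group
is paired with replicate *i* of the other; p is the proportion of pairs
whose difference is zero or opposite in sign to the observed pooled
difference (resolution 1/n_reps, default 1000). When the observed
difference is exactly zero the two tail proportions are averaged (~0.5
under a null). Because the p conditions on the observed direction it is
uniform on [0, 0.5] under a null; calibration is therefore assessed on
the folded value min(2p, 1). Groups with a single animal are computed but
flagged underpowered.

## Synthetic sessions

Each unit is an inhomogeneous Poisson process: log-normal baseline rate
(default median 4.5 Hz, log-SD 0.5, matching typical cortical averages)
plus three additive components, each realised exactly by superposition:

* a rectangular evoked transient confined to 10–50 ms after every sound,
  with amplitude `E · a · g(Δt)` for self-generated sounds and
  `E · g(Δt)` for random sounds, where `a` is the attenuation factor and
  `g(Δt) = 1 − A·exp(−Δt/τ)` (defaults A = 0.5, τ = 0.3 s) is an
  exponential-recovery adaptation gain in the time Δt since the previous
  sound. The exponential form is the simplest law reproducing paired-pulse
  recovery over a few hundred milliseconds; its analytic value, e.g.
  g(0.4 s) ≈ 0.868, is the oracle for the paired-pulse tests, and
  (a−1)/(a+1) is the oracle for MI recovery.
* a linear pre-press ramp from zero at 0.6 s before each press to the
  configured amplitude at the press (the onset matches when genotype
  differences in preparatory activity emerge; the linear shape is the
  simplest gradual increase). Its mean over the last 200 ms, e.g. 2.5 Hz
  for a 3 Hz ramp, is the oracle for the preparatory analysis.
* optogenetic terms: a configured fraction of units deeper than 600 µm
  fire ~1.5 extra spikes per 100 ms pulse at a fixed 2–8 ms latency with
  0.3 ms jitter; inhibited units have baseline spikes thinned by 85 % for
  60 ms starting 10 ms after light onset. Pulses arrive every 2–3 s over
  a 600 s block (~240 pulses), a realistic passive-stimulation session.

Behavior: presses arrive in bouts (geometric length, mean 15; within-bout
intervals uniform 2–6 s; inter-bout pauses uniform 30–120 s), each press
triggering a 100 ms self sound, release and reward; random sounds arrive
with uniform 5–10 s gaps. A two-hour default session yields > 600 self
sounds so both 300-sound blocks are populated. Depths are uniform over
100–1100 µm; waveforms are biphasic Gaussian trough-then-peak templates
(broad class: trough-to-peak 700 ± 70 µs, half-width 300 ± 30 µs; narrow:
300 ± 30 / 150 ± 15 µs; 14 % narrow), which at these separations are
almost perfectly separable by the mixture model.

Per-trial response variance is governed purely by Poisson counting around
the configured amplitudes — a free modelling choice, since real
trial-to-trial variability is not published. The `high_snr` preset
(50 Hz transients, no ramp, tight rate spread) defines the
parameter-recovery conditions under which the pipeline's mean MI must
match (a−1)/(a+1) to within Monte-Carlo noise; with a ramp enabled the
ramp tail leaks into the self-sound baseline window and biases MI
slightly negative, which is a property of the measurement definition, not
of the code.

What the generator does **not** emulate: raw voltage, spike-sorting
errors, non-Poisson spiking (refractoriness, bursting), frequency tuning,
behavioral-state fluctuations outside the bout structure, and
correlations between units. Passing tests therefore demonstrate
correctness of the analysis chain under the stated statistical model, not
robustness to every property of real recordings.

## Problem sizes and determinism

Simulated studies in the test suite use cohorts of 9 animals × 20 units
(parameter recovery), 161-unit control cohorts across six seeds (opto
null calibration), ~1000 units for cell-typing, and 500 simulated
datasets for bootstrap calibration — sizes chosen so every check runs
comfortably on a laptop. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; identical configuration and seed give
byte-identical tables and reports (JSON keys sorted, floats at fixed
precision).
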