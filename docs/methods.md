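# Methods

This note documents the models, conventions and design choices behind
`ripplescale`: what the synthetic sessions contain, exactly how each
statistic is computed, which parameters matter, and what the validation
battery does and does not establish.

## The synthetic session model

A session emulates a simultaneous recording of macro-scale iEEG and a
micro-scale 96-channel MEA (both at 1000 Hz) during a cued-retrieval
task: trials of 4 s (alignment point — "vocalization" — 1 s before trial
end, 1 s inter-trial gap, 2 s session padding), each labeled correct or
incorrect with probability `p_correct` (default 0.5).

**Background.** Each channel is an independent Gaussian process with
power spectral density ∝ f^(−`noise_exponent`) (default 1.5, flattened
below 2 Hz), normalized to `background_sd`, plus 60 Hz and 120 Hz
sinusoids with per-channel random phase (`line_noise_amp`, default 0.2;
the 120 Hz component at half amplitude).

**Ripple events.** Events occur as Poisson processes within trials at
`ripple_rate_correct` = 0.4 Hz on correct and 0.2 Hz on incorrect
trials per channel.  A fraction `cross_channel_alignment` of that rate
is carried by session-wide *shared* events — identical plateau interval,
center frequency and phase on every MEA channel — the rest is
channel-private.  Per event:

* center frequency uniform in 80–120 Hz;
* amplitude log-normal with median 2.5 and σ_log 0.4, in SD units of the
  band-passed background trace (so the amplitude is, by construction,
  the approximate envelope z-score the detector assigns);
* duration gamma (shape 3, mean 40 ms), floored at 15 ms.

The waveform is a constant-amplitude sinusoid held for the drawn
duration with 5 ms half-cosine on/off ramps appended *outside* that
interval; ground truth records the plateau.  A fully tapered (e.g. Hann)
profile was rejected because its supra-threshold extent is far shorter
than its nominal duration, which would make duration-conditioned
recovery statements meaningless.  The injected peak voltage is
`(mean envelope + A · trace SD) / |H(f)|²`, where `|H(f)|²` is the
zero-phase band-pass power gain at the event frequency — without this
compensation, events near the band edges would be silently attenuated by
up to 4× by the measurement filter, and "amplitude" would not mean what
the ground truth says.  Events are placed with a 20 ms clearance;
infeasible placements are re-drawn a bounded number of times and then
dropped with a log message.

**iEEG.** Each iEEG channel is `w · mean(MEA) + (1 − w) · noise` with
`ieeg_mix` w = 0.6 and independent 1/f noise.  Averaging across the
array cancels private events (by ~1/n_channels) and preserves shared
ones, so the iEEG inherits exactly the shared-event structure — the
mechanism the cross-scale analyses are meant to recover.  The effective
iEEG amplitude of a shared event is ≈ 1.5× its MEA SD-units amplitude.

**Spikes.** Units are assigned round-robin to MEA channels.  Baseline
firing is Poisson at `spike_baseline_rate` = 2.5 Hz.  Within each event
on the unit's channel, extra spikes are added with expectation
`spikes_per_ripple` (default 3) scaled linearly by the event amplitude
(relative to the median), so larger ripples carry more spikes — the
amplitude–spiking correlation the analyses test.  Locked-spike phases
are von Mises around `spike_lock_phase` = π with concentration
`locking_kappa` (default 2); the phase convention throughout is
x(t) = A·cos(φ), trough at φ = π.  κ = 0 yields uniform phases.
Synthetic 32-sample waveforms (fixed biphasic template plus Gaussian
residuals) support the SNR quality measure.

**Artifacts.** Optional stereotyped ~50 ms biphasic transients (IED
surrogates) are inserted at shared times into both scales, scaled to
`ied_amp_sd` = 10 broadband SDs so the z > 5 artifact rule fires.

**Reproducibility.** One RNG stream per sub-generator (trials,
backgrounds, events, spikes, IEDs), all spawned from the master seed:
identical config + seed ⇒ bit-identical session.

## Preprocessing

* Line noise is removed by least-squares regression of 60/120 Hz sine
  and cosine terms over 10 s windows with 50% overlap, Hann-blended;
  the window tracks slow drifts in line amplitude.
* Slow fluctuations ≤ 2 Hz are removed by subtracting a zero-phase
  4th-order low-pass of the signal.
* Trial rejection: the per-trial statistic is the mean *absolute*
  voltage per channel aggregated across channels by the maximum (raw
  signed means cancel and cannot index artifact severity; both choices
  are configurable).  Trials with statistic > Q3 + 2.3·(Q3 − Q1) are
  dropped.  The strict inequality handles the zero-IQR case: an
  all-equal set is kept in full, while a lone extreme trial above a
  degenerate Q3 is still dropped.
* Transient artifacts: per channel, the signed first difference and the
  Hilbert amplitude of the > 250 Hz high-passed signal are z-scored;
  samples with |gradient z| > 5 or amplitude z > 5 are flagged and
  dilated ±100 ms (clipped at edges).  Note the amplitude channel has a
  Rayleigh-tailed null (P(z > 5) ≈ 3.5e-5 per sample), so even clean
  recordings carry ~0.7% flagged samples after dilation; this is the
  intrinsic operating point of the z > 5 rule, not a defect.
* Common average referencing subtracts the per-sample cross-channel
  mean.  The pipeline applies it only on request: with a handful of
  simulated iEEG channels that all overlay the same MEA, the common
  average *is* the shared ripple signal, whereas in large clinical
  montages any single source is diluted.

## Spectral estimation

Morlet wavelets (6 cycles, zero-mean, via `mne`) on 200 linearly spaced
frequencies between 2 and 200 Hz by default; power is squared magnitude,
log-transformed, and z-scored per frequency and channel over the
session.  A 1 s edge buffer is trimmed before any statistic.  HFA is the
70–200 Hz mean of z-scored power, smoothed with a sliding 600 ms window
at 90% overlap.  Band-limited amplitude and phase come from a
second-order Butterworth band-pass applied forward–backward (zero phase,
effective order 4) followed by the Hilbert transform; the exact wavelet
normalization only affects raw power, never z-scored quantities.

## Ripple detection

The envelope is thresholded at `envelope_threshold` SDs above the mean
amplitude of the filtered trace, where the SD is that of the band-passed
*voltage trace*.  This reading of "standard deviations above the mean
amplitude" matters: normalizing by the envelope's own SD (≈ 0.66 of the
trace SD for Gaussian signals) lowers all thresholds by a third and
raises the false-event rate on ripple-free noise by ~20×.  Candidate
intervals separated by less than `join_gap` = 15 ms (end-to-start,
strict inequality) are merged; survivors need ≥ `min_duration` and a
peak > `max_threshold`; there is no upper duration limit.  Envelope
statistics are computed per channel over the whole session excluding
masked samples, and events overlapping any masked sample are discarded.
Strict preset: 2 / 3 SD, 25 ms.  Relaxed preset: 1 / 2 SD, 10 ms.  Every
strict event is contained in some relaxed event on the same signal.
A 120–200 Hz control band is available through `DetectionParams.band`.

The independent narrowband detector fits, per trial, a robust
(Theil–Sen) line to log mean wavelet power vs log frequency over
70–200 Hz; contiguous supra-fit frequency ranges define bands, each
band-passed and Hilbert-transformed; instantaneous frequency is the
smoothed derivative of unwrapped phase (frequency sliding, 10 ms boxcar);
samples whose band power falls below the fit level are removed and the
surviving runs are episodes.

## Phase-locking statistics

PPC is computed via the unit-vector identity
(|Σe^{iθ}|² − N)/(N(N−1)), equal to the pairwise double loop to
machine precision (validated to 1e-12 on 1000 random sets).  Its range
is [−1/(N−1), 1]; its expectation for i.i.d. von Mises(κ) phases is
(I₁(κ)/I₀(κ))², the squared population phase-locking value.  The APCD
descriptive statistic, mean over pairs of (|θ_j − θ_k| mod π), is
reported alongside for N ≤ 5000.  Rayleigh p-values use Zar's
approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)) with R = n·R̄
(cross-checked against pingouin).

Spike–field PPC spectra use 60 log-spaced frequencies (2–400 Hz),
computed per trial (trials with < 2 spikes skipped) and averaged across
trials, then units.  The z-scoring null re-pairs each trial's relative
spike pattern with the LFP phases of a randomly chosen other trial
(default 100 shuffles).  Condition contrasts pool spikes across trials,
require ≥ 10 spikes per condition, subsample the larger condition to the
smaller count (200 draws, averaged) and use raw PPC, since the contrast
is within unit.  Cross-channel alignment PPC treats every sample inside
a macro-scale ripple as one observation over channels and takes the
per-event maximum; a variant restricts the observation set to channels
with a concurrently detected micro-scale ripple.

One practical caveat: with 6-cycle wavelets and spikes clustered inside
brief bursts, the locking peak in the PPC spectrum is smeared across the
ripple band and skewed slightly low; band-level statements are robust,
single-bin peak positions are not.

## Event-level statistics

Correlograms use 1 ms bins over ±200 ms lags of event peak times within
trials, pooled across trials; autocorrelograms exclude self-pairs.  The
shift predictor cross-correlates each trial's events with every *other*
trial's events (n−1 correlograms averaged per trial, then across
trials), capturing stimulus-locked but trial-independent coincidence.
The synchronization metric is the ±50 ms windowed mass ratio (1 =
chance).  The cross-scale coincidence ratio replaces the predictor with
per-trial uniform circular shifts of the micro-scale events.  The burst
metric compares the ±25 ms mass of the population-spiking
autocorrelogram inside ripples against random duration-matched windows
between ripples (5 draws per event, averaged, to stabilize the sparse
chance term).

The dip statistic is computed from its definition — the minimum sup-norm
distance between the empirical (binned, 200 bins) CDF and any unimodal
CDF — by bisection on the tolerance with an exact convex/concave branch
feasibility check; the implementation agrees with a direct
linear-programming solution of the definition on 600 random tied cases
and with closed forms (two points → 1/4, n equispaced → 1/(2n)).  The
bimodality z-score references the dip of uniform samples of the same
size, binned identically; nulls may be cached across calls keyed by
(n, bins, n_null) since they depend on nothing else.

Cluster permutation across frequencies: per-frequency one-sample t
against zero, clusters of adjacent same-sign significant frequencies
(cluster-forming α = .05), cluster statistic = summed t, null = maximum
|cluster statistic| under participant sign flips.  Flips are enumerated
exhaustively when 2^k ≤ n_perm.  With few participants the exhaustive
null is heavily discrete — flips come in ± pairs with identical maxima,
so only 2^(k−1) distinct values exist — and the usual ≥-counting p can
only attain multiples of 1/2^(k−1) (at k = 6: FWER ≈ 0.031 at nominal
.05).  Exhaustive p-values therefore use the mid-p convention (half
weight on ties, which include the identity flip); sampled permutations
use (b+1)/(n+1).  Neither is ever zero.  Measured family-wise error over
500 null datasets at k = 6 is ≈ 0.05–0.06.

Circular-shift correlation nulls shift spike indices within each trial
by an independent uniform non-zero amount and recompute an arbitrary
caller-supplied statistic; p-values use (b+1)/(n+1).  The r-equivalent
effect is the true correlation z-scored against its shuffle null,
carried into the meta-analysis with sampling variance 1/(n−3) (the
variance of a Fisher-z correlation; the construction itself does not fix
one).  Random-effects pooling estimates τ² by REML (bounded scalar
optimization of the restricted likelihood, exact zero preferred when the
boundary fits at least as well) and weights by 1/(vᵢ + τ²); the
implementation reproduces R `metafor::rma(method="REML")` to ~1e-7 on
frozen test cases.

## Validation battery and its limits

`scripts/acceptance.py` (and the mirroring tests) verify, on freshly
simulated data: PPC correctness and the von Mises identity; ≥ 90% strict
recall of large (≥ 3.5 SD, ≥ 30 ms) ground-truth events on a ~600 s
default session with < 0.05 false events/s on ripple-free noise, and
relaxed recall ≥ strict; threshold monotonicity and event invariants
over 50 random configurations; null calibration of the synchronization
metric and the coincidence ratio (within [0.8, 1.2] on ~300 independent
events — dense trains, because the window-mass estimator's relative SD
scales as (pairs in window)^(−1/2)); cluster-permutation FWER and
circular-shift p uniformity; recovery of strong effects (κ = 5, full
alignment, 40-trial sessions sized so the spike-field cluster test has
adequate power); dip ordering and calibration; REML recovery (k = 50,
τ² = 0.04); and the ripple-removal HFA control (excising detected ripple
samples lowers correct-trial HFA, paired across 20 seeds).

What the generator does *not* emulate: volume conduction and electrode
geometry, biophysical ripple waveforms (phase-amplitude asymmetries,
sharp-wave coupling), non-stationary background spectra, spike sorting
errors, or pathological high-frequency oscillations beyond stereotyped
IED transients.  Passing this battery shows the estimators recover the
statistical structure they target under known ground truth with
calibrated nulls — not that thresholds tuned here are optimal for any
particular clinical recording.

## Problem sizes and defaults used by the battery

Simulated sessions in the battery use 4 MEA channels (96 is the package
default), 2 iEEG channels, 6–20 units and 10–119 trials depending on the
check; permutation counts are 50–1000 as stated above; the dip null uses
500 uniform draws with caching.  These sizes were chosen so the full
battery completes in minutes on a single CPU while leaving every
assertion comfortably away from its sampling noise floor.
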