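# Methods

This note documents the models, numerical choices and limitations of the
`percept` package: what each analysis assumes, which knobs matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Data model and normalization

A session is a tensor of spike counts per (unit, trial, 10 ms bin) on a
common grid with stimulus onset at t = 0 and a 300 ms fixation baseline,
plus a trial table and optional LFP traces. Bins are half-open
[t, t + 10); a window [a, b] includes exactly the bins whose full extent
lies inside [a, b); latencies are reported as bin midpoints.

Net rates subtract the per-trial baseline mean, making the baseline mean
of every trial exactly zero. Z-normalization standardizes each unit by
the mean and standard deviation of its net rate over every
response-window bin pooled across all trials and conditions; we use the
population (n-denominator) SD, matching the definition of a z-score (the
choice is configurable and immaterial at the bin counts involved). The
per-array response windows are [100 250], [130 280], [130 280],
[200 350], [140 290] ms for arrays 1–5 (selectivity latency + 150 ms),
and the signal-loss windows [60 210], [80 230], [130 280], [200 350],
[130 280] ms (response latency + 150 ms). Units with zero window variance
are flagged degenerate and excluded from z-based analyses rather than
propagating NaNs.

Responsiveness screening tests every condition separately in four 100 ms
windows at p < 0.005 (two-sided one-sample t on net window means —
baseline is already subtracted, so the paired-against-baseline contract
reduces to a test against zero). Testing per condition keeps units with a
strong preference for a single category from being washed out by a
pooled test. Under pure noise the per-unit family-wise hit rate is
bounded by 1 − (1 − 0.005)^(4K) for K conditions; the tests verify this
empirically.

## Latency criteria

Response latency is the first of 3 consecutive bins of the trial-averaged
net trace that (i) rise relative to the previous bin and (ii) exceed
2 SD of the baseline. An anticipation guard — an increase of more than
50% relative to the previous bin and more than 5 sp/s absolute — must
hold on the first bin of the run. Applying the guard to every bin of the
run was considered and rejected: any saturating response grows by less
than 50% per bin near its peak, so the all-bins variant rejects genuine
onsets almost surely; the guard's purpose is to reject slow anticipatory
ramps, which the first-bin form already does (a ramp never produces a
>50%-and->5 sp/s jump). The number of guarded bins is a parameter
(`guard_bins`). The baseline SD is computed from the baseline bins of the
same trial-averaged trace the criterion is applied to — computing it from
single-trial 10 ms bins would give SDs of tens of sp/s for Poisson-like
counts and make criterion (ii) unsatisfiable — with a floor of 0.1 sp/s
against silent baselines.

Selectivity latency uses per-bin one-sided two-sample t-tests (pooled
variance by default, Welch available) with the same 3-bin run rule.
Divergence latency (perceived > nonperceived) uses per-bin one-sided
permutation tests with a 3-bin run, matching the latency convention; the
run length is configurable.

With the generator's onset shape, recovered latencies carry a
deterministic +1-bin bias (the criterion fires on the first bin with
appreciable response mass, one bin after the programmed drive onset);
recovery tests therefore accept a ±1 bin tolerance.

## d′, category rules, and unit-level permutation tests

d′ = (μ₁ − μ₂)/√((σ₁² + σ₂²)/2) on response-window mean net rates, with
sample (ddof = 1) variances. Significance comes from 1000 label
permutations, one-sided toward the observed sign, with +1 smoothing:
p = (1 + #{null at least as extreme on the observed side})/(1 + 1000).
Because the side is chosen by the observed sign, this p is uniform on
(0, ½) under the null; calibration tests therefore check uniformity of
the doubled value.

Category selectivity: one-way ANOVA over face/body/object window means
(objects pool the object-like categories), then Tukey HSD
(scipy's studentized-range implementation, Tukey–Kramer for unequal n).
A unit is face-selective if μ_face exceeds both μ_object and μ_body at
Tukey p < 0.05 (body and object symmetric), and face-and-body selective
if both exceed object while face vs body is not significant; no label is
assigned if the ANOVA is not significant.

## Backward masking

Delay groups are the fixed partitions ([16 32], [50 66], [83 100],
[116 132], [150 166 183]) and ([16 32 50 66], [83 100 116 132],
[150 166 183]). 200 ms, a presented delay the partitions omit, is
assigned to the last group and logged.

The bimodality test asks whether the population response to a masked
stimulus contains one peak (merged target + mask) or two (separable
responses): z-traces are averaged in random non-overlapping triples
(remainder dropped), smoothed with a centered 50 ms moving average
(edges shrunk, no padding), and up to two peaks per averaged trace are
kept — local maxima at least 30 ms apart whose height exceeds 30% of the
highest average rate across all delays for the tested class. The pooled
peak times are resampled 1000 times with replacement; each bootstrap
sample gets a Gaussian KDE with bandwidth 2 bins (= 20 ms; the bandwidth
unit is stated only as "2", and bins are the natural unit of the trace —
configurable). At least one KDE peak always counts; a further peak counts
if its height exceeds 30% of the tallest and its nearest flanking valleys
(local density minima, with the support boundary counting as a valley)
are at least 30 ms away on both sides. p is the fraction of bootstrap
samples with exactly one peak, so small p indicates bimodality. The
procedure is type-I-inflated when responses are weak (few detected
peaks make the KDE ragged); the implementation returns an undefined
result with a diagnostic when no peaks are found at all, and the
calibration tests use strong responses.

Signal loss = (1 − A_np/A_p) × 100%, where each activity is the mean
z-rate in the 150 ms window after response latency minus that arm's mean
baseline z-rate; undefined (flagged) when A_p ≤ 0. Two caveats the
simulations make explicit: nonperceived trials concentrate at short
delays, where the Mondrian response overlaps the measurement window, and
units that respond to the mask dilute the measured loss toward zero. The
recovery tests therefore use the clean design — a single intermediate
delay (83 ms, where perception is near 50/50) and mask-insensitive units
— under which the estimate matches the programmed loss within sampling
error.

The prestimulus-state decoder uses all 30 baseline bins of every unit as
features. Because normalization is global (train and test are not
re-normalized separately, matching the stated protocol), held-out trials
are weakly coupled to the training set; on exchangeable baselines this
leaves the AUC at chance within ~0.02.

## Flash suppression and rivalry

Units are face/place selective (two-sided t, phase-1 monocular trials),
sustained (mean net rate over [800, 1000) ms of continued preferred
viewing above the fixation level, paired one-sided t — on net rates the
fixation mean is zero by construction, so this is a one-sample test on
the phase-1 tail), and/or inhibitory (RA preferred→nonpreferred below
continuation, one-sided t). Phase-2 statistics use the array's response
window re-referenced to the phase-2 onset at 1000 ms, since the window is
defined relative to a stimulus event.

Percept-following has two paths, each behind the printed gates.
Selective units must additionally show significant phase-2 activity
after real alternation to the preferred image; they follow perception if
flash suppression to the preferred image exceeds continued nonpreferred
viewing (one-sided permutation, 1000 shuffles of trial labels within the
compared pair — the exchange scheme is not further specified and
trial-label exchange is the natural choice). Sustained/inhibitory units
follow if both FS and RA shifts away from the preferred image reduce the
response below continuation. Units failing gates are "not-evaluable";
both paths are reported separately.

Rivalry decoding trains only on non-rivalrous data: binocular trials
plus every 1 Hz-alternation epoch as an extra labeled sample (the
best-bin window re-anchored to the epoch onset; with 10 s trials this
multiplies the training set roughly tenfold, consistent with the
per-epoch reading of the training-set expansion). The best bin is the
highest face-vs-place AUC window; when several windows saturate the AUC
the one with the widest feature-space class margin is used. From the LOO
ensemble, 10 decoders are drawn uniformly without replacement (seeded)
and averaged. Press-locked analysis aligns probability trajectories to
each button press, compares face-report vs place-report groups per lag
(one-sided t), and reports the start of the significant run containing
the latest significant lag as the divergence onset; its negative is the
perceptual lead. The estimate carries a ~100–150 ms early-detection
smear from the 100 ms decoding windows and the motor jitter, within the
±0.2 s recovery tolerance used in tests.

## Decoding engine

Features are per-unit mean z-rates in 100 ms windows stepped by 10 ms
(150 ms for probability comparisons); window times are midpoints.
The classifier is L1-regularized logistic regression with C = 0.1
(small C = strong penalty; liblinear solver with a large
intercept-scaling so the intercept is effectively unpenalized) and class
weights N/(K·N_k). Multiclass uses explicit one-vs-rest with
macro-averaged AUC. Each window is scored on stratified 80/20 splits,
averaged over 10 repetitions; "tenfold cross-validation on the 80%" is
retained as an optional sanity metric that never affects the reported
AUC (the final model is refit on the full 80%). The null distribution
per window comes from 250 label-shuffled decoding runs; the observed
mean AUC is compared one-sidedly against this empirical null with +1
smoothing — for a scalar observed statistic and an empirical null, extra
resampling of the comparison adds nothing. Significance requires runs of
at least 5 consecutive windows.

Sparsity is a feature, not an accident: at C = 0.1 the LASSO zeroes the
coefficients of uninformative units, which the tests verify on
populations containing 50% pure-noise units.

## LFP

Preprocessing demeans each trace, applies zero-phase second-order IIR
notches at 50/100/150 Hz (Q = 35, generously padded — narrow notches
ring), then a zero-phase FIR band-pass at 1–450 Hz. The FIR length
adapts to the trace (odd, at most two-thirds of the trace length): a
literal 1 Hz transition band would need a filter longer than a trial, so
on short traces the low edge is as sharp as the data allow and DC removal
is guaranteed by the demeaning. The band's upper edge clips to 0.45·fs
with a warning when the sampling rate is too low.

Morlet power uses MNE's `tfr_array_morlet` with 7 cycles per frequency
on a 10–150 Hz grid in 2 Hz steps (7-cycle wavelets at lower frequencies
would not fit the 1.7 s synthetic trials). Power is normalized per trial
by dividing each frequency's trace by its mean over the 200 ms
pre-stimulus interval — the baseline mean is exactly 1 by construction.
Note that a 200 ms baseline contains only a few independent gamma-power
samples, so the normalized ratio is Jensen-biased upward away from the
baseline; the sustained-gamma classification (late phase 1 vs fixation,
paired one-sided t) is therefore run on raw wavelet power, where the
bias cannot masquerade as sustained activity. The spiking analyses keep
their 300 ms baseline and the LFP its 200 ms baseline, as the two
conventions are stated per modality.

## The synthetic generator

Spiking is inhomogeneous Poisson: rate = baseline + Σ amplitude ×
envelope. The envelope rises convexly to its peak over ~30 ms
(interpolated profile that roughly triples across successive 10 ms bins
before saturating — cortical onsets are expansive, and a concave
(alpha-function) onset cannot satisfy a 3-bin run criterion with a >50%
per-bin growth guard at any SNR), settles onto a sustain-fraction
plateau while the stimulus is on, and decays exponentially after offset
or interruption. Interruption (masking) cuts the drive one response
latency after mask arrival. A 16 ms flash still completes its transient.

Defaults mirror the experimental conditions: 12 masking delays from 16 to 200 ms
with a logistic psychometric (d50 = 83 ms, slope 25 ms — the delay range
is bracketed by near-zero and near-complete perception, and the midpoint
of the presented delays is the natural half-way point); 16 ms targets and
250 ms Mondrians; flash suppression with a 1000 ms phase 1 and 400 ms
phase 2; rivalry trials of 10 s with gamma(k = 3) dominance durations of
mean 2 s (a right-skewed unimodal shape typical of rivalry timing; no
quantitative distribution is stated, so this is a documented placeholder,
not a claim about the data); a 1500 ms percept lead before the button
press with 150 ms Gaussian motor jitter; eye-dominance bias 0.75 on the
first percept (the middle of the observed 62–95% range); b-CFS
breakage latencies lognormal with medians 5 s/3 s and censoring at the
10 s contrast ramp. Percept gain g (response to a perceptual shift
relative to real alternation) defaults to 0.6 and the suppression
residual r (response to a physically present but suppressed stimulus)
to 0.1; both are per-unit parameters. Note that low r is itself percept
modulation — a purely stimulus-driven unit has g = 0 and r = 1.

What the generator does not emulate: correlated noise between units,
adaptation across trials, eye movements, spike-sorting artifacts, true
LFP spatial structure, and mixed selectivity. Passing recovery tests
therefore shows the estimators are correct under the stated model, not
that clinical recordings will be as clean; in particular decoding AUCs
and percept-following fractions on real data will sit below the
synthetic ceiling.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sessions (tens of units,
tens of trials per condition, rivalry decoding on 50 ms steps) chosen so
the full suite runs in a few minutes on one CPU; all statistical claims
are calibrated at these sizes. Every randomized step takes a seed;
identical seeds reproduce bundles and reports bit-for-bit. Seeds for
sub-streams are derived deterministically from the root seed.

## Known limitations

- The bimodality test is undefined (with a diagnostic) when no trace
  peaks are found, and anti-conservative for weak responses.
- Signal loss is only interpretable when the perceived-arm activity is
  positive and the measurement window is not dominated by
  perception-independent (mask) responses; both conditions are flagged.
- The press-locked lead estimator needs enough presses per percept
  (≥ 2 segments each) and underestimates the lead slightly because
  detection requires accumulated significance.
- LFP filtering on trials much shorter than ~1 s cannot realize the
  nominal 1 Hz band edge.
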