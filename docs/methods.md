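# Methods

This note documents the models, conventions and numerical choices behind
`ipcquant`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and quantification

**Inverse FRET (cAMP).** The Epac1-camps sensor loses FRET as cAMP rises:
CFP emission increases, sensitized YFP emission decreases. After background
subtraction of both channels and removal of the CFP→YFP spectral spillover
(a fixed fraction `k` of the CFP signal, default 0.357 as determined for
this optical configuration), the per-frame readout is

    iFRET(t) = CFP(t) / (YFP(t) − k·CFP(t)).

**Baseline normalization.** "Normalized to baseline" is implemented as
division by the baseline mean, expressed as percent change:
`(signal/mean_baseline − 1) × 100`. Division rather than subtraction is the
deliberate choice: raw iFRET magnitudes differ across cells (expression
level, optical path), and published response magnitudes are percent changes.
The baseline window is the half-open interval `[0, application_time)`
(default application at 100 s); it needs ≥ 3 valid frames and a positive
mean, otherwise the ROI is rejected.

**Windows and maxima.** Response scores are per-neuron maxima of the
normalized trace over closed time windows — default `[100, 1000]` s (long)
and `[100, 200]` s (short). Windows select frames by time membership, not
frame index, so dropped frames do not shift them. No smoothing or detrending
is applied before taking maxima; the score is the raw windowed maximum.
When the short window is contained in the long one, `max_long ≥ max_short`
by construction.

**Invalid-frame policy.** A non-positive iFRET denominator would flip the
sign of the ratio; such frames are marked invalid (excluded from baseline
and maxima) rather than silently propagated. An ROI with more than 10 % of
its frames invalid (configurable) is rejected with a per-ROI reason in the
rejection report. Background-corrected intensities are floored at
ε = 1e-9 channel units.

**ΔF/F₀ (Ca²⁺).** Single-channel GCaMP traces use the same machinery:
`ΔF/F₀ = (Fₙ − F₀)/F₀ × 100` with `F₀` the baseline mean, after background
subtraction.

**Treatment summaries.** Traces are averaged pointwise per treatment; the
dispersion shown is the SEM across neurons (ddof = 1), because neurons are
the counting unit of these experiments. Brain-level nesting is reported
(`n_brains`) but not modeled; there is no mixed-effects layer. Traces of
unequal length are truncated to the common grid with a log message. A
single-neuron treatment gets SEM 0 rather than NaN.

## Statistics

**Test-path selection.** `select_test_path` applies Shapiro–Wilk per group
and returns "parametric" only if every group has p > 0.05 (constant groups
count as non-normal). The imaging pipelines default to the nonparametric
path regardless — Kruskal–Wallis (tie-corrected, χ² approximation) followed
by two-sided Wilcoxon rank-sum pairwise tests — since windowed maxima are
generally skewed; the auto mode is available via configuration.

**Exact vs approximate rank-sum.** p-values are exact (full enumeration)
when both groups have n ≤ 8 and the pooled data are tie-free; otherwise the
tie-corrected normal approximation with continuity correction is used. The
method actually used is recorded per comparison. All-identical data returns
p = 1 (no rank information); similarly Kruskal–Wallis returns (H, p) =
(0, 1) in that degenerate case.

**Multiple comparisons.** Bonferroni: `p_adj = min(1, p_raw × m)` with `m`
the explicit comparison family size. The family is configured, never
inferred, so restricting the reported pairs changes the multiplier
transparently. Significance tiers are the conventional 0.05 / 0.01 / 0.001
stars on adjusted p-values.

**Synergy bootstrap.** No standard test exists for "response to A+B exceeds
the sum of the responses to A and to B"; the package formalizes it as
`excess = median(combined) − [median(A) + median(B)]` with a percentile
bootstrap (default 10 000 resamples, each group resampled independently), a
95 % CI and a one-sided p for excess > 0 computed as
`(1 + #{excess* ≤ 0}) / (n_boot + 1)`. Medians match the nonparametric
treatment of the scores; a mean-based variant is selectable. Each group's
resampling substream is keyed by the group's own sorted content, which makes
the result exactly invariant under relabeling A ↔ B. The smallest
attainable p is `1/(n_boot+1)` — a deliberate floor of the resampling
formulation.

**Dormancy.** Replicate vials are the experimental unit; per-vial arrest
proportions are transformed with `arcsin(√p)` (radians, range [0, π/2]) and
analyzed by one-way ANOVA + Tukey HSD (studentized-range p-values) across
genotypes, or by a two-factor genotype × photoperiod ANOVA with interaction.
The two-factor path requires a full factorial with ≥ 2 replicates per cell
and uses Type-II sums of squares, which coincide with Type-I on balanced
designs and stay interpretable under mild imbalance. Display summaries stay
on the untransformed percent scale. A fully constant response table is
reported as F = 0, p = 1 rather than 0/0. Note that under exact additivity
with zero noise the interaction *sum of squares* vanishes while the F ratio
is undefined (0/0); the tests therefore assert the vanishing interaction SS,
not a limiting p-value.

**qPCR.** `ΔCt = Ct_target − Ct_reference` per sample, `ΔΔCt` relative to
the mean ΔCt of the calibrator group, ratio `2^(−ΔΔCt)`. The calibrator
group has geometric mean ratio 1 by construction; group summaries report
arithmetic mean ± SEM of the ratios.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics. Latent per-neuron response kinetics are phenomenological
(the source experiments report trace shapes, not rate equations):

    c(t) = A_slow (1 − e^{−(t−t_app)/τ_slow}) + A_fast α(t−t_app),  t ≥ t_app

with α a unit-peak double exponential (rise/decay time constants), an
optional delayed exponential decline beyond `t_decline`, and a
`ttx_blocks_fast` flag that zeroes the fast component (TTX removes
action-potential-dependent, i.e. indirect, signaling). Channel mixing is

    CFP = C0(1 + g·c)·bleach + bg + ε,   YFP = Y0(1 − g·c)·bleach + k·CFP_true + bg + ε,

so the spillover the analysis subtracts is actually present in the data, and
a shared multiplicative bleach cancels exactly in the iFRET ratio (a tested
invariant). With exact spillover removal the normalized iFRET change is the
closed form `200·g·c/(1 − g·c)` %, which both the round-trip tests and the
peak-scaling helper (`kinetics_for_peak_percent`) use.

Defaults (one choice, not tuned per experiment): frame rate 0.2 Hz,
1000 s duration, application at 100 s, C0 = 1000, Y0 = 1500, G0 = 800
arbitrary units, gain g = 0.5, spillover k = 0.357, background 50 units
(drift 0), additive Gaussian channel noise sd 1.5 units (≈ 0.15 % of
baseline CFP — appropriate for ROI-averaged intensities of thousands of
camera counts), log-normal neuron-to-neuron amplitude jitter with CV 0.15
(mean 1), 5 brains × 4 neurons per treatment (each brain receives one bath
application). Per-neuron substreams are derived deterministically from
(seed, treatment, brain, roi), so runs are reproducible and individual
neurons stable under panel changes. Dormancy counts are binomial per
replicate with logit-additive photoperiod effects (probabilities of exactly
0 or 1 pass through unchanged).

The shipped `default_experiment` spec sets latent amplitudes so the
noiseless peaks land near the approximate percent changes that the
treatment classes are meant to illustrate (~10 % slow rises for single
peptides, ~15 % plus an ~8 % fast transient for the co-application, a
post-400 s decline for the half dose, TTX variants). These are
demonstration values, not measurements.

**What passing tests show — and don't.** Parameter recovery, calibration and
round-trip tests establish that the *computations* are correct and unbiased
under the generator's assumptions (additive Gaussian noise, shared bleach,
exact spillover, ideal background estimates). Real recordings add effects
the generator deliberately omits: photon shot noise, focus drift and motion,
channel-specific bleaching, imperfect background ROIs, and receptor-level
nonlinearities. Results on real data therefore inherit only the arithmetic
guarantees, not the noise-model ones.

## Problem sizes and numerical tolerances

The verification suite uses sizes chosen to make the statistical assertions
stable: 1000 random 20-frame traces for the chain oracle (agreement to
1e-12 relative), 200 simulation replicates for parameter recovery (within
1.5 percentage points in ≥ 90 % of replicates at 20 neurons/treatment),
1000 simulated experiments for each type-I calibration (acceptance band
5 % ± 1.5 %), all 36 tie-free group-size pairs (3..8)² for exact-test
agreement, and 10 000 bootstrap resamples for synergy estimates. Maxima of
noisy traces are upward-biased estimators (extreme values over ~180 frames);
at the default noise this bias is ≈ 0.5 percentage points and is included in
the recovery tolerance rather than corrected.

## Known limitations

* No photobleaching correction (none is applied upstream either); bleaching
  only cancels when shared across channels.
* No mixed-effects modeling of brain-level nesting; SEMs count neurons.
* No logistic/binomial GLM alternative for dormancy proportions (a possible
  extension); the arcsine-ANOVA path mirrors standard practice for this
  assay.
* Whether per-neuron maxima should be taken on smoothed traces is an open
  convention; this package takes them on raw normalized traces and documents
  it.
* The Bonferroni family must be specified by the analyst; the package does
  not guess which comparisons form a family.
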