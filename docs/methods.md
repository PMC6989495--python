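# Methods

`repstab` implements a single coherent analysis chain: how stable are the
EEG patterns a stimulus evokes over repeated study, how strongly are sleep
spindles grouped by slow oscillations in the following night, how much of
the encoding pattern is reinstated at retrieval, and how do these three
quantities jointly predict single-trial recognition.  Every stage also has a
synthetic generator with known ground truth, so the whole chain is testable
by parameter recovery.

## Spatiotemporal pattern similarity (STPS)

A trial is a 1-s, 250-Hz epoch summarised as six regional mean voltages
(left/right x frontal/central/parietal).  Similarity between two trials is
the Pearson correlation of the two single-region voltage segments inside a
200-ms (50-sample) window that slides in 1-sample steps, giving 201 window
positions per epoch.  Window correlations are Fisher-z transformed
(`atanh`), after clipping |r| at 1 - 1e-7 so identical segments stay finite,
and averaged within consecutive 20-ms bins (5 window starts per bin); the
201st window does not fill a bin and is dropped, leaving a 6-region x 40-bin
map.  Windows with a zero-variance segment have undefined correlation; they
score 0 and are counted in a QC flag on the map.

Two pairings are analysed per subject:

* **encoding stability** — repetitions (1,2), (2,3), (3,4) of the same
  paired associate, item-wise, then averaged over items; the three contrasts
  are kept separate.
* **reinstatement (STPS_E-R)** — the 4th encoding presentation against the
  retrieval presentation of the same (intact) pair, windows matched at the
  same post-onset latency.  Cross-lag generalisation maps are out of scope.

Similarity is computed per region over time (regions are the map's spatial
axis) rather than on one concatenated spatiotemporal vector, because the
group results are region-resolved clusters.  Pearson correlation makes every
map exactly invariant to per-trial gain and offset; this is tested.

Remembered/forgotten contrasts are computed only after per-subject trial
balancing: within each subject, the items of the larger outcome class are
subsampled (seeded, without replacement) to the smaller class's item count,
keeping all repetitions of a retained pair together, so the two classes have
equal signal-to-noise ratio.

## Preprocessing

Band-pass 0.5-30 Hz with a linear-phase Kaiser-window FIR (order 1326 at
250 Hz, beta sized for 60 dB stopband); the filter is applied in a single
forward pass with group-delay compensation, which for an odd, symmetric
kernel is exactly zero-phase without squaring the magnitude response.
Common-average re-referencing subtracts the per-sample channel mean.
Epochs are [0, 1.0) s from stimulus onset (half-open, 0-based indexing);
whether a pre-stimulus portion is included is a config choice, with the
post-onset default motivated by the 100-800 ms analysis windows.
Events that spill past the recording edge are dropped with a logged count.
The montage (channel -> region TSV) is an input; the built-in default
partitions the lateral extended 10-20 channels into the six regions and
leaves midline electrodes unmapped, since they have no natural lateralised
home.  Region adjacency is homologous left-right pairs plus
anterior-posterior chains within hemisphere.

## Sleep events

**Slow oscillations.** The signal (frontal/frontocentral channels by
default) is band-passed 0.5-4 Hz (zero-phase Butterworth, order 3).  Every
pair of consecutive positive-to-negative zero crossings bounding a negative
then a positive half-wave is a candidate; acceptance requires full-wave
duration 0.9-2.0 s, trough <= -40 uV and trough-to-peak >= 75 uV.  An
adaptive mode keeps the top 25% of duration-valid candidates by
trough-to-peak amplitude instead of the fixed thresholds; both modes are
config keys because published variants of this detector differ exactly
here.

**Fast spindles.** Band-pass 13-16 Hz, RMS envelope in a 200-ms moving
window, event where the envelope exceeds its per-channel mean + 1.5 SD for
0.5-3.0 s.  The envelope peak is the spindle's reference time; the band
signal minimum inside the event is stored for the trough-referenced
histogram variant.  Mean frequency comes from the zero-crossing count.
Events are detected per channel and deliberately not de-duplicated across
channels, because the coupling histogram normalises per electrode before
averaging.

**Macrostructure.** From a 30-s-epoch hypnogram: TST (non-wake epochs in
bed), sleep-onset latency (lights out to first N1), REM latency (sleep onset
to first R), stage durations and percentages of TST, and efficiency
(TST / time in bed).  Scoring itself is an input, not a computation.

## SO-spindle coupling

For each SO trough, spindle reference times within +-3 s are collected into
48-ms bins (125 bins).  Per electrode: counts / n_SO / 0.048 s gives a rate
in Hz; subtracting the electrode's mean rate over bins removes the baseline;
electrodes of a site group (frontocentral or centroparietal) are then
averaged.  Conservation holds exactly: sum(raw rate) x 0.048 x n_SO equals
the number of binned spindle events.  **Coupling strength** is the mean
centred rate over bins whose centres fall in an up-state interval that must
be given explicitly; the study configuration uses +0.3 to +0.7 s after the
trough, where the synthetic up-state and the empirical up-state effects
live.  The histogram's time axis is trough-centred; a window-start origin
(trough at +3 s) is sometimes seen in figures elsewhere, so axes are always
labelled.

## Statistics

**Cluster-level permutation test.** Cell-wise statistic over the 6 x 40
maps: a pooled-variance two-sample t across groups, or Pearson r across
subjects against a covariate (Fisher-z transformed for cluster mass).
Cells with two-tailed p below the cluster-forming threshold (default 0.05)
are grouped into same-sign connected components under region adjacency x
temporal contiguity; a cluster's mass is the sum of its statistics.  The
null is the maximum |mass| over random relabelings (group shuffles or
covariate permutations); corrected p = (1 + #{null >= observed}) /
(n_perm + 1), so p is never below 1/(n_perm+1).  For small groups an
exhaustive mode enumerates every distinct assignment, making p exact.
The production setting is 10,000 randomizations; simulation suites use
500 for runtime, which changes p by no more than binomial noise.
Uncorrected cluster lists are always reported alongside corrected p-values;
the package does not adjudicate between them.

**Effect sizes.** Cohen's d with the pooled SD; positive d means the first
group's mean is larger.  The 95% CI is a percentile bootstrap over subjects
(raw-data mode); a summary-statistics mode (means, SDs, n) computes d and
the common-language effect size when only group summaries are available.
CL is the McGraw-Wong probability of superiority,
Phi((m1 - m2) / sqrt(s1^2 + s2^2)).

**Behaviour.** d' = z(hit rate) - z(false-alarm rate), with extreme rates
corrected to 1/(2N); the log-linear alternative was rejected to keep the
quantile form literal.  iCV is the intra-individual SD/mean of hit RTs.
Group comparisons use Student's t when both groups pass the
Lilliefors-corrected KS normality screen at 0.05 and Mann-Whitney U
otherwise, with Bonferroni adjustment across the declared number of tests.

## Mixed-effects logistic regression

P(correct | u_j) = logistic(beta . x + u_j), u_j ~ N(0, sigma_u^2), one
random intercept per subject.  The marginal likelihood integrates u out by
*adaptive* Gauss-Hermite quadrature: per subject the integrand is re-centred
on its mode (found by a Newton iteration on the strictly concave
log-integrand) and re-scaled by the curvature there, after which 20 nodes
agree with direct numerical integration to ~1e-10 even for 50-plus trials
per subject.  sigma_u is optimised on the log scale (L-BFGS-B, bounded in
[1e-6, 20]).  Standard errors come from the finite-difference Hessian at
the optimum; coefficients are reported as Wald z, odds ratios and
exp(estimate +- 1.96 SE) CIs.  |estimate| > 15 flags separation and marks
the fit unstable.  AIC = 2k - 2 logL with k counting the intercept, the
fixed effects and sigma_u.

Model building mirrors the analysis design: two parallel models (early vs
late reinstatement window) plus forward-stepwise AIC selection over the
candidate fixed effects, with a VIF screen (threshold 5) that rejects a
candidate before fitting if its addition makes any VIF exceed the
threshold.  Interaction terms are products of the standardized main effects
and are not re-standardized, keeping odds ratios interpretable per SD of
the main effects.  The exact interaction set is named explicitly in the
study config (`coupling x reinstatement` by default) rather than implied.

## Synthetic data

The generator's defaults are the study conditions the analysis assumes:
13 + 14 subjects, 48 items x 4 repetitions + 48 intact retrieval trials,
250 Hz, 1-s epochs, 6 regions.

* **Wake.** Each item owns a fixed region x sample template of 0.5-30 Hz
  band-limited Gaussian noise.  Repetition k is
  sqrt(rho) * template + sqrt(1-rho) * fresh noise, so the expected
  correlation between any two repetitions equals rho (NSD default 0.6, ASR
  0.35).  Retrieval mixes the template at a latency-dependent template
  correlation: 0.5 in the 150-350 ms window, 0.4 in the 350-700 ms window,
  0 elsewhere.
* **Sleep.** Pink (1/f) background, RMS 15 uV.  Slow oscillations are a
  brief negative half-sine (trough -120 uV +-10%, 30% of the wave) followed
  by a broader positive half-sine at half amplitude, full wave 1.0-1.5 s,
  placed with a refractory-plus-exponential point process at 5/min.  The
  sharp down-state matches canonical SO morphology, keeps the planted trough
  a local minimum of the band-passed noisy signal within +-40 ms, and gives
  steep zero crossings so the measured full-wave duration equals the planted
  one.  Each SO seeds spindle bursts (13-16 Hz, 1 s, Tukey envelope, 25-uV
  envelope peak) whose centre offset from the trough is von Mises around
  +0.45 s with concentration kappa, scaled so kappa = 0 is uniform over one
  SO cycle.  Events are planted on all channels over independent noise.
* **Outcomes.** Bernoulli(logistic(beta . x + u)) with known beta over the
  standardized trial predictors and u ~ N(0, sigma_u^2).

One master seed; per-subject streams are spawned deterministically from it,
so any single subject can be regenerated bit-identically.

What the generator does *not* emulate: volume conduction and realistic
topography, artifacts (ocular/muscle), non-N3 sleep microstructure,
stimulus-evoked potentials superimposed on the similarity structure, and
item-difficulty heterogeneity.  Passing recovery tests therefore shows the
*estimators* are correct and calibrated under the assumed generative
structure — not that real recordings satisfy that structure.

## Problem sizes and numerical choices

Simulation suites run at reduced scale chosen as the package's test budget:
FWE calibration uses 500 null datasets x 500 relabelings (the acceptance
script uses 500 x 500); coefficient-coverage uses 200 replicates of
30 subjects x 50 trials; per-subject synthetic N3 defaults to 20 min
(10 min in the analysis drivers).  r is clipped at 1 - 1e-7 before atanh;
correlations on zero-variance cells are excluded from clustering; quadrature
uses 20 nodes (tests verify convergence against 25-30 and against direct
integration); the FIR design validates the order against the Kaiser length
formula at a 40-dB floor.  Ties in stepwise AIC resolve to the first-listed
candidate.  All permutation and bootstrap machinery is seeded and
reproducible.

## Known limitations

* The GLMM supports a single random intercept only (no random slopes or
  crossed effects), matching the analysis design.
* Wald CIs can undercover near separation; the `unstable` flag marks such
  fits but does not repair them.
* The spindle detector's fixed SD threshold assumes reasonably stationary
  background power within the analysed N3 stretch.
* The six-region default montage is a convention; analyses of real data
  should supply the recording's own montage file.
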