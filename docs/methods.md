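# Methods

## Hypnodensity construction and consensus

A hypnodensity row is the weighted vote share of each stage across the
panel: with uniform weights, entries are integer multiples of
1/n_scorers.  Scorer weights, when requested, are each scorer's mean
pairwise Cohen's kappa against the rest of the panel, floored at zero and
normalized to sum 1.  This is one of several possible kappa-weighting
conventions (an alternative weights against an interim consensus); mean
pairwise kappa was chosen because it is symmetric, needs no reference
scoring, and reduces to uniform weights for an internally consistent
panel.  A scorer whose labels leave kappa undefined against every peer
(constant output matching a constant peer) raises a degenerate-scorer
error rather than receiving an arbitrary weight.

Consensus is a weighted per-epoch majority vote.  Weighting usually
breaks ties, but a residual deterministic rule is still required: ties go
to the stage backed by the single heaviest scorer among the tied stages,
then to a sleep stage over W, then to vocabulary order (W, N1, N2, N3,
R).  Stage codes are case-insensitive on input and canonicalized.

Two stage-assignment rules are provided.  Argmax takes the most probable
stage (ties to the earlier vocabulary stage).  The hierarchical cascade —
W if p_W > 0.5; else R if p_R exceeds the summed NREM probability; else
N3 if p_N3 > p_N1 + p_N2; else N2 if p_N2 > p_N1; else N1 — scores an
epoch as sleep whenever combined sleep probability dominates, even when W
is the single most probable stage.  All comparisons are strict, so p_W
exactly 0.5 yields sleep.  Epoch duration defaults to 30 s and is carried
on every container, so other durations work throughout.

The four-stage (cardiorespiratory/HSAT) vocabulary W, LS, DS, R is
reached by summing N1 and N2 into LS and renaming N3 to DS; row sums and
wake probability are preserved exactly.

## Agreement statistics

Cohen's kappa is the unweighted (p_o − p_e)/(1 − p_e) on the 5×5
confusion matrix; p_e = 1 is signalled as undefined.  The agreement curve
reports, for each panel size k, the percentage of epochs where all k
scorers agree, averaged over scorer subsets of size k.  Averaging over
unordered subsets equals averaging over ordered permutations (epoch-wise
complete agreement is order-invariant), so enumeration over combinations
is exact and far cheaper; when C(n, k) exceeds a threshold (default
10,000) a seeded Monte Carlo subsample is used and flagged.  The curve is
non-increasing in k by subset containment.

The power-law model y = a·k^b is fitted by nonlinear least squares on the
raw percentage scale, initialized from the ordinary least-squares
solution in log–log space; R² is reported on the raw scale.  A log–log
fit alone would re-weight small agreement values; the raw-scale fit and
raw-scale R² match how the model's explained variance is normally
quoted.  The fit requires at least three distinct k values and strictly
positive agreements.

Probability curves are compared with ICC(A,1) — the McGraw–Wong two-way
random-effects, single-rater, absolute-agreement ICC, computed from the
two-way ANOVA mean squares with epochs as subjects and the two curves as
raters — per stage, as the macro mean over stages, and as a micro average
on the concatenated per-stage curves.  Absolute agreement penalizes
systematic offsets, unlike a plain correlation.  Qualitative labels
(poor/moderate/good/excellent at 0.5/0.75/0.9) are annotations only.
Average cosine similarity (ACS) is the mean per-epoch cosine between
paired probability rows; both ACS and micro-ICC equal 1 only for
identical hypnodensities.

## Sleep parameters and hypnodensity features

Hypnogram parameters follow the standard report conventions: TST counts
non-W epochs; sleep latency runs from lights-off to the first sleep
epoch; REM latency from sleep onset to the first R epoch; WASO counts W
epochs strictly between sleep onset and the last sleep epoch (trailing
wake is excluded from WASO and counted only in recording time); sleep
efficiency is TST over the analysis duration.  Undefined quantities (no
sleep, no REM) propagate as NaN, never as zero.

Hypnodensity parameters integrate each stage's probability curve: stage
minutes = Σ_epochs p_stage × epoch minutes.  By linearity, for a
uniform-weight panel these equal the mean of the per-scorer stage minutes
exactly — the identity the test suite asserts on random panels.  Sleep
onset is the first epoch whose sleep probability exceeds its wake
probability (p_W < 0.5).  The probability analogues of WASO (wake
probability integrated strictly between onset and the last sleep-dominant
epoch) and REM latency (first R epoch of the hierarchical assignment
after onset) are package conventions: only the stage areas and the onset
rule are fixed by the construction, and both choices reduce to the
hypnogram definitions on one-hot input.

Feature denominators (NREM/REM membership) come from the hierarchical
assignment, the rule used for reported staging, not from argmax.  The
ambiguity threshold (p_max ≤ 0.95, boundary inclusive) and the stability
rule (p_N2+p_N3 > 0.95, resp. p_R > 0.95, strict, in both epochs of an
adjacent same-class pair) are as defined; empty denominators yield NaN.
The printed depth formula is normalized to 100·(p_N1 + 2·p_N2 +
4·p_N3)/4 so that pure N1/N2/N3 epochs score 25/50/100, and the
continuity bracketing to 100·(1 − |Δp_max|).  Whether "same class" for
continuity means the same assigned stage or the same W/NREM/REM class is
ambiguous in the source material; the same assigned stage is the default,
with the coarser class comparison available as an option.

## SDB metrics

Events are attributed to sleep state by the epoch containing their
termination, consistent with termination-anchored desaturation analysis.
AHI divides state-attributed event counts by state hours (events
terminating in wake count toward no AHI); REI divides all events by
monitoring hours, hence REI ≤ AHI whenever monitoring time ≥ TST.

Hypoxic burden follows the Azarbarzin convention: per event, baseline =
maximum SpO2 in the 100 s preceding the termination (configurable), and
the area of max(0, baseline − SpO2) is integrated (trapezoidal) over a
search window positioned at the termination, in %·min; HB is the summed
area per hour of sleep, with NREM/REM components splitting events by
terminal state and normalizing by state hours.  The sum of per-event
areas equals HB × TST hours by construction.

Two numerical choices deserve note:

* **Baseline under sampling noise.**  The true saturation varies slowly,
  so on a noisy trace the raw per-sample maximum overestimates the
  baseline by the extreme-value bias of the noise (~2.5 σ at 1 Hz over
  100 s), which inflates every event's area.  The maximum is therefore
  taken on a centred moving-average copy of the trace (default width
  60 s — long enough to suppress sampling noise, shorter than typical
  inter-event spacing); the raw trace is still what is integrated.
  Width 0 restores the raw maximum.  On noiseless traces the two are
  identical.
* **Search-window derivation.**  The exact rule for the subject-specific
  window is not printed in the source material; this package derives it
  from the ensemble-averaged desaturation curve (all events aligned at
  termination; default window −60 s to +120 s, the pre side short enough
  not to reach the previous event).  Baseline for the scan is the mean of
  the earliest quarter of the pre-termination segment; the window is the
  contiguous below-baseline run containing the curve's nadir, snapped to
  sample resolution.  A curve never dipping below baseline yields a
  zero-width window, flagged.  A fixed (pre, post) window can be supplied
  instead.

Events whose search window leaves the trace, or overlaps an SpO2 dropout
longer than the 3 s interpolation limit, are excluded and counted in a
diagnostics field; the baseline lookback truncates at the trace start
rather than excluding the event.  HB and AHI are invariant to the
sampling rate up to O(1/rate) discretization error.

The REM-related OSA rule is literal: AHI_NREM < 5 (strict) and
AHI_REM ≥ 5 with at least 30 min of REM sleep.

## Synthetic data

The generators define the study conditions for all tests.  The latent
hypnogram is a first-order Markov chain over the five stages
(`presets.yaml`, preset `adult_sleep`); it reproduces plausible stage
proportions and bout lengths but **not** the ~90-minute REM periodicity
or the within-night redistribution of deep sleep — features irrelevant to
the agreement and burden statistics under test but important for any
claim about real sleep architecture.  Scorer panels draw each label from
a per-scorer confusion row conditioned on the true stage, independently
across scorers and epochs; correlated scorer errors (shared training,
drift) are deliberately out of scope.  The shipped templates span a
precision-to-sensitivity axis for N1/N3 calling — the documented source
of most human inter-scorer variance — and the `typical` template yields
pairwise agreements near the ~0.76 level reported for experienced
scorers, producing agreement curves whose power-law exponents fall in the
observed −0.3 to −0.75 range.  Hypnodensities are Dirichlet rows centred
on the true stage (α = concentration on the true stage, 1 elsewhere);
concentration → ∞ gives one-hot rows, concentration 1 the symmetric
Dirichlet.  Oximetry is a constant baseline (default 95%) plus optional
Gaussian noise, with a trapezoidal desaturation trailing each event
termination (default: 5 s delay, 10 s fall, 20 s hold at −4%, 15 s rise,
at 1 Hz — a moderate-OSA profile); the analytic trapezoid areas are
returned so burden estimates can be validated against ground truth.
Passing tests on these inputs demonstrate the estimators' correctness and
calibration, not robustness to artefacts, motion dropouts, or oximeter
quantization, none of which are modelled.

All generators are pure functions of (parameters, seed).  Test problem
sizes (up to 20,000 epochs for independence checks, 100 replicates for
power-law recovery, hour-scale oximetry at 1–10 Hz) were chosen so the
standard errors of the Monte Carlo oracles are small relative to the
asserted tolerances.

## Known limitations

* Agreement weighting implements mean pairwise kappa only; kappa against
  an interim consensus is not provided.
* No Fleiss kappa, Krippendorff alpha, or bootstrap confidence intervals.
* No AASM context smoothing of R/N2 (requires arousal/spindle/K-complex
  events), no event detection from airflow, no EDF ingestion.
* The hypnodensity WASO/REM-latency conventions above are package
  definitions; alternative conventions would differ on highly ambiguous
  nights.
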