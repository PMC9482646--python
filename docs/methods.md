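# Methods

## Model

The model explains underestimation in temporal numerosity judgment (TNJ)
as a by-product of temporal integration of a population code for
numerosity.

**Tuning.** Ten units (configurable 7–13) prefer numerosities 1..10.
Unit *i* responds to the *k*-th vibration of a sequence with mean rate
`A·exp(−(log2 k − log2 i)²/(2σ_t²))`: numerosity tuning is Gaussian on a
log2 axis, and the unit tuned to *n* is driven by the *n*-th signal of a
train. The peak rate `A` (spikes per presentation, default 10) is not a
free parameter: the decoder is scale invariant, so `A` only sets the
Poisson signal-to-noise ratio of a single presentation. Rates are
homogeneous across units.

**Spiking.** Each presentation draws independent Poisson counts at these
mean rates — the population response to that vibration.

**Temporal window.** Vibrations are mapped onto the time axis with the
last onset at 0 ms and earlier onsets at −SOA, −2·SOA, …. A Gaussian
gain centered at 0 ms with SD `σ_w` (ms) multiplies each presentation's
counts; the gain is exactly 1 at 0 ms and is deliberately not normalized
to unit sum (normalization would cancel in the decoder). The window is
evaluated only at vibration onsets, so truncation before the first
vibration never arises. Gained counts are summed per unit over the
sequence.

**Repetitions.** The spiking-plus-integration stage is repeated 100
times (configurable); the integrated per-unit responses are averaged
element-wise across repetitions and decoded once. Averaging versus
summing is immaterial to the decoder (scale invariance); each repetition
uses its own substream spawned deterministically from the seed, so
results are independent of evaluation order.

**Decoding.** `N = 2^(Σ_i (S_i/ΣS_i)·log2 i)` — a weighted average of
preferred numerosities on the log2 axis. Any fixed logarithm base gives
the identical `N`; base 2 is used throughout. `N` always lies within
[1, 10]; an all-zero response raises an error rather than returning a
fallback (the fitting layer converts it to an infinite loss). Preferred
numerosities stay fixed at 1..10 regardless of the 2..6 stimulus range;
mass falling beyond unit 10 is simply truncated, not renormalized.

**A discretization caveat.** Because the integers 1..10 are unevenly
spaced on the log2 axis (denser above a small count than below it), the
decoded value of a profile centered on a small numerosity is biased
slightly upward. Consequently the intuition "the decoded value never
exceeds the true count" holds without exception only in the regime that
matters for fitting human data (σ_t ≲ 0.6 log2 units with windows of
a few hundred ms or more); with broad tuning and narrow windows the
model can *over*estimate small counts by a few tenths. This is
documented in the tests and is consistent with humans showing no
underestimation at n = 2.

## Fitting

Two free parameters: `σ_t` (tuning SD, log2 units, bounds [0.05, 3]) and
`σ_w` (window SD, ms, bounds [1, 2000]); the bounds comfortably contain
every fitted value we observe. The objective is the mean absolute
difference between the model's decoded numerosity and the target value
over the 4 SOA × 5 number design cells. The default target is the mean
reported numerosity per cell; fitting to the *actual* count instead is
selectable (`objective_target="actual_number"`) but drives `σ_w → 0`
and near-veridical decoding, so it cannot produce underestimation — the
human-means target is the default for that reason.

The minimizer is sequential model-based (Bayesian) optimization written
against scikit-learn: 10 uniform-random evaluations, then a Matern-5/2
Gaussian-process surrogate (normalized inputs; `σ_w` searched on a log10
axis since it spans three decades) with expected-improvement acquisition
maximized over 1024 random candidates per iteration. Budgets are
nested: the first k evaluations are identical for any budget ≥ k under
the same seed. A run performs 50 evaluations; 20 independent runs give
the parameter mean and a t-based 95% CI. Each run fixes one simulation
seed for all of its objective evaluations (common random numbers), so
the surrogate sees a deterministic function; a noise-free "oracle"
objective (Poisson draws replaced by their means) is available for
parameter-recovery tests, where the fitted SDs return the generating
values well within ±20% (typically within a few percent).

## Behavioral analysis

Exclusions: a participant is dropped when catch-trial accuracy is below
15/16 (93.75%), when more than 5% of the 80 vibration trials are
answered "0" (4/80 = 5% exactly is retained), or when the trial count is
not 96. "Correct" on a catch trial means reporting exactly 0.
Responses outside 0..9 are schema errors, never clipped.

Condition means average the 4 repetitions per (SOA, number) cell;
difference scores are mean reported − actual (negative =
underestimation). One-sample t-tests of the differences against zero
are Holm-corrected within one display panel's family of 20 cells (whole
sample, or each age band when grouped); Cohen's d = (m − μ)/s with the
n−1 sample SD. Cells with zero SD are flagged, not dropped.

The three-way mixed ANOVA (age band between; SOA and number within) is
computed by projecting each participant's 20-cell vector onto
orthonormal Helmert-contrast bases for each within effect, which yields
the classical univariate strata exactly for balanced-within data and
handles unequal group sizes. Greenhouse–Geisser ε comes from the pooled
within-group covariance of the contrast scores and rescales only the
degrees of freedom of within effects (F ratios are unchanged);
generalized η² puts all subject-stratum error SS in the denominator.
During development the implementation was verified against R's `aov`
and `car::Anova` (with sum contrasts) to print precision; the shipped
test oracle is an independent brute-force marginal-means computation.

## Synthetic data generator

The generator emulates the study conditions: five age bands with
51/50/52/51/52 participants, a 96-trial factorial per participant
(4 SOAs × {0, 2..6} vibrations × 4 repetitions; the 16 zero-vibration
trials are catch trials), and pseudo-random per-participant trial order.
Each band has its own (σ_t, σ_w); the defaults (0.45/200 through
0.65/600 across bands) make both SDs grow with age, the window most
sharply in the 60s band, reproducing the observed age-graded
underestimation. An attentive participant's report is the band's
noise-free decoded numerosity for the trial's cell plus Gaussian
response noise (SD 0.5 — the simplest mechanism giving integer reports
with model-governed means), rounded and clipped to the 0..9 keypad;
catch trials are answered 0 with probability 0.99. A configurable
fraction of participants (default 0.14, matching the study's 36/256
exclusion rate; per-band fractions supported) responds uniformly at
random and reliably trips the catch-trial filter.

What the generator does *not* emulate: sequential effects and learning
across trials, device heterogeneity, reaction times, response biases
other than the model's own, and any misfit between the population-coding
model and real observers. Tests passing on synthetic data therefore
demonstrate that the pipeline is correct and self-consistent — that the
filters, statistics and fits recover what was planted — not that the
model is an accurate account of any particular empirical dataset.

## Evaluation

Model–data agreement over the 20 cells is summarized by the squared
Pearson correlation (r²; chosen over the coefficient of determination
because agreement between two mean series is a correlation question —
the residual report preserves offsets and direction) and the mean
squared error. Fivefold cross-validation partitions the 20 design cells
(not participants) into 5 folds of 4, fits on 16 cells and scores the
held-out 4, iterated with fresh random splits (default 20); fold fit
failures yield NaN rows rather than aborting. Per-age-band reports
rerun exclusions, means and the fit ensemble within each band.

## Problem sizes and numerics

Defaults follow the study design (100 repetitions, 50 optimization
calls, 20 runs, 20 iterations of CV). The test suite and the acceptance
script scale some of these down — fewer participants per band in most
synthetic studies, 5 CV iterations at 25 calls in the acceptance script
— chosen so the full statistical structure is exercised while runs stay
in the minutes range; the full-scale settings are plain configuration.
Monte-Carlo-versus-oracle agreement is asserted at 10⁴ repetitions with
absolute tolerance 0.05; decoder identities at 10⁻¹² relative tolerance;
ANOVA against its brute-force oracle at 10⁻⁸. Ties in expected
improvement resolve to the first maximizer; infinite objective values
are excluded from surrogate fitting, and a fit run fails only if every
evaluation was infinite.
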