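# Methods

## Problem and model

`accuprof` implements total-error validation of a quantitative bioanalytical
assay by accuracy profile. A method is acceptable over a concentration range
when, at every tested level, the difference between a single future
measurement *x* and the true value *μ_T* stays inside predefined acceptance
limits ±λ with probability at least β:

    P(|x − μ_T| < λ) ≥ β.

The experimental design is the standard balanced one: validation standards
(VS) at several nominal concentrations, each measured on *p* series (days)
with *n* replicates per day, against day-matched calibration standards (CS).
The defaults mirror a typical plasma-assay validation: p = 3 days, n = 4 VS
replicates (CS in triplicate), β = 0.95, λ = 15 %.

Back-calculated concentrations at one level are modelled as a balanced
one-way random-effects layout

    x_ij = μ + τ_i + ε_ij,   τ_i ~ N(0, σ_B²),   ε_ij ~ N(0, σ_W²),

with day effect τ and within-day error ε. Repeatability variance is σ_W²;
intermediate-precision variance is σ_IP² = σ_W² + σ_B².

## Estimators

Variance components use the method-of-moments ANOVA estimator on the p×n
matrix: s²_W = MS_within, s²_B = (MS_between − MS_within)/n. **s²_B is not
truncated at zero.** Published validation tables routinely print an
intermediate-precision RSD below the repeatability RSD, which can only arise
from a negative s²_B; truncating would also break the exact reproduction of
published tolerance limits from summary triples (see below). When the implied
variance ratio is so negative that nR + 1 ≤ 0 (which cannot occur from a raw
p×n matrix but can from inconsistent summary inputs), the interval falls back
to R = 0 with a warning.

Relative quantities are expressed against the *nominal* concentration:
bias % = 100 (x̄ − μ_T)/μ_T, RSD_r = 100 s_W/μ_T, RSD_IP = 100 s_IP/μ_T.
Using the nominal rather than the observed mean keeps bias and precision on
the same scale; at biases within ±10 % the difference is second order.

## β-expectation tolerance interval

The interval for a single future result is of the Mee type, computed on the
relative-error scale:

    [bias − k·RSD_IP,  bias + k·RSD_IP],
    k = t_{(1+β)/2, ⌊ν⌋} · sqrt(1 + 1/(p n B²)),
    B² = (R + 1)/(nR + 1),   R = s²_B / s²_W,

with ν the Satterthwaite effective degrees of freedom of s²_IP,

    ν = (R+1)² / [ (R + 1/n)²/(p−1) + (1 − 1/n)/(p n) ],

**floored to an integer** (minimum 1) before the t quantile. The floor is
deliberate: against published 3×4 validation tables, non-integer ν misses the
printed limits by 0.5–3 %, while ⌊ν⌋ reproduces 11 of 12 printed limit pairs
to better than ±0.02 percentage points. (The twelfth row of that table is
internally inconsistent — its printed limits do not follow from its printed
bias/RSD triple under any df convention we tried — and is treated as a
transcription artefact.)

Because the interval is a deterministic function of (bias, RSD_r, RSD_IP, p,
n, β), the package exposes a summary-triple entry point
(`level_statistics_from_summary`, `MethodValidation.from_summary`) that
reproduces published tables without raw data, alongside the raw-matrix entry
point.

Degenerate inputs: a level whose replicates are all identical (RSD_r = 0)
gets the point interval [bias, bias]; RSD_r = 0 with RSD_IP > 0 is rejected
as inconsistent.

## Decision rule and LLOQ/ULOQ

A level is valid iff max(|lower|, |upper|) ≤ λ; boundary equality counts as
valid (the acceptance inequality is non-strict). The validated range is the
contiguous run of valid levels ending at the highest valid level. Where a
tolerance-limit curve crosses ±λ between adjacent levels, the crossing is
located by linear interpolation on the concentration axis (not
log-concentration: the simplest defensible rule, and immaterial when all
levels pass, as in the worked examples). LLOQ/ULOQ are undefined when no
level is valid.

## Calibration

Calibration is a straight line fitted per series (day) to that day's CS
response ratios (analyte area / internal-standard area) against nominal
concentration; VS are back-calculated by exact inverse prediction against
their own day's curve. Day-matched calibration keeps day effects in the VS
data estimable and absorbs day-level extraction and instrument drifts.
Weighted least squares with 1/x or 1/x² weights is available; the default is
unweighted, but for wide calibration ranges (50-fold here) 1/x² weighting is
strongly recommended — with unweighted fits, intercept estimation error
propagates into large relative errors at the bottom of the range. Negative
back-calculated concentrations are retained: clipping would bias low-level
statistics.

## Extraction recovery

Recovery per determination is 100 · (extracted peak area)/(non-extracted
reference area); the per-level figure is the mean over its determinations,
and the overall figure is the unweighted mean of per-level means with the
sample SD of those means.

## Synthetic data generator

The generator emulates the assumed data structure so the whole pipeline is
testable without laboratory data.

* **Concentration mode** draws x_ij = μ_T(1 + δ/100) + τ_i + ε_ij directly
  (per-level δ, σ_B %, σ_W %). Day effects are drawn independently across
  levels; cross-level day correlation is not modelled.
* **Response mode** additionally simulates the measurement chain:
  response = intercept + slope · c_true · recovery · (1 + noise), with
  multiplicative response noise (default CV 0.5 %) and one extraction-
  recovery factor drawn per series — all samples of a day are treated as one
  extraction batch, so the day-matched calibration absorbs the day's yield,
  as it does in practice. (Drawing recovery per series×level instead would
  inject an uncancelled ~√2·recovery-CV batch effect into the back-calculated
  VS and produce intermediate-precision RSDs far above what published tables
  show.) Matching non-extracted reference areas are emitted for recovery
  statistics.

Default scenarios (`afatinib_like_params`, `ibrutinib_like_params`) use the
published designs (3×6 levels over 5–250 and 5–400 ng/mL) with per-level
bias and SDs set to the published summary magnitudes, and extraction yields
0.88 (CV 2.5 %) and 0.93 (CV 9.7 %). All randomness flows through one
`numpy.random.Generator` seeded from `SimulationParams.seed`.

What passing tests on synthetic data do **not** show: real chromatographic
data have non-Gaussian tails, heteroscedastic integration noise, carryover
and matrix effects, none of which are modelled; the generator validates the
statistics, not the chemistry.

## Coverage of the interval, and a caveat

`simulate_coverage` checks the defining property empirically: simulate an
experiment, compute the interval, draw one fresh observation from the same
model, repeat. At p = 3, n = 4, β = 0.95 the measured expected coverage is
0.950 at σ_B/σ_W = 0.5 and 0.954 at σ_B = 0 (20,000 experiments). The
approximation degrades when between-day variance dominates with so few days:
0.939 at σ_B/σ_W = 1 and 0.928 at σ_B/σ_W = 2. This mild undercoverage is a
known property of Satterthwaite-based β-expectation intervals at small p, not
an implementation artefact; with day-to-day variability that large, a 3-day
validation design is simply underpowered.

A related statistical point: with true RSD ≈ 5.6 % at a level (as published
at the 5 ng/mL levels), a 3×4 experiment produces tolerance limits beyond
±15 % roughly 40 % of the time. A single passing validation at such a level
is therefore partly fortunate; the simulation utilities make this easy to
quantify.

## Numerical choices

* Satterthwaite ν floored (min 1); t quantiles from scipy, memoised per
  (β, ν) for Monte-Carlo loops.
* Unbalanced designs are rejected by the statistics (the closed-form ν and B²
  assume balance); the reader only flags them.
* Profile CSV round-trips floats at 17 significant digits (< 1e-9 error).
* Parameter-recovery tests compare SD estimates on the unbiased variance
  scale; on the SD scale the estimator carries the usual c₄ small-sample
  factor (≈ 0.973 at 9 df), which is expected, not an error.

## Problem sizes in the test-suite and reproduction script

Monte-Carlo checks use 10,000 experiments for interval coverage (standard
error ≈ 0.2 percentage points), 1,000–2,000 for parameter recovery, and 120
end-to-end pipeline runs; the exhaustive variance-component sweep covers
every integer matrix in [0,3] of shapes 2×2, 2×3, 3×2 plus randomised larger
shapes. These sizes put Monte-Carlo error well inside each assertion's
tolerance.
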