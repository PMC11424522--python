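# Methods

## Model

Each (sex, completed-year age, measure) cell is modelled by the
three-parameter Box–Cox-normal (Cole–Green) distribution: for a positive
measurement *Y*, `Z = ((Y/M)^L − 1)/(L·S)` is standard normal, with the
log-normal limit `Z = ln(Y/M)/S` at `L = 0`. L captures skewness, M is
the median, S the coefficient of variation. Centiles and z-scores are
closed-form inverses of one another; the package computes the centile as
`M·exp(log1p(L·S·z)/L)`, which is algebraically identical to
`M·(1+L·S·z)^(1/L)` but stays accurate as `L → 0`, and switches to the
log form below `|L| < 1e−7`. Normal quantiles always come from SciPy's
inverse CDF at full floating precision — published table cells only
reproduce with full-precision z, never with 1.28/1.64-style lookups.

The density's positivity truncation term is omitted, the standard
Cole–Green practice; for the S values seen in adolescent anthropometry
(0.04–0.25) the truncated mass over the reported percentile range is
negligible.

## Fitting

Age is treated as integer groups (the artifact being produced is a
per-age table, not a continuous curve), so each cell is fitted
independently by maximizing the Box–Cox-normal log-likelihood

`ℓ(L,M,S) = Σ [(L−1)·ln y − L·ln M − ln S − ½ln 2π − z²/2]`

with a bounded Nelder–Mead simplex, started at `(L=1, M=median,
S=sd/mean)` and restarted once from its own optimum to polish. Bounds:
`L ∈ [−5, 7]`, `S ∈ (10⁻⁴, 1)`, `M` within a wide data-driven band. The
fit is deterministic, and the sample is sorted internally (the
likelihood is permutation-invariant) so any reordering of the same
records yields a bitwise-identical fit. Cells below the minimum group
size (default 20 — three-parameter maximum likelihood is unstable below
that) raise an error unless skipping is requested; all-equal samples are
rejected as degenerate. In tests the optimum is checked against a
brute-force 50×50×50 grid over (L, M, S).

Optional cross-age smoothing replaces each of the L/M/S series with a
least-squares polynomial of `edf − 1` degrees evaluated on the age grid;
`edf` equal to the number of ages is the interpolation limit (series
unchanged). The default is **no smoothing**: with five age groups of
~300 subjects the per-age fits are already smooth in practice, and raw
per-age values are what the published table format contains.

## Percentile sets and rendering

Height and weight tables report {P3, P10, P35, P50, P65, P90}; BMI
reports {P5, P15, P50, P85, P90, P95}. Both are overridable. Published
rendering rounds half-away-from-zero to 2 decimals; internal values are
never rounded, so tables stay invertible. Written reference files carry
L/M/S at full precision (and are re-read with round-trip float parsing)
next to the 2-dp display columns.

## Validation (back-substitution)

A seeded simple random subsample without replacement is drawn within
each (sex, age, measure) group — default fraction 0.5, chosen because
the source procedure only says "a small dataset"; the stratified scheme
preserves the survey design. The model is refitted per group and the
refitted median compared with the full-data median as a signed relative
error `(actual − fitted)/actual`. Two summary quantities are reported
deliberately: the mean of the *unrounded signed* errors (the quantity
the published validation table prints per row and averages, with
inconsistent rounding between measures) and the true MAPE (mean absolute
percentage error). Lewis classification uses the true MAPE, with
boundary values (10, 20, 50%) assigned to the *higher* band since
"below 10%" excludes 10. With fraction 1 the refit sees the identical
multiset and returns exactly zero errors.

## Comparison with external standards

External references supply medians only, so the comparison is
`local P50 − external P50` per overlapping key, with min/max/mean per
source, sex and measure. Missing external cells (e.g. WHO weight) are
absent, never zero. A >3× ratio between local and external medians
raises a unit-mismatch error.

## Synthetic cohorts

The generator inverts the LMS transform on seeded standard-normal draws
per cell, so the generated data satisfy the model's own distributional
assumption exactly; z-scoring a generated cell against its generating
triple returns standard-normal values (checked by Kolmogorov–Smirnov).
Defaults mirror the emulated survey: ages 12–16, both sexes, 297
subjects per cell (2,970 total, matching the study's realized sample of
~295–300 per age–sex group), generating parameters taken from the
packaged published height/weight table. Design labels (3 strata × 20
schools × 50 students) can be attached for design-aware tests; they do
not alter distributions.

Choices where the emulated survey is silent:

- **Height–weight dependence.** Within a child, the height and weight
  z-draws share a Gaussian-copula correlation ρ, default 0.5 — some
  positive dependence is physiologic, but the true value is unknown, so
  ρ is an exposed parameter, not an estimate. BMI is derived
  arithmetically from the sampled height and weight (`derive_from_hw`),
  keeping records internally consistent; `independent_lms` mode instead
  samples BMI from its own triple when distributional fidelity to a
  published BMI table matters more than record-level consistency.
- **Ages** are uniform within the completed year, because the model
  treats age as integer groups.
- **Box–Cox positivity** is enforced by rejection sampling with a hard
  1% cap on the rejection rate; silent truncation would bias the
  parameter-recovery tests, and a higher rate signals implausible
  parameters.

What passing tests on these cohorts shows: the estimator recovers the
parameters of data that follow the model, and the pipeline's arithmetic
is correct. What it does not show: robustness to the ways real survey
data deviate from Box–Cox normality (measurement rounding to 0.1 cm/kg,
digit preference, cluster effects, secular trends within a school year).

The cluster-survey sample-size helper implements
`n = ceil(Z²·P·Q/e² · D)`; with the conventional inputs (P = 0.4,
Z = 1.96, e = 0.05, D = 1) it gives 369.

## Known limitations and data caveats

- The packaged published reference table contains internal
  inconsistencies which the package reports but does not imitate: the
  girls' BMI off-median cells do not follow the LMS transform at their
  own printed L/S/M; the girls' weight P65/P90 cells at ages 15 and 16
  appear swapped between the two rows; and four boys' BMI cells sit
  0.02 from their row's parameters (the level expected from parameters
  printed at three decimals). The transform is never contorted to match
  such cells.
- No four-parameter (BCT/BCPE) extension: kurtosis is not modelled.
- Cross-sectional only; no within-child velocity modelling.
- Problem sizes in the test suite (cells of 50–10,000; full pipeline at
  297 per cell) were chosen to exercise every contract at the emulated
  study's scale while keeping the default run fast.
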