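# Methods

## Population model

Each population condition is a (k+1)-variate standard normal vector:
k predictors with a compound-symmetric correlation block
(1 − ρ_xx)·I + ρ_xx·J and one outcome correlated ρ_xy with every
predictor. Given a target squared multiple correlation ρ²_yŷ, the
common validity solves

    ρ²_xy = ρ²_yŷ · (1 + (k−1)ρ_xx) / k,

which follows from R² = r′R_xx⁻¹r with an equal-validity vector, because
the compound-symmetric block maps the constant vector to
(1 + (k−1)ρ_xx) times itself. The squared population structure
coefficient is then the ratio

    ρ²_xŷ = ρ²_xy / ρ²_yŷ = (1 + (k−1)ρ_xx) / k,

independent of ρ²_yŷ. Only the nonnegative validity root is used;
negative-validity populations are outside the design. Feasibility
requires ρ_xx > −1/(k−1) (positive-definite predictor block) and an
implied ρ²_xy ≤ 1; the assembled joint matrix must have smallest
eigenvalue above 1e−10, otherwise construction fails loudly — silently
near-singular populations would corrupt everything downstream.

The study grid crosses ρ²_yŷ ∈ {0.2, 0.5, 0.8}, ρ_xx ∈ {0.1, 0.3, 0.5},
n ∈ {20, 40, 60, 100, 200}, k ∈ {2, 4, 8}: 135 design cells, 27 distinct
populations. Cells are enumerated lexicographically by
(k, ρ²_yŷ, ρ_xx, n); the ordinal position is the stable `cell_id` that
keys the per-cell random stream. Every cell satisfies n > k + 3, which
keeps the shrinkage denominators positive.

Printed-parity columns use decimal half-up rounding via `Decimal` on the
float's shortest repr: several analytic values are exact decimal
midpoints (0.275, 0.475, 0.2125) that binary bankers rounding would
misprint.

## Sample estimators

All coefficients are computed from the sample Pearson correlation matrix
(n−1 denominator): standardized betas solve R_xx β = r_xy, R² = r_xy′β,
and the squared structure coefficient of predictor j is r²_xy[j]/R².
This is algebraically identical to correlating the predictor with the
fitted scores, which a dedicated test verifies to 1e−10. Samples with
R² below 1e−12 have undefined structure coefficients; they are recorded
as NaN with a flag and excluded only from structure-coefficient
summaries (measure-zero under this design, but the path is exercised in
tests). A singular sample predictor correlation matrix raises a
degenerate-sample error rather than producing pseudo-inverse estimates.

The simulation's hot path is a vectorized variant: one einsum produces
all replicate cross-product matrices and one batched solve fits all
normal equations, which is what keeps a full 135-cell, 1000-replicate
run around five seconds on one core. The batch and scalar paths are
cross-checked against each other in the tests, and the scalar path
against an independent closed-form 2×2 solve.

## Shrinkage correction

Pratt's adjustment of a squared correlation, with N the sample size and
p the number of predictors:

    adj = 1 − [(N−3)(1−R²)/(N−p−1)] · [1 + 2(1−R²)/(N−p−2.3)].

The constant 2.3 is part of the formula. Negative values are clamped to
zero. R² is corrected with p = k; each squared validity is corrected as
a one-predictor model (p = 1), following the literature's practice of
applying R²-correction formulas directly to Pearson r². The corrected
squared structure coefficient is composed from the clamped pieces in
this order:

1. corrected R² = 0 → 0 (the division guard comes first);
2. corrected r²_xy > corrected R² > 0 → 1 (ratio capped);
3. otherwise the plain ratio.

The ordering matters at the clamp mass points: treating a positive
corrected validity over a zero corrected R² as "greater than" (branch 2)
instead of zeroing it shifts the pooled corrected-structure bias from
about −0.012 to about −0.004 and visibly changes its spread. The
zero-guard order is the one whose pooled mean and SD reproduce the
study's summary statistics, and it is also the defensible reading: a
model whose corrected explained variance is zero attributes no effect to
any predictor.

With p = 1 the formula can exceed the input r² slightly (by up to ~0.007
at N = 20, vanishing as N grows); with p ≥ 2 it never does. This is a
property of the printed formula, not an implementation artifact, and is
pinned by tests.

## Simulation design

Two sampling modes:

* **finite** (default): one population of 1,000,000 multivariate-normal
  cases per cell, from which each replicate draws n cases without
  replacement (with replacement across replicates);
* **direct**: every replicate is a fresh multivariate-normal draw.

At the default population size the modes are statistically
indistinguishable (a test checks per-statistic mean agreement within
three combined Monte Carlo standard errors); direct mode is the fast
path used for scaled runs. Bias is always measured against the
*analytic* population parameters, not the finite population's empirical
ones — at 10⁶ cases the distinction is negligible, and the analytic
baseline keeps reduced-size runs well-defined.

Randomness: each cell owns a child `SeedSequence(entropy=seed,
spawn_key=(cell_id,))` stream, so any cell or subset reproduces
bit-exactly in any run order. Replicates within a cell are drawn in one
vectorized batch from that stream rather than from per-replicate
sub-streams; per-cell reproducibility is the contract the tests pin.

Default settings are the full study conditions (5000 replicates per
cell, finite 10⁶ populations, all 135 cells ≈ 675,000 samples). The
test suite and the acceptance script run the scaled configuration —
1000 replicates per cell, direct mode — chosen because the Monte Carlo
standard error of every pooled summary is already an order of magnitude
below the tolerances being checked, while a full run completes in
seconds.

## Summaries

Six statistics are tracked per replicate: uncorrected and corrected bias
of r²_xŷ, R²_yŷ and r²_xy (signed, estimate − parameter, positive =
overestimate). Per-predictor records are reduced to a per-sample
average across predictors by default. The predictors are exchangeable
by construction, so this leaves every mean unchanged; it is the
reduction whose SDs and η² partition match the study's summary tables,
which is how the otherwise-unstated recording convention was identified
(keeping a single predictor's record roughly doubles the SD of the
structure-coefficient bias and divides its explained η² by five).
Single-predictor and pooled reductions remain available options.

η² for the 15 design terms (4 main effects, 6 two-way, 4 three-way, 1
four-way) is computed on per-replicate records, so within-cell sampling
noise sits in SS_total — this is why totals are small percentages. Sums
of squares come from the classical balanced-factorial
inclusion–exclusion on cell means; statsmodels' Type-I ANOVA is the
independent oracle in tests, never the implementation. Undefined-record
exclusions that unbalance the design are rejected unless an explicit
flag opts into the equal-cell-weight decomposition (harmonic-mean cell
count), in which case the reported SS_total is the sum of components. A
constant response reports all-zero η² by convention.

Marginal means are per-cell record means (identical to ANOVA estimated
marginal means in a balanced design, which a test asserts), and the
proportion tables count cells whose |mean bias| falls within the
threshold (default ±0.01) at each main-effect level.

## What the generator emulates, and what it does not

Populations are exactly multivariate normal with homogeneous validities
and a single common predictor intercorrelation. Real data feature
heterogeneous validities and intercorrelations, non-normality, missing
values and model misspecification (e.g. a strong predictor omitted from
the fitted model); none of these are modeled, so passing tests say
nothing about bias behavior under those conditions. Within the modeled
conditions the qualitative findings are: uncorrected squared structure
coefficients underestimate (most severely at low ρ²_yŷ with high
ρ_xx, small n and large k), uncorrected R² overestimates, and the
Pratt-corrected versions remove most of the pooled bias at the price of
a wider per-sample distribution (clamp mass at 0 and cap mass at 1).

## Known limitations

* Finite mode draws each replicate's indices with a separate
  without-replacement `choice` call; at the default 10⁶ population this
  is the slow path and exists for fidelity, not speed.
* The corrected-structure distribution is a mixture with atoms at 0 and
  1; its SD is therefore not a good dispersion summary near small n,
  and no inference (CIs, tests) on η² values is provided — they are
  descriptive.
* The equal-cell-weight η² decomposition under imbalance is an
  approximation appropriate only for the near-balanced case it guards
  (a handful of undefined replicates), not for general unbalanced
  ANOVA.
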