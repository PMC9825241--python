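# Methods

This note records the statistical model, the algorithmic and numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.  It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and factorization

A designed experiment yields `X` (N observations × M variables) and a
design table of categorical factors.  The model partitions `X` as
`X = 1 mᵀ + Σ_terms Z_term + E`, estimated by regressing `X` on a
deviation-coded matrix `C = [1, C_A, C_B, C_AB, …]`:

* a factor with `L` levels contributes `L − 1` columns; an observation at
  level `l < L` has a 1 in column `l`, an observation at the last level
  has −1 in all the factor's columns.  Levels are taken in
  first-appearance order unless an explicit order is given; the last
  level in that order receives the −1 coding.
* a two-way interaction contributes the `(L_Z−1)(L_Y−1)` element-wise
  products of its parents' columns.  Higher-order interactions are
  rejected (the supported designs never need them).

`Θ` is estimated with a QR-based least-squares solve (`numpy.lstsq`), not
the normal-equations inverse — identical estimator, better conditioning.
Singular values below `1e-10 ×` the largest are treated as zero; a
rank-deficient coding matrix is rejected with the aliased terms named.
Residual degrees of freedom are `N − rank(C)`.  On balanced designs the
term blocks are mutually orthogonal, the effect matrices equal the
classical cell-mean ANOVA decomposition, and sums of squares are
additive; Type-III sums of squares (reduced-minus-full residual SSQ)
coincide with the per-term effect SSQ there and remain well defined under
mild unbalancedness.  No balance check beyond the rank condition is
enforced.

### Preprocessing

Columns may be left raw, centered (default), or autoscaled (mean 0,
variance 1, sample sd with ddof = 1).  The raw `ssq` statistic *requires*
autoscaling — without it, high-variance variables dominate every
sum-of-squares comparison — and the model constructor enforces this with
an explicit error.  The per-variable F-ratio is scale-invariant, but the
whole-matrix and cumulative F statistics are not (their numerators and
denominators sum across variables), so the simulation benchmarks
autoscale for both statistics; that choice is part of the study
conditions, and without it the strong-bias scenario is trivially detected
by the holistic test.  Zero-variance columns raise an error under
autoscaling (or are left unscaled with a warning under an explicit flag).

## Test statistics

Per variable: `ssq` is the squared norm of the variable's effect column;
`f_ratio` is `(SSQ_Z/df_Z)/(SSQ_D/df_D)` with the residuals as the
default denominator.  Sub-matrix statistics are the corresponding sums
over the subset (`pc2_ssq`, the energy of the first two principal
components, is offered for whole-matrix tests only — it is not
column-additive, so it cannot drive the selection curve).  A variable
with zero denominator SSQ maps to an infinite F-ratio with a warning; it
still participates in the ordering, and cumulative statistics stay finite
because they use summed SSQs.  Ties in the ordering break by ascending
column index so permutation results are reproducible.

## Permutation inference

The null model shuffles the rows of `X` with K independent uniform
permutations (permuting the coded rows instead is equivalent for
whole-row shuffles; only one code path exists).  The same unrestricted
scheme is used for all terms, including interactions.  P-values use the
add-one-corrected count `p = (#{S* ≥ S} + 1)/(K + 1)`, so `p ≥ 1/(K+1)`
and ties count as exceedances.  Default `K = 1000`; default α is 0.01 in
the benchmark suite and 0.05 in the CLI.

One `PermutationPlan` (count + seed) generates the permutation sequence
once; ASCA, VASCA, the FDR baseline and ASCA-genes all consume the same
per-variable effect/residual SSQ tables computed from those draws, so
method comparisons are paired by construction.  Memorywise the engine
processes permutations in chunks (default 256) with batched matrix
algebra; the K×M SSQ tables (a few MB at the benchmark sizes) are kept,
from which all methods' statistics derive.

### VASCA

The observed curve orders variables by decreasing per-variable statistic
and accumulates the sub-matrix statistic over the nested prefixes.
Inside **each** permutation the variables are re-sorted by their permuted
statistic before the permuted curve is formed — the null at m variables
is each permutation's own best m variables, which is what keeps the
step-up selection calibrated (re-using the observed ordering in the null
would anti-conservatively freeze the selection).  Selection takes the
*largest* m with `p_m < α`, even when intermediate p-values are not
significant; the full curve is always reported so non-monotonicity stays
visible.  The m = M point of both observed and null curves is computed
with the same whole-matrix reduction as the plain ASCA test, making the
VASCA p-curve endpoint bit-identical to the ASCA p-value under a shared
plan.  A selected matrix can contain variables that are not individually
significant — that is the filtering nature of a multivariate statistic,
and the reason for the post hoc pruning step below.

### FDR baseline

Per-variable permutation p-values are BH-adjusted (step-up, clamped at
1; the implementation is cross-checked against an independent
multiple-testing library in the tests).  The empirical null for a
variable pools the permuted statistics of **all** variables by default
(resolution `1/(K·M + 1)`), which is valid because the autoscaled-SSQ and
F-ratio statistics are exchangeable across variables under the null and
is what makes a BH correction at small levels attainable with moderate K:
with per-variable nulls the smallest possible raw p is `1/(K+1)`, and at
K = 1000, M = 400 no variable could ever pass BH at α = 0.01 unless ≥ 40
variables tie at the minimum.  `pooled=False` restores the per-variable
null for users who want it.

### ASCA-genes baseline

For terms with at least two degrees of freedom (the two indices need ≥ 2
components; one-df terms get an error advising the selection test), a
PCA of the effect matrix with `r = min(df, 2)` components yields
per-variable leverage `Σ_a P(v,a)²` and SPE
`‖Z(·,v) − Ẑ(·,v)‖²`.  The published description of the control limits
is not algorithmic, so the limits here are the pooled empirical `1 − α`
quantiles of the permuted leverage and SPE values (across permutations
and variables, without re-sorting — the methodological contrast with the
selection test).  A variable is flagged when it exceeds either limit
(any flag other than "not relevant"); under the null this union is ≈ 2α.
Because the limit construction is an approximation of an unpublished
recipe, comparisons against published ASCA-genes rates carry an extra
±0.01 margin on top of Monte-Carlo error.  Permuted-effect PCAs are
computed from the small Gram factor `R Θ_t` (`Rᵀ R = C_tᵀ C_t`), so the
per-permutation SVD is `df × M`, not `N × M`.

## Post hoc components and bootstrap pruning

PCA of a significant term's effect matrix (restricted to the selected
variables) uses at most `df` components — the effect matrix cannot have
higher rank; asking for more truncates with a warning.  Score plots show
the projection of `Z + E` onto the effect loadings (projected scores
equal effect scores plus `E·P`, exactly); a PCA-on-`Z+E` variant is
available behind a separate method for users who prefer that view.

Loading uncertainty comes from a bootstrap over observations, resampled
with replacement **within each design cell** (the combination of all
model factors).  Per-cell resampling preserves the design exactly — the
multiset of coding rows is unchanged, so the fit operator is constant, no
stratum can empty, and the same batched algebra applies.  Per resample
the GLM is refitted on the selected variables and the leading right
singular vectors extracted; components are matched to the point estimate
by maximal absolute congruence (Hungarian assignment) and sign-flipped to
positive congruence before pooling — without alignment the intervals
would mix arbitrary SVD sign/order conventions.  Intervals are percentile
intervals at `1 − α` (B = 1000 by default, B ≥ 100 enforced; percentile
rather than BCa as the simplest method consistent with how the intervals
are used).  A variable is retained when any component's interval excludes
zero; bootstrap components default to `r = min(df, 2)`.

## Synthetic data

### Correlated background

The background generator emulates an omics-like measurement background: a
zero-mean multivariate normal with unit-variance columns and a
correlation level dialled between 0 and 10.  Construction: one global
component whose loadings have constant magnitude and random sign, plus
geometrically damped Gaussian minor components `λ_j = exp(−β j)`; rows of
the loading matrix are normalised to unit variance.  The level sets the
global component's nominal variance share

    s(level) = 0.95 · (level/10)³,        β = −ln(1 − s),

so level 0 gives independent columns, levels 7/8 give moderate global
correlation (realized first-PC share ≈ 0.35/0.51, measured in the test
suite), and level 10 is nearly rank-one (first-PC share ≈ 0.95, above
0.9).  Average absolute pairwise correlation is monotone in the level.
The cubic map keeps the mid-range levels used by the benchmarks in the
weak-to-moderate dependence regime, where null testing behaviour matches
an independent multinormal background — the robustness property the
null benchmarks rely on.  A steeper map (e.g. first-PC share ≈ 0.9 at
level 7) makes all 400 variables track one latent factor; whenever the
observed class split is extreme relative to its own permutations, *every*
variable's statistic is extreme simultaneously and the BH baseline flags
hundreds of variables at once, which changes the pooled null FPR by an
order of magnitude.  Such correlation cascades still occur — rarely — at
the calibrated levels, and they are the dominant contribution to the
FDR baseline's (tiny) false-positive rate, so that quantity is the most
surrogate-sensitive number in the benchmark suite.

What the generator does **not** emulate: heavy-tailed or skewed
intensities, block/pathway correlation structure, missingness, batch
effects, or count-type noise.  Passing null benchmarks therefore show
calibration under exchangeable multinormal backgrounds, not under every
real omics noise regime (permutation tests remain exact under
exchangeability regardless).

### Scenarios

All scenarios use 400 variables and α = 0.01 with K = 1000 permutations.

* **ex1** — 40 observations, binary factor from the sign of independent
  `N(0,1)` draws, background level 7; no association (null).
* **ex1b** — 4×3 full factorial with 4 replicates (48 rows), background
  level 7, factors independent of the data (null).
* **ex2** — as ex1, but variables 1–3 are `N(0,1)` plus `bias · c` with
  `c = ±1` the deviation class code; `bias = 5` (strong, class-mean
  difference 10) or `0.5` (weak).  Background level 7 for the other 397.
* **ex3** — variables 1–3 are `N(0,1)` and the class is the sign of their
  sum: a purely additive multivariate association.
* **ex4** — 4×3×4 full factorial; for each informative variable i ≤ 3,
  per-level effects `0.5·v_i(l1) + 0.5·v_i(l2)` (`v ~ N(0,1)` per level)
  plus a 4×3 correlated cell-noise block (level 8) shared by the four
  replicates of a cell; 397 level-7 background variables.  The analysis
  model fits the two main effects only: the benchmark reports per-factor
  results, and an interaction term would absorb the shared cell noise
  entirely (the informative variables have no within-cell replication
  noise by construction).

Benchmarks autoscale the data (see Preprocessing).  Replicate r of a
scenario derives its generator, permutation and bootstrap seeds from
`SeedSequence([master, scenario, r])`, so any subset of replicates is
reproducible in isolation and all methods within a replicate share one
permutation plan.  False-positive conventions: per-dataset for the
whole-matrix tests (ASCA rejection; VASCA selecting any variable on a
null dataset), per-variable for the selection methods (fraction of
non-informative variables flagged, pooled over replicates).

### Problem sizes

The acceptance script runs the null scenarios at 1000 replicates × 1000
permutations, the ex4 power quantities at 500 replicates, the bootstrap
false-retention rate at 200 replicates with B = 1000, and the strong-bias
mean p-curve at 100 replicates — sizes chosen so the whole recomputation
stays in the minutes range on one CPU while the Monte-Carlo standard
errors remain small against the published precision.  The test-suite
versions of the same checks run at further reduced replicate counts with
3-binomial-SE tolerances (plus a 0.05 systematic margin on power values,
because the background generator is a surrogate, and 0.01 on the
ASCA-genes rate, because its limit construction is approximated).

## Numerical notes

* Residual column SSQs under permutation are computed as
  `‖x_v‖² − ‖(CΘ*)_v‖²` (the total is permutation-invariant) and clipped
  at zero against cancellation.
* BH adjustment groups the factor as `p · (M/i)` so the rank-M factor is
  exactly 1.0 and an adjusted value can never round below the raw one.
* Permuted effect-matrix PCAs use the `df × M` Gram factor; batched SVDs
  across permutation chunks.
* The identity permutation may appear among random draws (it is not
  excluded); with the add-one correction this only makes p-values
  conservative by at most one grid step.
* Degenerate inputs: empty designs, single-level factors, unused declared
  levels, missing cells, non-numeric data, row-count mismatches and
  rank-deficient codings all raise typed errors naming the offending
  row/column/term.

## Limitations

* Fixed-effects, crossed designs only: no random effects, nesting,
  covariates, or missing-data handling.
* Unrestricted permutations for every term; restricted/exact schemes
  (e.g. residual permutation for interactions) are out of scope.
* The ASCA-genes limits approximate an unpublished construction; the
  baseline is for comparison, not a reference implementation.
* The background generator's correlation-level scale is a documented
  surrogate for the original simulator's; absolute agreement of
  correlation-sensitive quantities (notably the FDR null FPR) is
  order-of-magnitude, not exact.
* `pc2_ssq` cannot drive variable selection (not column-additive).
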