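# Methods

This note documents the statistical model, the algorithmic choices, and the
limits of what the test suite demonstrates.

## The cross-lagged panel network model

Given p items measured at two waves, X⁽¹⁾ and X⁽²⁾ (n × p), and an expanded
covariate block C (n × c′), the CLPN is assembled from p node-wise penalized
regressions: for each target item j,

    x_j⁽²⁾ = β₀ⱼ + X⁽¹⁾ bⱼ + C gⱼ + εⱼ,

estimated by minimizing (1/2n)·RSS + λⱼ Σ_k w_k |b_k|.  Column j of the
coefficient matrix B is bⱼ, so **B[i, j] is the edge i → j** (row = source,
column = target) and the diagonal carries the autoregressive effects.  Item
predictors carry penalty factor w = 1; covariates carry w = 0 by default —
they are confounder adjustments, not network edges, and shrinking them would
leak confounded variance back into the item coefficients (a
`penalize_covariates` flag exposes the alternative).

Assumptions worth keeping in mind: linearity and additivity of wave-1
effects; ordinal items treated as continuous; and, as with any two-wave
cross-lagged model, within- and between-person variance are conflated, so
edges are predictive, not causal, statements.

### Standardization

With `standardize=True` (default) items are z-scored within wave and
continuous covariates are z-scored; binary indicators are left on their 0/1
scale.  Edge weights are therefore standardized regression coefficients and
are invariant to affine rescaling of any input variable.

### Solver

The weighted-L1 objective is solved by cyclic coordinate descent on the Gram
matrix (numba-compiled), with soft-threshold updates that produce exact
zeros, warm starts along the penalty path, and a convergence tolerance of
1e-12 on the maximum coefficient change per sweep.  A predictor with zero
variance is pinned at zero with a warning.  Correctness is checked in the
test suite against three independent oracles: closed-form least squares at
λ = 0, the KKT subgradient conditions, and a bound-constrained
quadratic-programming solution of the same objective (plus sklearn's Lasso
in the all-unit-weight case).

### Penalty selection

λⱼ is chosen per node by K-fold cross-validation (K = 10) over a 100-point
log-spaced grid from λ_max down to 10⁻³·λ_max, where λ_max is the entry
threshold computed on the residual after projecting the response onto the
unpenalized covariates.  The default rule is **cv_1se** — the largest λ
within one standard error of the CV-minimal error.  The minimizing rule
(cv_min) is exposed but not the default: at two-wave clinical sample sizes
cv_min admits a substantial number of spurious edges under a null network
(the suite measures the false-positive fraction under a true-zero
cross-lagged structure and the 1SE rule is what keeps it below 10%), and a
sparse conservative network is the interpretational premise of this kind of
analysis.  Fold assignment derives deterministically from `fold_seed` and
the node index, so a fit is bit-reproducible given data + config.

## Synthetic data generator

The generator is the package's substitute for the (non-public) clinical
cohort; its defaults encode the study conditions: n = 222 participants,
p = 15 ordinal items on heterogeneous scales (five 0–3 depression items —
one a three-item sleep composite — six 0–4 anxiety/social-anxiety items,
four 0–8 attenuated-psychosis items), exactly 79 of 210 possible
cross-lagged edges with 92.4% positive signs, autoregressive effects uniform
on (0.2, 0.6), cross-lagged magnitudes uniform on (0.05, 0.35), residual sd
0.6, and covariates: age (continuous), gender and two treatment indicators
(binary), and a 7-level diagnostic category with the largest group at 39.6%.

The model is linear-Gaussian with post-hoc discretization: wave-1 scores are
multivariate normal with a single-factor-plus-noise correlation structure
(all pairwise correlations positive, emulating symptom co-occurrence);
latent wave-2 scores are X⁽¹⁾B + CG + ε; ordinal items are produced by
per-wave equal-probability quantile thresholds, so both waves share marginal
level distributions and rank structure is preserved (Spearman ≥ 0.8 for
items with ≥ 4 levels).  This choice — rather than a generative ordinal
model — keeps the recorded truth on the same scale that node-wise linear
LASSO can recover, so parameter-recovery tests compare like with like.

Missingness is injected into item cells only.  MCAR sets cells missing
uniformly at `missing_rate`; the default cell rate of 0.0035 makes roughly
10% of rows (≈ 22 of 222) carry at least one missing score across the 30
item cells, matching the row-level incidence of the study design.  MAR keys
cell missingness to the (always observed) age covariate through a logistic
link whose intercept is calibrated to the target mean rate; this gives
Little's test a clean power scenario.

What the generator does **not** emulate: skewed symptom marginals (levels
are equal-frequency), floor effects, measurement error structure, selective
attrition, or diagnostic-group-specific network differences (covariates
shift means only).  Passing recovery tests therefore demonstrate the
estimator's behavior under the model's own assumptions, not robustness to
every feature of real questionnaire data.

## Item reduction (wTO screen)

Redundant near-duplicate items are detected on the wave-1 absolute
correlation matrix A (Spearman by default, pairwise complete) via weighted
topological overlap

    ω_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    k_i = Σ_{u≠i} a_iu .

A pair is flagged when ω exceeds **both** the `threshold_quantile` quantile
of off-diagonal ω values and an absolute floor `min_overlap` (default 0.20).
The floor matters: a pure quantile rule would always flag a fixed fraction
of pairs, even among mutually independent items; the floor makes "nothing is
redundant" an attainable outcome.  Within each connected component of
flagged pairs the hub — the item with the highest mean absolute correlation
to all items, rounded to 10 decimals so exact duplicates tie, ties broken
lexicographically — is retained and the rest are dropped with a logged
reason.  Lowering the quantile can only grow the dropped set (components
merge; the merged hub is one of the previous hubs).

The procedure is a reconstruction of a standard redundancy-reduction screen;
the original study's exact variant is not published in its main text, so
correlation kind, quantile, floor and retention rule are all configuration.
The content-based first step of item selection is by design a manual
include-list, not an algorithm.

## Missing-data handling

**Little's MCAR test.**  The mean vector μ and covariance Σ are estimated by
EM for the multivariate normal (ML, denominator n; convergence when the
largest parameter change falls below 1e-6, cap 500 iterations — the test's
inputs here are far from that cap).  The statistic sums, over missingness
patterns j with observed variable set o(j),

    d² = Σ_j n_j (ȳ_j − μ_{o(j)})′ Σ_{o(j)}⁻¹ (ȳ_j − μ_{o(j)}),

and is referred to χ² with df = Σ_j k_j − k.  A pattern with a singular
observed submatrix is pooled via a ridge-stabilized inverse and flagged in
the result.  The statistic is invariant to column order and affine
rescaling.  Monte-Carlo calibration on Gaussian MCAR data (n = 300, p = 5,
10% missing, 1000 replicates) holds the α = 0.05 type-I error near nominal;
on coarse ordinal items the normality assumption bites and p-values should
be read with that in mind.  Following the workflow this package mirrors, the
diagnostic informs but never gates: imputation proceeds regardless of the
test result, and cases are never deleted.

**Random-forest imputation** follows the missForest algorithm: initialize
missing cells at column means (modes for categorical columns); visit
incomplete columns in ascending missingness order, refitting a random
forest of each column on all others (current completed values, originally
observed rows only) and predicting the originally missing rows; iterate
until the normalized squared change (continuous) or proportion changed
(categorical) first increases, then return the previous iterate.  Ordinal
item columns are treated as continuous and rounded/clipped to their scale
range at the end.  All forest seeds derive from one integer seed, so the
result is bit-reproducible.  All columns are used jointly as predictors.

## Centrality

Cross-lagged expected influence sums signed edge weights: out-EI over a
node's row of B, in-EI over its column, excluding the diagonal by default —
the "cross-lagged" qualifier in this literature refers to influence on and
from *other* symptoms; `include_autoregressive=True` adds the self-loop for
sensitivity since the verbal definition ("all edge strengths connected to a
node") is ambiguous.  z-columns standardize across nodes.  Row/column sums
necessarily share a grand total, which the suite checks to 1e-12 against a
brute-force double loop.

## Stability diagnostics

All bootstrap machinery resamples participants and refits the entire
network, re-selecting λ inside every resample by default (honest bootstrap);
`freeze_lambda=True` reuses the full-sample per-node penalties for speed at
the cost of slightly anti-conservative intervals.  Edge CIs are 2.5%/97.5%
percentile bounds (not BCa); edge-pair and node-pair difference tests call a
difference significant when the percentile interval of the bootstrapped
difference excludes zero, with no multiplicity adjustment (the convention of
the bootstrap toolkits in this literature; interpret counts of significant
differences, not individual pairs).  A resample on which estimation fails is
redrawn and counted.

The case-dropping bootstrap drops a proportion π of participants without
replacement (grid 0.05–0.75 by default), refits, and records the Pearson
correlation between full-sample and subsample centralities.  The
**CS coefficient** is the largest tested π at which ≥ 95% of correlations
remain ≥ 0.7; below 0.25 a centrality order is conventionally considered
uninterpretable, 0.25–0.5 acceptable, above 0.5 good (the boundary 0.25 is
inclusive, per "should not be below 0.25").  Degenerate subsample
centralities (zero variance) yield NaN correlations, which count as
failures.

Default resample counts are 1000 for edge/centrality bootstraps and 250 per
dropped proportion; the bundled acceptance script uses a 7-point grid at 100
resamples per point — CS resolution 0.1 — as its stated problem size.

## Sensitivity comparison

`compare_networks` correlates the full vectorized coefficient matrices
(zeros included by default; a zeros-excluded variant is a flag, since "edge
list" is ambiguous between the two) and reports asymmetric replication:
the fraction of A's nonzero edges nonzero in B and vice versa — asymmetric
denominators are why the two percentages differ in typical reports.
`subgroup_refit` drops rows matching a covariate predicate, refits with
fresh penalty selection, and compares against the full-sample network; the
retained subsample must exceed p + c′ + 10 rows.

## Numerical and degenerate-input conventions

* Exact zeros from the soft threshold are preserved end to end (edge counts
  are meaningful, not threshold artifacts).
* Ties in rankings and hub retention break lexicographically by label.
* Constant columns: excluded from correlation screens with a warning;
  pinned at zero with a warning in regressions; flagged by `validate_panel`.
* Missing values are NaN in memory and empty cells in CSV; no numeric
  sentinel is ever valid.
* One master seed feeds named substreams per pipeline stage (CRC-keyed
  SeedSequence), so enabling or disabling a stage does not perturb the draws
  of any other stage.

## Known limitations

* Two waves only; no intensive time-series (temporal/contemporaneous VAR)
  estimation, and no within/between-person decomposition.
* Single imputation, not multiple imputation; imputation uncertainty is not
  propagated into edge CIs.
* Node-wise LASSO edges are penalized point estimates; the bootstrap CIs
  around them inherit the usual post-selection caveats.
* The wTO screen is a reconstruction with free parameters, not a replication
  of any specific published item list.
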