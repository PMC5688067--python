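# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Epistasis scoring

For each unordered pair (a, b) the expected double-knockdown viability under
non-interaction is the product of the single-knockdown means,
E(W_ab) = mean(W_a)·mean(W_b), and the score is
ε = mean(W_ab) − E(W_ab).  Pair keys are canonical sorted tuples; self-pairs
are excluded; all scores are invariant under swapping the pair's gene order.
Replicate means are computed exactly for constant replicate vectors (the
zero-noise degenerate case), so a noise-free null panel yields ε ≡ 0 with no
floating-point residue.

**Z-test caller.** The statistic is z = ε / SE with the delta-method error
of the product of sample means folded in:

    SE² = Var(W̄_ab) + W̄_b²·Var(W̄_a) + W̄_a²·Var(W̄_b)

The O(σ⁴) cross term of the product variance is dropped.  By default the
technical-noise variance is **pooled** over every measurement in the panel
(singles, doubles, controls; weighted by replicate degrees of freedom).
With technical triplicates, per-measurement variance estimates have 2
degrees of freedom each and make the statistic t-like with roughly 4–6
effective degrees of freedom, which inflates the nominal false-call rate at
α = 0.05 to ~0.10–0.19; pooling across a screen's thousands of replicates
restores the standard-normal reference a Z-test assumes, and is justified
here because plate-reader noise is a property of the assay, not of the
individual well.  `var_mode="per-pair"` and a Student-t reference
(Welch–Satterthwaite degrees of freedom) are available for sensitivity
analysis.  Zero-variance measurements with nonzero ε are flagged degenerate
and called by sign rather than producing an infinite z.

**Density caller.** A pair is significant when its ε lies outside the
central empirical-probability region of all pairwise ε in the same cell
line: symmetric percentiles at coverage 0.95 (strict, solid edges) or 0.90
(loose, dotted edges), midpoint interpolation.  This is the simplest
estimator consistent with calling scores outside the bulk of the
interaction density; it needs at least 20 pairs.

**Cell-cycle phases.** Per phase k with control fraction F0_k, the expected
double fraction is (F_a,k/F0_k)·(F_b,k/F0_k)·F0_k, renormalized across
phases to sum to 1 (the multiplicative null on fold changes does not
preserve compositional closure, and renormalization is the minimal
correction).  Phases with zero control fraction are excluded with a
warning.  The per-phase score is observed minus expected fraction; positive
scores are increases in that phase.  Each phase is called independently;
the density caller is the default because replicate-level phase fractions
are usually unavailable.

**Summaries.** ε bins are equal-width over the observed range (five by
default), interior edges right-inclusive.  Bin summaries report median and
quartiles with linear interpolation — declared so independent recomputation
agrees exactly.  Cross-cell-line agreement uses Spearman's ρ on the shared
pair set; overlap counts enumerate every region of the Venn partition.

## Latent-factor network inference

Inputs are the averaged double matrix G (diagonal unobserved), the single
vector S, and H = S Sᵀ.  Stage (i) fits Ĝ = L·σ(k(UVᵀ − x₀)), symmetrized,
by minimizing squared error over observed entries.  The optimizer is Adam
(learning rate 0.05) over all parameter blocks with an iteration cap
(default 5,000), a 1e-8 relative-objective tolerance, seeded uniform(0, 1)
initialization, ceiling initialized at max(G), and best-iterate tracking so
the returned objective never exceeds any visited one.  The rank sweep
warm-starts rank r+1 from rank r with the extra V column zeroed (identical
predictions at the start), which makes NRMSE — RMSE over observed entries
divided by their range — nonincreasing in rank by construction.  The
selected rank is the smallest within 1% of the minimum on the grid
(parsimony when the curve plateaus).

Stage (ii) scores, for each ordered pair (u, v) with denoised g = Ĝ_uv,
four predictions: S_u (linear, u's phenotype masks v's), S_v, S_u·S_v
(parallel), and λ·(nearest single) + (1−λ)·product with λ clamped to
[0.05, 0.95] and chosen to minimize the residual (partial interdependence).
Residuals become probabilities through Gaussian likelihoods with scale
σ = max(replicate-based standard error, model reconstruction RMSE, 1e-3);
tying σ to the reconstruction RMSE keeps a coarse fit from masquerading as
a confident call.  The partial hypothesis pays a one-parameter penalty of 1
nat (AIC-style) for its fitted λ.  Probabilities sum to 1 per ordered pair;
swapping the pair swaps the two linear slots and fixes the other two.
Class names are explicit strings (`linear_first`, `linear_second`,
`parallel`, `partial`) — never indices — to avoid orientation bugs.

Stage (iii) draws a directed edge u→v when P(linear_first) for (u, v)
exceeds the threshold (default 0.5, exposed), an undirected edge for
partial interdependence, and nothing for parallel.  Stability: for each
noise SD on a grid spanning 1e-6 to SD(G)/3 (three levels by default), M
(default 100) independent symmetric Gaussian perturbations of G are refit
at the rank selected on the unperturbed data and their networks recorded.
Refits warm-start from the unperturbed fit so run-to-run variation reflects
the injected data noise rather than optimizer randomness.  Appearance
fractions are reported per level and pooled; classes follow the fixed rule
solid ≥ 0.40, dashed [0.20, 0.40), absent below.

## Collective matrix tri-factorization

Every relation is first normalized in two steps — each nonzero row divided
by its Euclidean norm, then each nonzero column of the result — with zero
rows/columns left untouched to preserve object indexing.  The solver
minimizes Σ‖R_ij − G_i S_ij G_jᵀ‖² with shared nonnegative factors via
multiplicative updates (cores kept nonnegative too, which gives the
standard monotonicity guarantee); a sweep that would raise the objective
reverts and stops, so the recorded trace is nonincreasing on every input.
Convergence: relative objective change below 1e-6 or 500 sweeps.  All-zero
relations are skipped with a warning.  Rank selection, where needed, is a
grid search minimizing reconstruction error on a seeded 10% held-out entry
mask (masked multiplicative updates), smallest rank within 1% of the
optimum.

Profiles of a target type are the rows of each reconstructed relation
touching it; cosine distance is 1 − cosine similarity (range [0, 2] in
general, [0, 1] for these nonnegative reconstructions); a zero profile's
distances are defined as 1 and flagged.  Distance matrices are averaged
unweighted across relations.  Hierarchical clustering uses average linkage
by default (exposed), with deterministic tie-breaking from label-ordered
input.

## Profile utilities

Activity ratios divide each absorbance cell by its matched
no-coupling-enzyme control; cells with nonpositive controls become missing.
"Active" means ratio > 1.5 by default (configurable; heat maps excluding
no-activity conditions motivate the filter).  Activity clustering drops
inactive rows and columns, then clusters on 1 − Pearson correlation.
Differential expression uses Welch's unequal-variance t on log2 values
(condition sample sizes differ by design) with Benjamini–Hochberg
adjustment; the bubble-size helper returns the square root of the
expression level.  Patristic distances sum branch lengths along the unique
leaf-to-leaf path (dendropy); trees with duplicate leaf labels or missing
branch lengths are rejected.  Activity similarity is pairwise Spearman ρ,
with constant profiles reported as missing.

## Synthetic-data generator

The generator's defaults encode the screen design: 24 siRNA targets (276
pairwise combinations), technical triplicates, viability noise SD 0.05,
single-knockdown means uniform in (0.4, 1.0] — a range that keeps products
well above zero, since floor effects are a separate phenomenon.  Replicate
noise is i.i.d. Gaussian truncated at 0 by resampling; the negative-control
replicate mean is fixed at exactly 1.  Planted interactions add ±0.3 to the
product mean; aggravating effects are planted only on pairs whose null mean
can absorb them, and a configuration whose effects cannot be placed is
rejected.  Phase-fraction noise is multiplicative log-normal on fold ratios
followed by renormalization, keeping vectors on the simplex; planted pairs
get a +0.1 deviation in one phase before renormalization.  Fusion
collections are planted block matrices (within-block mean exceeds
between-block by a configurable margin) plus clipped Gaussian noise; trees
are random binary joins with exponential branch lengths.  One master seed
derives independent per-component streams, so equal seeds give byte-identical
outputs.

What the generator does **not** emulate: plate-position and batch effects,
correlated siRNA off-target signatures, heteroscedastic noise at low
viability, compositional count noise in phase fractions, or realistic
cross-relation dependence in the fusion matrices.  Passing the planted-
recovery benchmarks therefore demonstrates correctness of the algorithms
under their stated assumptions, not robustness to every artifact of real
screens.

## Problem sizes and benchmarks

The packaged benchmarks use desk-scale sizes chosen to exercise every code
path: calibration on 1,000–5,000 independent null pairs, power on a
24-gene panel with 20 planted interactions, four-way relationship recovery
on 12 genes, stability with M = 100 over three noise levels on 20 genes,
and fusion recovery on 12×8 collections over 20 seeds.  Under these
conditions the stringent caller's null false-call rate sits within binomial
error of its nominal level, the 90% density region covers 90% of null
scores to within a point, planted |ε*| = 0.3 interactions are recovered
with recall ≥ 0.9 and correct signs, hypothesis recovery exceeds 95%, and
planted fusion blocks are recovered exactly at high signal and with median
ARI ≥ 0.8 when the block margin is only 1.5× the noise SD — all recomputed,
not quoted, by the test suite and `scripts/acceptance.py`.

## Known limitations

The Z-test's pooled-variance default assumes homoscedastic technical noise
across the plate; strong mean-variance coupling would call for the per-pair
mode.  The four-way scorer evaluates the denoised reconstruction, so a
relationship visible only in a single matrix entry can be absorbed by an
aggressively low selected rank; the rank-selection rule (within 1% of the
NRMSE minimum) errs toward higher ranks to limit this.  The partial
hypothesis is nested against both linear and parallel; with nearly
saturated singles (S close to 1) its best interpolation can sit within σ of
the parallel prediction and the 1-nat penalty decides the call.  Fusion
ranks must be supplied or grid-searched; there is no per-type automatic
selection beyond the shared-grid helper.
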