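# Methods

This note documents the statistical model behind `innomod`, the defaults
it ships, and what the synthetic data do and do not establish.

## Data model

An osteometric table holds one row per individual and the eight DSP 2
innominate measurements (mm): PUM (acetabulo-symphyseal pubic length),
SPU (cotylo-pubic width), DCOX (innominate height), IIMT (greater sciatic
notch height), ISMM (post-acetabular ischium length), SCOX (iliac
breadth), SS (spino-sciatic length), SA (spino-auricular length). The two
"rescue" measurements of the DSP protocol (SIS, VEAC) are out of scope.
Sex labels are F/M/unknown; missing cells are first-class and survive
every stage — **no imputation anywhere**. Every computation that needs
complete data restricts to complete cases *for the traits it uses*, so
different trait subsets generally retain different sample sizes. Side
(left/right) is not modelled; measurements are one set per individual.

## Integration statistic

For an M×M Pearson correlation matrix R with eigenvalues λ₁…λ_M
(mean 1), the package reports

SDrelλ = sqrt( Σ (λᵢ − 1)² / (M(M−1)) ),

i.e. the population standard deviation of the eigenvalues divided by its
maximum √(M−1). Algebraically Σ(λᵢ−1)² = ‖R‖²_F − M = Σ_{i≠j} r²_ij, so
SDrelλ is exactly the RMS off-diagonal correlation — the identity the
test suite uses as an independent oracle. Consequences: SDrelλ ∈ [0, 1];
an equicorrelation matrix scores exactly ρ; the statistic is invariant
to trait order. The population-variance (divide by M) convention is
required by this identity; with the M−1 denominator, or with SD(λ)/mean(λ),
none of the closed-form checks hold.

Under no integration, each sample off-diagonal correlation at sample
size N has variance ≈ 1/N... more precisely (1−ρ²)²/N = 1/N at ρ=0, and
E[r²] ≈ 1/N, giving

E[SDrelλ | independence] ≈ √(1/(2N))

after the small-sample refinement E[r²] = 1/(N−1) ≈ 1/N is averaged over
pairs; the √(1/(2N)) form is the one whose values at N = 1885, 1967 and
1989 round to 0.0163, 0.0159 and 0.0159 — the published no-integration
benchmarks this package reproduces. The expectation depends on N only,
not on M.

## Module identification

PCA is the eigendecomposition of the complete-case correlation matrix
(correlation-based, pooled across sexes by default, matching the biplot
convention in which both sexes share one decomposition). Loadings are the
orthonormal eigenvectors, columns ordered by decreasing eigenvalue and
signed so each column's dominant entry is positive. Modules are obtained
by average-linkage hierarchical clustering of the trait loading vectors
restricted to the first `n_pcs` PCs (default 2) under distance
1 − cosine similarity, cut at `k` clusters (default 3). Traits are
processed in lexicographic order so linkage ties resolve
deterministically; a zero loading vector (norm < 1e−12) is placed at
maximal distance from everything. `k` and `n_pcs` are exposed on the CLI
because the choice of three modules is itself an analytic judgment, not
a mathematical necessity.

## Classifier

A two-class Gaussian linear discriminant over an arbitrary trait subset:
per-sex means and the pooled within-class covariance with the unbiased
denominator n_F + n_M − 2, equal priors by default (the reference sample
is nearly balanced; priors are configurable). The posterior of "female"
is the logistic of the linear score wᵀx + b with w = S⁻¹(μ_F − μ_M),
which equals the two-density Bayes posterior under the equal-covariance
assumption (tested against direct density evaluation to 1e−10, and
invariant to unit rescaling to 1e−8). A sex is assigned only when the
winning posterior reaches the threshold (default 0.85; must lie in
(0.5, 1) so at most one class can win); otherwise the individual is
indeterminate. Singular pooled covariance raises an error naming the
collinear traits rather than being silently regularised — with ~1,900
training rows and at most eight traits, singularity signals a data bug.

Scoring conventions: accuracy = correct / assigned (indeterminates
excluded from numerator and denominator; reported as NaN when nothing
was assigned, never as 0); percent assigned = assigned / evaluated ×
100, where "evaluated" means complete cases for the traits in use. A
fixed denominator (e.g. the whole validation table) is available via
`score_classification(..., n_total=...)`; the complete-case denominator
is the default because the assignment gate is an event among the
individuals actually scored.

## Resampling comparison

Each iteration draws a trait subset (one-per-module, or k = 4 uniformly
without replacement from all eight), refits the discriminant on the
reference complete cases for that subset, classifies the validation
complete cases at the threshold, and records accuracy and percent
assigned. Individuals missing a drawn variable sit out that iteration
only. One RNG stream per simulation run, seeded once; the two schemes in
`compare_schemes` use independent child streams spawned from the master
seed. Iterations with no assigned individual contribute 0-assignment to
the percent-assigned statistics but are excluded (and counted) in the
accuracy statistics. Subset draws are with replacement across
iterations — with 12 (cluster) or 70 (random-4) possible subsets,
repeats are the norm, exactly as in a naive repeated-draw protocol.

The accuracy distributions are compared by the one-sided two-sample KS
statistic D⁺ = supₓ[ECDF_b(x) − ECDF_a(x)] evaluated over all pooled
sample points (floored at 0), a = cluster-based, b = random-4, so a
positive D⁺ indicates the cluster-based accuracies stochastically
dominate. The p-value is the one-sided asymptotic form
exp(−2mnD⁺²/(m+n)), cross-checked in tests against a brute-force ECDF
sup and scipy's one-sided statistic.

## Synthetic data: what it emulates and what it does not

`generate_table` draws sex-labelled multivariate-normal measurement
vectors with a shared covariance D·R·D: R has 1 on the diagonal,
`rho_within` = 0.7 inside the planted modules {IIMT},
{PUM, SA, SCOX}, {DCOX, SS, ISMM, SPU} and `rho_between` = 0.2 across
them (positive-definiteness is checked explicitly); D holds per-trait
SDs. Default sizes mirror the study datasets: reference 944 F + 941 M
fully observed; validation 360 F + 367 M with exact per-trait
missing-cell counts {PUM 313, SPU 200, DCOX 149, IIMT 15, ISMM 128,
SCOX 220, SS 12, SA 12} imposed completely at random (exact counts, not
Bernoulli rates, so the missingness summary is an exact test). Equal
covariance across sexes is deliberate — it is the classifier's own
assumption. Records with a non-positive draw are resampled a bounded
number of times (8 rounds), then the generator errors: persistent
failures mean the means are too close to zero relative to the SDs.

Female means and SDs are round plausible millimetre values; absolute
location does not affect any statistic downstream (the classifier is
affine-invariant, correlations are scale-free). What matters is the
dimorphism-to-noise ratio, which was **calibrated once** and frozen
(`scripts/calibrate.py` reproduces the numbers): standardized
male−female offsets of 1.0 (IIMT), 1.1 (outlet traits) and 2.4 (inlet
traits). Two considerations fixed this pattern:

* *module-constant offsets* make every one-per-module draw statistically
  exchangeable, so the cluster-based scheme's consistency arises from
  the redundancy structure itself rather than from which trait happened
  to be drawn;
* *between-module grading* (weak outlet/ilium, strong inlet) spreads the
  quality of unconstrained four-variable subsets, placing the
  one-per-module draw at a ~96%-accuracy operating point (subset
  Mahalanobis distance ≈ 2.5 at threshold 0.85).

Known departures from real skeletal data, and hence limits on what
passing tests show: real measurements are not exactly multivariate
normal, and their between-module correlations are stronger (real
whole-set SDrelλ ≈ 0.52 implies typical cross-module r ≈ 0.4); real
missingness may co-occur within individuals (only marginal counts are
known; MCAR-by-trait is an assumption); the inlet dimorphism is
deliberately exaggerated relative to anthropometric values so that
subset quality varies visibly; and the synthetic assignment rates
(~70–80% at threshold 0.85) are far above the ~30–40% seen in practice —
under a clean equal-covariance Gaussian model, ~96% accuracy among
assigned individuals co-occurs with high assignment rates, so the
real-data combination of high accuracy with low assignment implies
heavier tails or population mixture that this generator does not model.
Distribution *shapes* (which scheme is tighter) are meaningful at this
operating point; absolute assignment levels are not.

## Numerical choices and degenerate inputs

* Correlation matrices are symmetrised and eigenvalues clipped at 0
  before dispersion statistics; validation tolerances for symmetry and
  unit diagonal are 1e−8.
* Fewer than 3 complete cases, a zero-variance trait, fewer than 2
  training individuals per sex, unknown-sex training records, empty
  trait subsets, thresholds outside (0.5, 1), and missingness counts
  exceeding the table size all raise typed errors naming the offending
  trait or value.
* The logistic is evaluated in a numerically safe split form, so extreme
  discriminant scores saturate at 0/1 without overflow.
* Determinism: generator output is byte-identical given a seed;
  simulations consume a single seeded stream; the pipeline manifest
  records seeds and SHA-256 hashes, and identical configs reproduce
  identical artifacts.

## Problem sizes used in the test suite

The suite exercises the full default fixture (1885 reference rows, 727
validation rows). Distribution-shape properties are asserted on a
1000-iteration run per scheme, and the scheme-consistency property on
twenty 200-iteration replicate streams; module-recovery is checked over
100 replicate reference samples. These sizes give sampling error well
below every asserted margin while keeping the default test run short.
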