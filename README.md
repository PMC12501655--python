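# innomod

Morphological integration and variable selection for innominate-based
skeletal sex estimation.

## The problem

Metric sex estimation from the human hip bone (innominate) — as in the
DSP 2 ("diagnose sexuelle probabiliste") method — treats each of eight
osteometric variables (PUM, SPU, DCOX, IIMT, ISMM, SCOX, SS, SA; all in
mm) as an independent carrier of information. They are not: shared
development and function make subsets of these measurements covary as
*modules*. For forensic anthropologists and skeletal biologists this
raises two practical questions:

1. **How integrated are the measurements?** Quantified here by the
   relative standard deviation of the eigenvalues of the trait
   correlation matrix,

   SDrelλ = sqrt( Σᵢ (λᵢ − 1)² / (M(M−1)) ),

   which equals the root-mean-square off-diagonal correlation: 0 for
   uncorrelated traits, 1 when a single dimension carries all variance.
   Its expectation under no integration at sample size N is
   √(1/(2N)) — sampling noise alone produces nonzero dispersion.

2. **Can redundant variables be dropped without losing accuracy?**
   Modules are identified by average-linkage clustering of
   correlation-PCA loading vectors (cosine distance, leading two PCs).
   A *cluster-based* scheme draws one measurement per module (three
   variables) and is compared against drawing four variables at random,
   using a two-class Gaussian linear discriminant: with pooled
   within-sex covariance S and class means μ_F, μ_M,

   P(F | x) = logistic(wᵀx + b),  w = S⁻¹(μ_F − μ_M),

   assigning a sex only when the winning posterior reaches a threshold
   (default 0.85), leaving the individual indeterminate otherwise.
   Repeated resampling of trait subsets (10,000 iterations by default)
   yields distributions of accuracy and percent-assigned per scheme,
   compared by a one-sided two-sample Kolmogorov–Smirnov statistic
   D⁺ = supₓ[ECDF_b(x) − ECDF_a(x)] with asymptotic p-value
   exp(−2mnD⁺²/(m+n)).

Because the underlying skeletal datasets are distributed as journal
supplements rather than packaged data, the library ships a synthetic
generator that emulates their structure: two-class multivariate-normal
measurements with a planted three-module block correlation
({IIMT}, {PUM, SA, SCOX}, {DCOX, SS, ISMM, SPU}; within-module r = 0.7,
between-module r = 0.2), a reference set of 944 females + 941 males, and
a 727-individual validation set with realistic per-trait missing-cell
counts (e.g. PUM 313, SPU 200, …, SA 12). All analyses are strictly
complete-case; nothing is imputed.

## Worked example

```python
import innomod as im

ref = im.generate_table(im.default_reference_config(seed=0))
val = im.generate_table(im.default_validation_config(seed=1))

# integration of the full set vs the planted modules
for traits in (im.CANONICAL_TRAITS, ("DCOX", "ISMM", "SPU", "SS"),
               ("PUM", "SA", "SCOX")):
    r = im.integration_report(ref, traits)
    print(r.m, r.n, round(r.sdrel, 4), round(r.null_expectation, 4))

# module identification from PCA loadings
pca = im.pca_loadings(ref, im.CANONICAL_TRAITS)
print(im.cluster_loadings(pca.loadings, k=3, n_pcs=2).to_dict()["modules"])

# scheme comparison: one-per-module vs random four-variable draws
res_c, res_r, ks = im.compare_schemes(ref, val, im.INNOMINATE_PARTITION,
                                      n_iterations=1000, seed=42)
print(res_c.summary["accuracy"], res_r.summary["accuracy"], ks.d_plus)
```

prints (abbreviated):

```
8 1885 0.6057 0.0163
4 1885 0.8753 0.0163
3 1885 0.7623 0.0163
[['DCOX', 'ISMM', 'SPU', 'SS'], ['IIMT'], ['PUM', 'SA', 'SCOX']]
cluster:  accuracy mean 0.9546, sd 0.0097
random-4: accuracy mean 0.9580, sd 0.0135   D+ = 0.079
```

Reading: every module is far more integrated than the no-integration
expectation (0.0163 at N = 1885) and more integrated than the full
eight-trait set (0.8753 and 0.7623 vs 0.6057); the clustering recovers
the planted modules exactly; and the cluster-based scheme matches the
random four-variable scheme's accuracy to within half a percentage point
while using three variables and producing a visibly tighter (more
consistent) distribution across draws.

The same stages are available from the shell:

```bash
innomod generate --outdir data --seed 0
innomod integrate --input data/reference.csv --traits all
innomod cluster --input data/reference.csv --k 3
innomod compare --reference data/reference.csv \
    --validation data/validation.csv --iterations 10000 --outdir out
innomod pipeline --outdir run1        # full generate→integrate→compare run
```

`innomod pipeline` writes a manifest with SHA-256 hashes of every
artifact; re-running the same config reproduces identical files.

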