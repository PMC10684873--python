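# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pleiomap`, in the order the pipeline runs them.

## Significance thresholding

Gene-level association statistics arrive as signed Z-scores (one
regions × genes matrix per MRI metric, one vector per disorder). Two-sided
p-values are derived as `2·Φ(−|z|)`; a p matrix may be supplied directly
instead. The per-test threshold is `alpha / (G × N_pheno)` with
`alpha = 0.05` by default.

`N_pheno`, the effective number of independent regional phenotypes, is
estimated from the eigenvalues λ of the inter-regional phenotype
correlation matrix. The default (Li–Ji-style) estimator sums
`f(λ) = 1[λ ≥ 1] + (λ − ⌊λ⌋)` and rounds to the nearest integer; a
Nyholt-style variance-of-eigenvalues estimator is selectable. Eigenvalues
are rounded to 10 decimals before the floor — the score is discontinuous at
integer eigenvalues and solver noise (e.g. `6 − 1e−15`) would otherwise
shift the count by ~1. Significance uses strict `p < threshold`; boundary
ties are measure-zero in continuous data, so the convention is immaterial
in practice but fixed for determinism.

Set-overlap inference reports the exact hypergeometric upper tail together
with a permutation test that redraws the second set uniformly from the gene
universe (10,000 draws by default), summarized as
`Z = (obs − mean_null)/sd_null` and a `+1`-smoothed empirical p. The
uniform null does not preserve gene length or LD structure; a length- or
LD-matched resampling scheme would require annotations the pipeline does
not demand, and this is a documented limitation rather than a default.

## PLS1 and leave-one-out influence

The predictor block X is the transposed gene-Z matrix (genes as
observations, regions as variables); the response y is the disorder Z
vector over the same genes. Columns of X and y are z-scored over genes
(sample SD, ddof 1) before fitting; the switch is exposed but standardized
fitting is the default.

With a univariate response the first PLS component is available in closed
form — `w_X ∝ Xᵀy` normalized to unit Euclidean norm, `w_Y = 1`,
`T = X·w_X`, `U = y` — and is implemented directly; it equals the
single-component iterative (NIPALS) solution exactly, and the test suite
cross-checks it against an independent PLS implementation. The orientation
is fixed so `corr(T, U) ≥ 0`. Variance explained is `corr(T, y)²`, an exact
identity asserted to 1e−12.

Inference:

* **Permutation** — y is permuted over genes and the model refit
  (1000 permutations by default); the p-value is the `+1`-smoothed upper
  tail of the null variance-explained distribution. Permuting before or
  after standardization is equivalent because the fit re-standardizes.
* **Bootstrap** — genes are resampled with replacement; each replicate's
  weight vector is sign-aligned to the point estimate before the SE is
  taken (the component's sign is arbitrary under resampling);
  `boot_z = w_X / SE` with BH-FDR flags at q = 0.05. Degenerate replicates
  (zero cross-covariance or a constant column) are redrawn, with a retry
  cap.
* **Leave-one-out influence** — for each gene g, the gene is dropped from X
  and y, columns re-standardized over the remaining genes, the component
  refit, and `R(T,U)` recomputed: `Δ_g = R − R_LOO`. The exact refit is the
  implementation, not an approximation; it is O(G·R) per gene and runs in
  seconds at desk scale (2,000 genes × 60 regions). R(T,U) is Spearman by
  default (product-moment selectable), and Δ inherits the choice.

Top-pleiotropic sets take the `⌊pct/100 × G⌋` genes with largest Δ, ties
broken lexicographically by gene ID so results are independent of input
order; top-1% ⊆ top-3% by construction.

## Networks

Structural covariance (SC) is the region × region Pearson correlation of a
phenotype across subjects (rank correlation selectable); genetic similarity
(GS) is the region × region Spearman correlation of gene-level Z profiles.
Both are symmetric, signed, unit-diagonal. A pre-residualization hook
exists for covariate-adjusted phenotypes, but no covariate model is
mandated.

* **Edge coupling**: Spearman over strictly upper-triangular edges.
  Distance adjustment regresses the edges of each network on geodesic
  distance (linear by default, `exp(−d)` selectable) and rank-correlates
  residuals; edges with undefined distance (cross-hemisphere on the sphere
  model) are excluded.
* **Cophenetic comparison**: each matrix's rows are embedded as Euclidean
  distance profiles, clustered by Ward linkage (the squared-increment
  `ward` variant of scipy, i.e. Ward.D2-equivalent), and the two cophenetic
  distance matrices Pearson-correlated. The null permutes the leaf labels
  of the second dendrogram while holding both topologies fixed (1000
  permutations, `+1`-smoothed upper-tail p). Which network is permuted is
  symmetric by construction and documented as GS by convention in the
  pipeline.
* **Modules and degree**: Louvain multi-level modularity optimization on
  the weight matrix after clamping negative edges to zero (absolute-value
  and signed policies selectable; the clamp matches community-detection
  routines that require non-negative weights). Weighted degree
  `k_i = Σ_{j≠i} w_ij` under the same positive-weight default;
  intra-modular degree is the mean edge weight from node i to same-module
  nodes, inter-modular to out-of-module nodes. The alternative reading of
  "mean weighted degree over all nodes in the same module" (mean of their
  degrees) is noted but not implemented; the edge-mean form keeps the
  quantity node-local. Singleton modules get intra = 0 with a warning.
* **Hub–pleiotropy coupling**: Spearman correlation of degree (or
  intra/inter-modular degree) with the regional PLS1 weight map,
  significance from the spin null below.

## Spin permutation nulls

Cortical maps are spatially autocorrelated; naive parcel-permutation
p-values are anti-conservative. The spin null draws a uniform random 3D
rotation (QR of a Gaussian matrix, sign-corrected), applies it to the
left-hemisphere parcel centroids and its sagittal mirror image to the
right, and reassigns parcels to the rotated positions by a bijection.

The assignment is the minimum-total-distance (Hungarian) matching by
default. The greedy closest-pair heuristic is available
(`assignment="greedy"`), but its poor tail assignments measurably corrupt
the smoothness of the spun map: on 180 mirrored parcels with smooth
bilateral null maps, greedy assignment inflates the spin test's type-I
error to ~0.11–0.18 at α = 0.05, while optimal assignment holds
~0.05–0.07. Spins preserve hemisphere membership exactly, and identical
seeds reproduce identical permutation tables.

Map–map spin tests report the observed Spearman correlation against the
null of one map spun (two-tailed, `+1`-smoothed; which map is spun is
immaterial within Monte-Carlo error). Atlas-class enrichment compares the
mean map value inside a class to outside under the spun map; the
within/between edge test compares mean within-class edge weight to
class-to-outside edge weight under spun class labels. Both are BH-FDR
corrected across classes, and classes with fewer than two parcels are
excluded with a warning. With coarse parcellations a near-identity rotation
occasionally reproduces the identity permutation, so even a perfect
self-correlation may receive p slightly above the 1/(n_spins+1) floor.

## Enrichment stages

* **Positional**: exact hypergeometric upper tail per chromosomal band,
  BH across tested bands; zero-overlap bands are reported untested by
  default. Band definitions are an input table; the synthetic generator
  emits a compatible toy catalogue.
* **Constraint**: logistic regression of set membership on the
  mutation-intolerance flag plus log gene length over the full universe;
  Wald inference on the flag coefficient. Perfect separation falls back to
  a ridge-penalized fit with a warning.
* **Cell type**: expression is log-transformed; each gene's per-type value
  is divided by its mean over all types (per-gene relative expression — the
  documented reading of an ambiguous centring convention), mean-centred,
  and used as the predictor in per-type membership regressions with log
  length as covariate; BH across cell types.
* **Developmental trajectories**: log-transform, centring to each sample's
  mean expression plus a unit offset (reproducing the `scale(center=T,
  scale=F)+1` convention — a constant panel therefore centres to 1, not 0),
  gene-set mean per sample, averaged within each of nine developmental
  windows with a normal-approximation 95% CI across samples; single-sample
  windows yield point estimates only.

## Mendelian randomization

Instruments: exposure SNPs with p < 5e−8, greedily clumped — keep the
lowest-p SNP, drop same-chromosome SNPs within 10,000 kb whose LD r² with
it exceeds 0.001 (distance-only when no LD table is supplied), repeat.
Regions enter the panel only with ≥ 5 instruments (power criterion).

Harmonization aligns outcome effects to the exposure's effect allele:
swapped alleles flip the sign, strand flips resolve via complements, and
palindromic SNPs with effect-allele frequency in [0.42, 0.58] are dropped
under strict mode (window configurable); every exclusion is logged with a
reason. Steiger filtering drops SNPs whose approximate variance explained
(z²/n) is larger in the outcome than the exposure.

Estimators: IVW is weighted least squares of `beta_out` on `beta_exp`
through the origin with weights `1/se_out²`; Cochran's
`Q = Σ w_j (beta_out,j − β̂ beta_exp,j)²` on n−1 df, and the IVW SE is
inflated by `sqrt(Q/(n−1))` whenever heterogeneity exceeds its expectation
(multiplicative random effects). MR-Egger adds a free intercept (the
directional-pleiotropy estimate) after orienting instruments to
`beta_exp ≥ 0`, with t-inference on n−2 df and the same multiplicative
inflation floored at 1. The weighted median interpolates the 50th
percentile of Wald ratios under inverse-delta-method-variance weights, with
a parametric bootstrap SE. MR-PRESSO-style outlier resampling is out of
scope; the packaged sensitivity summary is sign concordance of
IVW/Egger/weighted-median plus Q.

## The synthetic-data generator

The generator's defaults define the desk-scale study conditions: 60
regions (two mirrored hemispheres of 30), 2,000 genes, 2,000 subjects,
3 metrics, unit noise SD. At this scale the full pipeline, including exact
leave-one-out refits and all 1000-draw resampling procedures, completes in
about a minute.

All generative models are linear-Gaussian so that every downstream
statistic has a closed-form oracle:

* **Gene associations**: `Z[i,g] = a_i f_g + s·(module term + spatial
  term) + ε`, `y[g] = c f_g + η`. The pleiotropic loadings are
  `a_i = shared_loading_scale × r_i` with `r_i ~ U(0.5, 1.5)` a
  region-strength (hub) gradient; genes in one planted chromosome band have
  `|f_g|` inflated 3×, clustering the top pleiotropic genes positionally.
  The expected row correlation `corr(Z[i,·], y) = a_i c /
  √((a_i²+b_i²+σ²)(c²+σ_y²))` is verified against large draws.
* **Phenotypes**: `pheno[s,i] = λ_i g_{s,m(i)} + spatial field + ε` with
  `λ_i = module_loading × r_i`; modules are spatially contiguous
  (nearest-of-k seed directions), and the spatial field has covariance
  `exp(−rate × chordal distance)`, planting monotone distance decay.
* **Shared structure**: the metric-private part of the gene model reuses
  the phenotype model's module assignment and spatial kernel (independent
  gene-level factors), which plants the SC–GS network coupling the analysis
  targets. The hub gradient `r_i` enters the genetic side only through the
  pleiotropic loadings `a_i`: if it also scaled the metric-private
  variance, hub regions' inflated private variance would attenuate
  `corr(Z[i,·], y)` and mask the planted hub–pleiotropy relation.
* **Parcellation**: unit-sphere centroids; the right hemisphere is the
  sagittal mirror of the left, with mirrored atlas-class labels — the
  bilateral correspondence that mirrored spin rotations assume, and a
  reasonable idealization of real atlases.
* **GWAS summaries**: `beta_out = β·beta_exp_true + α + e` with planted
  causal effect β = 0.26, pleiotropy intercepts
  `α ~ N(mr_pleiotropy_mean, τ²)`, 50 strong instruments in separated LD
  blocks, and configurable palindromic/strand-flip fractions for
  harmonization tests.

What the generator does **not** emulate: LD between instruments beyond
block labels, gene-length or LD structure in association statistics,
non-Gaussian phenotype distributions, site/age/sex covariates, and any
realistic magnitude calibration of gene-level Z-scores. Passing tests
demonstrate that the estimators recover planted signal under the stated
linear-Gaussian conditions — not that real MRI-GWAS data satisfy those
conditions. The cross-metric correlation of metric-private factors is a
free knob, not an inferred quantity, since nothing in the target analyses
identifies it.

Determinism: one master seed; each generator and each resampling procedure
draws from its own named substream (`SeedSequence` spawn keyed by a stable
label hash), so adding draws in one stage never perturbs another, and
identical config + seed reproduces byte-identical outputs end to end.

## Numerical and degenerate-input conventions

Empirical p-values always use `+1` smoothing and are never zero. Constant
maps, constant phenotype columns, zero-variance responses, and empty gene
sets raise errors naming the offending unit; zero-variance predictor
columns in PLS are dropped with a warning. `Xᵀy` below 1e−12 is a
degenerate-response error. All tabular outputs are TSV with stable column
order and explicit ID columns; matrices carry ID headers to prevent silent
misalignment.

## Known limitations

* The spin null is a parcel-centroid approximation; vertex-level spins and
  surface-based geodesics are out of scope.
* Cross-hemisphere geodesic distances are undefined on the sphere model and
  excluded rather than imputed.
* The overlap permutation null ignores gene length and LD (above).
* No multi-component or regularized PLS, no LD-aware competitive gene-set
  tests, no multivariable MR or colocalization.
* Reported desk-scale effect sizes (e.g. PLS1 variance explained ~31%) are
  properties of the synthetic conditions, deliberately strong for testable
  recovery, and are not calibrated to any empirical dataset.
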