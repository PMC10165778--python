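# Methods

This note documents the models and procedures implemented in `migbiome`,
the choices made where the underlying methods literature leaves the design
open, and what the synthetic-data tests do and do not establish.

## Synthetic cohort generator

The generator emulates a multi-ethnic, two-generation gut-microbiome cohort
with the statistical structure the downstream analyses assume. It is a
log-normal latent-factor compositional model:

1. Each planted block *b* (a trophic-network stand-in) carries one latent
   factor per sample, `z_b ~ N(0,1)`. An ASV *i* in block *b* has
   log-abundance `μ_i + σ(√ρ_b z_b + √(1−ρ_b) ε_i)`, so any two block
   members correlate at ρ_b on the log scale. `μ_i` is the block's
   per-ethnicity baseline, plus the generation shift for 2nd-generation
   samples, plus a fixed per-ASV offset (sd 0.3–0.5) so members differ in
   abundance.
2. Background ASVs are i.i.d. log-normal (σ = 1) around a power-law mean
   profile (`−decay · ln rank`), making "top-N most abundant" selection
   non-degenerate.
3. Log-abundances are softmaxed to proportions; counts are multinomial at a
   library size uniform over `library_size_range`.

Defaults mirror a large urban multi-ethnic cohort at reduced size: 5
ethnic strata, 60–150 samples per generation, 600 ASVs, four planted blocks
(BBB 40 ASVs, *P. copri* network 30, *P. stercorea* network 25, CMO 25) at
within-block correlation 0.7, Prevotella-type blocks more abundant in the
Turkish/Moroccan/South-Asian strata, and generation shifts (BBB +0.5,
Prevotella networks −0.8, CMO −0.5 log units) in the Turkish, Moroccan and
Dutch strata only — the Dutch "generations" standing for the age-cutoff
split. Library sizes default to 16,000–45,000 reads so the standard
rarefaction depth retains every sample.

**Planted correlations are calibrated, not nominal.** Two attenuation
sources exist between a planted parameter and the rank correlation measured
on counts: the normal-score/rank conversion and mechanism noise. Requested
correlations are therefore converted to latent Pearson values via
`r' = 2 sin(πr/6)`; covariates (age, BMI, triglycerides) are generated as
linear functions of the normal-scores of the realized block share plus
Gaussian noise, which plants the requested Spearman ρ almost exactly.

**Diversity coupling.** Alpha-diversity is emergent, so a planted
correlation between a block and the Shannon index is implemented by tilting
the per-sample background power-law exponent
(`decay · exp(−0.45·u)`, `u` correlated with the block factor; the tilted
profile is renormalized to constant total background mass so block shares
are unaffected in expectation). The tilt mechanism has a measured
correlation ceiling of ≈ 0.92 (multinomial noise and the block share itself
also move Shannon), which is divided out so the planted value names the
realized rank correlation. Because the tilt moves all background ASVs
coherently, it induces diffuse background–block correlations that
contaminate correlation-heatmap blocks; the coupling is therefore **off in
the default design** and used only in dedicated association designs. The
coupled latent includes the block's generation shift (in factor units), so
a planted block reduction propagates to lower 2nd-generation diversity, as
observed in real migrant cohorts.

What the generator does **not** emulate: real marginal abundance
distributions, sequencing-read artifacts (chimeras, primer bias),
zero-inflation beyond the multinomial, phylogenetic signal in background
abundances, or household/diet covariate structure. A green recovery test
establishes that the pipeline detects the planted structure under this
model — not that it would behave identically on real data.

## Diversity

Shannon entropy uses natural log; "effective number" is `exp(H)`. Faith's
PD sums branch lengths over the union of root-to-tip paths of observed tips
and **includes the path to the root** by default (the convention of the
common R implementation), switchable via `include_root=False`. Rarefaction
is multivariate-hypergeometric (without replacement) at depth 15,221;
samples below depth are dropped and logged. Each sample's draw comes from a
substream keyed by (global seed, CRC32 of the sample id), so adding or
removing samples never perturbs the others.

## Beta diversity and PERMANOVA

Bray–Curtis is computed on rarefied counts (equivalent to proportions at
even depth). Generalized UniFrac uses the branch-wise formula with
α ∈ [0, 1]; α = 0.5 is the default (the method's recommended compromise
between unweighted and weighted extremes); α = 1 reproduces normalized
weighted UniFrac, which is cross-checked against an independent
implementation in the tests. PERMANOVA uses sequential (Type-I) sums of
squares on the Gower-centered squared-distance matrix with terms in the
order given (`generation + age`); each term's pseudo-F is taken against the
full-model residual; p-values permute sample labels freely,
`p = (#{F* ≥ F} + 1)/(n_perm + 1)`, ties counted conservatively. The
dissimilarity-to-reference contrast compares each 1st-generation sample to
the older (≥ 42 y) reference samples and each 2nd-generation sample to the
younger ones, correcting the age confound before the Mann–Whitney contrast.

## Phylogenetic agglomeration

A node is agglomerable when its maximum distance to any descendant tip is
≤ the height threshold (default 0.10); clusters are the tip sets under
maximal agglomerable nodes. Node height (not cophenetic distance) is used:
it is well defined on non-ultrametric trees and matches common
tree-agglomeration practice, but it admits tip pairs up to cophenetic
distance 2 × 0.10 — callers wanting the cophenetic convention should pass
half their threshold. Cluster ids are the most abundant member's id.

## Consensus trophic networks

Per stratum, Spearman ρ among the top-200 ASVs by mean relative abundance
(rarefied counts; constant ASVs get ρ = 0 off-diagonal). Blocks come from
agglomerative clustering on Euclidean distances between ρ rows. Three
design points are open in the underlying procedure and were fixed here:

- **Linkage**: complete (the default of the heatmap tooling such figures
  are typically drawn with); `average` and `ward` are accepted.
- **Block count**: maximal mean silhouette width over k ∈ [3, 15] — an
  objective surrogate for reading blocks off a heatmap by eye.
- **Cross-stratum matching**: each named cluster takes the block holding
  most of its anchor-tagged ASVs (ties → higher mean anchor correlation);
  the two Prevotella networks are distinguished by species-level anchors.

An ASV is core when matched in ≥ 6 of the 10 strata; the denominator stays
10 even when an ASV misses a stratum's top-200. These surrogates are not
claimed identical to a by-eye procedure; the recovery tests show they
recover planted blocks at Jaccard ≥ 0.96 on the default cohort.

## Enterotypes

The classical scheme: relative genus abundances + pseudocount 1e-9,
square-root Jensen–Shannon divergence (base e; a metric), PAM (BUILD +
best-improvement SWAP, deterministic) at k = 3. The DMM scheme: counts of
phylogeny-agglomerated clusters filtered at detection > 0.1 % (strict) in
≥ 50 % of samples (non-strict), fitted with a K = 4 mixture of
Dirichlet-multinomials. EM details: responsibilities in log space; π by
responsibility means; α by the Minka fixed point
`α_j ← α_j · Σᵢ rᵢ(ψ(x_ij+α_j) − ψ(α_j)) / Σᵢ rᵢ(ψ(Nᵢ+A) − ψ(A))`
(≤ 15 inner iterations), which is a minorize–maximize step, so the
log-likelihood trace is non-decreasing (asserted in tests to 1e-7
relative). Five starts from k-means centers (computed on canonically sorted
rows, making the fit invariant to sample order) × jitter; best likelihood
kept; convergence at relative change < 1e-6. K is fixed (3 and 4) — no
model selection. Rarefied counts are used for comparability; the raw-count
alternative is a one-line change at the call site.

## Stability-selection classifier

Features are relative abundances from the rarefied table: top-1000 by mean
abundance, then top-100 by one-way ANOVA F against the binary label
(zero-variance features get F = 0). Per subset (20 by default): undersample
the majority class to the minority size, draw a class-stratified 0.5
fraction, then leave-one-out: each training fold runs a randomized search
(10 draws from the grid) scored by stratified 3-fold CV AUC on a 90 % split
with the winner confirmed on the held-back 10 %, refits on the whole fold,
and contributes the held-out class probability and its impurity
importances. Per-subset AUC pools the LOO probabilities (a per-fold AUC is
undefined for single observations); importances are averaged over all
refitted models and normalized so the maximum is 100 %.

The classifier is a pluggable contract (fit / predict_proba /
feature_importances_, deterministic given a seed); the default is
scikit-learn's `GradientBoostingClassifier`. The default grid — depth
{2,3,4,6}, learning rate {0.01,0.05,0.1,0.3}, estimators {50,100,200},
subsample and feature-subsample {0.6,0.8,1.0} — is a configurable substitute
for an unpublished original.

**Small-sample behavior worth knowing.** Pooled-LOO AUC on balanced sets is
not unbiased at small n: each fold trains on a 9-vs-10 split whose minority
is the held-out sample's class. Probability-threshold classifiers show the
classic pessimistic bias (a depth-1 stump nulls at ≈ 0.35 AUC on 20-sample
LOO sets); the boosted ensemble is near-calibrated (≈ 0.52). Additionally,
at 40 samples all subsets of one label permutation share the same chance
feature–label correlation, so a single-permutation null has sd ≈ 0.09; the
calibration test therefore draws an independent permutation per subset.
Both effects vanish at realistic cohort sizes.

## Statistical conventions

All group contrasts are two-sided Mann–Whitney U (exact enumeration when
n₁+n₂ ≤ 20 without ties, otherwise normal approximation with tie and
continuity correction). BH correction is applied within each family of
comparisons (per metric, per report) — the narrowest defensible family,
configurable by passing families explicitly. Spearman ρ uses average ranks;
constant inputs yield missing values with a warning rather than errors so
report tables can carry missing cells. Significance tiers follow
(.) ≤ 0.1, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001.

## Known limitations

- GUniFrac pairwise loops are O(n² · branches) in Python; fine to ~1,000
  samples, not tuned beyond that.
- PAM is exact BUILD+SWAP, O(k·n²) per sweep; practical to a few thousand
  samples.
- The B/P ratio uses a pseudocount of 1 read on both sums; at very shallow
  depths this shrinks extreme ratios toward zero.
- The agglomeration height convention (node height vs cophenetic) changes
  cluster granularity by up to a factor of two; both are available but only
  node height is tested against the brute-force oracle.
- No plotting: the pipeline emits tables; heatmap/ordination rendering is
  left to the caller.
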