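# migbiome

Analysis pipeline for **generational gut-microbiome transitions** in
multi-ethnic cohorts: given a 16S ASV count table, a rooted phylogeny and
sample metadata (ethnicity, migration generation, age, sex, BMI,
triglycerides), it quantifies how the microbiota of 1st-generation migrants
(born abroad) differs from the 2nd generation (born in the host country) and
which community structures drive that shift. It is aimed at microbiome
researchers studying westernization/assimilation of the gut ecosystem who
need the full analysis stack behind such studies as tested, reusable code —
together with a synthetic cohort generator that stands in for
controlled-access cohort data.

## What it computes

- **Rarefaction & α-diversity** — subsampling without replacement to a fixed
  depth (default 15,221 reads); Shannon index `H = −Σ pᵢ ln pᵢ`, effective
  number `e^H`, richness, Faith's phylogenetic diversity; Mann–Whitney U
  generation contrasts with Benjamini–Hochberg FDR per metric family.
- **β-diversity** — Bray–Curtis `d(a,b) = Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ)` and
  generalized UniFrac
  `d = Σ_b l_b (p_A+p_B)^α |p_A−p_B|/(p_A+p_B) / Σ_b l_b (p_A+p_B)^α`
  (α = 0.5 default); classical PCoA; sequential (Type-I) PERMANOVA with
  permutation p-values (`d ~ generation + age`, 999 permutations); mean
  dissimilarity of each migrant generation to an age-matched reference group.
- **B/P ratio** — `log10(Σ Bacteroides+Phocaeicola / Σ Prevotella)` per
  sample (pseudocount 1), a westernization index.
- **Phylogenetic agglomeration** — ASVs collapsed at tree height 0.10
  (genus-like clusters), counts conserved exactly.
- **Consensus trophic networks** — per ethnicity × generation stratum, the
  Spearman ρ matrix of the top-200 most abundant ASVs is hierarchically
  clustered (Euclidean distance of ρ rows, complete linkage, silhouette-chosen
  block count); blocks are labeled by anchor genera
  (BBB = *Bacteroides/Blautia/Bifidobacterium*, the *P. copri* and
  *P. stercorea* networks, CMO =
  *Christensenellaceae/Methanobrevibacter/Oscillibacter*); an ASV is a **core**
  member when it sits in the labeled block in ≥ 6 of the 10 strata.
- **Enterotypes** — the classical 3-type scheme (sqrt Jensen–Shannon
  divergence on genus abundances + PAM, k = 3) and a 4-component
  Dirichlet-multinomial mixture (EM with a Minka fixed-point M-step) on
  agglomerated clusters filtered at 0.1 % detection / 50 % prevalence.
- **Stability-selection classifier** — per stratum, gradient-boosted trees
  distinguish generation 1 from 2 over 20 random balanced subsets
  (undersampling + a stratified 0.5 fraction), leave-one-out evaluation with
  per-fold randomized hyperparameter search (10 settings, 3-fold CV on 90 %
  of the training fold, winner checked on the 10 % split); per-subset AUC
  from pooled LOO probabilities; mean-decrease-in-impurity importances
  normalized to 0–100 %.
- **Synthetic cohorts** — log-normal latent-factor + multinomial generator
  with planted correlated ASV blocks, per-stratum baselines and generation
  shifts, coupled covariates, and ground truth for recovery testing.

## Worked example

```bash
migbiome synth --seed 1 --out cohort/
migbiome trophic --table cohort/asv_table.tsv --tree cohort/tree.nwk \
    --meta cohort/metadata.csv --taxonomy cohort/taxonomy.tsv --out core.json
```

```
BBB: 40 core ASVs
P_copri: 29 core ASVs
P_stercorea: 24 core ASVs
CMO: 25 core ASVs
```

The four consensus clusters recover the generator's planted blocks (40, 30,
25, 25 ASVs). Running the whole pipeline on the same cohort
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
prints, among other stages:

```
[  10.7s] PERMANOVA (Bray-Curtis ~ generation + age): R2(generation)=0.01955 p=0.001
[  11.1s] median log10 B/P: Turkish gen1 -0.62 -> gen2 0.02; Dutch gen1 0.01
[  11.9s] consensus core recovery (Jaccard vs planted): BBB=1.00, P_copri=0.97, P_stercorea=0.96, CMO=1.00
[  40.7s] DMM enterotypes (K=4): weights [0.36, 0.27, 0.14, 0.22], loglik -627593 in 30 EM iterations
[ 161.2s] stability selection (Turkish): AUC 0.75 +/- 0.05; top feature ASV0001 (gen2)
```

Reading the output: migration generation explains ~2 % of Bray–Curtis
variance at the permutation floor p = 0.001; the Turkish stratum's B/P
log-ratio rises from −0.62 to 0.02 across generations (the planted
Prevotella-to-Bacteroides shift); all four planted trophic networks are
recovered essentially exactly; and the generation classifier reaches
AUC 0.75 on the stratum with a planted shift, its top marker being a
BBB-block ASV enriched in the 2nd generation.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
default synthetic cohort from the seed and re-runs every pipeline stage end
to end (rarefaction, α/β-diversity with PERMANOVA, B/P ratios,
agglomeration, trophic consensus, both enterotype schemes, the association
report, and the stability-selection classifier), printing a stage-by-stage
summary and writing the results JSON to `--out`.

## Layout

- `src/migbiome/syndata.py` — cohort generator with planted ground truth
- `src/migbiome/io.py` — TSV/newick/CSV readers & writers, `AnalysisConfig`
- `src/migbiome/stats.py` — Mann–Whitney U, BH adjustment, Spearman ρ
- `src/migbiome/diversity.py` — rarefaction, α-diversity, contrasts
- `src/migbiome/beta.py` — Bray–Curtis, GUniFrac, PCoA, PERMANOVA
- `src/migbiome/agglom.py` — phylogenetic agglomeration, genus aggregation
- `src/migbiome/taxon.py` — B/P ratio, cluster abundances, association report
- `src/migbiome/trophic.py` — correlation blocks & 6-of-10 consensus
- `src/migbiome/enterotypes.py` — JSD+PAM and the DMM model
- `src/migbiome/ml.py` — stability-selection classifier harness
- `src/migbiome/cli.py` — `migbiome` command-line entry point

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
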