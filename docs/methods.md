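# Methods

`femr` estimates how medications and modifiable exposures shift a cancer
field-effect (FE) gene-expression signature in healthy colon mucosa, in two
modes that share one analysis chain: an **observational** mode using the
measured exposure, and an **instrumental** (Mendelian-randomization, MR)
mode that replaces the exposure with a genetic instrument — the oriented
dosage of a drug-target cis-eQTL, or a GWAS-weighted allele score.  Because
alleles are randomized at conception, the instrumental contrast is immune to
the lifestyle/comorbidity confounding that afflicts the observational one.

## Analysis chain

For a cohort with counts `Y` (genes × samples), phenotypes and genotypes:

1. **Gene filtering.** Genes shorter than 300 bp are removed, then genes
   whose CPM fails to reach 1.0 in at least `ceil(0.225 · n)` samples.  The
   fraction generalizes an absolute cutoff of "more than 100 of 445
   samples" so smaller cohorts behave proportionally; the absolute form
   remains available (`min_samples_abs`).  Length is applied before the CPM
   prevalence rule.
2. **Normalization.** Trimmed-mean-of-M-values (TMM) factors, computed
   against the sample whose upper-quartile CPM is closest to the cohort
   mean: per gene, M = log2 CPM ratio and A = mean log2 abundance over
   genes positive in both samples; 30 % of each M tail and 5 % of each A
   tail are trimmed by rank; the factor is 2^(inverse-asymptotic-variance
   weighted mean of surviving M), centred to geometric mean 1.  Fewer than
   20 surviving genes triggers a warning and an untrimmed fallback.
   Log-CPM uses effective library sizes with a prior count of 0.5.
3. **Differential expression.** Per gene, a negative-binomial GLM with log
   link and `log(effective library size)` offset.  The gene-wise NB2
   dispersion φ_g is a method-of-moments estimate,
   φ̂ = Σ[(y−μ̂)² − μ̂] / Σ μ̂², from a covariates-only Poisson fit, floored
   at 1e−4; the full model is then fit by IRLS (tol 1e−8, ≤ 50 iterations,
   batched across genes) and the exposure coefficient tested with a Wald z.
   Continuous exposures are standardized first, so log2FC is per SD;
   binary exposures are per category.  Covariates: sex, age, tissue
   location, sequencing batch.  Non-converged genes keep their estimate but
   are excluded from ranking and from the Benjamini–Hochberg denominator
   (q computed by exact step-up).  A second engine (`lm_logcpm`, OLS on
   log-CPM with t tests) provides a fast cross-check; the two agree in sign
   for ≥ 95 % of q < 0.1 genes on simulated data.

   This NB-Wald default deliberately replaces the quasi-likelihood
   empirical-Bayes machinery of the usual count-model packages: downstream
   enrichment consumes only the ranking, which is robust to that
   substitution, and the OLS engine supplies the second opinion.  Exact
   numerical replication of those packages is a non-goal.
4. **Ranking.** Genes sorted by `signed_z = sign(log2FC)·|Φ⁻¹(p/2)|`
   (default; `log2fc` available), ties broken lexicographically by gene id
   so rankings are reproducible.
5. **Enrichment (GSEA).** Weighted Kolmogorov–Smirnov running sum: walking
   the ranking, signature genes add `|r|^w / Σ_hits |r|^w` (w = 1), others
   subtract `1/(N − n_set)`; the enrichment score (ES) is the signed
   maximum deviation.  NES divides ES by the mean |ES| of same-sign null
   draws; p is the add-one-smoothed same-sign tail probability, so p can
   never fall below `1/(1 + same-sign draws)` — use enough permutations for
   your alpha.  A positive significant NES labels the exposure *risk*
   (signature pushed up), a negative one *protective*, at alpha = 0.01.

### Choice of permutation null

Two nulls are implemented.  `enrichment.gsea()` draws random same-size gene
sets from the ranked universe (drawn by gene identity under the seed, which
makes an exposure-orientation flip negate every null ES exactly).  This is
calibrated when set members are exchangeable with the background — true for
random sets, demonstrably false for a co-regulated signature: any shared
factor (here the latent confounder driving the FE genes) moves the whole
set coherently in the ranking and inflates the observed ES variance
relative to random sets, making the gene-set null anticonservative.

The pipeline therefore defaults to an **exposure-permutation null**
(`gsea_null: phenotype`): the exposure vector is shuffled across samples,
every gene's statistic is recomputed, and the set's ES re-evaluated, which
preserves inter-gene correlation under the null.  To make 500+ refits
cheap, the permuted statistics are OLS t-values on covariate-residualized
log-CPM (Frisch–Waugh, fully vectorized; ~1 s per 500 permutations at
2,000 genes), used for both the observed and the null ES so the test is
internally consistent; the NB-GLM table still provides the reported
per-gene effects.  `gsea_null: gene_set` restores the competitive null.

6. **Eligibility and reporting.** Binary exposures run only if the minority
   category holds at least `max(20, ceil(0.05 · n))` individuals.  Counts
   of genes with q < 0.1 up/down accompany each ES.  Alcohol is categorized
   per sex: non-drinkers, then moderate/heavy split at the sex-specific
   median among drinkers (at the median → moderate).

## Instruments

**Drug-target proxies.** The top cis-eQTL of the target gene: every SNP
with MAF ≥ 0.01 in a ±1 Mb closed window (configurable; the window size is
a convention) is regressed against inverse-normal (Blom,
Φ⁻¹((rank−3/8)/(n+¼))) expression, optionally with covariates projected
out; the smallest-p SNP wins.  Strength: F = t² (= r²(n−2)/(1−r²) for the
single-SNP case); F < 10 flags a weak instrument and the pipeline refuses
the MR run.  The effect allele is the expression-increasing one; drug
action orients the instrument — inducer/agonist/ligand count those alleles,
inhibitor/antagonist use 2 − dosage, so the two orientations of one SNP
give exactly mirrored enrichment.  Replication requires p < 0.01 *with a
consistent beta sign* in at least one independent cohort; the sign
condition goes beyond a bare p threshold because a sign-flipped replication
is not mechanistic validation.  Cohorts missing the SNP are untestable,
not failures.

**Allele scores.** `score_i = Σ_j w_j d_ij` over GWAS weights (beta per SD
of trait, per effect allele).  Dosages are harmonized to the weight file:
used as-is when the effect allele is the genotype alt allele, flipped to
2 − d when it is the ref allele, dropped (logged) otherwise.
Strand-ambiguous A/T and C/G SNPs are dropped; proxy substitution through
an external LD panel is out of scope.  The weights file is assumed LD-pruned
and genome-wide significant — an input contract, not recomputed.  Score
strength uses the score-on-exposure regression R² and the F formula above.
A validity screen regresses each measured exposure on the standardized
score with age/sex/PC adjustment; the score is reliable only if it
associates (p < 0.05) with its own exposure and with nothing else, and
unreliable scores are refused.  Genetic PCs come from the SVD of the
standardized dosage matrix with a deterministic sign convention.

## Synthetic cohorts

The generator (`femr.simulate`) emulates the statistical shape of a healthy
colon-mucosa cohort with a known causal diagram: latent confounder
U ~ N(0,1) → exposure and FE genes; score SNPs → continuous exposure → FE
genes (coefficient δ, log2FC per exposure unit); an eQTL SNP → target-gene
expression.  Defaults are the study-scale conditions: n = 400 samples,
2,000 genes, 211 FE genes, binary medication prevalence 33/399, eQTL MAF
0.3, NB dispersion φ = 0.2 (a conventional bulk-tissue figure; the
variance model is μ + φμ²), baseline log2 CPM ~ N(4, 2), nominal depths
log-uniform in [5 × 10⁵, 2 × 10⁶] (scaled down from real depths for speed;
realized column sums are proportionally lower), covariate effect sizes of
0.02–0.1 log2 units, allele-score R² target 0.1, and eqtl_beta = 0.48
SD/allele, calibrated once so the realized single-SNP F averages ≈ 30 at
the default n.  Continuous exposures are stored on a BMI-like scale
(27.5 ± 4.2) and re-standardized by the DEA.  A `structure_seed` separates
gene/SNP-level draws from sample-level draws so replication cohorts can
share a transcriptome.

What the generator does **not** emulate: LD between score SNPs (instruments
are assumed pre-pruned), gene–gene correlation beyond the single shared
confounder, per-gene dispersions, cell-type mixture effects, and any
mediation of drug effects through the target gene's expression (the
medication effect acts directly, so a drug-target proxy run on a default
cohort is a negative control).  Passing tests therefore certify the
statistical machinery and the confounding/causal contrast, not robustness
to every failure mode of real cohorts.

## Numerical choices and degenerate inputs

Dispersion floored at 1e−4 and capped at 100; IRLS linear predictors
clipped to ±30 to avoid overflow; a 1e−10 ridge on the per-gene Fisher
information guards all-zero weights; p-values clipped at 1e−300 before
Φ⁻¹.  Constant exposures, singular designs (aliased columns are named),
empty cis windows, all-hit or no-hit gene sets, zero-margin 2×2 tables and
constant expression vectors all raise informative errors.  Missing
genotypes are mean-imputed per SNP (logged), preserving sample alignment;
missing phenotype entries drop the sample for that exposure only
(complete-case per analysis, n recorded in the output).

## Problem sizes used in the checks

The test-suite simulations use n = 400 / 2,000 genes where effect recovery
is asserted, and n = 300 / 800 genes / 120 FE genes across the 50-seed
confounding-vs-causal scenario sweeps, with 500 permutations per run —
sizes chosen so a full run of suite plus acceptance script completes on a
laptop-class single core in a couple of minutes while leaving every
assertion comfortably powered.  A known small bias: CPM/TMM normalization
absorbs part of a widespread one-sided expression shift (10 % of genes
moving 1 log2 unit per SD shifts library sizes themselves), attenuating
the mean recovered FE effect by ~5–10 %; the recovery band in the tests
accounts for this composition effect, which real count pipelines share.
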