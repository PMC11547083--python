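"""Synthetic cohorts with known causal and confounding structure.

The generator emulates the statistical shape of a healthy-colon-mucosa
expression cohort: negative-binomial bulk counts over ~2,000 genes and ~400
samples, a 211-gene field-effect (FE) signature, sex/age/location/batch
covariate structure, a latent confounder U driving both the exposure and the
FE genes, a cis-eQTL for a designated drug-target gene, and a polygenic
allele score instrumenting a continuous exposure.  The causal diagram:

    U -> exposure,  U -> FE genes      (confounding path)
    G_score -> exposure -> FE genes    (instrumented causal path, delta)
    G_eqtl  -> target gene expression  (drug-target proxy)

All ground-truth parameters travel with the outputs in a
:class:`SimulationTruth`, enabling parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, GenotypeMatrix, PhenotypeTable

_LN2 = math.log(2.0)

#: unambiguous allele pairs used for simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass
class SimulationTruth:
    """Generator parameters = ground truth for recovery tests."""

    seed: int = 0
    structure_seed: int | None = None  # gene/SNP-level draws; defaults to seed,
                                       # share it across replication cohorts
    n_samples: int = 400
    n_genes: int = 2000
    n_fe_genes: int = 211
    exposure_type: str = "binary"          # "binary" (medication) or "continuous"
    exposure_name: str = "ATC:A10BA02"     # column written into the phenotype table
    medication_prevalence: float = 33 / 399  # metformin-like minority fraction
    causal_effect_delta: float = 0.0       # log2FC on FE genes per exposure unit
    confounder_effect_on_fe: float = 0.0   # log2FC per SD of U on FE genes
    confounder_effect_on_exposure: float = 0.0  # logit (binary) or linear (cont.) coef
    # eQTL instrument for the drug-target gene
    eqtl_beta: float = 0.48     # SD of inverse-normal target expression per alt allele
    eqtl_maf: float = 0.3
    n_cis_snps: int = 50
    target_gene_log2cpm: float = 6.0
    # polygenic score instrument
    score_snp_count: int = 20
    score_r2_target: float = 0.1
    # count model
    nb_dispersion: float = 0.2
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 2.0
    library_size_range: tuple = (5e5, 2e6)
    # nuisance covariate effect scales (log2 units)
    batch_effect_sd: float = 0.1
    sex_effect_sd: float = 0.05
    location_effect_sd: float = 0.05
    age_effect_sd: float = 0.02
    # filled by simulate_cohort
    fe_gene_ids: list = field(default_factory=list)
    target_gene: str = ""
    eqtl_snp: str = ""
    score_snp_ids: list = field(default_factory=list)
    score_betas: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.01 < self.eqtl_maf <= 0.5:
            raise ValueError("eqtl_maf must lie in (0.01, 0.5]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_fe_genes > self.n_genes:
            raise ValueError("requested FE set larger than n_genes")
        if self.exposure_type not in ("binary", "continuous"):
            raise ValueError("exposure_type must be 'binary' or 'continuous'")
        for v in (self.causal_effect_delta, self.confounder_effect_on_fe,
                  self.confounder_effect_on_exposure, self.eqtl_beta):
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(truth: SimulationTruth
                    ) -> tuple[CountMatrix, PhenotypeTable, GenotypeMatrix, SimulationTruth]:
    """Draw one cohort under the generative model.

    Steps: latent confounder U ~ N(0,1); independent score and cis SNPs at
    their MAFs; allele score scaled so it explains ``score_r2_target`` of the
    continuous exposure's variance; exposure = score + U + noise (continuous)
    or Bernoulli(logistic(a0 + c_U * U)) (binary medication); per-gene log2
    mean = baseline + library offset + delta * FE * exposure + f * FE * U +
    covariate terms (+ eQTL shift per alt allele for the target gene);
    counts ~ NB(mean, dispersion).  Same seed, bit-identical outputs.

    Gene- and SNP-level structure (baselines, FE membership, covariate
    coefficients, MAFs, alleles, true score weights) is drawn from
    ``structure_seed`` (default: ``seed``); sample-level draws come from
    ``seed``.  Cohorts sharing a structure_seed emulate independent sample
    sets measured on the same transcriptome/genome, as in cross-dataset
    replication.
    """
    rng = np.random.default_rng(truth.seed)
    rng_s = np.random.default_rng(truth.seed if truth.structure_seed is None
                                  else truth.structure_seed)
    n, g = truth.n_samples, truth.n_genes

    # --- samples: covariates and confounder ----------------------------------
    sex = np.where(rng.random(n) < 0.64, "F", "M").astype(object)
    age = np.clip(np.round(rng.normal(60.0, 8.0, n), 1), 39.0, 80.0)
    location = rng.choice(np.array(["ascending", "transverse", "descending"],
                                   dtype=object), size=n, p=(0.315, 0.327, 0.358))
    batch = rng.choice(np.array(["B1", "B2"], dtype=object), size=n)
    u = rng.normal(0.0, 1.0, n)

    # --- genotypes ------------------------------------------------------------
    gene_ids = np.array([f"G{i:05d}" for i in range(g)], dtype=object)
    if truth.fe_gene_ids:
        # preset FE membership (e.g. shared across replication cohorts)
        fe_set = np.isin(gene_ids, np.asarray(truth.fe_gene_ids, dtype=object))
        if fe_set.sum() != len(truth.fe_gene_ids):
            raise ValueError("preset fe_gene_ids not all present among gene ids")
        rng_s.choice(g, size=truth.n_fe_genes, replace=False)  # keep stream aligned
    else:
        fe_idx = rng_s.choice(g, size=truth.n_fe_genes, replace=False)
        fe_set = np.zeros(g, dtype=bool)
        fe_set[fe_idx] = True
    # target gene: a non-FE gene hosting the drug-target eQTL
    target_idx = int(rng_s.choice(np.flatnonzero(~fe_set)))

    n_score, n_cis = truth.score_snp_count, truth.n_cis_snps
    score_maf = rng_s.uniform(0.1, 0.5, n_score)
    cis_maf = rng_s.uniform(0.05, 0.5, n_cis)
    eqtl_idx = int(rng_s.integers(n_cis))
    cis_maf[eqtl_idx] = truth.eqtl_maf
    mafs = np.concatenate([score_maf, cis_maf])
    dosages = rng.binomial(2, mafs[:, None], size=(n_score + n_cis, n)).astype(float)

    snp_ids = np.array([f"rs9{j:06d}" for j in range(n_score)]
                       + [f"rs1{j:06d}" for j in range(n_cis)], dtype=object)
    chrom = np.array(["1"] * n_score + ["12"] * n_cis, dtype=object)
    locus_pos = 120_000_000
    cis_pos = np.sort(rng_s.integers(locus_pos - 500_000, locus_pos + 500_000, n_cis))
    pos = np.concatenate([np.arange(1, n_score + 1) * 2_000_000, cis_pos])
    pair_idx = rng_s.integers(len(_ALLELE_PAIRS), size=n_score + n_cis)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    geno = GenotypeMatrix(snp_ids, chrom, pos, ref, alt, dosages, sample_ids)

    # --- exposure -------------------------------------------------------------
    w = rng_s.normal(0.0, 1.0, n_score)
    raw_score = w @ dosages[:n_score]
    s_sd = raw_score.std(ddof=0)
    score_std = (raw_score - raw_score.mean()) / (s_sd if s_sd > 0 else 1.0)
    c_u = truth.confounder_effect_on_exposure
    if truth.exposure_type == "continuous":
        r2 = truth.score_r2_target
        resid_var = 1.0 - r2 - c_u ** 2
        if resid_var < 0:
            raise ValueError("score_r2_target + confounder^2 exceeds unit variance")
        x = (math.sqrt(r2) * score_std + c_u * u
             + math.sqrt(resid_var) * rng.normal(0.0, 1.0, n))
        exposure_for_genes = x
        # store on a BMI-like scale; DEA standardizes back to unit SD
        pheno_exposure = 27.5 + 4.2 * x
    else:
        a0 = math.log(truth.medication_prevalence / (1 - truth.medication_prevalence))
        m = (rng.random(n) < _sigmoid(a0 + c_u * u)).astype(float)
        exposure_for_genes = m
        pheno_exposure = m.astype(int)

    # --- expression -----------------------------------------------------------
    lib_lo, lib_hi = truth.library_size_range
    lib = np.exp(rng.uniform(math.log(lib_lo), math.log(lib_hi), n))
    b_g = rng_s.normal(truth.baseline_log2cpm_mean, truth.baseline_log2cpm_sd, g)
    b_g[target_idx] = truth.target_gene_log2cpm

    sex_coef = rng_s.normal(0.0, truth.sex_effect_sd, g)
    batch_coef = rng_s.normal(0.0, truth.batch_effect_sd, g)
    loc_coef = rng_s.normal(0.0, truth.location_effect_sd, (g, 2))
    age_coef = rng_s.normal(0.0, truth.age_effect_sd, g)

    is_m = (sex == "M").astype(float)
    is_b2 = (batch == "B2").astype(float)
    is_tr = (location == "transverse").astype(float)
    is_de = (location == "descending").astype(float)
    age_z = (age - age.mean()) / age.std(ddof=0)

    log2_mu = (b_g[:, None]
               + np.log2(lib / 1e6)[None, :]
               + sex_coef[:, None] * is_m[None, :]
               + batch_coef[:, None] * is_b2[None, :]
               + loc_coef[:, [0]] * is_tr[None, :]
               + loc_coef[:, [1]] * is_de[None, :]
               + age_coef[:, None] * age_z[None, :])
    fe_col = fe_set.astype(float)[:, None]
    log2_mu += truth.causal_effect_delta * fe_col * exposure_for_genes[None, :]
    log2_mu += truth.confounder_effect_on_fe * fe_col * u[None, :]

    # eQTL shift on the target gene, expressed per SD of its residual spread
    phi = truth.nb_dispersion
    mu_target = 2.0 ** truth.target_gene_log2cpm * lib.mean() / 1e6
    sd_log2 = math.sqrt(phi + 1.0 / mu_target) / _LN2
    eqtl_shift_log2 = truth.eqtl_beta * sd_log2
    log2_mu[target_idx] += eqtl_shift_log2 * dosages[n_score + eqtl_idx]

    mean = 2.0 ** np.clip(log2_mu, -20.0, 25.0)
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mean)).astype(np.int64)
    lengths = rng_s.integers(300, 5000, g)  # all pass the length filter by default

    counts_cm = CountMatrix(gene_ids, sample_ids, counts, lengths)
    pheno_df = pd.DataFrame({
        "sample_id": sample_ids, "sex": sex, "age": age, "location": location,
        "batch": batch, "U_latent": u,
    }).set_index("sample_id")
    pheno_df[truth.exposure_name] = pheno_exposure
    pheno = PhenotypeTable(pheno_df)

    truth.fe_gene_ids = list(gene_ids[fe_set])
    truth.target_gene = str(gene_ids[target_idx])
    truth.eqtl_snp = str(snp_ids[n_score + eqtl_idx])
    truth.score_snp_ids = list(snp_ids[:n_score])
    truth.score_betas = list(w)
    return counts_cm, pheno, geno, truth


def target_gene_locus(truth: SimulationTruth) -> tuple[str, int]:
    """Genomic locus used for cis-eQTL scans of the simulated target gene."""
    return ("12", 120_000_000)


def weights_from_truth(truth: SimulationTruth, geno: GenotypeMatrix):
    """Instrument-weight table matching the simulated score SNPs.

    Effect alleles are the genotype alt alleles for positive true weights
    and the ref alleles otherwise, so all betas are trait-increasing as in
    a discovery GWAS weight file.
    """
    from .instruments import InstrumentWeights

    rsids, eff, oth, beta = [], [], [], []
    for rsid, wj in zip(truth.score_snp_ids, truth.score_betas):
        i = geno.index_of(rsid)
        if wj >= 0:
            eff.append(str(geno.alt_allele[i]))
            oth.append(str(geno.ref_allele[i]))
        else:
            eff.append(str(geno.ref_allele[i]))
            oth.append(str(geno.alt_allele[i]))
        rsids.append(rsid)
        beta.append(abs(wj))
    order = np.argsort(rsids)
    return InstrumentWeights(
        rsid=np.asarray(rsids, dtype=object)[order],
        effect_allele=np.asarray(eff, dtype=object)[order],
        other_allele=np.asarray(oth, dtype=object)[order],
        beta=np.asarray(beta, dtype=float)[order],
        ambiguous=np.zeros(len(rsids), dtype=bool)[order],
        source="simulated",
    )


def make_toy_signature_tables(seed: int = 0
                              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two small paired DE tables with known pass/fail status per gene.

    Returns ``(table_a, table_b, labels)``; ``labels`` has columns ``gene``
    and ``status`` in {pass-up, pass-down, fail-direction, fail-magnitude,
    fail-p, fail-missing}.  Boundary genes probe the strict |logFC| > 1 and
    adjusted p < 0.01 rules, including a raw p of 1e-5 that Bonferroni
    inflation over 20,000 tests pushes to 0.2.
    """
    rng = np.random.default_rng(seed)
    rows_a, rows_b, labels = [], [], []

    def add(gene, lfc_a, p_a, lfc_b, p_b, status, in_b=True):
        rows_a.append((gene, lfc_a, p_a))
        if in_b:
            rows_b.append((gene, lfc_b, p_b))
        labels.append((gene, status))

    add("UP01", 1.2, 0.001, 1.5, 0.005, "pass-up")
    add("UP02", 2.4, 1e-6, 1.1, 0.003, "pass-up")
    add("DN01", -1.3, 0.002, -1.8, 0.004, "pass-down")
    add("DIR1", 1.2, 0.001, -1.5, 0.001, "fail-direction")
    add("MAG1", 0.9, 0.001, 1.5, 0.001, "fail-magnitude")
    add("MAG2", 1.0, 0.001, 1.5, 0.001, "fail-magnitude")  # exactly 1: excluded
    add("PVL1", 1.4, 0.2, 1.6, 0.001, "fail-p")            # 1e-5 * 20000 = 0.2
    add("PVL2", 1.4, 0.01, 1.6, 0.001, "fail-p")           # exactly 0.01: excluded
    add("MIS1", 1.4, 0.001, np.nan, np.nan, "fail-missing", in_b=False)
    for i in range(20):  # unremarkable filler genes: neither large nor significant
        lfc = float(np.clip(rng.normal(0.0, 0.4), -0.9, 0.9))
        add(f"BG{i:02d}", lfc, rng.uniform(0.05, 1.0),
            lfc + float(rng.normal(0.0, 0.05)), rng.uniform(0.05, 1.0), "fail-null")

    table_a = pd.DataFrame(rows_a, columns=["gene", "logFC", "p_adj"])
    table_b = pd.DataFrame(rows_b, columns=["gene", "logFC", "p_adj"])
    label_df = pd.DataFrame(labels, columns=["gene", "status"])
    return table_a, table_b, label_df
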