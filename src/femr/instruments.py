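"""Genetic instruments: cis-eQTL proxies for drug targets and GWAS-weighted
allele scores for modifiable exposures.

A drug-target proxy is the top cis-eQTL of the target gene (smallest p in a
window around the gene), oriented by the drug's action: carrying more copies
of the expression-increasing allele mimics an inducer/agonist/ligand, the
reflected dosage (2 - d) mimics an inhibitor/antagonist.  Allele scores sum
GWAS per-SD effect weights over trait-increasing allele dosages after
harmonizing genotype alleles to the weight file (strand-ambiguous A/T and
C/G SNPs are dropped).  Strength is diagnosed with the instrument
F-statistic (F < 10 flags a weak instrument) and validity with an adjusted
association screen of the instrument against its own exposure and the other
measured exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import is_ambiguous_pair
from .types import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

INCREASING_ACTIONS = frozenset({"inducer", "agonist", "ligand"})
DECREASING_ACTIONS = frozenset({"inhibitor", "antagonist"})


@dataclass
class EqtlProxy:
    """Top cis-eQTL of a drug-target gene, usable as an MR instrument."""

    target_gene: str
    rsid: str
    chrom: str
    pos: int
    effect_allele: str          # the expression-increasing allele
    other_allele: str
    effect_allele_is_alt: bool  # relative to the genotype matrix coding
    beta: float                 # SD of inverse-normal expression per effect allele
    se: float
    p: float
    r2: float
    fstat: float
    n: int
    action: str | None = None
    validated: bool | None = None

    @property
    def weak(self) -> bool:
        return self.fstat < 10.0


@dataclass
class InstrumentWeights:
    """GWAS summary weights (beta per SD of trait, per effect allele)."""

    rsid: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta: np.ndarray
    ambiguous: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.rsid)) != len(self.rsid):
            raise ValueError("duplicate rsid in instrument weights")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite weight beta")

    def __len__(self) -> int:
        return len(self.rsid)


@dataclass
class AlleleScore:
    """Weighted allele score per sample, with strength diagnostics."""

    sample_ids: np.ndarray
    values: np.ndarray
    n_snps_used: int
    n_dropped_ambiguous: int
    n_dropped_unmatched: int
    r2_vs_exposure: float | None = None
    fstat: float | None = None
    exposure_name: str | None = None
    reliable: bool | None = None


def _residualize(v: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None:
        return v - v.mean()
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def _covar_matrix(covariates: np.ndarray | None, n: int) -> tuple[np.ndarray | None, int]:
    if covariates is None:
        return None, 1  # intercept only (handled by centering)
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    return C, C.shape[1]


def scan_cis_eqtl(expr: np.ndarray, geno: GenotypeMatrix,
                  gene_locus: tuple[str, int], target_gene: str = "",
                  window_bp: int = 1_000_000, maf_min: float = 0.01,
                  covariates: np.ndarray | None = None) -> EqtlProxy:
    """Scan the cis window (closed interval ``pos +/- window_bp``) of a gene
    for its top eQTL.

    ``expr`` should already be inverse-normal transformed.  Each SNP is
    tested by linear regression of expression on dosage (plus covariates,
    projected out of both sides); the SNP with the smallest p becomes the
    proxy, reported with its partial r2 and F-statistic, and with the
    effect allele set to the expression-increasing allele.
    """
    chrom, pos = gene_locus
    expr = np.asarray(expr, dtype=float)
    n = expr.size
    in_window = ((geno.chrom.astype(str) == str(chrom))
                 & (geno.pos >= pos - window_bp) & (geno.pos <= pos + window_bp)
                 & (geno.maf >= maf_min))
    if not in_window.any():
        raise ValueError(f"no SNP with MAF >= {maf_min} in the cis window of "
                         f"{chrom}:{pos} +/- {window_bp}")
    sub = geno.subset_snps(in_window)

    C, k_cov = _covar_matrix(covariates, n)
    ey = _residualize(expr, C)
    dfree = n - k_cov - 1
    best = None
    for i in range(sub.n_snps):
        d = _residualize(sub.dosages[i], C)
        sxx = float(d @ d)
        if sxx <= 0:
            continue
        b = float(ey @ d) / sxx
        resid = ey - b * d
        s2 = float(resid @ resid) / dfree
        se = np.sqrt(s2 / sxx) if s2 > 0 else 0.0
        t = b / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(t), dfree)
        if best is None or p < best[0]:
            best = (p, i, b, se, t)
    if best is None:
        raise ValueError("all cis-window SNP fits were singular")
    p, i, b, se, t = best
    r2 = t * t / (t * t + dfree)
    fstat = t * t
    eff_is_alt = b >= 0
    return EqtlProxy(
        target_gene=target_gene,
        rsid=str(sub.snp_ids[i]), chrom=str(sub.chrom[i]), pos=int(sub.pos[i]),
        effect_allele=str(sub.alt_allele[i] if eff_is_alt else sub.ref_allele[i]),
        other_allele=str(sub.ref_allele[i] if eff_is_alt else sub.alt_allele[i]),
        effect_allele_is_alt=bool(eff_is_alt),
        beta=abs(b), se=float(se), p=float(p), r2=float(r2), fstat=float(fstat),
        n=n,
    )


def orient_dosage(proxy: EqtlProxy, geno: GenotypeMatrix,
                  action: str) -> np.ndarray:
    """Dosage vector mimicking the drug's effect on the target.

    Inducers/agonists/ligands count copies of the expression-increasing
    allele; inhibitors/antagonists use the reflection ``2 - dosage``.
    """
    d_alt = geno.dosages[geno.index_of(proxy.rsid)]
    d_increasing = d_alt if proxy.effect_allele_is_alt else 2.0 - d_alt
    action = action.lower()
    if action in INCREASING_ACTIONS:
        return d_increasing.copy()
    if action in DECREASING_ACTIONS:
        return 2.0 - d_increasing
    raise ValueError(f"unknown drug action {action!r}; expected one of "
                     f"{sorted(INCREASING_ACTIONS | DECREASING_ACTIONS)}")


def validate_proxy(proxy: EqtlProxy,
                   replications: list[tuple[np.ndarray, GenotypeMatrix]],
                   alpha: float = 0.01,
                   covariates_list: list[np.ndarray | None] | None = None
                   ) -> EqtlProxy:
    """Replicate the proxy association in independent cohorts.

    ``replications`` pairs an inverse-normal expression vector for the target
    gene with that cohort's genotypes.  The proxy is validated when at least
    one replication shows p < alpha with a beta of consistent sign (same
    effect allele orientation).  Cohorts missing the SNP are untestable and
    do not count either way.
    """
    if covariates_list is None:
        covariates_list = [None] * len(replications)
    validated = False
    tested = 0
    for (expr, geno), cov in zip(replications, covariates_list):
        try:
            idx = geno.index_of(proxy.rsid)
        except KeyError:
            logger.info("proxy %s untestable in a replication cohort (SNP absent)",
                        proxy.rsid)
            continue
        tested += 1
        d = geno.dosages[idx]
        if not proxy.effect_allele_is_alt:
            d = 2.0 - d
        n = len(d)
        C, k_cov = _covar_matrix(cov, n)
        ey = _residualize(np.asarray(expr, dtype=float), C)
        ed = _residualize(d, C)
        sxx = float(ed @ ed)
        if sxx <= 0:
            continue
        b = float(ey @ ed) / sxx
        resid = ey - b * ed
        dfree = n - k_cov - 1
        s2 = float(resid @ resid) / dfree
        se = np.sqrt(s2 / sxx)
        t = b / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(t), dfree)
        if p < alpha and b > 0:  # proxy.beta > 0 by construction
            validated = True
    proxy.validated = validated if tested else None
    return proxy


def build_allele_score(geno: GenotypeMatrix, weights: InstrumentWeights,
                       drop_ambiguous: bool = True,
                       exposure: np.ndarray | None = None,
                       exposure_name: str | None = None) -> AlleleScore:
    """Weighted sum of trait-increasing allele dosages per sample.

    Each weight SNP is aligned to the genotype coding: dosage is used as-is
    when the weight's effect allele is the genotype alt allele, flipped to
    ``2 - d`` when it is the ref allele, and the SNP is dropped (logged) when
    the allele pair cannot be reconciled.  Strand-ambiguous SNPs are dropped
    when ``drop_ambiguous``.  Passing the measured exposure adds r2/F
    diagnostics from the score-on-exposure regression.
    """
    n = len(geno.sample_ids)
    score = np.zeros(n)
    used = 0
    dropped_amb = 0
    dropped_unmatched = 0
    for j in range(len(weights)):
        rsid = weights.rsid[j]
        if drop_ambiguous and weights.ambiguous[j]:
            dropped_amb += 1
            continue
        try:
            i = geno.index_of(rsid)
        except KeyError:
            dropped_unmatched += 1
            logger.info("score SNP %s absent from genotypes; dropped", rsid)
            continue
        ea, oa = weights.effect_allele[j], weights.other_allele[j]
        ref, alt = str(geno.ref_allele[i]).upper(), str(geno.alt_allele[i]).upper()
        if (ea, oa) == (alt, ref):
            d = geno.dosages[i]
        elif (ea, oa) == (ref, alt):
            d = 2.0 - geno.dosages[i]
        else:
            dropped_unmatched += 1
            logger.info("score SNP %s alleles %s/%s irreconcilable with "
                        "genotype %s/%s; dropped", rsid, ea, oa, ref, alt)
            continue
        score += weights.beta[j] * d
        used += 1
    if used == 0:
        raise ValueError("no weight SNP could be matched to the genotypes")
    result = AlleleScore(sample_ids=geno.sample_ids, values=score,
                         n_snps_used=used, n_dropped_ambiguous=dropped_amb,
                         n_dropped_unmatched=dropped_unmatched,
                         exposure_name=exposure_name)
    if exposure is not None:
        x = np.asarray(exposure, dtype=float)
        ok = np.isfinite(x)
        r = np.corrcoef(score[ok], x[ok])[0, 1]
        result.r2_vs_exposure = float(r * r)
        result.fstat = instrument_fstat(float(r * r), int(ok.sum()))
    return result


def instrument_fstat(r2: float, n: int, k: int = 1) -> float:
    """Instrument strength F: ``(r2/k) / ((1 - r2)/(n - k - 1))``."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def genetic_pcs(geno: GenotypeMatrix, n_pcs: int = 10) -> np.ndarray:
    """Principal components of the standardized dosage matrix (samples x PCs).

    Column-centred, variance-standardized dosages are decomposed by SVD; the
    sign of each PC is fixed so its largest-magnitude SNP loading is
    positive, making the output reproducible.
    """
    n = len(geno.sample_ids)
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of samples")
    Z = geno.dosages.T.astype(float)  # samples x snps
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    keep = sd > 0
    Z = Z[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_pcs = min(n_pcs, len(S))
    pcs = U[:, :n_pcs] * S[:n_pcs]
    for j in range(n_pcs):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def validity_screen(instrument: np.ndarray | AlleleScore, pheno: PhenotypeTable,
                    exposures: list[str], own_exposure: str,
                    adjust: tuple = ("age", "sex"),
                    pcs: np.ndarray | None = None,
                    alpha: float = 0.05) -> tuple[pd.DataFrame, bool]:
    """Screen an instrument against its own exposure and other variables.

    Each listed variable is regressed on the (standardized) instrument with
    age/sex/PC adjustment.  The instrument is deemed reliable iff it
    associates (p < alpha) with its own exposure and with none of the other
    screened variables; unreliable instruments should be excluded from MR.
    """
    values = instrument.values if isinstance(instrument, AlleleScore) else instrument
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    z = (values - values.mean()) / sd if sd > 0 else values - values.mean()
    df = pheno.data
    adj_parts: list[np.ndarray] = []
    for a in adjust:
        if a not in df.columns:
            continue
        s = df[a]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for lev in sorted(s.dropna().unique())[1:]:
                adj_parts.append((s == lev).astype(float).to_numpy())
        else:
            adj_parts.append(s.to_numpy(dtype=float))
    if pcs is not None:
        adj_parts.extend(np.asarray(pcs, dtype=float).T)

    rows = []
    for var in exposures:
        y = df[var]
        if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
            if isinstance(y.dtype, pd.CategoricalDtype) and y.cat.ordered:
                y = y.cat.codes.astype(float).replace(-1, np.nan)
            else:
                levels = sorted(y.dropna().unique())
                y = (y == levels[-1]).astype(float).where(df[var].notna())
        y = pd.to_numeric(y, errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(y)
        X = np.column_stack([np.ones(int(ok.sum())), z[ok],
                             *[a[ok] for a in adj_parts]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        dfree = X.shape[0] - X.shape[1]
        s2 = float(resid @ resid) / dfree
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(s2 * XtX_inv[1, 1])
        t = beta[1] / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), dfree)
        rows.append({"variable": var, "beta": float(beta[1]), "p": float(p),
                     "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    own = table.loc[table["variable"] == own_exposure, "p"]
    others = table.loc[table["variable"] != own_exposure, "p"]
    reliable = bool(len(own) and (own.iloc[0] < alpha) and (others >= alpha).all())
    if isinstance(instrument, AlleleScore):
        instrument.reliable = reliable
    return table, reliable
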