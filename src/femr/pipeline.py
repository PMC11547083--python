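"""End-to-end observational and instrumental (MR) analyses per exposure.

Both modes share one recipe once the exposure column is fixed: filter genes,
TMM-normalize, fit the per-gene differential-expression model with
sex/age/location/batch adjustment, rank genes, and run GSEA of the
field-effect up-signature on the ranking.  The observational mode uses the
measured exposure (binary medications must pass the minority-category rule);
the instrumental mode swaps in an oriented drug-target eQTL dosage or a
GWAS-weighted allele score, refusing weak (F < 10) or validity-screen-failed
instruments.  A positive significant enrichment reads as risk (the exposure
pushes the field-effect genes up), a negative one as protective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .dea import DesignSpec, build_design, fit_dea, minority_rule, rank_statistic
from .enrichment import GseaResult, es_from_positions, gsea
from .expression import filter_genes, normalize
from .instruments import AlleleScore, EqtlProxy, orient_dosage
from .types import DatasetBundle, FESignature


@dataclass
class ExposureResult:
    """One exposure x dataset x mode outcome row."""

    exposure: str
    mode: str                   # observational / instrumental
    dataset: str
    skipped: bool = False
    skip_reason: str | None = None
    n_no: int | None = None
    n_yes: int | None = None
    n_used: int | None = None
    n_up_fdr: int = 0
    n_down_fdr: int = 0
    es_raw: float | None = None
    nes: float | None = None
    p_perm: float | None = None
    direction: str | None = None
    instrument_fstat: float | None = None
    instrument_label: str | None = None
    dea_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "dea_table"}
        return d


@dataclass
class ReplicationSummary:
    exposure: str
    datasets: list[str]
    spearman_r: float
    spearman_p: float
    n_shared_top_quartile: int
    es_signs_agree: bool
    replicated: bool


def _ols_exposure_t(Y_resid: np.ndarray, x: np.ndarray, Q: np.ndarray,
                    dfree: int) -> np.ndarray:
    """t-statistics of the exposure coefficient for all genes at once.

    ``Y_resid`` is log-CPM residualized against the covariate design whose
    orthonormal basis is ``Q``; ``x`` is the raw exposure vector, which is
    residualized here (Frisch–Waugh) so permuted exposures stay valid.
    """
    xr = x - Q @ (Q.T @ x)
    sxx = float(xr @ xr)
    if sxx <= 0:
        raise ValueError("exposure has no variation after covariate adjustment")
    beta = Y_resid @ xr / sxx
    rss = np.einsum("gn,gn->g", Y_resid, Y_resid) - beta ** 2 * sxx
    s2 = np.maximum(rss, 0.0) / dfree
    se = np.sqrt(s2 / sxx)
    return np.where(se > 0, beta / se, 0.0)


def _phenotype_null_gsea(Y: np.ndarray, C: np.ndarray, x: np.ndarray,
                         is_member: np.ndarray, n_perm: int, seed: int,
                         alpha: float, weight_exp: float) -> GseaResult:
    """GSEA with an exposure-permutation null.

    The ranking metric is the per-gene OLS t-statistic of the exposure on
    log-CPM given the covariates.  The null shuffles the exposure vector
    across samples and recomputes every gene's statistic and the set's
    enrichment score, so inter-gene correlation within the signature is
    preserved under the null — the property a competitive gene-set
    permutation cannot provide for a co-regulated signature.
    """
    n, k = C.shape
    dfree = n - k - 1
    Q, _ = np.linalg.qr(C)
    Y_resid = Y - (Y @ Q) @ Q.T
    n_genes = Y.shape[0]
    m = int(is_member.sum())

    def set_es(t: np.ndarray) -> float:
        order = np.argsort(-t, kind="stable")
        ranks = np.empty(n_genes, dtype=np.int64)
        ranks[order] = np.arange(n_genes)
        pos = ranks[is_member]
        return es_from_positions(pos, np.abs(t[is_member]) ** weight_exp, n_genes)

    es = set_es(_ols_exposure_t(Y_resid, x, Q, dfree))
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        null_es[b] = set_es(_ols_exposure_t(Y_resid, rng.permutation(x), Q, dfree))

    same_sign = null_es * np.sign(es) > 0
    kk = int(same_sign.sum())
    if kk == 0:
        p = 1.0 / (1.0 + n_perm)
        denom = np.abs(null_es).mean()
    else:
        exceed = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1.0 + exceed) / (1.0 + kk)
        denom = np.abs(null_es[same_sign]).mean()
    nes = es / denom if denom > 0 else np.nan
    if p < alpha and nes > 0:
        direction = "risk"
    elif p < alpha and nes < 0:
        direction = "protective"
    else:
        direction = "null"
    return GseaResult(es_raw=es, nes=float(nes), p_perm=float(p), n_perm=n_perm,
                      seed=seed, set_size_used=m, n_dropped=0, direction=direction)


def _run_with_exposure(bundle: DatasetBundle, exposure_col: str,
                       exposure_values: np.ndarray | None,
                       signature: FESignature, config: RunConfig,
                       mode: str, label: str,
                       covariates: tuple | None = None) -> ExposureResult:
    """Shared stage chain for both analysis modes."""
    pheno = bundle.pheno
    if exposure_values is not None:
        df = pheno.data.copy()
        df[exposure_col] = np.asarray(exposure_values, dtype=float)
        pheno = type(pheno)(df)

    has_lengths = bundle.counts.gene_lengths_bp is not None
    filtered, report = filter_genes(
        bundle.counts,
        min_length_bp=config.min_gene_length_bp if has_lengths else 0,
        cpm_threshold=config.cpm_threshold,
        min_samples_frac=config.min_samples_frac,
        min_samples_abs=config.min_samples_abs,
    )
    norm = normalize(filtered, report)
    design = DesignSpec(exposure=exposure_col,
                        covariates=covariates if covariates is not None
                        else ("sex", "age", "location", "batch"))
    dea = fit_dea(filtered, norm, pheno, design, engine=config.engine,
                  fdr_level=config.fdr_level)
    if config.gsea_null == "phenotype":
        X, _, e_idx, mask = build_design(pheno, design)
        is_member = np.isin(filtered.gene_ids, np.asarray(signature.up_genes,
                                                          dtype=object))
        if not is_member.any():
            raise ValueError("no signature gene present after filtering")
        res = _phenotype_null_gsea(norm.logcpm[:, mask], np.delete(X, e_idx, axis=1),
                                   X[:, e_idx], is_member,
                                   n_perm=config.gsea_n_perm, seed=config.seed,
                                   alpha=config.gsea_alpha,
                                   weight_exp=config.gsea_weight)
    else:
        ranked = rank_statistic(dea, metric=config.rank_metric)
        res = gsea(ranked, signature.up_genes, n_perm=config.gsea_n_perm,
                   seed=config.seed, alpha=config.gsea_alpha,
                   weight_exp=config.gsea_weight)
    sig_de = dea[dea["q"] < config.fdr_level]
    return ExposureResult(
        exposure=label, mode=mode, dataset=bundle.label,
        n_used=int(dea["n_used"].iloc[0]),
        n_up_fdr=int((sig_de["log2fc"] > 0).sum()),
        n_down_fdr=int((sig_de["log2fc"] < 0).sum()),
        es_raw=res.es_raw, nes=res.nes, p_perm=res.p_perm,
        direction=res.direction, dea_table=dea,
    )


def run_observational(bundle: DatasetBundle, exposure: str,
                      signature: FESignature, config: RunConfig,
                      covariates: tuple | None = None) -> ExposureResult:
    """Observational mode: measured exposure -> DEA -> GSEA.

    Binary exposures (medication flags) are skipped, with the reason
    recorded, when the minority category is smaller than
    ``max(minority_min_count, ceil(minority_min_frac * n))``.
    """
    series = bundle.pheno.data[exposure].dropna()
    is_binary = series.nunique() == 2
    result_skeleton = ExposureResult(exposure=exposure, mode="observational",
                                     dataset=bundle.label)
    if is_binary:
        if not minority_rule(series, config.minority_min_count,
                             config.minority_min_frac):
            result_skeleton.skipped = True
            result_skeleton.skip_reason = (
                f"minority category below max({config.minority_min_count}, "
                f"{config.minority_min_frac:.0%} of n)")
            return result_skeleton
        counts = series.value_counts()
        n_no, n_yes = int(counts.max()), int(counts.min())
    else:
        n_no = n_yes = None
    res = _run_with_exposure(bundle, exposure, None, signature, config,
                             "observational", exposure, covariates)
    res.n_no, res.n_yes = n_no, n_yes
    return res


def run_instrumental(bundle: DatasetBundle,
                     instrument: EqtlProxy | AlleleScore,
                     signature: FESignature, config: RunConfig,
                     action: str | None = None, label: str | None = None,
                     covariates: tuple | None = None) -> ExposureResult:
    """Instrumental mode: oriented eQTL dosage or allele score -> DEA -> GSEA.

    Refuses weak drug-target proxies (F below ``config.fstat_min``) and
    allele scores that failed the validity screen.
    """
    if isinstance(instrument, EqtlProxy):
        if instrument.fstat < config.fstat_min:
            raise ValueError(
                f"weak instrument: F = {instrument.fstat:.2f} < {config.fstat_min}; "
                f"refusing MR run for {instrument.rsid}")
        if instrument.validated is False:
            raise ValueError(f"proxy {instrument.rsid} failed replication; refusing MR run")
        if action is None:
            action = instrument.action
        if action is None:
            raise ValueError("drug action required to orient an eQTL proxy")
        if bundle.geno is None:
            raise ValueError("instrumental run needs genotypes in the bundle")
        values = orient_dosage(instrument, bundle.geno, action)
        ilabel = label or f"{instrument.target_gene}:{instrument.rsid}:{action}"
        fstat = instrument.fstat
    elif isinstance(instrument, AlleleScore):
        if instrument.reliable is False:
            raise ValueError(
                f"allele score for {instrument.exposure_name!r} failed the "
                "validity screen; refusing MR run")
        if instrument.fstat is not None and instrument.fstat < config.fstat_min:
            raise ValueError(
                f"weak instrument: F = {instrument.fstat:.2f} < {config.fstat_min}")
        values = instrument.values
        ilabel = label or f"score:{instrument.exposure_name}"
        fstat = instrument.fstat
    else:
        raise TypeError("instrument must be an EqtlProxy or AlleleScore")

    res = _run_with_exposure(bundle, "__instrument__", values, signature,
                             config, "instrumental", ilabel, covariates)
    res.instrument_fstat = fstat
    res.instrument_label = ilabel
    return res


def categorize_alcohol(pheno) -> pd.Series:
    """Ordered non-drinker / moderate / heavy factor from grams-per-day.

    Zero intake is non-drinker; drinkers split at the sex-specific median
    among drinkers (at or below the median is moderate, above is heavy).
    """
    df = pheno.data if hasattr(pheno, "data") else pheno
    alcohol = pd.to_numeric(df["alcohol_g_day"], errors="coerce")
    if (alcohol < 0).any():
        raise ValueError("negative alcohol intake")
    out = pd.Series(pd.NA, index=df.index, dtype=object)
    out[alcohol == 0] = "non-drinker"
    for sex in df["sex"].dropna().unique():
        drinkers = (df["sex"] == sex) & (alcohol > 0)
        if not drinkers.any():
            continue
        med = alcohol[drinkers].median()
        out[drinkers & (alcohol <= med)] = "moderate"
        out[drinkers & (alcohol > med)] = "heavy"
    return pd.Series(pd.Categorical(out, categories=["non-drinker", "moderate", "heavy"],
                                    ordered=True), index=df.index, name="alcohol_cat")


def replicate(results: list[ExposureResult], mean_expr: list[pd.Series],
              alpha: float = 0.01) -> ReplicationSummary:
    """Cross-dataset replication summary for one exposure.

    Restricts to genes in the top quartile of mean expression in *both*
    datasets (first two results), correlates their log2FCs with Spearman's
    rho, and declares the finding replicated when the ES signs agree and the
    replication dataset reaches ``p_perm < alpha``.
    """
    if len(results) < 2:
        raise ValueError("replication needs at least two datasets")
    r0, r1 = results[0], results[1]
    tops = []
    for me in mean_expr[:2]:
        cut = me.quantile(0.75)
        tops.append(set(me.index[me >= cut]))
    shared = tops[0] & tops[1]
    t0 = r0.dea_table.set_index("gene_id")
    t1 = r1.dea_table.set_index("gene_id")
    shared = sorted(shared & set(t0.index) & set(t1.index))
    if not shared:
        raise ValueError("no shared top-quartile genes between datasets")
    rho, p = stats.spearmanr(t0.loc[shared, "log2fc"], t1.loc[shared, "log2fc"])
    signs_agree = (np.sign(r0.es_raw) == np.sign(r1.es_raw))
    replicated = bool(signs_agree and any(r.p_perm is not None and r.p_perm < alpha
                                          for r in results[1:]))
    return ReplicationSummary(
        exposure=r0.exposure, datasets=[r.dataset for r in results],
        spearman_r=float(rho), spearman_p=float(p),
        n_shared_top_quartile=len(shared),
        es_signs_agree=bool(signs_agree), replicated=replicated,
    )


def results_table(results: list[ExposureResult]) -> pd.DataFrame:
    """Flatten ExposureResults into one reporting DataFrame."""
    return pd.DataFrame([r.to_row() for r in results])
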