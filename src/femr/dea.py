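"""Per-gene differential expression against a measured or instrumental
exposure.

The default engine fits, per gene, a negative-binomial GLM with log link and
a log effective-library-size offset; the gene-wise dispersion is a
method-of-moments estimate from a null (covariates-only) Poisson fit, and
the exposure coefficient is tested with a Wald z.  A second engine runs
ordinary least squares on log2-CPM with the same design as a cross-check.
Continuous exposures are standardized to unit SD first, so the reported
log2 fold change is per SD of the exposure; categorical exposures give the
log2FC per category against the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import NormalizedExpression
from .types import CountMatrix, PhenotypeTable

_LN2 = math.log(2.0)


@dataclass
class DesignSpec:
    """Exposure + adjustment covariates for a DEA fit."""

    exposure: str
    covariates: tuple = ("sex", "age", "location", "batch")
    standardize_exposure: bool = True
    reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure cannot also be a covariate")


def _encode_exposure(series: pd.Series, standardize: bool) -> np.ndarray:
    if isinstance(series.dtype, pd.CategoricalDtype) and series.cat.ordered:
        x = series.cat.codes.to_numpy(dtype=float)
    elif series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        levels = sorted(series.dropna().unique())
        if len(levels) != 2:
            raise ValueError(
                f"categorical exposure must be binary or ordered; got levels {levels}"
            )
        x = (series == levels[1]).astype(float).to_numpy()
    else:
        x = series.to_numpy(dtype=float)
    uniq = np.unique(x[np.isfinite(x)])
    if uniq.size < 2:
        raise ValueError("exposure has no variation")
    if uniq.size == 2:
        # binary: recode to 0/1, never standardize
        x = (x == uniq[1]).astype(float)
    elif standardize:
        x = (x - np.nanmean(x)) / np.nanstd(x, ddof=1)
    return x


def build_design(pheno: PhenotypeTable, design: DesignSpec
                 ) -> tuple[np.ndarray, list[str], int, np.ndarray]:
    """Build the model matrix.

    Returns ``(X, column_names, exposure_column_index, sample_mask)`` where
    ``sample_mask`` marks the complete cases actually used (missing exposure
    or covariate values drop the sample).
    """
    df = pheno.data
    cols = [design.exposure, *[c for c in design.covariates if c in df.columns]]
    missing = [c for c in (design.exposure,) if c not in df.columns]
    if missing:
        raise KeyError(f"exposure column {missing[0]!r} not in phenotype table")
    mask = df[cols].notna().all(axis=1).to_numpy()
    sub = df.loc[mask]

    parts: list[np.ndarray] = [np.ones(len(sub))]
    names: list[str] = ["intercept"]
    x = _encode_exposure(sub[design.exposure], design.standardize_exposure)
    parts.append(x)
    exposure_idx = 1
    names.append(design.exposure)
    for cov in design.covariates:
        if cov not in df.columns:
            continue
        s = sub[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.unique())
            ref = design.reference.get(cov, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                parts.append((s == lev).astype(float).to_numpy())
                names.append(f"{cov}[{lev}]")
        else:
            parts.append(s.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _find_aliased(X, names)
        raise ValueError(f"design matrix is singular; aliased column(s): {aliased}")
    return X, names, exposure_idx, mask


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# batched IRLS

def _wls_batch(y_weighted_X: np.ndarray, A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, y_weighted_X[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.stack([np.linalg.lstsq(A[g], y_weighted_X[g], rcond=None)[0]
                         for g in range(A.shape[0])])


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             phi: np.ndarray | float, tol: float = 1e-8, max_iter: int = 50
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS for G simultaneous NB (or Poisson, phi=0) log-link GLMs sharing X.

    Returns (beta: G x p, fisher: G x p x p at convergence, converged: G bool).
    """
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).reshape(G, 1)
    # initial fit: OLS of log(y + 0.5) - offset on X (same projector for all genes)
    z0 = np.log(y + 0.5) - offset
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z0.T).T  # G x p
    converged = np.zeros(G, dtype=bool)
    A = np.empty((G, p, p))
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        A[:, np.arange(p), np.arange(p)] += 1e-10
        b = np.einsum("gn,ni->gi", w * z, X, optimize=True)
        new_beta = _wls_batch(b, A)
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged = delta < tol
        if converged.all():
            break
    return beta, A, converged


def _mom_dispersion(y: np.ndarray, X0: np.ndarray, offset: np.ndarray,
                    floor: float = 1e-4, ceil: float = 100.0) -> np.ndarray:
    """Method-of-moments NB2 dispersion from a null (covariate-only) Poisson
    fit: phi = sum[(y - mu)^2 - mu] / sum mu^2, floored."""
    beta0, _, _ = _irls_nb(y, X0, offset, 0.0, max_iter=25)
    mu = np.exp(np.clip(beta0 @ X0.T + offset, -30.0, 30.0))
    num = ((y - mu) ** 2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    return np.clip(num / np.maximum(den, 1e-300), floor, ceil)


def fit_dea(counts: CountMatrix, norm: NormalizedExpression,
            pheno: PhenotypeTable, design: DesignSpec,
            engine: str = "nbglm", fdr_level: float = 0.1) -> pd.DataFrame:
    """Differential expression of every gene against the design's exposure.

    Returns a table with columns ``gene_id, log2fc, se, stat, p, q, n_used,
    converged``; non-converged genes keep their estimate but get missing
    p/q and are excluded from the BH denominator.
    """
    if list(counts.sample_ids) != list(norm.sample_ids):
        raise ValueError("counts and normalization cover different samples")
    pheno = pheno.aligned_to(counts.sample_ids)
    X, names, e_idx, mask = build_design(pheno, design)
    n_used = int(mask.sum())

    if engine == "nbglm":
        y = counts.counts[:, mask].astype(float)
        offset = np.log(norm.effective_library_sizes[mask])
        X0 = np.delete(X, e_idx, axis=1)
        phi = _mom_dispersion(y, X0, offset)
        beta, A, converged = _irls_nb(y, X, offset, phi)
        cov = np.linalg.inv(A)
        se_nat = np.sqrt(np.maximum(cov[:, e_idx, e_idx], 0.0))
        coef = beta[:, e_idx]
        stat = np.where(se_nat > 0, coef / np.where(se_nat > 0, se_nat, 1.0), np.nan)
        p = 2.0 * stats.norm.sf(np.abs(stat))
        log2fc = coef / _LN2
        se = se_nat / _LN2
    elif engine == "lm_logcpm":
        Y = norm.logcpm[:, mask]
        dfree = n_used - X.shape[1]
        if dfree <= 0:
            raise ValueError("not enough samples for the design")
        XtX_inv = np.linalg.inv(X.T @ X)
        B = Y @ X @ XtX_inv  # G x p
        resid = Y - B @ X.T
        s2 = (resid ** 2).sum(axis=1) / dfree
        se = np.sqrt(s2 * XtX_inv[e_idx, e_idx])
        log2fc = B[:, e_idx]
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), np.nan)
        p = 2.0 * stats.t.sf(np.abs(stat), dfree)
        converged = np.isfinite(stat)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    ok = converged & np.isfinite(p)
    p = np.where(ok, p, np.nan)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "log2fc": log2fc,
        "se": se,
        "stat": stat,
        "p": p,
        "q": q,
        "n_used": n_used,
        "converged": ok,
    })


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_statistic(dea: pd.DataFrame, metric: str = "signed_z"):
    """Ranked gene list feeding GSEA.

    ``signed_z`` (default) ranks by sign(log2fc) * |Phi^-1(p/2)|; ``log2fc``
    ranks by the fold-change estimate.  Non-converged genes are excluded;
    ties are broken by gene id for determinism.
    """
    from .enrichment import RankedList

    tab = dea[dea["converged"]] if "converged" in dea.columns else dea
    if len(tab) == 0:
        raise ValueError("empty DEA table")
    if metric == "signed_z":
        pclip = np.clip(tab["p"].to_numpy(dtype=float), 1e-300, 1.0)
        vals = np.sign(tab["log2fc"].to_numpy()) * np.abs(stats.norm.ppf(pclip / 2.0))
    elif metric == "log2fc":
        vals = tab["log2fc"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown rank metric {metric!r}")
    genes = tab["gene_id"].to_numpy(dtype=object)
    order = np.lexsort((genes, -vals))
    return RankedList(gene_ids=genes[order], metric_values=vals[order])


def minority_rule(values, min_count: int = 20, min_frac: float = 0.05) -> bool:
    """Eligibility rule for binary exposures: the minority category must hold
    at least ``max(min_count, ceil(min_frac * n))`` individuals."""
    v = pd.Series(values).dropna()
    levels = v.unique()
    if len(levels) != 2:
        raise ValueError(f"minority_rule needs a binary variable, got {len(levels)} levels")
    n = len(v)
    minority = int(v.value_counts().min())
    return minority >= max(min_count, math.ceil(min_frac * n))
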