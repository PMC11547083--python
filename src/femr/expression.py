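"""Count filtering and normalization for bulk RNA-seq.

Genes are filtered on length and on a counts-per-million (CPM) prevalence
rule, between-sample normalization uses trimmed-mean-of-M-values (TMM)
factors, and the per-gene inverse-normal (Blom) transform prepares
expression vectors for eQTL scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix


@dataclass
class NormalizedExpression:
    """TMM-normalized log2-CPM with the normalization bookkeeping."""

    logcpm: np.ndarray            # genes x samples
    tmm_factors: np.ndarray       # per sample, geometric mean 1
    library_sizes: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    filter_report: pd.DataFrame | None = None

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors


def filter_genes(counts: CountMatrix, min_length_bp: int = 300,
                 cpm_threshold: float = 1.0, min_samples_frac: float = 0.225,
                 min_samples_abs: int | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove short genes and genes expressed in too few samples.

    A gene is kept when its length is >= ``min_length_bp`` (skipped if no
    lengths are attached or ``min_length_bp`` is 0) and its CPM reaches
    ``cpm_threshold`` in at least ``ceil(min_samples_frac * n_samples)``
    samples (or ``min_samples_abs + 1`` samples when the absolute rule is
    used: "less than threshold CPM in at most k samples" removes the gene).
    The length rule is applied first, the CPM prevalence is then evaluated
    on the full sample set.

    Returns the filtered matrix and a report of removals with reasons.
    """
    n = counts.n_samples
    if min_samples_abs is not None:
        required = int(min_samples_abs) + 1
    else:
        required = math.ceil(min_samples_frac * n)
    removed: list[tuple[str, str]] = []
    keep = np.ones(counts.n_genes, dtype=bool)

    if min_length_bp > 0:
        if counts.gene_lengths_bp is None:
            raise ValueError("gene lengths required for the minimum-length filter")
        short = counts.gene_lengths_bp < min_length_bp
        keep &= ~short
        removed += [(g, "length") for g in counts.gene_ids[short]]

    c = cpm(counts)
    prevalent = (c >= cpm_threshold).sum(axis=1) >= required
    low = keep & ~prevalent
    keep &= prevalent
    removed += [(g, "cpm") for g in counts.gene_ids[low]]

    if not keep.any():
        raise ValueError(
            "all genes removed by filtering; relax cpm_threshold / min_length_bp"
        )
    report = pd.DataFrame(removed, columns=["gene_id", "reason"])
    return counts.subset_genes(keep), report


def cpm(counts: CountMatrix | np.ndarray,
        library_sizes: np.ndarray | None = None) -> np.ndarray:
    """Counts per million: counts / library size * 1e6, per sample."""
    if isinstance(counts, CountMatrix):
        mat, lib = counts.counts, counts.library_sizes
    else:
        mat = np.asarray(counts, dtype=float)
        lib = mat.sum(axis=0) if library_sizes is None else np.asarray(library_sizes, float)
    if np.any(lib <= 0):
        raise ValueError("zero or negative library size")
    return mat / lib * 1e6


def log_cpm(counts: CountMatrix, tmm_factors: np.ndarray | None = None,
            prior_count: float = 0.5) -> np.ndarray:
    """log2 CPM on TMM-effective library sizes with a prior count.

    ``log2((count + prior) / (efflib + 2*prior) * 1e6)``.
    """
    lib = counts.library_sizes.astype(float)
    if tmm_factors is not None:
        lib = lib * np.asarray(tmm_factors, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("zero or negative effective library size")
    return np.log2((counts.counts + prior_count) / (lib + 2 * prior_count) * 1e6)


def _quantile_per_sample(mat: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(mat[:, j] / lib[j], p) for j in range(mat.shape[1])])


def tmm_factors(counts: CountMatrix | np.ndarray, ref_sample: int | None = None,
                logratio_trim: float = 0.30, abs_trim: float = 0.05,
                a_cutoff: float = -1e10) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference column, per-gene log2 CPM ratios (M)
    and average log2 abundances (A) are computed over genes with positive
    counts in both; the M distribution is trimmed by ``logratio_trim`` at
    each tail and the A distribution by ``abs_trim`` at each tail; the factor
    is 2 to the inverse-asymptotic-variance-weighted mean of the surviving M
    values.  Factors are centred to geometric mean 1.  The reference is the
    sample whose upper-quartile CPM is closest to the mean upper quartile.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    n_genes, n_samples = mat.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    if ref_sample is None:
        q75 = _quantile_per_sample(mat, lib)
        ref_sample = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[:, ref_sample]
    ref_lib = lib[ref_sample]

    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref_sample:
            continue
        factors[j] = _tmm_pair(mat[:, j], lib[j], ref, ref_lib,
                               logratio_trim, abs_trim, a_cutoff)
    # centre to geometric mean 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs: np.ndarray, lib: float, ref: np.ndarray, ref_lib: float,
              logratio_trim: float, abs_trim: float, a_cutoff: float) -> float:
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    m = np.log2((o / lib) / (r / ref_lib))
    a = 0.5 * np.log2((o / lib) * (r / ref_lib))
    # asymptotic variance of M (delta method on binomial counts)
    v = (lib - o) / (lib * o) + (ref_lib - r) / (ref_lib * r)
    ok = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, v = m[ok], a[ok], v[ok]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical-profile shortcut
        return 1.0
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < 20:
        warnings.warn(
            f"only {int(keep.sum())} genes survive TMM trimming; "
            "falling back to the untrimmed weighted mean",
            RuntimeWarning, stacklevel=3,
        )
        keep = np.ones(n, dtype=bool)
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def normalize(counts: CountMatrix, filter_report: pd.DataFrame | None = None,
              prior_count: float = 0.5) -> NormalizedExpression:
    """Convenience: TMM factors + log2 CPM in one NormalizedExpression."""
    factors = tmm_factors(counts)
    return NormalizedExpression(
        logcpm=log_cpm(counts, factors, prior_count),
        tmm_factors=factors,
        library_sizes=counts.library_sizes.astype(float),
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        filter_report=filter_report,
    )


def inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    ``Phi^-1((rank - 3/8) / (n + 1/4))`` with average ranks for ties; used to
    put per-gene expression on a standard-normal scale before eQTL scans.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("inverse_normal expects a 1-D vector of length >= 3")
    if np.all(x == x[0]):
        raise ValueError("constant vector: ranks undefined for instrument scan")
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))
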