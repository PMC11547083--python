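"""Field-effect signature derivation and signature-level descriptive tests.

The signature is the set of genes differentially expressed — same direction,
|log2FC| > 1 and Bonferroni-adjusted p < 0.01 — in two independent studies
comparing healthy tissue adjacent to tumor with tissue from healthy
individuals.  Descriptive tests: a 2x2 chi-squared for overlap with an
external gene set, and a Wilcoxon rank-sum comparing signature genes' mean
expression with the remaining genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import FESignature


def _adjusted_p(table: pd.DataFrame, m_tests: int | None) -> pd.Series:
    if "p_adj" in table.columns:
        return table["p_adj"]
    if "p" in table.columns:
        m = m_tests if m_tests is not None else len(table)
        return np.minimum(table["p"] * m, 1.0)
    raise ValueError("DE table needs a 'p_adj' column, or 'p' (+ optional m_tests)")


def derive_signature(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     lfc_min: float = 1.0, p_adj_max: float = 0.01,
                     m_tests_a: int | None = None, m_tests_b: int | None = None,
                     provenance: tuple[str, str] | None = None) -> FESignature:
    """Intersect two DE tables into an up/down gene signature.

    Tables are indexed (or keyed by a ``gene`` column) by gene id with a
    ``logFC`` column and either ``p_adj`` or raw ``p``; raw p-values are
    Bonferroni-adjusted with ``m_tests`` (defaulting to the table's row
    count).  A gene enters the signature iff it appears in both tables with
    the same logFC sign, |logFC| strictly greater than ``lfc_min`` in both,
    and adjusted p strictly below ``p_adj_max`` in both.
    """
    tabs = []
    for t, m in ((table_a, m_tests_a), (table_b, m_tests_b)):
        t = t.set_index("gene") if "gene" in t.columns else t
        tabs.append(pd.DataFrame({"logFC": t["logFC"], "p_adj": _adjusted_p(t, m)}))
    a, b = tabs[0], tabs[1].reindex(tabs[0].index)
    shared = a.index[b["logFC"].notna()]
    a, b = a.loc[shared], b.loc[shared]
    same_sign = np.sign(a["logFC"]) == np.sign(b["logFC"])
    nonzero = (a["logFC"] != 0) & (b["logFC"] != 0)
    big = (a["logFC"].abs() > lfc_min) & (b["logFC"].abs() > lfc_min)
    sig = (a["p_adj"] < p_adj_max) & (b["p_adj"] < p_adj_max)
    selected = same_sign & nonzero & big & sig
    up = sorted(shared[selected & (a["logFC"] > 0)])
    down = sorted(shared[selected & (a["logFC"] < 0)])
    return FESignature(up_genes=up, down_genes=down, lfc_min=lfc_min,
                       p_adj_max=p_adj_max, provenance=provenance)


def overlap_test(set_a, set_b, universe_size: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) for overlap of
    two gene sets over a common universe."""
    sa, sb = set(set_a), set(set_b)
    if len(sa) > universe_size or len(sb) > universe_size:
        raise ValueError("set larger than universe")
    in_both = len(sa & sb)
    only_a = len(sa) - in_both
    only_b = len(sb) - in_both
    neither = universe_size - in_both - only_a - only_b
    if neither < 0:
        raise ValueError("universe smaller than the union of the sets")
    table = np.array([[in_both, only_a], [only_b, neither]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def expression_shift_test(logcpm: np.ndarray, gene_ids: np.ndarray,
                          signature: FESignature | list[str],
                          background: list[str] | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of signature genes' mean log-CPM against
    background genes (all remaining genes by default).

    Returns the rank-sum statistic of the signature group and the p-value
    (exact for small untied samples, normal approximation with tie
    correction otherwise).
    """
    genes = signature.all_genes if isinstance(signature, FESignature) else list(signature)
    if not genes:
        raise ValueError("empty signature")
    gene_ids = np.asarray(gene_ids, dtype=object)
    means = pd.Series(np.asarray(logcpm).mean(axis=1), index=gene_ids)
    in_sig = means.index.isin(set(genes))
    if not in_sig.any():
        raise ValueError("no signature gene present in the expression matrix")
    if background is None:
        bg = means[~in_sig]
    else:
        bg = means[means.index.isin(set(background))]
    res = stats.mannwhitneyu(means[in_sig], bg, alternative="two-sided",
                             method="auto")
    return float(res.statistic), float(res.pvalue)
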