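"""In-memory containers shared by every analysis module.

Three matrix-like types carry the data through the pipeline: gene-by-sample
integer counts (:class:`CountMatrix`), SNP-by-sample allele dosages
(:class:`GenotypeMatrix`) and the per-sample phenotype/covariate table
(:class:`PhenotypeTable`).  All three validate their invariants on
construction so downstream code can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS = ("F", "M")
LOCATION_LEVELS = ("ascending", "transverse", "descending")
SMOKING_LEVELS = ("never", "former", "current")

#: phenotype columns that must be non-negative when present
_NONNEG_COLS = ("age", "bmi", "alcohol_g_day", "met_h_w")


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(arr) != len(set(arr)):
        seen: set = set()
        dup = next(x for x in arr if x in seen or seen.add(x))
        raise ValueError(f"duplicate {what}: {dup!r}")
    return arr


@dataclass
class CountMatrix:
    """Genes x samples matrix of raw sequencing read counts.

    Parameters
    ----------
    gene_ids : sequence of str
        Stable gene identifiers, unique.
    sample_ids : sequence of str
        Sample identifiers, unique.
    counts : (n_genes, n_samples) array of non-negative integers
    gene_lengths_bp : optional (n_genes,) array of int
        Needed only for the minimum-length gene filter.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray
    gene_lengths_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene id")
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                bad = np.argwhere((counts != np.round(counts)) | ~np.isfinite(counts))[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        neg = np.argwhere(counts < 0)
        if neg.size:
            g, s = neg[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        self.counts = counts
        if self.gene_lengths_bp is not None:
            lengths = np.asarray(self.gene_lengths_bp, dtype=np.int64)
            if lengths.shape != (len(self.gene_ids),):
                raise ValueError("gene_lengths_bp length does not match gene_ids")
            self.gene_lengths_bp = lengths

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums of the raw counts."""
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix restricted to a boolean mask or index array over genes."""
        lengths = None if self.gene_lengths_bp is None else self.gene_lengths_bp[keep]
        return CountMatrix(self.gene_ids[keep], self.sample_ids,
                           self.counts[keep], lengths)

    def subset_samples(self, keep: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.gene_ids, self.sample_ids[keep],
                           self.counts[:, keep], self.gene_lengths_bp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GenotypeMatrix:
    """SNPs x samples alt-allele dosage matrix with allele metadata.

    Dosages live in [0, 2] (expected alt-allele count); hard genotype calls
    are the integers 0/1/2.  Positions are 1-based as in VCF.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosages: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _check_unique(self.snp_ids, "SNP id")
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if np.any(self.pos <= 0):
            raise ValueError("positions must be strictly positive (1-based)")
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        dos = np.asarray(self.dosages, dtype=float)
        if dos.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape does not match snp_ids x sample_ids")
        if np.any(~np.isfinite(dos)) or np.any(dos < 0) or np.any(dos > 2):
            raise ValueError("dosages must be finite and within [0, 2]")
        self.dosages = dos

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, derived from mean dosage."""
        af = self.dosages.mean(axis=1) / 2.0
        return np.minimum(af, 1.0 - af)

    def index_of(self, rsid: str) -> int:
        idx = np.flatnonzero(self.snp_ids == rsid)
        if idx.size == 0:
            raise KeyError(f"SNP {rsid!r} not present")
        return int(idx[0])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.snp_ids[keep], self.chrom[keep], self.pos[keep],
                              self.ref_allele[keep], self.alt_allele[keep],
                              self.dosages[keep], self.sample_ids)


class PhenotypeTable:
    """Per-sample phenotype/covariate table.

    Wraps a DataFrame indexed by sample id.  Recognised columns: ``sex``
    (F/M), ``age`` (years), ``location`` (colon segment), ``batch``, ``bmi``,
    ``smoking`` (never/former/current), ``alcohol_g_day``, ``met_h_w``
    (physical activity in MET-hours/week), binary medication flags prefixed
    ``ATC:`` (WHO drug codes), binary disease flags prefixed ``ICD10:`` and
    numeric genetic principal components prefixed ``PC``.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        for col, levels in (("sex", SEX_LEVELS), ("location", LOCATION_LEVELS),
                            ("smoking", SMOKING_LEVELS)):
            if col in df.columns:
                bad = set(df[col].dropna()) - set(levels)
                if bad:
                    raise ValueError(f"invalid {col} level(s): {sorted(bad)}")
        for col in _NONNEG_COLS:
            if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
                raise ValueError(f"negative values in {col!r}")
        self.data = df

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    @property
    def medication_flags(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("ATC:")]

    @property
    def disease_flags(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("ICD10:")]

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c.startswith("PC") and c[2:].isdigit()]

    def __len__(self) -> int:
        return len(self.data)

    def aligned_to(self, sample_ids: Iterable[str]) -> "PhenotypeTable":
        """Inner-join alignment to a sample ordering; every id must exist."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        return PhenotypeTable(self.data.loc[ids])


@dataclass
class FESignature:
    """Field-effect gene signature: genes up- or down-regulated in healthy
    tissue adjacent to tumor relative to tissue from healthy individuals."""

    up_genes: list[str]
    down_genes: list[str]
    lfc_min: float = 1.0
    p_adj_max: float = 0.01
    method: str = "bonferroni"
    provenance: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {sorted(overlap)[:5]}")

    @property
    def all_genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)


@dataclass
class DatasetBundle:
    """One cohort's worth of aligned inputs for a pipeline run."""

    label: str
    counts: CountMatrix
    pheno: PhenotypeTable
    geno: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        self.pheno = self.pheno.aligned_to(self.counts.sample_ids)
        if self.geno is not None and list(self.geno.sample_ids) != list(self.counts.sample_ids):
            raise ValueError("genotype sample ordering does not match counts")
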