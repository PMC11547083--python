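"""Readers and writers for the external file formats.

Counts come as TSV (gene id column + one column per sample) or MatrixMarket
triplets with row/column name side files; genotypes as VCF (GT and/or DS
FORMAT fields, parsed with cyvcf2) or a plain SNP-by-sample TSV; gene sets
as GMT; GWAS instrument weights and phenotypes as TSV.  All TSV output is
tab-separated UTF-8 with a ``# femr schema v1`` comment header; ``#``-prefixed
lines are ignored on read.  Readers canonicalise row order (sort by id) so
the in-memory objects are independent of file row order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import CountMatrix, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# femr schema v1"

#: strand-ambiguous allele pairs (indistinguishable from their complement)
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def is_ambiguous_pair(a1: str, a2: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved."""
    return {str(a1).upper(), str(a2).upper()} in _AMBIGUOUS_PAIRS


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# counts

def read_counts(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    """Read a gene-by-sample count matrix.

    ``path`` may be a TSV (first column = gene id) or a MatrixMarket ``.mtx``
    file; in the latter case ``<stem>.genes.txt`` and ``<stem>.samples.txt``
    must sit alongside it, one name per line.  ``lengths_path`` optionally
    supplies a two-column TSV (gene_id, length_bp).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + ".samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = _read_tsv(path, index_col=0)
        df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene id: {df.index[df.index.duplicated()][0]!r}")
    df = df.sort_index()
    lengths = None
    if lengths_path is not None:
        ldf = _read_tsv(lengths_path, index_col=0)
        ldf.index = ldf.index.astype(str)
        lengths = ldf.iloc[:, 0].reindex(df.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"gene {missing!r} missing from lengths file")
        lengths = lengths.to_numpy(dtype=np.int64)
    return CountMatrix(df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object),
                       df.to_numpy(), lengths)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV, or as MTX + name files when path ends ``.mtx``."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts), field="integer")
        stem = str(path)[: -len(".mtx")]
        Path(stem + ".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(stem + ".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        with open(path, "w") as fh:
            fh.write(SCHEMA_HEADER + "\n")
            cm.to_frame().rename_axis("gene_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a SNP-by-sample dosage matrix from VCF or TSV.

    VCF records use the DS FORMAT field when present, otherwise the alt-allele
    count from GT.  Missing genotypes are imputed to the per-SNP mean dosage
    (the number of imputed cells is logged).  Multiallelic records are
    rejected; split them first (e.g. ``bcftools norm -m-``).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; "
                "split multiallelic sites before loading (bcftools norm -m-)"
            )
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            dos = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3=missing
            dos[dos == 3] = np.nan
        miss = ~np.isfinite(dos)
        if miss.any():
            if miss.all():
                raise ValueError(f"all genotypes missing at {var.ID or var.POS}")
            dos[miss] = dos[~miss].mean()
            n_imputed += int(miss.sum())
        if np.any(dos < 0) or np.any(dos > 2):
            raise ValueError(f"dosage outside [0, 2] at {var.ID or var.POS}")
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    if n_imputed:
        logger.info("imputed %d missing genotype cells to per-SNP mean", n_imputed)
    order = np.argsort(np.asarray(ids, dtype=object))
    return GenotypeMatrix(np.asarray(ids, dtype=object)[order],
                          np.asarray(chroms, dtype=object)[order],
                          np.asarray(poss, dtype=np.int64)[order],
                          np.asarray(refs, dtype=object)[order],
                          np.asarray(alts, dtype=object)[order],
                          np.vstack(rows)[order], samples)


_GENO_TSV_COLS = ["rsid", "chrom", "pos", "ref", "alt"]


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = _read_tsv(path, dtype={"chrom": str})
    for col in _GENO_TSV_COLS:
        if col not in df.columns:
            raise ValueError(f"genotype TSV missing mandatory column {col!r}")
    sample_cols = [c for c in df.columns if c not in _GENO_TSV_COLS]
    df = df.sort_values("rsid")
    dos = df[sample_cols].to_numpy(dtype=float)
    miss = ~np.isfinite(dos)
    if miss.any():
        means = np.nanmean(dos, axis=1, keepdims=True)
        dos = np.where(miss, means, dos)
        logger.info("imputed %d missing genotype cells to per-SNP mean", miss.sum())
    return GenotypeMatrix(df["rsid"].to_numpy(dtype=object),
                          df["chrom"].to_numpy(dtype=object),
                          df["pos"].to_numpy(dtype=np.int64),
                          df["ref"].to_numpy(dtype=object),
                          df["alt"].to_numpy(dtype=object),
                          dos,
                          np.asarray(sample_cols, dtype=object))


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write genotypes as TSV, or as a minimal sites-only text VCF with GT
    calls (dosages are rounded to hard calls in VCF mode)."""
    path = Path(path)
    if format == "tsv":
        meta = pd.DataFrame({"rsid": gm.snp_ids, "chrom": gm.chrom, "pos": gm.pos,
                             "ref": gm.ref_allele, "alt": gm.alt_allele})
        df = pd.concat([meta, pd.DataFrame(gm.dosages, columns=gm.sample_ids)],
                       axis=1)
        with open(path, "w") as fh:
            fh.write(SCHEMA_HEADER + "\n")
            df.to_csv(fh, sep="\t", index=False)
    elif format == "vcf":
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in dict.fromkeys(gm.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(gm.sample_ids) + "\n")
            order = np.lexsort((gm.pos, gm.chrom.astype(str)))
            for i in order:
                calls = "\t".join(gt_map[int(round(d))] for d in gm.dosages[i])
                fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.snp_ids[i]}\t"
                         f"{gm.ref_allele[i]}\t{gm.alt_allele[i]}\t.\t.\t.\tGT\t{calls}\n")
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype TSV missing mandatory column 'sample_id'")
    return PhenotypeTable(df.set_index("sample_id").sort_index())


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        pheno.data.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name, description, then tab-separated members."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        name, members = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "femr") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# GWAS instrument weights

def read_gwas_weights(path: str | Path):
    """Read a GWAS summary-weight table (rsid, effect_allele, other_allele,
    beta per SD).  Strand-ambiguous SNPs (A/T, C/G) are flagged, not dropped;
    the score builder decides their fate.

    The weights file is expected to contain independent, genome-wide
    significant SNPs (LD-pruned in the discovery GWAS); this is an input
    contract, not re-checked here.
    """
    from .instruments import InstrumentWeights

    df = _read_tsv(path, dtype=str)
    for col in ("rsid", "effect_allele", "other_allele", "beta"):
        if col not in df.columns:
            raise ValueError(f"weights TSV missing mandatory column {col!r}")
    if df["rsid"].duplicated().any():
        raise ValueError(f"duplicate rsid {df['rsid'][df['rsid'].duplicated()].iloc[0]!r}")
    df = df.sort_values("rsid")
    return InstrumentWeights(
        rsid=df["rsid"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].str.upper().to_numpy(dtype=object),
        other_allele=df["other_allele"].str.upper().to_numpy(dtype=object),
        beta=df["beta"].to_numpy(dtype=float),
        ambiguous=np.array([is_ambiguous_pair(a, b) for a, b in
                            zip(df["effect_allele"], df["other_allele"])]),
        source=str(path),
    )


# ---------------------------------------------------------------------------
# result tables

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named DataFrame as ``<name>.tsv`` with the schema header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write(SCHEMA_HEADER + "\n")
            df.to_csv(fh, sep="\t", index=False)
        written.append(p)
    return written
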