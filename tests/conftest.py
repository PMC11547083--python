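import numpy as np
import pandas as pd
import pytest

from femr import (CountMatrix, DatasetBundle, FESignature, GenotypeMatrix,
                  PhenotypeTable, SimulationTruth, simulate_cohort)


def make_counts(counts, gene_ids=None, sample_ids=None, lengths=None):
    counts = np.asarray(counts)
    g, s = counts.shape
    return CountMatrix(
        gene_ids=np.array(gene_ids or [f"G{i}" for i in range(g)], dtype=object),
        sample_ids=np.array(sample_ids or [f"S{j}" for j in range(s)], dtype=object),
        counts=counts,
        gene_lengths_bp=None if lengths is None else np.asarray(lengths),
    )


def make_genotypes(dosages, mafs_irrelevant=None, sample_ids=None, **kw):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    return GenotypeMatrix(
        snp_ids=kw.get("snp_ids", np.array([f"rs{i}" for i in range(m)], dtype=object)),
        chrom=kw.get("chrom", np.array(["1"] * m, dtype=object)),
        pos=kw.get("pos", np.arange(1, m + 1) * 1000),
        ref_allele=kw.get("ref", np.array(["A"] * m, dtype=object)),
        alt_allele=kw.get("alt", np.array(["G"] * m, dtype=object)),
        dosages=dosages,
        sample_ids=np.array(sample_ids or [f"S{j}" for j in range(n)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort with a causal signal, reused read-only."""
    truth = SimulationTruth(seed=11, n_samples=200, n_genes=400, n_fe_genes=60,
                            exposure_type="continuous", exposure_name="bmi",
                            causal_effect_delta=-0.5)
    counts, pheno, geno, truth = simulate_cohort(truth)
    return counts, pheno, geno, truth


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    counts, pheno, geno, truth = small_cohort
    bundle = DatasetBundle("sim", counts, pheno, geno)
    sig = FESignature(up_genes=truth.fe_gene_ids, down_genes=[])
    return bundle, sig, truth
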