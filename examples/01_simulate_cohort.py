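"""Simulate a colon-mucosa expression cohort with known causal structure.

Builds a cohort of 400 donors and 2,000 genes: negative-binomial bulk
counts, a 211-gene field-effect (FE) signature, sex/age/location/batch
covariates, a metformin-like medication flag, a cis-eQTL for a drug-target
gene and 20 score SNPs for a polygenic instrument.
"""

from femr import SimulationTruth, simulate_cohort

truth = SimulationTruth(seed=1, causal_effect_delta=-0.3, exposure_type="binary")
counts, pheno, geno, truth = simulate_cohort(truth)

print(f"genes x samples: {counts.n_genes} x {counts.n_samples}")
print(f"library sizes: {counts.library_sizes.min()} .. {counts.library_sizes.max()}")
print(f"medication takers: {int(pheno.data[truth.exposure_name].sum())} "
      f"of {len(pheno)} (flag {truth.exposure_name})")
print(f"FE signature size: {len(truth.fe_gene_ids)} genes")
print(f"drug-target gene {truth.target_gene} with causal cis-SNP {truth.eqtl_snp}")
print(f"SNPs simulated: {geno.n_snps} (MAF {geno.maf.min():.2f}..{geno.maf.max():.2f})")
# The truth object records every generative parameter, so downstream
# analyses can be scored against the known effect sizes.
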