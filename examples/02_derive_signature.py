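"""Derive a field-effect signature from two differential-expression tables.

A gene enters the signature only if both studies agree: same logFC
direction, |logFC| strictly above 1 and Bonferroni-adjusted p below 0.01.
Here the two tables are a labelled toy fixture whose expected outcome is
known gene by gene.
"""

from femr import derive_signature, make_toy_signature_tables

table_a, table_b, labels = make_toy_signature_tables(seed=0)
sig = derive_signature(table_a, table_b)

print(f"input genes: {len(table_a)} (study A) / {len(table_b)} (study B)")
print(f"up-regulated signature: {sig.up_genes}")
print(f"down-regulated signature: {sig.down_genes}")
print("filter outcomes by reason:")
print(labels["status"].value_counts().to_string())
# Only the up-regulated list feeds enrichment analysis downstream; the
# boundary genes (logFC exactly 1.0, adjusted p exactly 0.01) are excluded
# because both thresholds are strict.
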