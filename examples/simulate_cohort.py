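"""Generate a toy sperm cohort and look at its basic statistics.

Builds a 20-gene toy genome, simulates deep duplex coverage for 20 donors
aged 24-75 and draws mutations under the default neutral model
(1.67 SNVs/year/haploid genome, 6x C>T at fully methylated CpGs).
"""

import germselect as gs

ref, meta, coverage, variants, cfg = gs.simulate_toy_cohort(
    seed=1, n_genes=20, exons_per_gene=3, exon_len=150,
    n_donors=20, mean_dx=10_000.0,
)
annotated = gs.annotate_variants(variants, ref)

print(f"genome: {ref.length:,} bp, {len(ref.genes)} genes, "
      f"{len(ref.cpg_positions):,} CpG sites")
print(f"cohort: {len(meta)} samples, mean duplex depth "
      f"{coverage.mean_depth():,.0f} dx")
print(f"variants called: {len(variants):,} "
      f"({(variants['vartype'] == 'snv').sum()} SNVs)")
print(f"single-molecule variants: {gs.singleton_fraction(variants):.1f}%")
print("\ncalls by consequence:")
print(annotated["impact_class"].value_counts().to_string())

# The singleton percentage sits near 100 because each mutant cell is a
# distinct spermatogonial lineage: bulk sperm is extremely polyclonal.
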