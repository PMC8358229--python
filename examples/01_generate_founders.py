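"""Generate a synthetic founder-haplotype panel and recombination map.

The panel emulates a set of 100 sequenced inbred D. simulans lines on one
chromosome arm: a power-law site-frequency spectrum and block-mosaic linkage
disequilibrium.  Both objects round-trip through tab-separated files.
"""

from secoer import generate_panel, generate_recmap
from secoer.founders import write_haplotype_table, write_recmap

panel = generate_panel(n_hap=100, n_snps=5000, chrom_length=23_500_000, seed=1)
recmap = generate_recmap(panel.chrom_length, n_windows=100,
                         total_map_length=0.5, seed=2)

f = panel.frequencies()
print(f"panel: {panel.n_hap} haplotypes x {panel.n_snps} SNPs on "
      f"{panel.chrom} ({panel.chrom_length/1e6:.1f} Mb)")
print(f"mean derived-allele frequency: {f.mean():.3f} "
      "(low: most variants are rare, as in a natural population)")
print(f"singletons (carried by one line): {(panel.alleles.sum(0) == 1).mean():.1%}")
print(f"map length: {recmap.total_map_length:.3f} Morgans "
      f"(~{100*recmap.total_map_length/(panel.chrom_length/1e6):.1f} cM/Mb)")

write_haplotype_table(panel, "founders.tsv")
write_recmap(recmap, "recmap.tsv")
print("wrote founders.tsv and recmap.tsv")
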