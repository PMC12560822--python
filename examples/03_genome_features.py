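"""Genome-feature arithmetic on the shipped assembly-statistics table.

Computes per-genome gene density, group range summaries in Mb, and a
shared-PSG overlap percentage from synthetic per-lineage gene-ID lists.
"""

import pathlib

import rifconv as rc

here = pathlib.Path(__file__).parent
table = rc.read_genome_table(here / "data" / "genome_features.tsv")

print(f"{'species':<30} {'size (Mb)':>10} {'proteins':>9} {'genes/Mb':>9}")
for _, row in table.iterrows():
    d = rc.gene_density(int(row.protein_count), int(row.genome_size_bp))
    print(f"{row.species:<30} {row.genome_size_bp / 1e6:>10.2f} "
          f"{row.protein_count:>9} {d:>9}")

summary = rc.group_summary(table, "genome_size_bp", as_mb=True)
rif = summary.set_index("group").loc["RIF"]
print(f"\nassembly size: {rif['min']}-{rif['max']} Mb "
      f"(mean {rif['mean']} +/- {rif['sd']} Mb, n={int(rif['n'])})")

# Overlap of positively-selected-gene lists across four lineages (toy IDs
# with the intersection structure of a four-way branch-site analysis).
core = {f"OG{i:04d}" for i in range(36)}
sets = [core | {f"L{j}_{i}" for i in range(n - 36)}
        for j, n in enumerate([662, 260, 526, 674])]
ov = rc.shared_psg_summary(sets, universe_size=3290)
print(f"\nPSGs shared by all {len(sets)} lineages: {ov.n_shared} of "
      f"{ov.universe_size} tested orthologs ({ov.shared_pct}%)")
print("\nGene density is gene models per Mb of assembly (rounded); the "
      "shared-PSG\npercentage is the intersection over the tested "
      "single-copy ortholog universe.")
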