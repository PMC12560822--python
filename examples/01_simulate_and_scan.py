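"""Simulate a small ortholog benchmark and scan it for convergence.

Builds 60 genes of 300 sites on the 9-leaf benchmark tree (three foreground
lineages: one two-taxon clade and two terminal branches), plants 3-site
convergence into the first 3 genes, and runs the full scan: ancestral
reconstruction per gene under JTT with gene-specific frequencies,
convergent-site calling, Poisson test against the analytic expectation,
and BH correction across genes.
"""

import rifconv as rc

config = rc.SimulationConfig(n_genes=60, sites_per_gene=300, seed=11,
                             n_injected_genes=3, sites_per_injected_gene=3)
alignments, manifest, tree = rc.simulate_benchmark(config)
results, summary = rc.scan_genes(alignments, tree)

print(f"scanned {summary['n_genes_scanned']} genes, "
      f"{summary['n_convergent_sites']} convergent sites in "
      f"{summary['n_genes_with_convergent_sites']} genes, "
      f"{summary['n_significant']} genes significant at q < 0.05\n")

print(f"{'gene':<10} {'k':>2} {'lambda':>9} {'p':>10} {'q':>10}  sites")
for r in results[:6]:
    print(f"{r.gene_id:<10} {r.observed:>2} {r.expected:>9.4f} "
          f"{r.p:>10.3g} {r.q:>10.3g}  {r.site_notation}")

planted = {m.gene_id: [] for m in manifest}
for m in manifest:
    planted[m.gene_id].append(m.site)
print("\nplanted convergence:", planted)
print("\nk = observed convergent sites per gene; lambda = expected count "
      "under the JTT+F_gene null;\nsmall q flags genes with more "
      "independent same-residue substitutions than chance allows.")
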