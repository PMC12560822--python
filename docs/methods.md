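# Methods

## The question the scan answers

Phylogenetically distant lineages colonizing the same extreme niche — the
motivating case is melanized rock-inhabiting fungi (RIF) scattered across
Dothideomycetes — sometimes fix the *same* amino-acid replacement
independently. A handful of shared derived residues is, by itself, weak
evidence of adaptation: with thousands of orthologs and millions of sites,
some identical substitutions arise by chance. The scan therefore asks, per
gene, whether the number of sites at which *every* designated foreground
lineage independently reached one common residue exceeds what the neutral
substitution process predicts.

## Null substitution process

Sites evolve independently under a reversible continuous-time Markov chain
on the 20 amino acids with generator

    Q_ab = s_ab * pi_b / c   (a != b),    Q_aa = -sum_{b!=a} Q_ab,

where `s` is the empirical JTT exchangeability matrix (shipped in
`src/rifconv/data/jtt.dat`, PAML lower-triangular layout, the canonical
published values) and `pi` is estimated per gene ("F_gene") as residue
counts over the gene's alignment, missing cells excluded, plus an add-one
pseudocount (default 1.0; with zero pseudocount a residue absent from the
gene would be unreachable under the null and the expected count would be
degenerate). The constant `c = -sum_a pi_a Q_aa` scales branch lengths to
expected substitutions per site. There is no among-site rate variation: the
model is deliberately the plain frequency-adjusted JTT process, and adding
gamma categories is future work, not a default.

Transition probabilities `P(t) = expm(Q t)` are computed through the
symmetric similarity transform `diag(sqrt(pi)) Q diag(1/sqrt(pi))`
(eigendecomposition done once per gene and reused for every branch); the
eigen path is cross-checked in the tests against `scipy.linalg.expm`
(scaling-and-squaring) to 1e-8. Rows are renormalized only to absorb
rounding below 1e-8; a genuinely negative entry (below -1e-12) is an error,
not something to clip silently.

## Ancestral reconstruction

Marginal reconstruction, not joint: each internal node and site gets the
posterior distribution over states given *all* leaf data, via a post-order
pruning pass (partial likelihoods scaled per node against underflow) and a
pre-order pass propagating above-node information. Assigned states are
posterior argmaxes with ties broken toward the lowest index in the fixed
alphabet order `ARNDCQEGHILKMFPSTWYV` (determinism). Gaps and unknowns
('X', ambiguity codes) are missing data: a missing leaf contributes a flat
indicator, a site with every descendant missing is flagged and reconstructs
to the above-node information (the prior `pi` at the root). The test suite
holds the implementation to exact (1e-8) agreement with brute-force joint
enumeration on all fixtures with up to three internal nodes.

## Convergence calling and the Poisson test

Foreground lineages are branches: terminal branches or the branch above a
designated clade's MRCA. Nested designations are rejected — convergence
requires independent lineages. For each foreground branch `(u -> c)` and
site, a substitution is called when the assigned state at `u` and the child
state (observed residue for leaves, assigned state for internal nodes)
both exist and differ. A site is a *convergent site* (default
`all_foreground` mode) when every foreground branch carries a call to one
common derived residue **and** every extant foreground leaf shows that
residue (a gap fails the identity requirement — identity is a statement
about extant sequences). Sites are classified `parallel` (all ancestral
residues equal), `convergent` (all distinct) or `mixed`; all classes count.
A `pairwise` mode applies the same rules per branch pair and counts a site
once; it exists because multi-target designs are often summarized per pair.

The per-gene expected count under the null is

    lambda_g = sum_sites sum_a prod_{b in F} m_b(a|s),
    m_b(a|s) = sum_{x != a} post_u(x|s) P_xa(t_b),

i.e. the probability that every foreground branch independently substitutes
*to* residue `a`, using the marginal posterior at each branch's parent
(posteriors, not point assignments, keep the expectation on the same
reconstruction as the observed calls; sites with a missing foreground
parent contribute zero). Observed counts use point assignments; the
expectation therefore slightly overstates what the discrete caller can see
(it does not condition on the foreground leaves retaining the residue below
an internal foreground branch), which makes the test mildly conservative —
acceptable for a screen whose failure mode of interest is false positives.
A Monte-Carlo oracle in the tests confirms the analytic per-site rate to
within binomial error.

Observed `k_g` is tested by Poisson exceedance `p = Pr(X >= k_g)` with
`X ~ Poisson(lambda_g)` (`p = 1` when `k_g = 0`; `lambda_g = 0` with
`k_g > 0` yields `p = 0` plus a degenerate-null warning), and
Benjamini-Hochberg correction runs over all scanned genes — genes with no
candidate sites enter the family at `p = 1`. The default significance bound
is q < 0.05. Run summaries report both the per-site and per-branch-event
tallies, since published counts do not always state which is meant.

## Synthetic benchmark generator

The generator stands in for genome-scale single-copy ortholog data. Default
study conditions: 200 genes x 300 sites on a fixed 9-leaf rooted tree
(two ingroup clades plus a two-leaf outgroup; branch lengths 0.05-0.3
substitutions/site, chosen so reconstruction posteriors stay concentrated)
with three foreground lineages — one two-leaf clade MRCA branch and two
terminal branches — mirroring a multi-lineage convergence design. Per-gene
frequencies are drawn from a Dirichlet centered on the JTT frequencies
(concentration 50 x 20 x pi_JTT), emulating gene-to-gene compositional
variation; `uniform` and `fixed` sources are available. Root states are
drawn from `pi` (stationarity), branch states from `P(t)` rows; the full
node-level history is retained so truth-aware tests can audit every call.

Positives are constructed by direct editing of leaves plus truth, not by
biasing rates: at an injection site, every foreground clade's leaves (and
the clade node's true state) are set to one derived residue differing from
the true state at every foreground parent. Two placement rules make the
positives resemble reported adaptive convergence rather than noise:
injection sites are drawn from columns whose non-foreground leaves share a
single residue (constrained positions), and the default "random" derived
policy additionally excludes residues already observed in the column (a
novel residue). Without these rules a planted event frequently lands on a
fast-evolving column where the derived residue coincides with background
variation, and the reconstruction — correctly — refuses to see three
independent origins; such sites are not what the procedure targets.
Injection never touches non-foreground leaves or other sites (asserted
byte-for-byte in the tests).

What the generator does *not* emulate: indels and alignment error, among-
site and among-branch rate variation, selection on the background, model
misspecification (data are generated under the same family the scan
assumes). Passing recovery tests therefore demonstrates correctness and
calibration of the machinery, not robustness of the method on real
proteomes.

## Genome-feature arithmetic

Small, exactly-reproducible summaries of an assembly-statistics table:
gene density `round(protein_count / (genome_size_bp / 1e6))` (half-up, to
integer genes/Mb); per-group mean ± sample SD (n-1) and min/max, with Mb
means rounded to 2 decimals and Mb ranges *truncated* to 1 decimal
(29,490,499 bp prints as 29.4 Mb, the convention of the tables this
mirrors); shared-PSG percentage `100 * |intersection| / universe`, rounded
to 2 decimals, over per-lineage positively-selected-gene ID lists with the
tested single-copy-ortholog count as universe; and a Wilcoxon rank-sum
comparison (exact enumeration when both n <= 10 and tie-free, else normal
approximation with continuity and tie correction; the method used is
recorded in the result). Phylogenetically corrected regressions are out of
scope — only the plain printed arithmetic is reproduced.

## Numerical and design notes

- Alignment columns are 1-based in every report; internal storage is
  0-based integer codes in the fixed alphabet order above.
- Node ids are deterministic post-order indices of the input newick, so
  ids 0..n-1 are themselves a traversal order and the root is always last.
- A trifurcating root is rejected as unrooted rather than silently resolved.
- Per-gene work is O(nodes x sites x 400) with one 20x20 eigendecomposition;
  the default 200-gene benchmark simulates and scans in a few seconds on
  one core, which is why the calibration and recovery experiments run at
  full size (200 genes x 300 sites) in the test suite.
- The "3 Monte-Carlo SE" band in the null-calibration check uses
  sqrt(mean(lambda)/n_genes), the Poisson sampling variance of the mean
  per-gene count.
- Reproducibility: every stochastic entry point takes an explicit seed or
  `numpy.random.Generator`; identical configurations produce byte-identical
  benchmark directories (hashed in the tests).

## Known limitations

- Marginal ASR contaminates ancestral posteriors with foreground data;
  when foreground leaves are a large fraction of the taxa, parents of
  foreground branches can be pulled toward the derived residue, hiding
  genuine events (lower sensitivity, not inflated significance).
- `lambda_g` conditions on the reconstruction of the observed data, as is
  conventional; it is not an unconditional process expectation.
- No rate heterogeneity, no codon-level information, no indel model.
- The Poisson test treats sites as independent given the gene, which
  ignores within-gene rate correlation; BH across genes controls FDR only
  under the usual positive-dependence caveats.
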