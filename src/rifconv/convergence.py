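"""Convergent-substitution scan with a Poisson test against the JTT+F_gene null.

For designated foreground branches the scan (i) enumerates inferred
amino-acid substitutions from the marginal ancestral reconstruction,
(ii) calls sites where every foreground lineage independently reaches the
same derived residue (pooling "parallel" — same ancestral residue — and
"convergent" — different ancestral residues), (iii) computes the expected
number of such sites per gene under the substitution model, and (iv) tests
the observed count by Poisson exceedance, adjusting across genes by
Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .asr import AncestralReconstruction, reconstruct
from .io import AMINO_ACIDS, MISSING, Alignment, Phylogeny, RifconvError
from .model import SubstitutionModel, build_model, estimate_f_gene

logger = logging.getLogger("rifconv")

MODES = ("all_foreground", "pairwise")


@dataclass
class SubstitutionCall:
    """One inferred substitution on a foreground branch at one site."""

    gene_id: str
    site: int            # 1-based alignment column
    branch: int          # child-node id of the branch
    parent_state: int
    child_state: int
    parent_posterior: float
    child_posterior: float  # 1.0 when the branch is terminal

    @property
    def notation(self) -> str:
        return (f"{AMINO_ACIDS[self.parent_state]}{self.site}"
                f"{AMINO_ACIDS[self.child_state]}")


@dataclass
class ConvergentSite:
    """A site where foreground lineages share an independently derived residue."""

    gene_id: str
    site: int            # 1-based
    derived_state: int
    ancestral_states: dict[int, int]  # branch id -> parent state
    n_branches_substituting: int

    @property
    def classification(self) -> str:
        anc = list(self.ancestral_states.values())
        if len(set(anc)) == 1:
            return "parallel"
        if len(set(anc)) == len(anc):
            return "convergent"
        return "mixed"

    @property
    def notation(self) -> str:
        """Table-style tokens, one per distinct ancestral residue: 'A162S,E162S'."""
        der = AMINO_ACIDS[self.derived_state]
        seen = sorted(set(self.ancestral_states.values()))
        return ",".join(f"{AMINO_ACIDS[a]}{self.site}{der}" for a in seen)


@dataclass
class ConvergenceResult:
    gene_id: str
    observed: int
    expected: float
    p: float
    q: float | None
    sites: list[ConvergentSite] = field(default_factory=list)
    mode: str = "all_foreground"

    @property
    def site_notation(self) -> str:
        return ";".join(s.notation for s in self.sites)


# ---------------------------------------------------------------------------
# Enumeration and site calling
# ---------------------------------------------------------------------------

def _branch_states(rec: AncestralReconstruction, aln: Alignment,
                   tree: Phylogeny, branch: int):
    """(child_states, child_posteriors, child_missing) along one branch."""
    if tree.is_leaf(branch):
        codes = aln.row(tree.labels[branch])
        post = np.ones(aln.length)
        miss = codes == MISSING
        return codes, post, miss
    states = rec.states[branch]
    post = rec.posteriors[branch, np.arange(aln.length), states]
    return states, post, rec.missing[branch]


def enumerate_substitutions(rec: AncestralReconstruction, aln: Alignment,
                            tree: Phylogeny,
                            min_posterior: float = 0.0) -> list[SubstitutionCall]:
    """All inferred substitutions on the foreground branches.

    A call compares the assigned state at a branch's parent node with the
    child state (the observed leaf residue for terminal branches, else the
    assigned state at the child node); missing data on either end yields no
    call.  ``min_posterior`` optionally drops calls whose parent or child
    posterior falls below the threshold (default 0: report, don't filter).
    """
    if not tree.foreground:
        raise RifconvError("no foreground branches resolved on the tree")
    calls: list[SubstitutionCall] = []
    n_sites = aln.length
    idx = np.arange(n_sites)
    for b in sorted(tree.foreground):
        u = int(tree.parent[b])
        child_states, child_post, child_miss = _branch_states(rec, aln, tree, b)
        parent_states = rec.states[u]
        parent_post = rec.posteriors[u, idx, parent_states]
        parent_miss = rec.missing[u]
        differs = (
            (child_states != parent_states) & ~child_miss & ~parent_miss
            & (parent_post >= min_posterior) & (child_post >= min_posterior)
        )
        for s in np.where(differs)[0]:
            calls.append(SubstitutionCall(
                gene_id=aln.gene_id, site=int(s) + 1, branch=b,
                parent_state=int(parent_states[s]),
                child_state=int(child_states[s]),
                parent_posterior=float(parent_post[s]),
                child_posterior=float(child_post[s]),
            ))
    return calls


def _foreground_leaf_rows(aln: Alignment, tree: Phylogeny,
                          branches) -> dict[int, np.ndarray]:
    rows = {}
    for b in branches:
        leaf_codes = [aln.row(tree.labels[leaf])
                      for leaf in tree.subtree_leaves(b)]
        rows[b] = np.vstack(leaf_codes)
    return rows


def call_convergent_sites(calls: list[SubstitutionCall],
                          rec: AncestralReconstruction, aln: Alignment,
                          tree: Phylogeny,
                          mode: str = "all_foreground") -> list[ConvergentSite]:
    """Sites where foreground lineages carry the same derived residue.

    ``all_foreground`` (default): every foreground branch must show a
    substitution to one common residue, and every extant foreground leaf
    must carry that residue at the site (a gap fails the identity check).
    ``pairwise``: the same rules restricted to each branch pair; a site
    qualifies if any pair does, and is counted once per gene.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    fg = sorted(tree.foreground)
    if len(fg) < 2:
        raise RifconvError("convergence needs at least 2 foreground branches")
    by_site: dict[int, dict[int, SubstitutionCall]] = {}
    for c in calls:
        by_site.setdefault(c.site, {})[c.branch] = c
    leaf_rows = _foreground_leaf_rows(aln, tree, fg)
    out: list[ConvergentSite] = []
    for site in sorted(by_site):
        branch_calls = by_site[site]
        s0 = site - 1
        if mode == "all_foreground":
            if set(branch_calls) != set(fg):
                continue
            derived = {c.child_state for c in branch_calls.values()}
            if len(derived) != 1:
                continue
            d = derived.pop()
            if not all((leaf_rows[b][:, s0] == d).all() for b in fg):
                continue
            out.append(ConvergentSite(
                gene_id=aln.gene_id, site=site, derived_state=d,
                ancestral_states={b: branch_calls[b].parent_state for b in fg},
                n_branches_substituting=len(fg),
            ))
        else:
            participants: set[int] = set()
            derived_state = None
            for b1, b2 in itertools.combinations(fg, 2):
                if b1 not in branch_calls or b2 not in branch_calls:
                    continue
                d1 = branch_calls[b1].child_state
                if d1 != branch_calls[b2].child_state:
                    continue
                if not ((leaf_rows[b1][:, s0] == d1).all()
                        and (leaf_rows[b2][:, s0] == d1).all()):
                    continue
                participants.update((b1, b2))
                derived_state = d1
            if participants:
                out.append(ConvergentSite(
                    gene_id=aln.gene_id, site=site, derived_state=derived_state,
                    ancestral_states={
                        b: branch_calls[b].parent_state
                        for b in sorted(participants)
                    },
                    n_branches_substituting=len(participants),
                ))
    return out


# ---------------------------------------------------------------------------
# Null expectation and tests
# ---------------------------------------------------------------------------

def expected_convergent_count(rec: AncestralReconstruction, aln: Alignment,
                              tree: Phylogeny, model: SubstitutionModel,
                              mode: str = "all_foreground") -> float:
    """Expected number of convergent sites per gene under the null model.

    For foreground branch ``b = (u -> c)`` of length ``t_b`` the probability
    of substituting *to* residue ``a`` at site ``s`` is
    ``m_b(a|s) = sum_{x != a} post_u(x|s) P_xa(t_b)``, using the marginal
    posterior at the parent node.  The per-site convergence probability is
    ``sum_a prod_b m_b(a|s)`` over all foreground branches (or summed over
    branch pairs in pairwise mode); sites where any foreground parent is
    missing contribute 0.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    fg = sorted(tree.foreground)
    if len(fg) < 2:
        raise RifconvError("convergence needs at least 2 foreground branches")
    n_sites = aln.length
    M = {}
    any_parent_missing = np.zeros(n_sites, dtype=bool)
    for b in fg:
        u = int(tree.parent[b])
        P = model.transition_matrix(tree.branch_lengths[b])
        post_u = rec.posteriors[u]                       # (S, 20)
        m = post_u @ P - post_u * np.diag(P)[None, :]    # exclude x == a
        M[b] = np.clip(m, 0.0, None)
        any_parent_missing |= rec.missing[u]
    if mode == "all_foreground":
        prod = np.ones((n_sites, 20))
        for b in fg:
            prod *= M[b]
        per_site = prod.sum(axis=1)
    else:
        per_site = np.zeros(n_sites)
        for b1, b2 in itertools.combinations(fg, 2):
            per_site += (M[b1] * M[b2]).sum(axis=1)
    per_site[any_parent_missing] = 0.0
    return float(per_site.sum())


def poisson_test(k: int, lam: float) -> float:
    """Poisson exceedance probability ``P(X >= k)`` for ``X ~ Poisson(lam)``."""
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be nonnegative")
    if k == 0:
        return 1.0
    if lam == 0.0:
        warnings.warn(
            "degenerate null: lambda = 0 with observed k > 0; p set to 0",
            RuntimeWarning, stacklevel=2,
        )
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# Whole-collection scan
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    mode: str = "all_foreground"
    pseudocount: float = 1.0
    q_threshold: float = 0.05
    min_posterior: float = 0.0


def scan_gene(aln: Alignment, tree: Phylogeny,
              config: ScanConfig = ScanConfig()) -> ConvergenceResult:
    """Run the full per-gene pipeline (model fit, ASR, calls, Poisson p)."""
    pi = estimate_f_gene(aln, pseudocount=config.pseudocount)
    model = build_model(pi)
    rec = reconstruct(aln, tree, model)
    calls = enumerate_substitutions(rec, aln, tree,
                                    min_posterior=config.min_posterior)
    sites = call_convergent_sites(calls, rec, aln, tree, mode=config.mode)
    lam = expected_convergent_count(rec, aln, tree, model, mode=config.mode)
    p = poisson_test(len(sites), lam)
    return ConvergenceResult(
        gene_id=aln.gene_id, observed=len(sites), expected=lam, p=p, q=None,
        sites=sites, mode=config.mode,
    )


def scan_genes(alignments, tree: Phylogeny,
               config: ScanConfig = ScanConfig()):
    """Scan a gene collection and BH-adjust across all scanned genes.

    Genes whose taxa do not cover the tree's leaves are skipped with a
    warning and reported in the run summary.  Returns
    ``(results, summary)``; results are sorted by (q, p, gene_id).
    """
    results: list[ConvergenceResult] = []
    skipped: list[str] = []
    leaf_set = set(tree.leaf_labels)
    for aln in alignments:
        if not leaf_set <= set(aln.taxa):
            missing = sorted(leaf_set - set(aln.taxa))
            logger.warning("skipping %s: missing taxa %s", aln.gene_id,
                           ",".join(missing))
            skipped.append(aln.gene_id)
            continue
        results.append(scan_gene(aln, tree, config))
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.gene_id))
    summary = {
        "n_genes_scanned": len(results),
        "n_genes_skipped": len(skipped),
        "skipped_genes": skipped,
        "mode": config.mode,
        "pseudocount": config.pseudocount,
        "q_threshold": config.q_threshold,
        "n_genes_with_convergent_sites": sum(r.observed > 0 for r in results),
        "n_convergent_sites": sum(r.observed for r in results),
        "n_branch_substitution_events": sum(
            r.observed * len(tree.foreground) if config.mode == "all_foreground"
            else sum(s.n_branches_substituting for s in r.sites)
            for r in results
        ),
        "n_significant": sum(
            r.q is not None and r.q < config.q_threshold for r in results
        ),
    }
    return results, summary


def results_to_frame(results: list[ConvergenceResult]) -> pd.DataFrame:
    """Tabulate scan results (Table-style columns) for TSV export."""
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "k": [r.observed for r in results],
        "lambda": [r.expected for r in results],
        "p": [r.p for r in results],
        "q": [r.q for r in results],
        "mode": [r.mode for r in results],
        "sites": [r.site_notation for r in results],
    })


def write_results_tsv(results: list[ConvergenceResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")
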