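"""Marginal ancestral state reconstruction on a fixed rooted tree.

Two passes over the tree give, for every internal node and alignment site,
the posterior distribution over the 20 amino acids conditional on all leaf
data: a post-order (pruning) pass computes below-node partial likelihoods
with per-node scaling against underflow, and a pre-order pass propagates
the complementary above-node information.  Assigned states are the argmax
of the marginal posterior, with ties broken toward the lowest alphabet
index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, Alignment, Phylogeny, RifconvError
from .model import N_STATES, SubstitutionModel


@dataclass
class PartialLikelihoods:
    """Below-node conditional likelihoods from the pruning pass.

    ``partials[v]`` is an ``(n_sites, 20)`` array proportional to
    P(leaf data below v | state at v); ``log_scale[v]`` holds the per-site
    log of the scaling factors absorbed below and at ``v``.  ``down[v]``
    caches ``partials[v] @ P_v.T`` (the child contribution seen from the
    parent), reused by the pre-order pass.
    """

    partials: np.ndarray    # (n_nodes, n_sites, 20)
    log_scale: np.ndarray   # (n_nodes, n_sites)
    down: np.ndarray        # (n_nodes, n_sites, 20); undefined at root
    trans: dict             # node id -> P(t_node)
    site_log_likelihood: np.ndarray  # (n_sites,)


@dataclass
class AncestralReconstruction:
    """Per-node, per-site marginal posteriors and assigned states."""

    gene_id: str
    posteriors: np.ndarray  # (n_nodes, n_sites, 20)
    states: np.ndarray      # (n_nodes, n_sites) int8; argmax of posterior
    missing: np.ndarray     # (n_nodes, n_sites) bool; all leaves below missing
    site_log_likelihood: np.ndarray


def _leaf_rows(aln: Alignment, tree: Phylogeny) -> dict[int, np.ndarray]:
    rows = {}
    for leaf in tree.leaves:
        label = tree.labels[leaf]
        if label not in aln.taxa:
            raise RifconvError(
                f"{aln.gene_id}: taxon {label!r} in tree but absent from "
                "alignment"
            )
        rows[leaf] = aln.row(label)
    return rows


def conditional_likelihoods(aln: Alignment, tree: Phylogeny,
                            model: SubstitutionModel) -> PartialLikelihoods:
    """Felsenstein pruning with per-node scaling.

    A leaf's partial vector is the indicator of its observed residue, or
    all-ones when missing; an internal node multiplies, over its children
    ``v`` with branch length ``t_v``, the vectors
    ``sum_b P_ab(t_v) L_v(b)``.  Site log-likelihood is
    ``log sum_a pi_a L_root(a)`` plus the absorbed log scalings.
    """
    n_sites = aln.length
    n_nodes = tree.n_nodes
    rows = _leaf_rows(aln, tree)
    trans = {
        v: model.transition_matrix(tree.branch_lengths[v])
        for v in range(n_nodes - 1)
    }
    partials = np.empty((n_nodes, n_sites, N_STATES))
    log_scale = np.zeros((n_nodes, n_sites))
    down = np.empty((n_nodes, n_sites, N_STATES))
    for v in tree.postorder():
        if tree.is_leaf(v):
            L = np.zeros((n_sites, N_STATES))
            codes = rows[v]
            obs = codes != MISSING
            L[np.arange(n_sites)[obs], codes[obs]] = 1.0
            L[~obs] = 1.0
            partials[v] = L
        else:
            L = np.ones((n_sites, N_STATES))
            for c in tree.children[v]:
                L *= down[c]
                log_scale[v] += log_scale[c]
            scale = L.max(axis=1)
            scale[scale == 0.0] = 1.0  # impossible site; keep zeros as-is
            L /= scale[:, None]
            log_scale[v] += np.log(scale)
            partials[v] = L
        if v != tree.root:
            down[v] = partials[v] @ trans[v].T
    root = tree.root
    site_ll = np.log(partials[root] @ model.pi) + log_scale[root]
    return PartialLikelihoods(partials=partials, log_scale=log_scale,
                              down=down, trans=trans,
                              site_log_likelihood=site_ll)


def marginal_posteriors(partials: PartialLikelihoods, aln: Alignment,
                        tree: Phylogeny,
                        model: SubstitutionModel) -> AncestralReconstruction:
    """Pre-order pass combining above- and below-node information.

    The posterior at node ``u`` is proportional to ``above_u(a) * L_u(a)``;
    at the root the above term is the prior ``pi``.  For a child ``c`` of
    ``u``, ``above_c(x) = sum_a [above_u(a) * prod_{siblings s} down_s(a)]
    * P_ax(t_c)``.  Posteriors are normalized per site, so scaling factors
    cancel.
    """
    n_sites = aln.length
    n_nodes = tree.n_nodes
    above = np.empty((n_nodes, n_sites, N_STATES))
    above[tree.root] = model.pi[None, :]
    for u in tree.preorder():
        if tree.is_leaf(u):
            continue
        kids = tree.children[u]
        for c in kids:
            sib = above[u].copy()
            for s in kids:
                if s != c:
                    sib *= partials.down[s]
            ac = sib @ partials.trans[c]
            norm = ac.sum(axis=1)
            norm[norm == 0.0] = 1.0
            above[c] = ac / norm[:, None]
    post = above * partials.partials
    norm = post.sum(axis=2)
    norm[norm == 0.0] = 1.0
    post /= norm[:, :, None]
    states = post.argmax(axis=2).astype(np.int8)

    rows = _leaf_rows(aln, tree)
    missing = np.zeros((n_nodes, n_sites), dtype=bool)
    for v in tree.postorder():
        if tree.is_leaf(v):
            missing[v] = rows[v] == MISSING
        else:
            m = np.ones(n_sites, dtype=bool)
            for c in tree.children[v]:
                m &= missing[c]
            missing[v] = m
    return AncestralReconstruction(
        gene_id=aln.gene_id, posteriors=post, states=states, missing=missing,
        site_log_likelihood=partials.site_log_likelihood,
    )


def reconstruct(aln: Alignment, tree: Phylogeny,
                model: SubstitutionModel) -> AncestralReconstruction:
    """Convenience wrapper: pruning pass then marginal posteriors."""
    return marginal_posteriors(conditional_likelihoods(aln, tree, model),
                               aln, tree, model)


def export_states_tsv(rec: AncestralReconstruction, tree: Phylogeny,
                      path) -> None:
    """Write per-node per-site assigned states and posteriors as TSV."""
    from .io import AMINO_ACIDS

    with open(path, "w") as fh:
        fh.write("node\tsite\tstate\tposterior\tmissing\n")
        for v in range(tree.n_nodes):
            if tree.is_leaf(v):
                continue
            for s in range(rec.states.shape[1]):
                a = rec.states[v, s]
                fh.write(
                    f"{v}\t{s + 1}\t{AMINO_ACIDS[a]}\t"
                    f"{rec.posteriors[v, s, a]:.6f}\t"
                    f"{int(rec.missing[v, s])}\n"
                )
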