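"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own pruning/posterior code paths: site likelihoods and marginals come from
exhaustive enumeration over internal-node state assignments, and convergent
sites from a literal re-implementation of the calling rules.
"""

from __future__ import annotations

import itertools

import numpy as np

from rifconv.io import MISSING, Alignment, Phylogeny
from rifconv.model import N_STATES, SubstitutionModel


def _leaf_vector(aln: Alignment, tree: Phylogeny, leaf: int, site: int) -> np.ndarray:
    c = aln.row(tree.labels[leaf])[site]
    if c == MISSING:
        return np.ones(N_STATES)
    v = np.zeros(N_STATES)
    v[c] = 1.0
    return v


def enumerate_site(aln: Alignment, tree: Phylogeny, model: SubstitutionModel,
                   site: int):
    """Exhaustive joint enumeration over internal-node states at one site.

    Returns ``(site_likelihood, marginals)`` where ``marginals`` maps each
    internal node id to its exact marginal posterior vector.
    """
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    P = {v: model.transition_matrix(tree.branch_lengths[v])
         for v in range(tree.n_nodes - 1)}
    leaf_vec = {v: _leaf_vector(aln, tree, v, site) for v in tree.leaves}
    total = 0.0
    marg = {v: np.zeros(N_STATES) for v in internal}
    for states in itertools.product(range(N_STATES), repeat=len(internal)):
        assign = dict(zip(internal, states))
        lik = model.pi[assign[tree.root]]
        for v in range(tree.n_nodes - 1):
            parent_state = assign[int(tree.parent[v])]
            if tree.is_leaf(v):
                lik *= float(P[v][parent_state] @ leaf_vec[v])
            else:
                lik *= P[v][parent_state, assign[v]]
        total += lik
        for v in internal:
            marg[v][assign[v]] += lik
    for v in internal:
        marg[v] /= total
    return total, marg


def brute_force_convergent_sites(aln: Alignment, rec, tree: Phylogeny,
                                 mode: str = "all_foreground") -> set[int]:
    """Literal site-by-site scan of the convergence calling rules.

    Returns the set of qualifying 1-based sites.  Independent of the
    package's call enumeration: it re-derives branch endpoint states from
    the reconstruction and leaf data directly.
    """
    fg = sorted(tree.foreground)
    qualifying = set()
    for s in range(aln.length):
        per_branch = {}
        for b in fg:
            u = int(tree.parent[b])
            if rec.missing[u, s]:
                per_branch[b] = None
                continue
            parent_state = int(rec.states[u, s])
            if tree.is_leaf(b):
                child_state = int(aln.row(tree.labels[b])[s])
                if child_state == MISSING:
                    per_branch[b] = None
                    continue
            else:
                if rec.missing[b, s]:
                    per_branch[b] = None
                    continue
                child_state = int(rec.states[b, s])
            per_branch[b] = (parent_state, child_state) \
                if parent_state != child_state else None

        def leaves_carry(branch, residue):
            return all(
                int(aln.row(tree.labels[leaf])[s]) == residue
                for leaf in tree.subtree_leaves(branch)
            )

        if mode == "all_foreground":
            if any(per_branch[b] is None for b in fg):
                continue
            derived = {per_branch[b][1] for b in fg}
            if len(derived) != 1:
                continue
            d = derived.pop()
            if all(leaves_carry(b, d) for b in fg):
                qualifying.add(s + 1)
        else:
            for b1, b2 in itertools.combinations(fg, 2):
                if per_branch[b1] is None or per_branch[b2] is None:
                    continue
                if per_branch[b1][1] != per_branch[b2][1]:
                    continue
                d = per_branch[b1][1]
                if leaves_carry(b1, d) and leaves_carry(b2, d):
                    qualifying.add(s + 1)
                    break
    return qualifying


def stepup_bh(p_values) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up arithmetic (test-side oracle)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = running
    return q
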