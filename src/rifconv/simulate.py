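"""Synthetic ortholog-alignment generator with optional injected convergence.

Genes evolve site-independently along a fixed rooted tree under the
JTT+F_gene process: the root sequence is drawn from the model's equilibrium
frequencies and each branch applies the transition matrix for its length.
Convergence positives are constructed by direct leaf editing: at a chosen
site, every foreground clade's extant leaves (and the clade's true node
state) are set to one derived residue that differs from the true state at
every foreground branch's parent, giving exact, auditable positives for
recovery experiments.

The default benchmark tree is a 9-leaf topology emulating the study design
this generator stands in for: two ingroup clades plus outgroup, with three
designated foreground lineages (one two-leaf clade MRCA and two terminal
branches) and branch lengths between 0.05 and 0.3 substitutions/site.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (AMINO_ACIDS, Alignment, Phylogeny, RifconvError,
                 read_tree, resolve_foreground, write_alignment, write_tree)
from .model import (JTT_FREQUENCIES, N_STATES, SubstitutionModel, build_model)

#: Default benchmark topology: a clade of four "rock-dweller"-bearing taxa
#: plus relatives, a sister clade, and a two-leaf outgroup.
DEFAULT_TREE_NEWICK = (
    "(((((Lapidomyces_sp:0.08,Catenulostroma_hermanusense:0.09):0.06,"
    "Teratosphaeria_rel:0.12):0.05,"
    "(Rachicladosporium_sp:0.10,Cladosporium_rel:0.11):0.07):0.06,"
    "(Coniosporium_apollinis:0.15,Dothidea_rel:0.13):0.08):0.10,"
    "(Sordaria_rel:0.18,Neurospora_rel:0.16):0.12);"
)

#: Default foreground designation on the benchmark tree: the MRCA branch of
#: the two-leaf clade plus two terminal branches (three independent lineages).
DEFAULT_FOREGROUND = (
    ("Lapidomyces_sp", "Catenulostroma_hermanusense"),
    ("Coniosporium_apollinis",),
    ("Rachicladosporium_sp",),
)


def default_tree(resolve: bool = True) -> Phylogeny:
    tree = read_tree(DEFAULT_TREE_NEWICK)
    if resolve:
        resolve_foreground(tree, DEFAULT_FOREGROUND)
    return tree


@dataclass
class SimulationConfig:
    """Study conditions for one benchmark set."""

    n_genes: int = 200
    sites_per_gene: int = 300
    seed: int = 0
    f_gene_source: str = "dirichlet"   # uniform | dirichlet | fixed
    dirichlet_concentration: float = 50.0
    fixed_frequencies: list | None = None
    n_injected_genes: int = 0
    sites_per_injected_gene: int = 3
    derived_policy: str = "random"     # random non-ancestral | fixed residue
    derived_residue: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if d["fixed_frequencies"] is not None:
            d["fixed_frequencies"] = list(map(float, d["fixed_frequencies"]))
        return d


@dataclass
class InjectionRecord:
    gene_id: str
    site: int                    # 1-based
    derived_state: int
    ancestral_states: dict[int, int]  # foreground branch id -> true parent state


def draw_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene equilibrium frequencies for simulation."""
    if config.f_gene_source == "uniform":
        return np.full(N_STATES, 1.0 / N_STATES)
    if config.f_gene_source == "fixed":
        if config.fixed_frequencies is None:
            raise RifconvError("fixed f_gene_source requires fixed_frequencies")
        pi = np.asarray(config.fixed_frequencies, dtype=float)
        return pi / pi.sum()
    if config.f_gene_source == "dirichlet":
        alpha = config.dirichlet_concentration * JTT_FREQUENCIES * N_STATES
        pi = rng.dirichlet(alpha)
        # keep frequencies strictly positive for the reversible model
        pi = np.clip(pi, 1e-6, None)
        return pi / pi.sum()
    raise RifconvError(f"unknown f_gene_source {config.f_gene_source!r}")


def simulate_gene(tree: Phylogeny, model: SubstitutionModel, n_sites: int,
                  rng: np.random.Generator, gene_id: str = "gene"):
    """Simulate one gene; returns ``(Alignment, truth)``.

    ``truth`` is an ``(n_nodes, n_sites)`` int8 array of true states at every
    node (the full substitution history at node resolution).
    """
    n_nodes = tree.n_nodes
    truth = np.empty((n_nodes, n_sites), dtype=np.int8)
    truth[tree.root] = rng.choice(N_STATES, size=n_sites, p=model.pi)
    cum = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        if v not in cum:
            P = model.transition_matrix(tree.branch_lengths[v])
            cum[v] = np.cumsum(P, axis=1)
        rows = cum[v][truth[tree.parent[v]]]
        r = rng.random(n_sites)
        truth[v] = (r[:, None] >= rows).sum(axis=1).astype(np.int8)
    leaves = tree.leaves
    taxa = [tree.labels[v] for v in leaves]
    codes = truth[leaves].copy()
    return Alignment(gene_id=gene_id, taxa=taxa, codes=codes), truth


def background_conserved_sites(aln: Alignment, tree: Phylogeny) -> np.ndarray:
    """1-based sites whose non-foreground leaves all share one observed residue.

    Adaptive convergent substitutions are reported at functionally
    constrained positions, so benchmark positives are planted on columns
    that are conserved outside the foreground clades.
    """
    if not tree.foreground:
        raise RifconvError("no foreground branches resolved on the tree")
    fg_leaves = set()
    for b in tree.foreground:
        fg_leaves.update(tree.subtree_leaves(b))
    bg = [lv for lv in tree.leaves if lv not in fg_leaves]
    rows = np.vstack([aln.row(tree.labels[lv]) for lv in bg])
    ok = (rows >= 0).all(axis=0) & (rows == rows[0]).all(axis=0)
    return np.where(ok)[0] + 1


def inject_convergence(aln: Alignment, truth: np.ndarray, tree: Phylogeny,
                       sites, rng: np.random.Generator,
                       derived_policy: str = "random",
                       derived_residue: str | None = None) -> list[InjectionRecord]:
    """Plant convergent substitutions at 1-based ``sites`` (in place).

    At each site, one derived residue differing from the true state at every
    foreground branch's parent is chosen; the default "random" policy draws
    it uniformly among residues additionally absent from the site's
    non-foreground leaves (a novel residue, as in reported adaptive
    convergence), while "fixed" uses ``derived_residue`` and rejects it if
    it equals any foreground parent's state.  All extant leaves of each
    foreground clade and the clade's true node state are set to the derived
    residue.  Non-foreground leaves and other sites are untouched.  Returns
    the injection manifest.
    """
    if not tree.foreground:
        raise RifconvError("no foreground branches resolved on the tree")
    fg = sorted(tree.foreground)
    leaf_row = {tree.labels[v]: i for i, v in enumerate(tree.leaves)}
    records = []
    for site in sites:
        s0 = int(site) - 1
        if not (0 <= s0 < aln.length):
            raise RifconvError(f"injection site {site} outside alignment")
        parents = {b: int(truth[tree.parent[b], s0]) for b in fg}
        forbidden = set(parents.values())
        if derived_policy == "fixed":
            if derived_residue is None:
                raise RifconvError("fixed derived policy needs derived_residue")
            d = AMINO_ACIDS.index(derived_residue.upper())
            if d in forbidden:
                raise RifconvError(
                    f"derived residue {derived_residue} equals an ancestral "
                    f"state at site {site}"
                )
        else:
            observed = set(int(c) for c in aln.codes[:, s0] if c >= 0)
            choices = [a for a in range(N_STATES)
                       if a not in forbidden and a not in observed]
            if not choices:  # < 20 residues can ever be excluded, but be safe
                choices = [a for a in range(N_STATES) if a not in forbidden]
            if not choices:
                raise RifconvError("no residue differs from all parent states")
            d = int(rng.choice(choices))
        for b in fg:
            truth[b, s0] = d
            for leaf in tree.subtree_leaves(b):
                truth[leaf, s0] = d
                aln.codes[leaf_row[tree.labels[leaf]], s0] = d
        records.append(InjectionRecord(
            gene_id=aln.gene_id, site=int(site), derived_state=d,
            ancestral_states=parents,
        ))
    return records


def manifest_to_frame(records: list[InjectionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.gene_id,
            "site": r.site,
            "derived": AMINO_ACIDS[r.derived_state],
            "ancestral": ";".join(
                f"{b}:{AMINO_ACIDS[a]}" for b, a in sorted(
                    r.ancestral_states.items())
            ),
        })
    return pd.DataFrame(rows, columns=["gene_id", "site", "derived", "ancestral"])


def read_manifest(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t",
                           dtype={"gene_id": str, "site": "int64"})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "site", "derived", "ancestral"])


def simulate_benchmark(config: SimulationConfig, tree: Phylogeny | None = None):
    """Simulate a full benchmark in memory.

    Returns ``(alignments, manifest_records, tree)``; the first
    ``config.n_injected_genes`` genes carry injected convergence at
    ``sites_per_injected_gene`` distinct random sites each.
    """
    if tree is None:
        tree = default_tree()
    if not tree.foreground:
        raise RifconvError("benchmark tree needs resolved foreground branches")
    if config.n_injected_genes > config.n_genes:
        raise RifconvError("n_injected_genes exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    alignments, manifest = [], []
    width = len(str(max(config.n_genes, 1)))
    for g in range(config.n_genes):
        gene_id = f"gene_{g + 1:0{width}d}"
        pi = draw_frequencies(config, rng)
        model = build_model(pi)
        aln, truth = simulate_gene(tree, model, config.sites_per_gene, rng,
                                   gene_id=gene_id)
        if g < config.n_injected_genes:
            eligible = background_conserved_sites(aln, tree)
            k = config.sites_per_injected_gene
            if len(eligible) >= k:
                sites = rng.choice(eligible, size=k, replace=False)
            else:  # very short or very divergent gene: fall back to any site
                rest = np.setdiff1d(np.arange(1, config.sites_per_gene + 1),
                                    eligible)
                extra = rng.choice(rest, size=k - len(eligible), replace=False)
                sites = np.concatenate([eligible, extra])
            manifest.extend(inject_convergence(
                aln, truth, tree, sorted(int(s) for s in sites), rng,
                derived_policy=config.derived_policy,
                derived_residue=config.derived_residue,
            ))
        alignments.append(aln)
    return alignments, manifest, tree


def make_benchmark(config: SimulationConfig, out_dir,
                   tree: Phylogeny | None = None, force: bool = False):
    """Write a benchmark directory: FASTA per gene, tree, manifest, config echo."""
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise RifconvError(
            f"output directory {out_dir} is not empty (use force to overwrite)"
        )
    os.makedirs(os.path.join(out_dir, "alignments"), exist_ok=True)
    alignments, manifest, tree = simulate_benchmark(config, tree)
    for aln in alignments:
        write_alignment(aln,
                        os.path.join(out_dir, "alignments", f"{aln.gene_id}.fasta"))
    write_tree(tree, os.path.join(out_dir, "tree.nwk"))
    manifest_to_frame(manifest).to_csv(
        os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    echo = config.to_dict()
    echo["foreground_branches"] = sorted(int(b) for b in tree.foreground)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return alignments, manifest, tree


def directory_digest(out_dir) -> str:
    """SHA-256 over the sorted file contents of a benchmark directory."""
    h = hashlib.sha256()
    for root, _dirs, files in sorted(os.walk(str(out_dir))):
        for name in sorted(files):
            path = os.path.join(root, name)
            h.update(os.path.relpath(path, str(out_dir)).encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
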