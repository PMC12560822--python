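"""Readers, writers and core containers for alignments, trees and genome tables.

The containers here are deliberately thin: an :class:`Alignment` is an
integer-coded residue matrix, a :class:`Phylogeny` is a set of parallel
arrays indexed by a deterministic post-order node id, and a genome-features
table is a typed :class:`pandas.DataFrame`.  All downstream modules
(substitution model, ancestral reconstruction, convergence scan, simulator)
work on these containers only.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("rifconv")

#: Amino acids in the conventional empirical-matrix order used by published
#: JTT/WAG/LG tables.  All integer residue codes index into this string.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Integer code for missing data (gap '-' or unknown 'X').
MISSING = -1


class RifconvError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(RifconvError):
    """Sequences in one alignment differ in length."""


class EmptyInputError(RifconvError):
    """An input file or container holds no usable records."""


class TreeError(RifconvError):
    """A phylogeny violates the rooted-binary-with-lengths contract."""


class ForegroundError(RifconvError):
    """Foreground designation is invalid (missing taxon, root MRCA, nesting)."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A protein multiple sequence alignment with integer-coded residues.

    ``codes`` is an ``(n_taxa, length)`` int8 matrix over the alphabet
    :data:`AMINO_ACIDS`; gaps and unknowns are stored as :data:`MISSING`.
    Site positions are 0-based internally; every user-facing report converts
    to 1-based alignment columns.
    """

    gene_id: str
    taxa: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentShapeError(
                f"{self.gene_id}: codes shape {self.codes.shape} does not "
                f"match {len(self.taxa)} taxa"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentShapeError(f"{self.gene_id}: duplicate taxon labels")

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        """Residue string for one taxon, missing rendered as '-'."""
        return "".join(
            AMINO_ACIDS[c] if c >= 0 else "-" for c in self.row(taxon)
        )


def encode_sequence(seq: str) -> np.ndarray:
    """Map a residue string to integer codes; unknown symbols become 'X'."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        else:
            out[i] = MISSING
    return out


def read_alignment(path, gene_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Symbols outside the 20-residue alphabet (including gaps) are stored as
    missing; non-gap unknowns (e.g. ambiguity codes 'B', 'Z') additionally
    trigger a logged warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    gene = gene_id if gene_id is not None else _stem(path)
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"{gene}: unequal sequence lengths {sorted(lengths)}"
        )
    taxa, rows = [], []
    for r in records:
        seq = str(r.seq).upper()
        odd = sorted({ch for ch in seq if ch not in AA_INDEX and ch != "-"})
        if odd:
            logger.warning(
                "%s: taxon %s has non-standard symbols %s; treated as 'X'",
                gene, r.id, ",".join(odd),
            )
        taxa.append(r.id)
        rows.append(encode_sequence(seq))
    return Alignment(gene_id=gene, taxa=taxa, codes=np.vstack(rows))


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n{aln.sequence(t)}\n")


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, stored as parallel arrays.

    Node ids are assigned by deterministic post-order traversal of the input
    newick, so ids ``0 .. n_nodes-1`` *are* a post-order sequence and the
    root is always ``n_nodes - 1``.  ``branch_lengths[i]`` is the length of
    the branch above node ``i`` (0.0 at the root).  ``foreground`` holds the
    node ids whose parent branches are designated foreground lineages.
    """

    parent: np.ndarray          # int64, -1 at root
    branch_lengths: np.ndarray  # float64, substitutions/site
    labels: list[str | None]    # leaf label per node, None for internal
    children: list[list[int]]
    foreground: frozenset = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def postorder(self):
        return range(self.n_nodes)

    def preorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def node_of_label(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise TreeError(f"taxon {label!r} is not a leaf of the tree")

    def ancestors(self, node: int) -> set[int]:
        out = set()
        u = self.parent[node]
        while u != -1:
            out.add(int(u))
            u = self.parent[u]
        return out

    def mrca(self, nodes) -> int:
        nodes = list(nodes)
        common = self.ancestors(nodes[0]) | {nodes[0]}
        for v in nodes[1:]:
            common &= self.ancestors(v) | {v}
        # the deepest common ancestor is the MRCA
        return max(common, key=lambda u: len(self.ancestors(u)))

    def subtree_leaves(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    def newick(self) -> str:
        def fmt(node: int) -> str:
            if self.is_leaf(node):
                core = self.labels[node]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            if node == self.root:
                return core
            return f"{core}:{self.branch_lengths[node]:.10g}"

        return fmt(self.root) + ";"


def read_tree(path_or_string) -> Phylogeny:
    """Parse a rooted newick tree with branch lengths on all non-root edges.

    A trifurcating root is rejected as unrooted; internal node ids are
    assigned by post-order index so repeated reads are reproducible.
    """
    s = str(path_or_string)
    if "(" in s:
        newick = s
    else:
        with open(s) as fh:
            newick = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    seed = dtree.seed_node
    if len(seed.child_nodes()) != 2:
        raise TreeError(
            f"root has {len(seed.child_nodes())} children; the tree is "
            "unrooted — root it (binary root) before analysis"
        )
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=np.float64)
    labels: list[str | None] = [None] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for i, nd in enumerate(nodes):
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                who = labels[i] or f"internal node {i}"
                raise TreeError(f"missing branch length above {who}")
            if nd.edge.length < 0:
                raise TreeError(f"negative branch length above node {i}")
            blen[i] = float(nd.edge.length)
    leaf_labs = [labels[i] for i in range(n) if not children[i]]
    if len(set(leaf_labs)) != len(leaf_labs):
        raise TreeError("duplicate leaf labels")
    return Phylogeny(parent=parent, branch_lengths=blen, labels=labels,
                     children=children)


def write_tree(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def resolve_foreground(tree: Phylogeny, specs) -> frozenset:
    """Resolve foreground designators to branch (node) ids on ``tree``.

    Each designator is a taxon label (terminal branch) or an iterable of
    labels (the branch above their MRCA).  Nested designations are rejected:
    convergence requires independently evolving lineages.  The resolved set
    is stored on ``tree.foreground`` and returned.
    """
    ids = []
    for spec in specs:
        names = [spec] if isinstance(spec, str) else list(spec)
        if not names:
            raise ForegroundError("empty foreground designator")
        leaf_ids = [tree.node_of_label(nm) for nm in names]
        node = leaf_ids[0] if len(leaf_ids) == 1 else tree.mrca(leaf_ids)
        if node == tree.root:
            raise ForegroundError(
                f"designator {names} resolves to the root, which has no "
                "parent branch"
            )
        ids.append(int(node))
    if len(set(ids)) != len(ids):
        ids = sorted(set(ids))
    for a in ids:
        anc = tree.ancestors(a)
        for b in ids:
            if a != b and b in anc:
                raise ForegroundError(
                    f"foreground branches {a} and {b} are nested; convergent "
                    "lineages must be independent"
                )
    fg = frozenset(ids)
    tree.foreground = fg
    return fg


# ---------------------------------------------------------------------------
# Genome features table
# ---------------------------------------------------------------------------

GENOME_TABLE_COLUMNS = [
    "species", "group", "scaffolds", "n50_bp", "genome_size_bp",
    "protein_count", "busco_pct", "gc_pct",
]
_INT_COLS = ["scaffolds", "n50_bp", "genome_size_bp", "protein_count"]
_FLOAT_COLS = ["busco_pct", "gc_pct"]


def read_genome_table(path) -> pd.DataFrame:
    """Read a per-species genome-features TSV (assembly statistics).

    Thousands separators inside numeric fields are accepted and stripped.
    An empty file yields an empty, correctly-typed table.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=GENOME_TABLE_COLUMNS)
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in df.columns]
    if missing and len(df.columns) and len(df):
        raise RifconvError(f"genome table missing columns: {missing}")
    if not len(df):
        return pd.DataFrame(columns=GENOME_TABLE_COLUMNS).astype(
            {c: "int64" for c in _INT_COLS} | {c: "float64" for c in _FLOAT_COLS}
        )
    out = df.copy()
    for col in _INT_COLS + _FLOAT_COLS:
        cleaned = out[col].str.replace(",", "", regex=False).str.strip()
        bad = cleaned.apply(lambda v: not _numeric(v))
        if bad.any():
            offenders = out.loc[bad, "species"].tolist()
            raise RifconvError(
                f"non-numeric {col} for species: {', '.join(offenders)}"
            )
        out[col] = cleaned.astype("int64" if col in _INT_COLS else "float64")
    bad_size = out["genome_size_bp"] <= 0
    if bad_size.any():
        raise RifconvError(
            "nonpositive genome size for species: "
            + ", ".join(out.loc[bad_size, "species"])
        )
    return out[GENOME_TABLE_COLUMNS]


def _numeric(v: str) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_genome_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
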