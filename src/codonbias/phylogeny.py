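"""Protein-distance phylogeny: Poisson correction, neighbor joining, bootstrap.

The procedure mirrors the classic distance pipeline for heterogeneous coding
sequences: translate, align (alignment construction is out of scope — an
aligned protein set is the input), drop every column containing a gap
(*complete deletion*), compute Poisson-corrected distances
``d = -ln(1 - p)`` from the proportion ``p`` of differing residues, build a
neighbor-joining (NJ) topology, and attach bootstrap supports by resampling
alignment columns with replacement.

The NJ implementation is deterministic: ties in the Q criterion are broken
by the lexicographically smallest pair of subtree labels (a subtree is
labelled by its smallest leaf), and negative branch lengths are clamped to
zero with the deficit logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .codon_core import CodonUsageError

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedProteinSet",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "poisson_distance",
    "neighbor_joining",
    "bootstrap_supports",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = set("-.?X")  # treated as missing data for complete deletion


@dataclass(frozen=True)
class AlignedProteinSet:
    """Equal-length amino-acid rows with gap symbols, one per taxon."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise CodonUsageError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise CodonUsageError("duplicate taxon labels")
        if not self.rows:
            raise CodonUsageError("empty alignment")
        rows = tuple(r.upper() for r in self.rows)
        width = len(rows[0])
        for label, row in zip(self.labels, rows):
            if len(row) != width:
                raise CodonUsageError(f"{label}: row length {len(row)} != {width}")
            bad = set(row) - _AA - _GAP
            if bad:
                raise CodonUsageError(f"{label}: invalid symbols {sorted(bad)}")
        object.__setattr__(self, "rows", rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedProteinSet":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise CodonUsageError(f"no FASTA records in {path}")
        return cls(tuple(r.id for r in recs), tuple(str(r.seq) for r in recs))

    def ungapped_columns(self) -> list[int]:
        """Indices of columns free of gaps/missing symbols in every row."""
        return [
            j
            for j in range(self.n_columns)
            if all(row[j] not in _GAP for row in self.rows)
        ]

    def complete_deletion(self) -> "AlignedProteinSet":
        cols = self.ungapped_columns()
        if not cols:
            raise CodonUsageError("complete deletion removed every column")
        return self.select_columns(cols)

    def select_columns(self, cols: Sequence[int]) -> "AlignedProteinSet":
        return AlignedProteinSet(
            self.labels,
            tuple("".join(row[j] for j in cols) for row in self.rows),
        )


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise CodonUsageError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12) or not np.allclose(np.diag(m), 0):
            raise CodonUsageError("distance matrix must be symmetric with zero diagonal")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise CodonUsageError("distances must be finite and non-negative")
        object.__setattr__(self, "matrix", m)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def poisson_distance(aln: AlignedProteinSet) -> DistanceMatrix:
    """Poisson-corrected distances ``-ln(1 - p)`` after complete deletion."""
    clean = aln.complete_deletion()
    n = len(clean.labels)
    cols = clean.n_columns
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(a != b for a, b in zip(clean.rows[i], clean.rows[j]))
            p = diff / cols
            if p >= 1.0:
                raise CodonUsageError(
                    f"infinite Poisson distance between {clean.labels[i]} "
                    f"and {clean.labels[j]} (p = 1)"
                )
            m[i, j] = m[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(clean.labels, m)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an (unrooted) tree; the root of an NJ tree is trifurcating."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # percent, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])  # type: ignore[list-item]
        return frozenset().union(*(ch.leaf_labels() for ch, _ in self.children))


@dataclass
class PhyloTree:
    root: TreeNode
    labels: tuple[str, ...]

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side *not* containing
        the lexicographically smallest taxon."""
        all_taxa = frozenset(self.labels)
        ref = min(self.labels)
        out = set()

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaf_labels()
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(side if ref not in side else all_taxa - side)
                walk(child)

        walk(self.root)
        return frozenset(out)

    def _edge_nodes(self) -> dict[frozenset[str], TreeNode]:
        all_taxa = frozenset(self.labels)
        ref = min(self.labels)
        nodes = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaf_labels()
                if 1 < len(side) < len(all_taxa) - 1:
                    nodes[side if ref not in side else all_taxa - side] = child
                walk(child)

        walk(self.root)
        return nodes

    def to_newick(self, with_support: bool = False) -> str:
        def render(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(render(ch, ln) for ch, ln in node.children)
                tag = ""
                if with_support and node.support is not None:
                    tag = f"{node.support:g}"
                body = f"({inner}){tag}"
            return body if length is None else f"{body}:{length:.6g}"

        inner = ",".join(render(ch, ln) for ch, ln in self.root.children)
        return f"({inner});"


def _nj_label(node: TreeNode) -> str:
    return min(node.leaf_labels())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Ties are broken by the smallest (lexicographic) pair of subtree labels;
    negative branch-length estimates are clamped to zero and the clamped
    deficit logged.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise CodonUsageError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    d = {
        frozenset((i, j)): dm.matrix[i, j]
        for i in range(n0)
        for j in range(i + 1, n0)
    }
    active = list(range(n0))
    next_id = n0
    clamped = 0.0

    def dist(a: int, b: int) -> float:
        return d[frozenset((a, b))]

    node_of: dict[int, TreeNode] = dict(enumerate(nodes))

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        row_sums = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (n - 2) * dist(a, b) - row_sums[a] - row_sums[b]
                pair_key = tuple(sorted((_nj_label(node_of[a]), _nj_label(node_of[b]))))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best  # type: ignore[misc]
        d_ab = dist(a, b)
        la = clamp(0.5 * d_ab + (row_sums[a] - row_sums[b]) / (2 * (n - 2)))
        lb = clamp(d_ab - (0.5 * d_ab + (row_sums[a] - row_sums[b]) / (2 * (n - 2))))
        parent = TreeNode(children=[(node_of[a], la), (node_of[b], lb)])
        node_of[next_id] = parent
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((next_id, c))] = 0.5 * (dist(a, c) + dist(b, c) - d_ab)
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    a, b, c = active
    la = clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))
    lb = clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))
    lc = clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))
    root = TreeNode(
        children=[(node_of[a], la), (node_of[b], lb), (node_of[c], lc)]
    )
    if clamped:
        logger.info("NJ clamped negative branch lengths; total deficit %.6g", clamped)
    return PhyloTree(root, dm.labels)


def bootstrap_supports(
    aln: AlignedProteinSet, replicates: int, seed: int
) -> PhyloTree:
    """NJ tree from the full data with bootstrap supports on internal edges.

    Each replicate resamples the gap-free alignment columns with
    replacement, rebuilds Poisson distances and the NJ topology, and scores
    which full-data bipartitions it recovers.  A replicate on which the
    distance is undefined (a pair with p = 1) recovers nothing but still
    counts in the denominator, keeping supports reproducible.
    """
    if replicates < 1:
        raise CodonUsageError("replicates must be >= 1")
    clean = aln.complete_deletion()
    tree = neighbor_joining(poisson_distance(clean))
    edge_nodes = tree._edge_nodes()
    hits = {split: 0 for split in edge_nodes}
    rng = np.random.default_rng(seed)
    n_cols = clean.n_columns
    failed = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_tree = neighbor_joining(
                poisson_distance(clean.select_columns(list(cols)))
            )
        except CodonUsageError:
            failed += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for split in hits:
            if split in rep_splits:
                hits[split] += 1
    if failed:
        logger.warning("bootstrap: %d/%d replicates undefined", failed, replicates)
    for split, node in edge_nodes.items():
        node.support = 100.0 * hits[split] / replicates
    return tree
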