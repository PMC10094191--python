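"""Multivariate analysis of RSCU matrices.

Correspondence analysis (CA) treats the genes × codons RSCU matrix as a
two-way table under the chi-square metric: with correspondence matrix
``P = X / X.sum()``, row masses ``r`` and column masses ``c``, the
standardized residual matrix is ``S = (P - r cᵀ) / sqrt(r cᵀ)``.  Its
singular value decomposition yields principal coordinates
``F = D_r^{-1/2} U Σ`` (genes) and ``G = D_c^{-1/2} V Σ`` (codons), and the
fraction of total inertia carried by axis *a* is ``σ_a² / Σ σ²``.  This is
the "COA on RSCU" analysis classically run by codonW on codon-usage data.

Hierarchical clustering and Pearson correlation panels are thin, contract-
enforcing layers over scipy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .codon_core import CodonUsageError, RSCUProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CAResult",
    "Dendrogram",
    "CorrelationPanel",
    "rscu_matrix",
    "correspondence_analysis",
    "hierarchical_cluster",
    "correlation_panel",
]

_SV_TOL = 1e-12


def rscu_matrix(profiles: Sequence[RSCUProfile]) -> pd.DataFrame:
    """Stack RSCU profiles into a genes × 59-codon DataFrame (NaN = undefined)."""
    df = pd.DataFrame([p.as_series() for p in profiles])
    df.index.name = "gene"
    return df


@dataclass(frozen=True)
class CAResult:
    """Gene/codon principal coordinates and per-axis inertia fractions.

    ``inertia_fraction`` covers *all* positive axes (sums to 1); the first
    ``k`` axes are retained in the coordinate frames.  ``degenerate`` marks
    a table with no variation (total inertia ~ 0), which has no axes.
    """

    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    inertia_fraction: np.ndarray
    k: int
    total_inertia: float
    n_imputed: int = 0

    @property
    def degenerate(self) -> bool:
        return self.k == 0


def _impute_column_mean(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n_missing = int(matrix.isna().to_numpy().sum())
    if n_missing:
        matrix = matrix.fillna(matrix.mean(axis=0))
        logger.info("CA: imputed %d undefined RSCU cells with column means", n_missing)
    return matrix, n_missing


def correspondence_analysis(
    rscu: pd.DataFrame, n_axes: int | None = None
) -> CAResult:
    """Classical CA of a non-negative genes × codons table.

    Undefined (NaN) cells are imputed with the codon's column mean before
    analysis; the imputation count is recorded on the result.  Axis signs
    are fixed by forcing the codon with the largest absolute loading on each
    axis to be positive.
    """
    if rscu.shape[0] < 2:
        raise CodonUsageError("correspondence analysis needs at least 2 genes")
    matrix, n_imputed = _impute_column_mean(rscu.astype(float))
    x = matrix.to_numpy()
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise CodonUsageError("CA input must be finite and non-negative")
    row_sums = x.sum(axis=1)
    col_sums = x.sum(axis=0)
    for labels, sums, what in (
        (matrix.index, row_sums, "gene"),
        (matrix.columns, col_sums, "codon"),
    ):
        dead = [str(l) for l, s in zip(labels, sums) if s == 0]
        if dead:
            raise CodonUsageError(f"degenerate zero-margin {what}(s) in CA input: {dead}")

    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s, full_matrices=False)

    keep = sv > _SV_TOL * max(sv[0], 1.0) if sv.size else np.array([], bool)
    sv = sv[keep]
    u = u[:, keep]
    vt = vt[keep, :]
    if sv.size == 0:
        empty = pd.DataFrame(index=matrix.index)
        return CAResult(
            empty, pd.DataFrame(index=matrix.columns),
            np.array([]), 0, 0.0, n_imputed,
        )

    inertia = sv**2
    inertia_fraction = inertia / inertia.sum()
    max_axes = sv.size
    k = max_axes if n_axes is None else min(n_axes, max_axes)

    f = (u * sv) / np.sqrt(r)[:, None]          # gene principal coordinates
    g = (vt.T * sv) / np.sqrt(c)[:, None]       # codon principal coordinates
    for a in range(max_axes):                   # deterministic axis orientation
        pivot = int(np.argmax(np.abs(g[:, a])))
        if g[pivot, a] < 0:
            g[:, a] = -g[:, a]
            f[:, a] = -f[:, a]

    axes = [f"axis{i + 1}" for i in range(k)]
    return CAResult(
        gene_coords=pd.DataFrame(f[:, :k], index=matrix.index, columns=axes),
        codon_coords=pd.DataFrame(g[:, :k], index=matrix.columns, columns=axes),
        inertia_fraction=inertia_fraction,
        k=k,
        total_inertia=float(inertia.sum()),
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history over lexicographically ordered leaves.

    ``merges`` is the scipy linkage matrix; rows merge clusters (by index,
    leaves first) at non-decreasing heights for monotone linkages.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    linkage_method: str
    distance_metric: str

    def flat_clusters(
        self, n_clusters: int | None = None, height: float | None = None
    ) -> dict[str, int]:
        if (n_clusters is None) == (height is None):
            raise CodonUsageError("give exactly one of n_clusters or height")
        if n_clusters is not None:
            assignment = hierarchy.fcluster(self.merges, n_clusters, "maxclust")
        else:
            assignment = hierarchy.fcluster(self.merges, height, "distance")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            inner = ",".join(walk(ch, node.dist) for ch in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(walk(ch, tree.dist) for ch in (tree.left, tree.right))
        return f"({inner});"


def hierarchical_cluster(
    rscu: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of gene RSCU profiles.

    Genes are sorted lexicographically by label before agglomeration, which
    makes the result invariant to input order and resolves distance ties
    deterministically.
    """
    if metric != "euclidean":
        raise CodonUsageError(f"unsupported metric {metric!r}")
    if linkage not in ("average", "ward", "complete"):
        raise CodonUsageError(f"unsupported linkage {linkage!r}")
    if rscu.shape[0] < 2:
        raise CodonUsageError("clustering needs at least 2 genes")
    matrix, _ = _impute_column_mean(rscu.astype(float))
    matrix = matrix.sort_index(key=lambda ix: ix.astype(str))
    x = matrix.to_numpy()
    if not np.all(np.isfinite(x)):
        raise CodonUsageError("non-finite values in clustering input")
    merges = hierarchy.linkage(x, method=linkage, metric=metric)
    return Dendrogram(merges, tuple(str(g) for g in matrix.index), linkage, metric)


# ---------------------------------------------------------------------------
# Correlation panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationPanel:
    """Pairwise Pearson r, two-sided p and pairwise-complete n per variable pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def pair(self, a: str, b: str) -> tuple[float, float, int]:
        return float(self.r.loc[a, b]), float(self.p.loc[a, b]), int(self.n.loc[a, b])

    def tidy(self) -> pd.DataFrame:
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append((a, b, *self.pair(a, b)))
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "n"])

    def write_tsv(self, path: str | Path) -> None:
        self.tidy().to_csv(path, sep="\t", index=False)


def correlation_panel(
    table: pd.DataFrame,
    extra_vars: Mapping[str, pd.Series] | pd.DataFrame | None = None,
) -> CorrelationPanel:
    """Pearson correlations between index columns (plus optional CA axes).

    Pairs use pairwise-complete observations; a pair with fewer than 3
    complete observations, or a variable with zero variance, yields NaN
    (flagged by NaN, never fatal).
    """
    data = table.copy()
    if extra_vars is not None:
        extra = pd.DataFrame(extra_vars)
        data = data.join(extra, how="outer")
    data = data.astype(float)
    cols = list(data.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    values = data.to_numpy()
    for i in range(m):
        for j in range(m):
            mask = ~(np.isnan(values[:, i]) | np.isnan(values[:, j]))
            n[i, j] = int(mask.sum())
            if n[i, j] < 3:
                continue
            xa, xb = values[mask, i], values[mask, j]
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(xa, xb)
            r[i, j] = res.statistic
            p[i, j] = res.pvalue
    return CorrelationPanel(
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(n, index=cols, columns=cols),
    )
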