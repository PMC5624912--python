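"""Cell-cell correlation, UPGMA dendrograms, flat cuts, PCA, and concordance.

The clustering core of the pipeline. Cells are compared by the Pearson
correlation coefficient (PCC) of their expression profiles over a selected
gene set, computed by default on log2(FPKM + 1); the clustering distance is
``1 - PCC``. Dendrograms use average linkage (UPGMA): the height of each
merge is the mean inter-cluster distance, which is non-decreasing over the
merge sequence.

UPGMA is implemented here rather than delegated so that tie-breaking is
fully specified (equal-distance ties merge the lexicographically smallest
node-index pair), making trees bit-reproducible across platforms. Flat cuts
of the resulting linkage matrix go through :mod:`scipy.cluster.hierarchy`.

PCA is performed on log-transformed, per-gene mean-centered values (no
unit-variance scaling by default, so highly expressed genes dominate the
loadings); component signs are fixed so the largest-magnitude loading of
each component is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "PCAResult",
    "UNASSIGNED",
    "log_transform",
    "pairwise_pcc",
    "upgma",
    "correlation_distance",
    "cut_tree",
    "adjusted_rand_index",
    "run_pca",
    "concordance_report",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with each FPKM value mapped to log2(value + 1)."""
    return ExpressionMatrix(
        np.log2(mat.values + 1.0),
        list(mat.gene_ids),
        list(mat.cell_ids),
        dict(mat.cell_labels),
    )


@dataclass
class CorrelationMatrix:
    """Symmetric cell-cell PCC matrix with unit diagonal."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix does not match cell ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")

    def to_distance(self) -> np.ndarray:
        """Clustering distance ``1 - PCC`` with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def pairwise_pcc(
    mat: ExpressionMatrix, genes: Iterable[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlation between cell profiles over the selected genes.

    ``genes`` restricts the profile to a gene subset (order-insensitive by
    construction of the correlation). Cells with zero variance over the gene
    set are an error, named in the message.
    """
    if genes is not None:
        genes = sorted(genes)
        if len(genes) < 2:
            raise ValueError("need at least 2 genes to correlate cell profiles")
        sub = mat.values[mat.gene_index(genes), :]
    else:
        sub = mat.values
        if sub.shape[0] < 2:
            raise ValueError("need at least 2 genes to correlate cell profiles")
    sd = sub.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"cell {mat.cell_ids[flat[0]]!r} has zero variance over the gene set"
        )
    r = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(r, list(mat.cell_ids))


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage convention.

    ``merges`` has one row per merge: ``(node_a, node_b, height, size)``
    where leaves are numbered ``0..n-1`` in ``leaf_ids`` order and merge
    ``i`` creates node ``n + i``. Heights are mean inter-cluster distances
    and are non-decreasing (the UPGMA guarantee).
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match leaf count")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights are not non-decreasing")
        if int(self.merges[-1, 3]) != n:
            raise ValueError("final merge does not contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick serialization; branch lengths are height differences."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = f"{nodes[a]}:{h - heights[a]:.10g}"
            lb = f"{nodes[b]}:{h - heights[b]:.10g}"
            nodes[n + k] = f"({la},{lb})"
            heights[n + k] = h
        return nodes[n + self.merges.shape[0] - 1] + ";"


def upgma(dist: np.ndarray, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) tree from a square distance matrix.

    ``dist`` must be symmetric with a zero diagonal (typically ``1 - PCC``).
    At every step the pair of clusters at minimal mean inter-cluster distance
    is merged; equal-distance ties merge the smallest ``(i, j)`` node-index
    pair in lexicographic order, so the tree is deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    leaf_ids = list(leaf_ids)
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids do not match distance matrix")

    # Working arrays indexed by node id; slots are retired after merging.
    size = 2 * n - 1
    D = np.full((size, size), np.inf)
    D[:n, :n] = dist
    np.fill_diagonal(D, np.inf)
    counts = np.zeros(size, dtype=int)
    counts[:n] = 1
    active = list(range(n))
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        # argmin with lexicographic (i, j) tie-break over active node ids
        best = (np.inf, -1, -1)
        for ai, i in enumerate(active):
            row = D[i]
            for j in active[ai + 1:]:
                d = row[j]
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        new = n + step
        ni, nj = counts[i], counts[j]
        counts[new] = ni + nj
        # average-linkage update: weighted by member counts, which makes the
        # new distance the mean over all cross-cluster leaf pairs
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = (ni * D[i, k] + nj * D[j, k]) / (ni + nj)
        active.remove(i)
        active.remove(j)
        active.append(new)
        merges[step] = (i, j, d, ni + nj)

    return Dendrogram(merges, leaf_ids)


def correlation_distance(mat: ExpressionMatrix, genes: Iterable[str] | None = None,
                         log: bool = True) -> tuple[np.ndarray, list[str]]:
    """Convenience: ``1 - PCC`` distance over a gene set (log2 by default)."""
    work = log_transform(mat) if log else mat
    pcc = pairwise_pcc(work, genes)
    return pcc.to_distance(), pcc.cell_ids


@dataclass
class ClusterAssignment:
    """Cell -> label map; the reserved label ``"unassigned"`` marks cells
    excluded from every retained cluster."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = {str(c): str(l) for c, l in self.labels.items()}

    @property
    def cell_ids(self) -> list[str]:
        return list(self.labels)

    def members(self, label: str) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out

    def assigned(self) -> dict[str, str]:
        return {c: l for c, l in self.labels.items() if l != UNASSIGNED}


def cut_tree(tree: Dendrogram, k: int, min_cluster_size: int = 1) -> ClusterAssignment:
    """Cut a dendrogram into ``k`` retained clusters.

    With ``min_cluster_size=1`` this is the ordinary flat cut into ``k``
    clusters. With a larger minimum, the tree is descended (increasing the
    flat-cluster count from ``k``) until exactly ``k`` clusters of size
    >= ``min_cluster_size`` exist; cells outside those clusters — stragglers
    that do not cluster well with any group — are labeled ``"unassigned"``.
    Retained clusters are named ``C1, C2, ...`` by decreasing size (ties by
    smallest leaf index).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    for n_flat in range(k, n + 1):
        flat = sch.cut_tree(tree.merges, n_clusters=n_flat).ravel()
        ids, counts = np.unique(flat, return_counts=True)
        big = [int(i) for i, c in zip(ids, counts) if c >= min_cluster_size]
        if len(big) == k:
            order = sorted(
                big,
                key=lambda i: (-int((flat == i).sum()), int(np.flatnonzero(flat == i)[0])),
            )
            name = {i: f"C{r + 1}" for r, i in enumerate(order)}
            labels = {
                cell: name.get(int(f), UNASSIGNED)
                for cell, f in zip(tree.leaf_ids, flat)
            }
            return ClusterAssignment(labels)
    raise ValueError(
        f"no cut of the tree yields {k} clusters of size >= {min_cluster_size}"
    )


def adjusted_rand_index(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Chance-corrected agreement between two partitions in [-1, 1].

    Cells labeled ``"unassigned"`` in either partition are excluded pairwise
    before the contingency table is formed.
    """
    common = [
        c
        for c in a.labels
        if c in b.labels and a.labels[c] != UNASSIGNED and b.labels[c] != UNASSIGNED
    ]
    if not common:
        raise ValueError("partitions share no assigned cells")
    return float(
        adjusted_rand_score([a.labels[c] for c in common], [b.labels[c] for c in common])
    )


@dataclass
class PCAResult:
    """Scores (cells x components), loadings (genes x components), and
    explained-variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12):
            raise ValueError("explained fractions must lie in [0, 1]")
        if np.any(np.diff(evf) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")


def run_pca(
    mat: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    n_components: int = 2,
    log: bool = True,
    standardize: bool = False,
) -> PCAResult:
    """PCA of cells in gene space.

    Values are log2(FPKM + 1)-transformed (unless ``log=False``) and
    mean-centered per gene; ``standardize=True`` additionally scales each
    gene to unit variance. Each component's sign is fixed so the gene with
    the largest absolute loading has a positive loading.
    """
    gene_ids = sorted(genes) if genes is not None else list(mat.gene_ids)
    work = log_transform(mat) if log else mat
    X = work.values[work.gene_index(gene_ids), :].T  # cells x genes
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 cells")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={min(X.shape)}"
        )
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    for c in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    return PCAResult(
        scores,
        loadings,
        pca.explained_variance_ratio_,
        list(mat.cell_ids),
        gene_ids,
    )


def concordance_report(
    hca: ClusterAssignment, pca: PCAResult, k: int
) -> dict:
    """Agreement between a hierarchical partition and a PCA-score partition.

    The top-2 PC scores are clustered by UPGMA on Euclidean distances and cut
    into ``k`` groups; the report carries the ARI against ``hca``, both size
    tables, and the separation between PC-space centroids. For ``k=1`` the
    ARI is undefined and reported as NaN with a warning.
    """
    pts = pca.scores[:, :2]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    tree = upgma(dist, pca.cell_ids)
    pca_assign = cut_tree(tree, k=k)

    centroids = np.array(
        [pts[[pca.cell_ids.index(c) for c in pca_assign.members(l)]].mean(axis=0)
         for l in sorted(pca_assign.sizes())]
    )
    if centroids.shape[0] > 1:
        cd = centroids[:, None, :] - centroids[None, :, :]
        sep = float(np.sqrt((cd**2).sum(-1))[np.triu_indices(centroids.shape[0], 1)].min())
    else:
        sep = float("nan")

    if k == 1 or len(set(hca.assigned().values())) < 2:
        warnings.warn("ARI undefined for a single-cluster partition; reporting NaN")
        ari = float("nan")
    else:
        ari = adjusted_rand_index(hca, pca_assign)
    return {
        "ari": ari,
        "k": k,
        "hca_sizes": hca.sizes(),
        "pca_sizes": pca_assign.sizes(),
        "min_centroid_separation": sep,
        "pca_assignment": pca_assign,
    }
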