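"""Dimensionality reduction, neighborhood graph and Leiden (sub)clustering."""
from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterAssignment, DataError, ParameterError, ResidualMatrix


def select_hvg(res: ResidualMatrix, n: int = 3000) -> list[str]:
    """Top-``n`` genes by residual variance; ties broken by lexicographically
    smaller gene id. ``n`` larger than the universe is clamped with a warning.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    if n > res.n_genes:
        warnings.warn(f"n={n} exceeds {res.n_genes} genes; selecting all genes")
        n = res.n_genes
    var = res.values.var(axis=1)
    order = sorted(range(res.n_genes), key=lambda i: (-var[i], res.genes[i]))
    return [res.genes[i] for i in order[:n]]


def pca_embed(
    res: ResidualMatrix, hvg: list[str], n_pcs: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Centered PCA scores (cells x n_pcs) on the HVG submatrix.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the embedding reproducible across runs and platforms.
    """
    gene_index = {g: i for i, g in enumerate(res.genes)}
    idx = [gene_index[g] for g in hvg]
    X = res.values[idx, :].T  # cells x hvg
    if n_pcs > min(X.shape):
        raise ParameterError(f"n_pcs={n_pcs} exceeds min(cells, hvg)={min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(scores, index=res.cells, columns=[f"PC{k+1}" for k in range(n_pcs)])


def knn_graph(scores: pd.DataFrame, k: int = 15, metric: str = "euclidean") -> igraph.Graph:
    """Undirected kNN graph: union of directed k-nearest-neighbor edges
    (self excluded), all edge weights 1."""
    n = scores.shape[0]
    if k <= 0:
        raise ParameterError("k must be positive")
    if k >= n:
        raise ParameterError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(scores.values)
    _, idx = nn.kneighbors(scores.values)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    g.vs["name"] = list(scores.index)
    return g


class LeidenClusterer(ClusterMixin, BaseEstimator):
    """Leiden community detection on a kNN graph of PCA scores.

    fit(X) expects a cells x features score matrix; ``labels_`` holds the
    integer community of each cell.
    """

    def __init__(self, resolution: float = 0.5, k: int = 15, seed: int = 0):
        self.resolution = resolution
        self.k = k
        self.seed = seed

    def fit(self, X, y=None):
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")
        scores = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        graph = knn_graph(scores, k=min(self.k, scores.shape[0] - 1))
        self.labels_ = np.array(leiden_partition(graph, self.resolution, self.seed))
        return self


def leiden_partition(graph: igraph.Graph, resolution: float, seed: int) -> list[int]:
    if graph.vcount() == 0:
        raise DataError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return list(part.membership)


def leiden_cluster(
    graph: igraph.Graph, resolution: float = 0.5, seed: int = 0
) -> ClusterAssignment:
    """Cluster a prebuilt graph; labels are stringified community indices."""
    membership = leiden_partition(graph, resolution, seed)
    names = graph.vs["name"] if "name" in graph.vs.attributes() else list(range(graph.vcount()))
    return ClusterAssignment(
        labels=pd.Series([str(m) for m in membership], index=names),
        resolution=resolution,
        seed=seed,
    )


def cluster_cells(
    res: ResidualMatrix,
    n_hvg: int = 3000,
    n_pcs: int = 50,
    k: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Full hvg -> PCA -> kNN -> Leiden pass on a residual matrix."""
    hvg = select_hvg(res, n_hvg)
    n_pcs_eff = min(n_pcs, len(hvg), res.n_cells)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_pcs_eff} for a small subset")
    scores = pca_embed(res, hvg, n_pcs_eff, seed)
    graph = knn_graph(scores, k=min(k, res.n_cells - 1))
    return leiden_cluster(graph, resolution, seed)


def subcluster(
    res: ResidualMatrix,
    assignment: ClusterAssignment,
    parent_label: str,
    resolution: float,
    seed: int = 0,
    n_hvg: int = 3000,
    n_pcs: int = 50,
    k: int = 15,
) -> ClusterAssignment:
    """Re-cluster the cells of ``parent_label`` at the given resolution.

    Child labels are namespaced ``parent.k``. Subsets smaller than the PC
    floor fall back to a reduced number of PCs with a warning.
    """
    if parent_label not in set(assignment.labels):
        raise ParameterError(f"unknown parent cluster {parent_label!r}")
    cells = assignment.cells_of(parent_label)
    sub = res.subset_cells(cells)
    child = cluster_cells(sub, n_hvg=n_hvg, n_pcs=n_pcs, k=k, resolution=resolution, seed=seed)
    return ClusterAssignment(
        labels=child.labels.map(lambda m: f"{parent_label}.{m}"),
        resolution=resolution,
        seed=seed,
        parent_cluster=parent_label,
    )
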