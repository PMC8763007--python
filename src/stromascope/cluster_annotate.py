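"""PCA, elbow-based dimensionality choice, graph clustering, marker annotation.

Dimension reduction is centered PCA on the scaled HVG matrix.  The number of
informative components is picked from the explained-variance elbow.  Cells
are clustered on a k-nearest-neighbor graph with modularity-based (Leiden)
community detection — the de-facto single-cell standard — and clusters are
annotated to major cell types by z-scored marker-set mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("stromascope")


@dataclass
class Embedding:
    """Cells × d PCA coordinates with per-component explained variance."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    cell_ids: list


@dataclass
class ClusterLabels:
    """Per-cell integer cluster ids, optionally annotated to major types."""

    cell_ids: list
    cluster: np.ndarray                      # int per cell
    cluster_types: dict | None = None        # cluster id → (type name, score)

    def cell_types(self) -> pd.Series:
        if self.cluster_types is None:
            raise ValueError("clusters are not annotated yet")
        return pd.Series(
            [self.cluster_types[c][0] for c in self.cluster],
            index=pd.Index(self.cell_ids, name="cell_id"), name="major_type")


def run_pca(scaled: ExpressionMatrix, max_components: int = 50) -> Embedding:
    """Centered PCA of cells over the (scaled) gene axis, via full SVD.

    Sign convention: each component is flipped so its largest-magnitude gene
    loading is positive, making the output deterministic.
    """
    x = scaled.values.T  # cells × genes
    k = min(max_components, min(x.shape))
    if max_components > min(x.shape):
        raise ValueError(
            f"max_components={max_components} exceeds min(n_cells, n_genes)={min(x.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    load = pca.components_  # k × genes
    flip = np.sign(load[np.arange(k), np.argmax(np.abs(load), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return Embedding(coords=coords,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     cell_ids=list(scaled.cell_ids))


def choose_dims_elbow(explained_variance_ratio, drop_tol: float = 0.001,
                      d_min: int = 10, d_max: int = 50) -> int:
    """Smallest d where the drop between consecutive variance ratios < drop_tol.

    Clamped to [d_min, d_max]; d_max when the spectrum never flattens.
    """
    evr = np.asarray(explained_variance_ratio, dtype=float)
    if len(evr) < d_min:
        raise ValueError(f"only {len(evr)} components for d_min={d_min}")
    if np.any(np.diff(evr) > 1e-12):
        raise ValueError("explained_variance_ratio must be non-increasing")
    d = d_max
    for j in range(1, len(evr)):
        if evr[j - 1] - evr[j] < drop_tol:
            d = j
            break
    return int(min(max(d, d_min), d_max))


def cluster_graph(embedding: Embedding, n_neighbors: int = 20,
                  resolution: float = 0.8, seed: int = 0) -> ClusterLabels:
    """kNN graph (Euclidean) + Leiden modularity communities.

    Deterministic under ``seed``.  Duplicated points share a neighborhood and
    therefore a community.
    """
    x = embedding.coords
    n = x.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in idx[i, 1:] if i != j}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1)
    labels = np.asarray(part.membership, dtype=int)
    logger.info("cluster_graph: %d cells → %d clusters", n, labels.max() + 1)
    return ClusterLabels(cell_ids=list(embedding.cell_ids), cluster=labels)


def annotate_clusters(expr: ExpressionMatrix, labels: ClusterLabels,
                      marker_sets: GeneSetCollection) -> ClusterLabels:
    """Assign each cluster the marker set with the highest z-scored set mean.

    For each cluster and marker set: mean expression of the set's genes over
    the cluster's cells, then z-scored across clusters per set (so high-
    expression sets cannot dominate).  Ties break to the lexicographically
    first type name, with a warning.  Marker sets with no genes in the
    universe are skipped with a warning.
    """
    if list(expr.cell_ids) != list(labels.cell_ids):
        raise ValueError("expression matrix and labels cover different cells")
    if expr.transform_tag not in ("lognorm10k", "log2tpm10"):
        raise ValueError("annotate_clusters expects normalized (not scaled) expression")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    clusters = np.unique(labels.cluster)
    set_names = []
    set_means = []  # per set: vector over clusters
    for name, genes in marker_sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            logger.warning("annotate_clusters: marker set %r absent from the "
                           "gene universe; skipped", name)
            continue
        per_cell = expr.values[idx, :].mean(axis=0)
        vec = np.array([per_cell[labels.cluster == c].mean() for c in clusters])
        set_names.append(name)
        set_means.append(vec)
    if not set_names:
        raise ValueError("no marker set intersects the gene universe")
    m = np.vstack(set_means)  # sets × clusters
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (m - mu) / sd

    name_order = sorted(range(len(set_names)), key=lambda s: set_names[s])
    cluster_types = {}
    for ci, c in enumerate(clusters):
        col = z[:, ci]
        # max() keeps the first maximal element, i.e. the lexicographically
        # first type name on an exact tie
        best = max(name_order, key=lambda s: col[s])
        if int(np.sum(col == col[best])) > 1:
            tied = sorted(set_names[s] for s in np.flatnonzero(col == col[best]))
            logger.warning("annotate_clusters: cluster %d tie among %s → %r",
                           c, tied, set_names[best])
        cluster_types[int(c)] = (set_names[best], float(col[best]))
    return ClusterLabels(cell_ids=labels.cell_ids, cluster=labels.cluster,
                         cluster_types=cluster_types)
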