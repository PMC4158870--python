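"""Patient stratification: cosine dissimilarity, average-linkage clustering
with a dendrogram cutoff, size filtering, and the patient similarity network.

Patients (rows of a tf-idf ProfileMatrix) are compared by cosine
dissimilarity, 1 - cos(theta) = 1 - a.b / (||a|| ||b||), which is 0 for
parallel profiles and 1 for orthogonal ones and is independent of vector
length, so patients with different record sizes remain comparable.

Clustering is unweighted average linkage (UPGMA): the distance between two
clusters is the arithmetic mean of all inter-cluster pairwise distances.
The dendrogram is cut so that exactly the merges at height strictly below
the cutoff are applied; documents never merged remain singletons. Cluster
ids are assigned by descending size starting at 1 (ties broken by the
smallest contained document id), so after filtering at a minimum size the
surviving clusters are ids 1..k.

A secondary clustering of the cluster-level characteristic vectors uses
Euclidean distance and yields the dendrogram leaf order used to arrange
heat-map columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "ClusterAssignment",
    "ClusterDendrogram",
    "cosine_dissimilarity_matrix",
    "hierarchical_cluster",
    "filter_clusters",
    "build_patient_network",
    "cluster_clusters",
]


@dataclass
class DissimilarityMatrix:
    document_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.document_ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square over document_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")


@dataclass
class ClusterAssignment:
    """Document -> cluster id map with metadata.

    Cluster ids are positive integers numbered by descending cluster size.
    """

    labels: dict[str, int]
    cutoff: float
    linkage: str = "average"
    cluster_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cluster_sizes:
            sizes: dict[int, int] = {}
            for c in self.labels.values():
                sizes[c] = sizes.get(c, 0) + 1
            self.cluster_sizes = dict(sorted(sizes.items()))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def members(self, cluster_id: int) -> list[str]:
        return sorted(d for d, c in self.labels.items() if c == cluster_id)


def cosine_dissimilarity_matrix(profiles: ProfileMatrix) -> DissimilarityMatrix:
    """Pairwise 1 - cos(theta) between profile rows.

    Rows with zero norm have no direction and are rejected with the
    offending document named.
    """
    norms = np.linalg.norm(profiles.values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(
            f"zero-norm profile rows cannot be compared: "
            f"{[profiles.document_ids[i] for i in zero[:5]]}"
        )
    if len(profiles.document_ids) == 1:
        values = np.zeros((1, 1))
    else:
        values = squareform(pdist(profiles.values, metric="cosine"))
        # non-negative vectors give distances in [0, 1]; clip float noise
        values = np.clip(values, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(document_ids=list(profiles.document_ids), values=values)


def _number_clusters(groups: list[list[str]]) -> dict[str, int]:
    """Assign ids 1..k by descending size, ties by smallest member id."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    labels: dict[str, int] = {}
    for cid, group in enumerate(ordered, start=1):
        for doc in group:
            labels[doc] = cid
    return labels


def hierarchical_cluster(
    dist: DissimilarityMatrix, cutoff: float
) -> ClusterAssignment:
    """UPGMA clustering cut strictly below ``cutoff``.

    Merges whose linkage height is < cutoff are applied; everything else is
    left apart, so unmerged documents form singleton clusters.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids = dist.document_ids
    n = len(ids)
    if n < 2:
        logger.info("fewer than 2 documents: single trivial cluster")
        return ClusterAssignment(labels={d: 1 for d in ids}, cutoff=cutoff)

    z = hierarchy.linkage(squareform(dist.values, checks=False), method="average")
    clusters: dict[int, list[str]] = {i: [ids[i]] for i in range(n)}
    for t, (a, b, height, _) in enumerate(z):
        a, b = int(a), int(b)
        # UPGMA heights are monotone, so applied merges form a prefix
        if height < cutoff and a in clusters and b in clusters:
            clusters[n + t] = clusters.pop(a) + clusters.pop(b)
    labels = _number_clusters(list(clusters.values()))
    return ClusterAssignment(labels=labels, cutoff=cutoff)


def filter_clusters(
    assignment: ClusterAssignment, min_size: int = 10
) -> ClusterAssignment:
    """Keep only clusters with at least ``min_size`` members.

    Ids are preserved; because ids are size-ordered, the retained set is a
    prefix 1..k. The number of retained patients is logged.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep = {c for c, s in assignment.cluster_sizes.items() if s >= min_size}
    labels = {d: c for d, c in assignment.labels.items() if c in keep}
    logger.info(
        "retained %d clusters of size >= %d accounting for %d documents",
        len(keep), min_size, len(labels),
    )
    return ClusterAssignment(
        labels=labels, cutoff=assignment.cutoff, linkage=assignment.linkage
    )


def build_patient_network(
    dist: DissimilarityMatrix,
    assignment: ClusterAssignment,
    threshold: float = 0.6,
) -> nx.Graph:
    """Patient similarity network over the documents in ``assignment``.

    Nodes carry their cluster id; an undirected edge links two patients iff
    their cosine dissimilarity is strictly below ``threshold``.
    """
    g = nx.Graph(threshold=threshold)
    index = {d: i for i, d in enumerate(dist.document_ids)}
    docs = [d for d in dist.document_ids if d in assignment.labels]
    for d in docs:
        g.add_node(d, cluster=int(assignment.labels[d]))
    if len(docs) >= 2:
        idx = np.array([index[d] for d in docs])
        sub = dist.values[np.ix_(idx, idx)]
        ii, jj = np.nonzero(np.triu(sub < threshold, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(docs[i], docs[j], dissimilarity=float(sub[i, j]))
    return g


@dataclass
class ClusterDendrogram:
    """Average-linkage dendrogram over cluster-level vectors.

    Holds the scipy linkage matrix, the heat-map leaf order, and a ``cut``
    method returning a ClusterAssignment at any height.
    """

    document_ids: list[str]
    linkage_matrix: np.ndarray
    metric: str = "euclidean"

    @property
    def leaf_order(self) -> list[str]:
        if len(self.document_ids) == 1:
            return list(self.document_ids)
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.document_ids[i] for i in order]

    def cut(self, cutoff: float) -> ClusterAssignment:
        n = len(self.document_ids)
        clusters: dict[int, list[str]] = {i: [self.document_ids[i]] for i in range(n)}
        for t, (a, b, height, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            if height < cutoff and a in clusters and b in clusters:
                clusters[n + t] = clusters.pop(a) + clusters.pop(b)
        labels = _number_clusters(list(clusters.values()))
        return ClusterAssignment(labels=labels, cutoff=cutoff)


def cluster_clusters(cluster_profiles: ProfileMatrix) -> ClusterDendrogram:
    """Cluster the clusters by Euclidean distance between their vectors.

    Input rows are typically characteristic-fraction vectors of the retained
    patient clusters; the resulting leaf order arranges heat-map columns so
    clusters with similar drug or diagnosis composition sit side by side.
    """
    if len(cluster_profiles.document_ids) < 2:
        raise ValueError("need at least 2 cluster documents to cluster clusters")
    z = hierarchy.linkage(
        pdist(cluster_profiles.values, metric="euclidean"), method="average"
    )
    return ClusterDendrogram(
        document_ids=list(cluster_profiles.document_ids), linkage_matrix=z
    )
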