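"""Seventeen-dimensional structural graph descriptor per region.

A region is summarized by a planar graph: its pixels are clustered into
``p`` color classes (k-means on LUV), every sufficiently large connected
blob of a class yields one node at the blob centroid (tagged with the class
id), and edges come from a Delaunay triangulation of the node coordinates,
weighted by Euclidean distance in pixels.  The descriptor then holds

* one average node degree per cluster (``p`` values),
* one cross-cluster average clustering coefficient per ordered cluster pair
  (``p*(p-1)`` values) — for a node of cluster ``a``, the ACC restricted to
  its neighbors of cluster ``b`` measures how densely that type of
  neighborhood is interconnected,
* the weighted diameter of the (largest component of the) graph,

for ``p + p(p-1) + 1`` features: 17 with the default ``p = 4``.

Near-black clusters are treated as padding and discarded before node
extraction, so black fill pixels never produce nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.color import rgb2luv
from sklearn.cluster import KMeans

from .segmentation import SegmentationMask

logger = logging.getLogger(__name__)

_CONN8 = np.ones((3, 3), dtype=bool)
_BLACK_L = 2.0  # clusters with mean L below this are padding


@dataclass
class RegionGraph:
    """Delaunay graph over cluster-blob centroids of one region."""

    graph: nx.Graph  # nodes carry 'pos' (x, y) and 'cluster' in 1..p
    p: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def find_centroids(
    image: np.ndarray,
    mask: SegmentationMask,
    region_id: int,
    p: int = 4,
    min_blob: int = 20,
    seed: int = 0,
) -> list[tuple[tuple[float, float], int]]:
    """Cluster-blob centroids of one region.

    Region pixels are k-means clustered into ``p`` LUV color classes
    (10 restarts, fixed seed); each 8-connected blob of a class with at
    least ``min_blob`` pixels contributes one node ``((x, y), cluster_id)``
    with 1-based cluster ids.  Near-black classes are dropped as padding.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    inside = mask.labels == region_id
    if not inside.any():
        raise ValueError(f"region {region_id} is empty")
    luv = rgb2luv(np.asarray(image))
    # padding pixels are black by convention; drop them before clustering
    inside = inside & (luv[..., 0] >= _BLACK_L)
    if not inside.any():
        return []
    pix = luv[inside]
    n_clusters = min(p, len(np.unique(pix.round(3), axis=0)))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(pix)

    ys, xs = np.nonzero(inside)
    nodes: list[tuple[tuple[float, float], int]] = []
    for c in range(n_clusters):
        if km.cluster_centers_[c, 0] < _BLACK_L:
            continue  # residual black cluster
        class_mask = np.zeros(inside.shape, dtype=bool)
        class_mask[ys[assign == c], xs[assign == c]] = True
        blobs, n_blobs = ndimage.label(class_mask, structure=_CONN8)
        for b in range(1, n_blobs + 1):
            by, bx = np.nonzero(blobs == b)
            if len(by) < min_blob:
                continue
            nodes.append(((float(bx.mean()), float(by.mean())), c + 1))
    return nodes


def delaunay_graph(nodes: list[tuple[tuple[float, float], int]], p: int = 4) -> RegionGraph:
    """Delaunay triangulation of node coordinates with Euclidean weights.

    Degenerate node sets (collinear, or fewer than 3 nodes) fall back to a
    path graph in coordinate order, logged as a warning.
    """
    g = nx.Graph()
    for i, (pos, cluster) in enumerate(nodes):
        g.add_node(i, pos=pos, cluster=cluster)
    pts = np.array([pos for pos, _ in nodes], dtype=float)

    def _path_fallback() -> None:
        logger.warning("degenerate node set (%d nodes); using path-graph fallback", len(pts))
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        for a, b in zip(order[:-1], order[1:]):
            g.add_edge(int(a), int(b), weight=float(np.linalg.norm(pts[a] - pts[b])))

    if len(pts) < 3:
        if len(pts) == 2:
            _path_fallback()
        return RegionGraph(g, p)
    try:
        tri = Delaunay(pts)
    except QhullError:
        _path_fallback()
        return RegionGraph(g, p)
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = int(simplex[a]), int(simplex[b])
            g.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
    return RegionGraph(g, p)


def acc(d_i: int, C_i: int) -> float:
    """Clustering coefficient of a node: ``2*C_i / (d_i*(d_i - 1))``.

    ``d_i`` is the node degree and ``C_i`` the number of edges among its
    neighbors; nodes with fewer than two neighbors get ACC 0.
    """
    if d_i < 0 or C_i < 0:
        raise ValueError("d_i and C_i must be non-negative")
    if d_i < 2:
        return 0.0
    if C_i > d_i * (d_i - 1) // 2:
        raise ValueError(
            f"C_i={C_i} exceeds the maximum {d_i * (d_i - 1) // 2} for d_i={d_i}"
        )
    return 2.0 * C_i / (d_i * (d_i - 1))


def _cross_cluster_acc(g: nx.Graph, node: int, cluster_b: int) -> float:
    """ACC of ``node`` restricted to its neighbors of cluster ``cluster_b``."""
    nbrs = [m for m in g.neighbors(node) if g.nodes[m]["cluster"] == cluster_b]
    d = len(nbrs)
    if d < 2:
        return 0.0
    C = sum(1 for i, a in enumerate(nbrs) for b in nbrs[i + 1:] if g.has_edge(a, b))
    return acc(d, C)


def graph_feature_vector(region_graph: RegionGraph) -> np.ndarray:
    """Length ``p + p(p-1) + 1`` descriptor (17 for p = 4).

    Layout: per-cluster average degrees (cluster 1..p), then cross-cluster
    ACC means for ordered pairs (1,2), (1,3), ..., (p,p-1), then the
    weighted diameter of the largest connected component.  Degenerate graphs
    (under 3 nodes) yield zeros with a warning.
    """
    p = region_graph.p
    g = region_graph.graph
    n_feat = p + p * (p - 1) + 1
    if g.number_of_nodes() < 3:
        logger.warning("degenerate region graph (<3 nodes); features set to 0")
        return np.zeros(n_feat)

    by_cluster = {c: [] for c in range(1, p + 1)}
    for n, data in g.nodes(data=True):
        by_cluster.setdefault(data["cluster"], []).append(n)

    avg_degree = np.zeros(p)
    for c in range(1, p + 1):
        members = by_cluster.get(c, [])
        if members:
            avg_degree[c - 1] = np.mean([g.degree(n) for n in members])

    accs = []
    for a in range(1, p + 1):
        for b in range(1, p + 1):
            if a == b:
                continue
            members = by_cluster.get(a, [])
            if members:
                accs.append(np.mean([_cross_cluster_acc(g, n, b) for n in members]))
            else:
                accs.append(0.0)

    if g.number_of_edges() == 0:
        diameter = 0.0
    else:
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        diameter = 0.0
        for _, dists in nx.all_pairs_dijkstra_path_length(sub, weight="weight"):
            diameter = max(diameter, max(dists.values()))
    return np.concatenate([avg_degree, accs, [diameter]])


def region_graph_features(
    image: np.ndarray,
    mask: SegmentationMask,
    region_id: int,
    p: int = 4,
    min_blob: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Convenience: centroids -> Delaunay -> feature vector for one region."""
    nodes = find_centroids(image, mask, region_id, p=p, min_blob=min_blob, seed=seed)
    return graph_feature_vector(delaunay_graph(nodes, p=p))
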