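"""Curve-skeleton extraction from root point clouds by Laplacian contraction.

Scattered points carry no connectivity, so length-dependent traits need a
skeleton: the cloud is iteratively contracted onto its medial curves by
solving, in least squares, the over-determined system

    [ w_L · L ]        [   0    ]
    [   W_H   ] P' =   [ W_H · P ]

where L is the graph Laplacian of the k-nearest-neighbor graph with
inverse-distance edge weights, w_L is a global contraction weight amplified
each iteration, and W_H is a per-point attraction weight grown as the point's
local neighborhood collapses (ratio of original to current neighborhood
extent). The contracted cloud is then resampled into a graph of nodes and
edges by farthest-point sampling and neighbor-graph connectivity, short
terminal twigs are pruned, and the total root length is the sum of edge
lengths.

All numeric defaults (k=12, amplification 3, ≤10 iterations, …) are choices
of this package, exposed through ContractionParams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .cloudio import ColorPointCloud

__all__ = [
    "ContractionParams",
    "Skeleton",
    "contract_point_cloud",
    "build_skeleton_graph",
    "total_root_length",
    "skeletonize",
]


@dataclass
class ContractionParams:
    """Tuning knobs for contraction and skeleton assembly (lengths in inches).

    ``w_l_scale`` sets the initial contraction weight as
    1 / (w_l_scale · mean k-NN distance); ``s_l`` multiplies it each
    iteration. ``h_scale`` sets the skeleton node spacing as
    h = h_scale · mean k-NN distance, and terminal branches shorter than
    ``prune_scale`` · h are pruned.
    """

    k_neighbors: int = 12
    w_l_scale: float = 10.0
    s_l: float = 3.0
    max_iters: int = 10
    convergence_ratio: float = 0.01
    h_scale: float = 4.0
    prune_scale: float = 2.0
    h: float | None = None  # explicit node spacing overrides h_scale
    prune_length: float | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 2 or self.max_iters < 1:
            raise ValueError("k_neighbors ≥ 2 and max_iters ≥ 1 required")
        if self.s_l <= 1:
            raise ValueError("s_l must exceed 1 (weights must amplify)")
        if not 0 < self.convergence_ratio < 1:
            raise ValueError("convergence_ratio must lie in (0, 1)")


@dataclass
class Skeleton:
    """Spatially embedded graph abstracting the root network."""

    nodes: np.ndarray  # M×3, in
    edges: np.ndarray  # E×2 node indices
    node_source_sets: list[np.ndarray]  # original-point indices per node

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.edges = np.asarray(self.edges, int).reshape(-1, 2)
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("skeleton contains self-loop edges")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_lengths(self) -> np.ndarray:
        if len(self.edges) == 0:
            return np.empty(0)
        return np.linalg.norm(
            self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]], axis=1
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, p in enumerate(self.nodes):
            g.add_node(i, pos=tuple(p))
        for (a, b), w in zip(self.edges, self.edge_lengths()):
            g.add_edge(int(a), int(b), length=float(w))
        return g


def _coords(cloud) -> np.ndarray:
    if isinstance(cloud, ColorPointCloud):
        return cloud.coords
    return np.asarray(cloud, float)


def _knn_graph(pts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric k-NN adjacency: (pairs E×2, mean neighbor distance)."""
    tree = cKDTree(pts)
    d, idx = tree.query(pts, k=k + 1)
    rows = np.repeat(np.arange(len(pts)), k)
    cols = idx[:, 1:].ravel()
    pairs = np.stack([np.minimum(rows, cols), np.maximum(rows, cols)], axis=1)
    pairs = np.unique(pairs, axis=0)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    return pairs, float(d[:, 1:].mean())


def _local_extent(pts: np.ndarray, pairs: np.ndarray, n: int) -> np.ndarray:
    """Mean incident-edge length per point on the fixed neighbor topology."""
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    s = np.zeros(n)
    c = np.zeros(n)
    np.add.at(s, pairs[:, 0], d)
    np.add.at(s, pairs[:, 1], d)
    np.add.at(c, pairs[:, 0], 1)
    np.add.at(c, pairs[:, 1], 1)
    return s / np.maximum(c, 1)


def _laplacian(pts: np.ndarray, pairs: np.ndarray, n: int) -> sparse.csr_matrix:
    """Graph Laplacian D − W with inverse-distance weights, clamped below."""
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    w = 1.0 / np.maximum(d, 1e-4 * max(d.mean(), 1e-12))
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    W = sparse.coo_matrix((np.concatenate([w, w]), (i, j)), shape=(n, n)).tocsr()
    D = sparse.diags(np.asarray(W.sum(axis=1)).ravel())
    return (D - W).tocsr()


def _contract_component(
    pts: np.ndarray, pairs: np.ndarray, params: ContractionParams
) -> tuple[np.ndarray, list[float]]:
    n = len(pts)
    extent0 = _local_extent(pts, pairs, n)
    total0 = extent0.sum()
    mean_knn = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1).mean()
    w_l = 1.0 / (params.w_l_scale * max(mean_knn, 1e-12))
    w_h = np.ones(n)
    cur = pts.copy()
    history = [float(total0)]
    for _ in range(params.max_iters):
        L = _laplacian(cur, pairs, n)
        WH2 = sparse.diags(w_h**2)
        A = (w_l**2) * (L.T @ L) + WH2
        B = WH2 @ cur
        try:
            new = np.column_stack([spsolve(A.tocsc(), B[:, ax]) for ax in range(3)])
        except Exception as e:  # singular solve
            raise ValueError(
                f"contraction solve failed ({e}); try a larger k_neighbors"
            ) from e
        extent = _local_extent(new, pairs, n)
        total = extent.sum()
        if not np.isfinite(total) or total >= history[-1]:
            break  # plateau: further amplification will not shrink
        cur = new
        history.append(float(total))
        if total < params.convergence_ratio * total0:
            break
        w_l *= params.s_l
        w_h = extent0 / np.maximum(extent, 1e-12)
    return cur, history


def contract_point_cloud(
    cloud, params: ContractionParams | None = None, full_output: bool = False
):
    """Contract a point cloud onto its medial curves.

    Returns one contracted coordinate per input point (N×3). Disconnected
    components of the neighbor graph are contracted independently. With
    ``full_output=True`` also returns a dict with the per-component
    total-local-extent history (strictly decreasing) and the neighbor pairs.
    """
    params = params or ContractionParams()
    pts = _coords(cloud)
    n = len(pts)
    if n <= params.k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={params.k_neighbors} points, got {n}"
        )
    pairs, mean_knn = _knn_graph(pts, params.k_neighbors)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(adj, directed=False)
    out = np.empty_like(pts)
    histories = []
    for c in range(n_comp):
        mask = comp == c
        idx = np.flatnonzero(mask)
        if len(idx) < 4:
            out[idx] = pts[idx]  # tiny fragments cannot be contracted
            continue
        remap = -np.ones(n, int)
        remap[idx] = np.arange(len(idx))
        sub_pairs = pairs[mask[pairs[:, 0]]]
        sub_pairs = np.stack([remap[sub_pairs[:, 0]], remap[sub_pairs[:, 1]]], axis=1)
        contracted, hist = _contract_component(pts[idx], sub_pairs, params)
        out[idx] = contracted
        histories.append(hist)
    if full_output:
        return out, {
            "extent_history": histories, "pairs": pairs,
            "components": comp, "mean_knn_distance": mean_knn,
        }
    return out


def _farthest_point_sample(pts: np.ndarray, h: float) -> np.ndarray:
    """Greedy FPS seeded at the lowest index; stops when coverage radius < h."""
    n = len(pts)
    chosen = [0]
    mind = np.linalg.norm(pts - pts[0], axis=1)
    while True:
        nxt = int(np.argmax(mind))
        if mind[nxt] < h:
            break
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.array(chosen, int)


def build_skeleton_graph(
    contracted: np.ndarray,
    original_cloud,
    h: float,
    pairs: np.ndarray | None = None,
    k_neighbors: int = 12,
    spanning_tree: bool = True,
) -> Skeleton:
    """Resample contracted points into a skeleton graph.

    Nodes come from farthest-point sampling of the contracted coordinates at
    radius ``h`` (deterministic: seeded from the lowest-index point); every
    contracted point joins its nearest node's source set; two nodes are
    connected iff their source sets contain points that are neighbors in the
    original k-NN graph; multi-edges collapse; each node is recentered to the
    centroid of its source points in the original cloud.

    With ``spanning_tree`` (the default) each connected component is reduced
    to its Euclidean minimum spanning tree. Neighbor-set adjacency also links
    nodes that are two steps apart along a branch; such a shortcut closes a
    triangle in which it is the longest edge, so the MST cycle property
    removes exactly these redundant edges (root systems are trees — genuine
    cycles are not expected), leaving centerline paths whose summed length is
    the root length.
    """
    contracted = np.asarray(contracted, float)
    orig = _coords(original_cloud)
    if pairs is None:
        pairs, _ = _knn_graph(orig, k_neighbors)
    if h <= 0:
        raise ValueError("node spacing h must be positive")
    samples = _farthest_point_sample(contracted, h)
    tree = cKDTree(contracted[samples])
    _, owner = tree.query(contracted)
    node_edges = np.stack([owner[pairs[:, 0]], owner[pairs[:, 1]]], axis=1)
    node_edges = node_edges[node_edges[:, 0] != node_edges[:, 1]]
    if len(node_edges):
        node_edges = np.unique(np.sort(node_edges, axis=1), axis=0)
    sources = [np.flatnonzero(owner == i) for i in range(len(samples))]
    nodes = np.array([orig[s].mean(axis=0) for s in sources])
    if spanning_tree and len(node_edges):
        g = nx.Graph()
        g.add_nodes_from(range(len(nodes)))
        for a, b in node_edges:
            g.add_edge(int(a), int(b),
                       length=float(np.linalg.norm(nodes[a] - nodes[b])))
        mst = nx.minimum_spanning_tree(g, weight="length")
        node_edges = np.array(sorted(tuple(sorted(e)) for e in mst.edges), int)
    return Skeleton(nodes=nodes, edges=node_edges, node_source_sets=sources)


def _tip_extension(skeleton: Skeleton, original: np.ndarray, g: nx.Graph) -> float:
    """Extra length from each leaf node out to the tip of its source set.

    A leaf node sits at the centroid of its cell, but the root continues to
    the cell's far end; project the leaf's original source points onto the
    outward direction of its incident edge and add the farthest reach.
    """
    extra = 0.0
    for leaf in (v for v in g.nodes if g.degree(v) == 1):
        nbr = next(iter(g.neighbors(leaf)))
        d = skeleton.nodes[leaf] - skeleton.nodes[nbr]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        src = original[skeleton.node_source_sets[leaf]]
        if len(src):
            reach = ((src - skeleton.nodes[leaf]) @ d).max()
            extra += max(reach, 0.0)
    return extra


def total_root_length(
    skeleton: Skeleton, prune_length: float = 0.0,
    original_cloud=None,
) -> float:
    """Total skeleton length (in) after pruning short terminal twigs.

    A terminal branch — the chain from a leaf up to the first junction — is
    removed when its cumulative length is below ``prune_length``; chains
    connecting two leaves (an unbranched skeleton) are never pruned. When the
    original cloud is supplied, each remaining leaf is extended to the
    farthest source point along its incident edge direction, compensating
    the half-cell truncation at root tips.
    """
    if skeleton.n_nodes <= 1 or len(skeleton.edges) == 0:
        if skeleton.n_nodes <= 1:
            warnings.warn("skeleton has no edges; total length is 0", stacklevel=2)
        return 0.0
    g = skeleton.to_networkx()
    changed = True
    while changed and prune_length > 0:
        changed = False
        for leaf in [v for v in g.nodes if g.degree(v) == 1]:
            if leaf not in g:
                continue
            chain = [leaf]
            length = 0.0
            cur, prev = leaf, None
            while g.degree(cur) <= 2:
                nbrs = [u for u in g.neighbors(cur) if u != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length"]
                if g.degree(nxt) != 2:
                    if g.degree(nxt) == 1:
                        chain = None  # leaf-to-leaf chain: the whole component
                    break
                prev, cur = cur, nxt
                chain.append(cur)
            if chain is not None and length < prune_length:
                g.remove_nodes_from(chain)
                changed = True
    total = float(sum(d["length"] for _, _, d in g.edges(data=True)))
    if original_cloud is not None and g.number_of_edges() > 0:
        total += _tip_extension(skeleton, _coords(original_cloud), g)
    return total


def skeletonize(
    cloud, params: ContractionParams | None = None
) -> tuple[Skeleton, float]:
    """Contract, build the skeleton graph, prune, and measure total length."""
    params = params or ContractionParams()
    contracted, info = contract_point_cloud(cloud, params, full_output=True)
    h = params.h if params.h is not None else params.h_scale * info["mean_knn_distance"]
    prune = (
        params.prune_length if params.prune_length is not None
        else params.prune_scale * h
    )
    skel = build_skeleton_graph(contracted, cloud, h, pairs=info["pairs"])
    return skel, total_root_length(skel, prune, original_cloud=cloud)
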