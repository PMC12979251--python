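"""Spatial niches from neighbor composition; adjacency and co-occurrence nets.

A niche is a group of cells that share the cell-type composition of their
immediate spatial neighborhood.  For each cell the types of its adjacent
neighbors (self excluded) are counted; the resulting cells x types
composition matrix is proportion-normalized, reduced by PCA and clustered by
modularity optimization (Leiden) on a k-NN graph.

Two network summaries of tissue organization are also provided: a directed
cluster adjacency network over crypt-top spots (edge weight = mean fraction
of a focal cluster's adjacent spots occupied by each cluster, self-loops
kept) and per-condition cell-type co-occurrence networks (Pearson
correlation of per-location type scores, keeping positive edges with
p < 0.01 and r >= 0.15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, cKDTree
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "neighbor_composition",
    "cluster_niches",
    "crypt_adjacency_network",
    "cooccurrence_network",
    "NicheMap",
]


# ---------------------------------------------------------------------------
# Neighbor composition
# ---------------------------------------------------------------------------


def _neighbor_lists(coords: np.ndarray, rule: str, k: int, radius: float,
                    mutual: bool):
    n = len(coords)
    if n == 1:
        return [set()]
    if rule == "knn":
        tree = cKDTree(coords)
        kk = min(k + 1, n)
        dist, idx = tree.query(coords, k=kk)
        nbrs = []
        for i in range(n):
            # self may appear at any position when points coincide
            s = {int(j) for d, j in zip(dist[i], idx[i])
                 if j != i and d <= radius}
            nbrs.append(s)
        if mutual:
            nbrs = [{j for j in s if i in nbrs[j]} for i, s in enumerate(nbrs)]
        return nbrs
    elif rule == "delaunay":
        if n < 3:
            d = np.linalg.norm(coords[0] - coords[-1])
            return [set([1]) if d <= radius else set(),
                    set([0]) if d <= radius else set()][:n]
        tri = Delaunay(coords)
        nbrs = [set() for _ in range(n)]
        for simplex in tri.simplices:
            for a in simplex:
                for b in simplex:
                    if a != b and np.linalg.norm(coords[a] - coords[b]) <= radius:
                        nbrs[a].add(int(b))
        return nbrs
    raise ValueError(f"unknown neighbor rule {rule!r}")


def neighbor_composition(coords, types, fov=None, rule: str = "knn",
                         k: int = 10, radius: float = 30.0,
                         mutual: bool = True) -> pd.DataFrame:
    """Count each cell's adjacent neighbors by cell type, excluding itself.

    Parameters
    ----------
    coords : (n, 2) array
    types : array of per-cell type labels
    fov : array, optional
        Field-of-view ids; neighbors are only sought within the same FOV.
    rule : {"knn", "delaunay"}
        "knn": (mutual) k-nearest neighbors with a radius cap — the default
        notion of "immediately adjacent" for segmented cells.  "delaunay":
        Delaunay triangulation edges with the same radius cap.
    radius : float
        Cap in the map's coordinate units (e.g. 30 um for segmented cells).
    """
    coords = np.asarray(coords, dtype=float)
    types = np.asarray(types)
    n = len(coords)
    fov = np.zeros(n, dtype=int) if fov is None else np.asarray(fov)
    type_levels = list(pd.unique(types))
    comp = np.zeros((n, len(type_levels)), dtype=int)
    t_idx = {t: j for j, t in enumerate(type_levels)}
    for f in pd.unique(fov):
        idx = np.where(fov == f)[0]
        nbrs = _neighbor_lists(coords[idx], rule, k, radius, mutual)
        for local_i, s in enumerate(nbrs):
            gi = idx[local_i]
            for local_j in s:
                comp[gi, t_idx[types[idx[local_j]]]] += 1
    return pd.DataFrame(comp, columns=type_levels)


# ---------------------------------------------------------------------------
# Niche clustering
# ---------------------------------------------------------------------------


@dataclass
class NicheMap:
    """Per-cell niche labels and per-niche mean composition profiles."""

    labels: np.ndarray
    profiles: pd.DataFrame  # niches x types, rows sum to 1

    @property
    def n_niches(self) -> int:
        return self.profiles.shape[0]


def cluster_niches(comp: pd.DataFrame, resolution: float = 0.7, seed: int = 0,
                   n_pcs: int = 10, n_neighbors: int = 50) -> NicheMap:
    """Cluster cells into niches by local cell-type composition.

    Rows are proportion-normalized (all-zero rows stay zero), reduced by
    PCA, embedded in a k-NN graph and partitioned by Leiden modularity
    optimization at the given resolution.
    """
    X = comp.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster niches")
    rs = X.sum(axis=1, keepdims=True)
    P = np.divide(X, rs, out=np.zeros_like(X), where=rs > 0)

    if np.allclose(P.var(axis=0), 0.0):
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        n_pcs = min(n_pcs, P.shape[1], P.shape[0] - 1)
        Z = PCA(n_components=n_pcs, random_state=seed).fit_transform(P)
        knn = kneighbors_graph(Z, n_neighbors=min(n_neighbors, len(Z) - 1),
                               mode="connectivity", include_self=False)
        sym = knn.maximum(knn.T).tocoo()
        g = igraph.Graph(
            n=len(Z), edges=list(zip(sym.row[sym.row < sym.col],
                                     sym.col[sym.row < sym.col])),
        )
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed,
        )
        labels = np.asarray(part.membership)

    profs = []
    for lab in range(labels.max() + 1):
        prof = P[labels == lab].mean(axis=0)
        tot = prof.sum()
        profs.append(prof / tot if tot > 0 else prof)
    profiles = pd.DataFrame(profs, columns=comp.columns)
    profiles.index.name = "niche"
    return NicheMap(labels=labels, profiles=profiles)


# ---------------------------------------------------------------------------
# Crypt-top cluster adjacency network
# ---------------------------------------------------------------------------


def crypt_adjacency_network(coords, clusters, crypt_scores=None,
                            crypt_axis_threshold: float = 1.0,
                            dist_window: tuple = (0.0, 4.0),
                            slides=None) -> tuple:
    """Directed cluster adjacency network over crypt-top locations.

    Subsets to locations with crypt-axis score above the threshold, finds
    each focal location's adjacent locations (``lo < dist < hi`` in the
    same units as the coordinates, per slide), computes its per-cluster
    neighbor fractions, and averages them over the focal locations of each
    source cluster.  Self-loops (same cluster adjacent to itself) are kept;
    locations with no in-window neighbors contribute nothing.

    Returns ``(networkx.DiGraph, edge DataFrame)`` with edge weights = mean
    adjacent fractions; outgoing weights from a node sum to 1 whenever all
    neighbors are labeled.
    """
    coords = np.asarray(coords, dtype=float)
    clusters = np.asarray(clusters)
    n = len(coords)
    slides = np.zeros(n, dtype=int) if slides is None else np.asarray(slides)
    if crypt_scores is not None:
        keep = np.asarray(crypt_scores, dtype=float) > crypt_axis_threshold
        if not keep.any():
            raise ValueError("no locations pass the crypt-axis threshold")
        coords, clusters, slides = coords[keep], clusters[keep], slides[keep]

    lo, hi = dist_window
    levels = list(pd.unique(clusters))
    li = {c: j for j, c in enumerate(levels)}
    frac_sum = np.zeros((len(levels), len(levels)))
    frac_n = np.zeros(len(levels), dtype=int)
    for s in pd.unique(slides):
        idx = np.where(slides == s)[0]
        tree = cKDTree(coords[idx])
        for local_i, gi in enumerate(idx):
            d, j = tree.query(coords[gi], k=len(idx))
            d, j = np.atleast_1d(d), np.atleast_1d(j)
            adj = idx[j[(d > lo) & (d < hi)]]
            if len(adj) == 0:
                continue
            counts = np.zeros(len(levels))
            for a in adj:
                counts[li[clusters[a]]] += 1
            frac_sum[li[clusters[gi]]] += counts / len(adj)
            frac_n[li[clusters[gi]]] += 1

    g = nx.DiGraph()
    rows = []
    for a, src in enumerate(levels):
        g.add_node(src)
        if frac_n[a] == 0:
            continue
        for b, dst in enumerate(levels):
            w = frac_sum[a, b] / frac_n[a]
            if w > 0:
                g.add_edge(src, dst, weight=float(w))
                rows.append({"source": src, "target": dst, "weight": float(w)})
    return g, pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# Cell-type co-occurrence networks
# ---------------------------------------------------------------------------


def cooccurrence_network(type_scores: pd.DataFrame, conditions=None,
                         r_min: float = 0.15, p_max: float = 0.01) -> dict:
    """Per-condition cell-type co-occurrence networks.

    Computes all pairwise Pearson correlations of per-location type scores
    within each condition, keeping positive edges with ``p < p_max`` and
    ``r >= r_min``; self-correlations are dropped and constant columns are
    excluded with a warning.  Returns condition -> networkx.Graph with
    correlation edge weights.
    """
    n = len(type_scores)
    conditions = (np.zeros(n, dtype=int) if conditions is None
                  else np.asarray(conditions))
    out = {}
    for cond in pd.unique(conditions):
        sub = type_scores.loc[np.asarray(conditions == cond)]
        if len(sub) < 3:
            raise ValueError(f"need at least 3 locations per condition "
                             f"(condition {cond!r} has {len(sub)})")
        cols = []
        for c in sub.columns:
            if np.isclose(sub[c].to_numpy(dtype=float).var(), 0.0):
                warnings.warn(
                    f"type score {c!r} is constant in condition {cond!r}; excluded"
                )
            else:
                cols.append(c)
        g = nx.Graph()
        g.add_nodes_from(cols)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r, p = stats.pearsonr(sub[cols[i]].to_numpy(dtype=float),
                                      sub[cols[j]].to_numpy(dtype=float))
                if r > 0 and r >= r_min and p < p_max:
                    g.add_edge(cols[i], cols[j], weight=float(r),
                               p_value=float(p))
        out[cond] = g
    return out
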