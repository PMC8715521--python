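"""LTP merging into final sLTPs via replacement-ratio graph partitioning.

The edge weight between two LTPs is the average replacement ratio: the
fraction of one pattern's ROIs that would be relabeled to the other (under
the labeling cost, restricted to patterns whose maximal intra-cluster
texture distance the ROI does not exceed) if the first pattern were removed,
symmetrized over both directions.  Edges below 0.5 are removed so patterns
that are not mutually replaceable stay separate.  The pruned graph is
partitioned by minimizing the two-level map equation (greedy node
aggregation with seeded restarts; isolated nodes stay singletons), and each
community's ROIs are pooled into one final sLTP whose centroids are their
feature means.  sLTPs are indexed 1..N in ascending mean ROI attenuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ltp import LtpModel, chi2_cdist, _mean_centroids

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# replacement ratios

def replacement_ratio(i: int, FT: np.ndarray, FS: np.ndarray,
                      model: LtpModel) -> np.ndarray:
    """Directed replacement ratios of LTP i into every other LTP.

    Removes centroid i and relabels each of its member ROIs to the admissible
    LTP (chi2 texture distance <= that LTP's max intra-cluster distance) with
    the smallest mixed chi2-l2 cost.  ROIs admissible nowhere stay unlabeled
    but remain in the denominator.  Returns a length-K vector with entry j =
    |relabeled to j| / |members of i| (entry i = 0).
    """
    members = np.flatnonzero(model.labels == i)
    k = model.k
    out = np.zeros(k)
    if members.size == 0:
        return out
    d_t = chi2_cdist(FT[members], model.ft_centroids)
    d_s = ((FS[members][:, None, :] - model.fs_centroids[None, :, :]) ** 2).sum(axis=2)
    cost = d_t + model.lam * model.w * d_s
    admissible = d_t <= model.max_intra[None, :]
    admissible[:, i] = False
    cost = np.where(admissible, cost, np.inf)
    target = np.argmin(cost, axis=1)
    ok = np.isfinite(cost[np.arange(members.size), target])
    counts = np.bincount(target[ok], minlength=k)
    return counts / members.size


def build_graph(model: LtpModel, FT: np.ndarray, FS: np.ndarray,
                threshold: float = 0.5) -> nx.Graph:
    """Symmetric replacement-ratio graph; edges strictly below threshold removed."""
    if model.k < 2:
        raise ValueError("need at least 2 LTPs to build a merge graph")
    ratios = np.stack([replacement_ratio(i, FT, FS, model) for i in range(model.k)])
    w = 0.5 * (ratios + ratios.T)
    g = nx.Graph()
    g.add_nodes_from(range(model.k))
    for i in range(model.k):
        for j in range(i + 1, model.k):
            if w[i, j] >= threshold:
                g.add_edge(i, j, weight=float(w[i, j]))
    return g


# ---------------------------------------------------------------------------
# two-level map equation

def _plogp(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def map_equation(graph: nx.Graph, partition: dict) -> float:
    """Two-level map-equation description length (bits) of a node partition.

    Node visit rates follow the stationary distribution of an undirected
    random walk (weighted-degree proportional); module exit rates are the
    normalized cut weights.  Edgeless graphs have zero description length.
    """
    total = graph.size(weight="weight")
    if total <= 0:
        return 0.0
    two_w = 2.0 * total
    nodes = list(graph.nodes)
    p = np.array([graph.degree(v, weight="weight") / two_w for v in nodes])
    modules = sorted(set(partition[v] for v in nodes))
    mod_idx = {m: i for i, m in enumerate(modules)}
    q = np.zeros(len(modules))
    p_mod = np.zeros(len(modules))
    for v, pv in zip(nodes, p):
        p_mod[mod_idx[partition[v]]] += pv
    for u, v, w in graph.edges(data="weight"):
        if partition[u] != partition[v]:
            q[mod_idx[partition[u]]] += w / two_w
            q[mod_idx[partition[v]]] += w / two_w
    q_tot = q.sum()
    term1 = _plogp(np.array([q_tot]))[0]
    term2 = -2.0 * _plogp(q).sum()
    term3 = _plogp(q + p_mod).sum()
    term4 = -_plogp(p).sum()
    return float(term1 + term2 + term3 + term4)


def _greedy_once(graph: nx.Graph, order: list) -> dict:
    """One Louvain-style pass hierarchy minimizing the map equation."""
    partition = {v: v for v in graph.nodes}
    improved = True
    current = map_equation(graph, partition)
    while improved:
        improved = False
        for v in order:
            best_mod, best_len = partition[v], current
            neighbor_mods = {partition[u] for u in graph.neighbors(v)}
            for m in sorted(neighbor_mods - {partition[v]}):
                trial = dict(partition)
                trial[v] = m
                length = map_equation(graph, trial)
                if length < best_len - 1e-12:
                    best_mod, best_len = m, length
            if best_mod != partition[v]:
                partition[v] = best_mod
                current = best_len
                improved = True
    return partition


def _quotient(graph: nx.Graph, partition: dict) -> tuple[nx.Graph, dict]:
    """Aggregate modules into super-nodes; returns (quotient graph, module->super)."""
    mods = sorted(set(partition.values()))
    sup = {m: i for i, m in enumerate(mods)}
    q = nx.Graph()
    q.add_nodes_from(range(len(mods)))
    for u, v, w in graph.edges(data="weight"):
        a, b = sup[partition[u]], sup[partition[v]]
        if a == b:
            continue
        if q.has_edge(a, b):
            q[a][b]["weight"] += w
        else:
            q.add_edge(a, b, weight=w)
    return q, sup


def _greedy_hierarchical(graph: nx.Graph, order: list,
                         rng: np.random.Generator) -> dict:
    """Local moves followed by module aggregation, repeated to convergence."""
    partition = _greedy_once(graph, order)
    current = map_equation(graph, partition)
    while True:
        q, sup = _quotient(graph, partition)
        q_order = list(rng.permutation(list(q.nodes)))
        q_part = _greedy_once(q, q_order)
        merged = {v: q_part[sup[partition[v]]] for v in graph.nodes}
        length = map_equation(graph, merged)
        if length < current - 1e-12:
            partition, current = merged, length
        else:
            return partition


def partition_graph(graph: nx.Graph, seed: int = 0, n_restarts: int = 10) -> dict:
    """Greedy two-level map-equation partition with seeded restarts.

    Returns ``{"communities": {node: community_id}, "codelength": bits}``.
    Community ids are re-numbered 0..m-1 in order of their smallest node.
    Isolated nodes always form singleton communities.
    """
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    best, best_len = None, np.inf
    for _ in range(max(1, n_restarts)):
        order = list(rng.permutation(nodes))
        part = _greedy_hierarchical(graph, order, rng)
        length = map_equation(graph, part)
        if length < best_len - 1e-12:
            best, best_len = part, length
    for v in nodes:  # isolated nodes stay singletons
        if graph.degree(v) == 0:
            best[v] = v
    remap = {}
    communities = {}
    for v in sorted(nodes):
        m = best[v]
        if m not in remap:
            remap[m] = len(remap)
        communities[v] = remap[m]
    return {"communities": communities, "codelength": float(map_equation(graph, communities))}


def _set_partitions(items: list):
    """All set partitions of a small item list (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def partition_graph_exhaustive(graph: nx.Graph, max_nodes: int = 12) -> dict:
    """Exhaustive minimum-description-length partition (oracle for small graphs)."""
    nodes = sorted(graph.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} nodes")
    best, best_len = None, np.inf
    for blocks in _set_partitions(nodes):
        part = {v: bi for bi, block in enumerate(blocks) for v in block}
        length = map_equation(graph, part)
        if length < best_len - 1e-12:
            best, best_len = part, length
    for v in nodes:
        if graph.degree(v) == 0:
            best[v] = max(best.values()) + 1 + v  # force singleton
    remap, communities = {}, {}
    for v in nodes:
        m = best[v]
        if m not in remap:
            remap[m] = len(remap)
        communities[v] = remap[m]
    return {"communities": communities, "codelength": float(map_equation(graph, communities))}


# ---------------------------------------------------------------------------
# final sLTPs

@dataclass
class SltpModel:
    """Final sLTP centroid pairs; class 0 is reserved for no-emphysema."""

    ft_centroids: np.ndarray      # (N, B_T), row k-1 = sLTP k
    fs_centroids: np.ndarray      # (N, B_S)
    member_ltps: list             # per sLTP, list of merged LTP ids
    labels: np.ndarray            # (n,) training-ROI sLTP ids in 1..N
    mean_hu: np.ndarray           # (N,) mean ROI attenuation per sLTP
    lam: float = 0.0
    w: float = 1.0

    @property
    def n_sltp(self) -> int:
        return self.ft_centroids.shape[0]


def finalize_sltps(communities: dict, model: LtpModel, FT: np.ndarray,
                   FS: np.ndarray, roi_mean_hu: np.ndarray) -> SltpModel:
    """Pool member-LTP ROIs per community into final sLTP centroids.

    sLTPs are indexed 1..N in ascending mean ROI attenuation (HU).
    """
    n_comm = len(set(communities.values()))
    groups = [[] for _ in range(n_comm)]
    for ltp_id, comm in communities.items():
        groups[comm].append(ltp_id)
    comm_labels = np.array([communities[l] for l in model.labels])
    ft_cent = _mean_centroids(FT, comm_labels, n_comm)
    fs_cent = _mean_centroids(FS, comm_labels, n_comm)
    hu = np.array([roi_mean_hu[comm_labels == c].mean() if (comm_labels == c).any()
                   else np.inf for c in range(n_comm)])
    order = np.argsort(hu, kind="stable")
    rank = np.empty(n_comm, dtype=int)
    rank[order] = np.arange(n_comm)
    return SltpModel(ft_centroids=ft_cent[order], fs_centroids=fs_cent[order],
                     member_ltps=[sorted(groups[c]) for c in order],
                     labels=rank[comm_labels] + 1, mean_hu=hu[order],
                     lam=model.lam, w=model.w)


def merge_ltps(model: LtpModel, FT: np.ndarray, FS: np.ndarray,
               roi_mean_hu: np.ndarray, threshold: float = 0.5,
               seed: int = 0) -> tuple[SltpModel, nx.Graph, dict]:
    """Full merge stage: graph, partition, finalized sLTPs."""
    graph = build_graph(model, FT, FS, threshold)
    part = partition_graph(graph, seed=seed)
    sltp = finalize_sltps(part["communities"], model, FT, FS, roi_mean_hu)
    logger.info("merged %d LTPs into %d sLTPs (codelength %.4f bits)",
                model.k, sltp.n_sltp, part["codelength"])
    return sltp, graph, part
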