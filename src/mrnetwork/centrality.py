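"""Twelve node-centrality algorithms and the rank-sum consensus ranking.

The hub-detection suite (the classical CytoHubba set): Maximal Clique
Centrality (MCC), Maximum Neighborhood Component (MNC), Density of Maximum
Neighborhood Component (DMNC), Degree, Edge Percolated Component (EPC),
BottleNeck, EcCentricity, Closeness (harmonic form, well-defined on
disconnected maps), Radiality, Betweenness, Stress and Clustering
Coefficient.  These algorithms are defined for undirected graphs, so the
directed causal maps are analysed on their undirected simple projection by
default (reciprocal edge pairs collapse to one edge).

Consensus: within each algorithm, nodes are ranked so the highest score gets
rank n and the lowest rank 1 (ties averaged); the per-node rank sum across
the twelve algorithms orders the key traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CentralityConfig",
    "CentralityReport",
    "ALGORITHMS",
    "compute_scores",
    "rank_sum",
    "report_to_tsv",
]

ALGORITHMS = (
    "MCC", "MNC", "DMNC", "Degree", "EPC", "BottleNeck",
    "EcCentricity", "Closeness", "Radiality", "Betweenness",
    "Stress", "ClusteringCoefficient",
)


@dataclass(frozen=True)
class CentralityConfig:
    """Algorithm constants (the originals' defaults) and the RNG seed for EPC."""

    dmnc_epsilon: float = 1.7
    epc_iterations: int = 1000
    epc_threshold: float = 0.5
    bottleneck_fraction: float = 0.25
    use_undirected_projection: bool = True
    invert_eccentricity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.epc_threshold < 1.0:
            raise ValueError("epc_threshold must lie in (0, 1)")
        if self.epc_iterations < 100:
            raise ValueError("epc_iterations must be >= 100")


@dataclass
class CentralityReport:
    """Scores, per-algorithm ranks, rank sums and the consensus order."""

    scores: pd.DataFrame
    ranks: pd.DataFrame
    rank_sums: pd.Series
    top_k: list = field(default_factory=list)


# --------------------------------------------------------------------------
# individual algorithms (on an undirected simple graph)
# --------------------------------------------------------------------------

def _mcc(g: nx.Graph) -> dict:
    """Sum over maximal cliques containing v of (|C|-1)!; degree when the
    neighborhood of v has no internal edge (which the clique sum reproduces
    for degree >= 1; isolated nodes score 0)."""
    scores = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        if len(clique) == 1:
            continue
        val = float(factorial(len(clique) - 1))
        for v in clique:
            scores[v] += val
    for v in g:
        nbrs = list(g.neighbors(v))
        if not any(g.has_edge(a, b) for i, a in enumerate(nbrs) for b in nbrs[i + 1:]):
            scores[v] = float(g.degree(v))
    return scores


def _neighborhood_component(g: nx.Graph, v) -> nx.Graph | None:
    """Largest connected component of the subgraph induced on N(v) (v excluded)."""
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return None
    sub = g.subgraph(nbrs)
    comps = list(nx.connected_components(sub))
    best = max(comps, key=lambda c: (len(c), sub.subgraph(c).number_of_edges()))
    return sub.subgraph(best)


def _mnc_dmnc(g: nx.Graph, epsilon: float) -> tuple[dict, dict]:
    mnc, dmnc = {}, {}
    for v in g:
        comp = _neighborhood_component(g, v)
        if comp is None:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        nv, ne = comp.number_of_nodes(), comp.number_of_edges()
        mnc[v] = float(nv)
        dmnc[v] = float(ne) / nv**epsilon if nv >= 2 else 0.0
    return mnc, dmnc


def _epc(g: nx.Graph, config: CentralityConfig) -> dict:
    """Mean size of v's component over K independent edge percolations.

    Each edge survives a percolation iff its uniform(0,1) draw is at least
    ``epc_threshold``; reproducible bit-for-bit under the seed.
    """
    nodes = sorted(g.nodes())
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    totals = {v: 0.0 for v in nodes}
    for _ in range(config.epc_iterations):
        draws = rng.uniform(0.0, 1.0, len(edges))
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(e for e, u in zip(edges, draws) if u >= config.epc_threshold)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                totals[v] += size
    k = float(config.epc_iterations)
    return {v: t / k for v, t in totals.items()}


def _bfs_tree_deterministic(g: nx.Graph, root) -> tuple[dict, dict]:
    """Shortest-path tree from root with lowest-id parent tie-break.

    Returns (parent, depth) over root's component.
    """
    depth = {root: 0}
    parent = {root: None}
    frontier = [root]
    d = 0
    while frontier:
        nxt = set()
        for u in frontier:
            for w in g.neighbors(u):
                if w not in depth:
                    nxt.add(w)
        for w in sorted(nxt):
            parent[w] = min(u for u in g.neighbors(w) if depth.get(u) == d)
            depth[w] = d + 1
        frontier = sorted(nxt)
        d += 1
    return parent, depth


def _bottleneck(g: nx.Graph, fraction: float) -> dict:
    """Count, over all BFS tree roots, how often v's subtree exceeds
    ``fraction`` of the tree."""
    scores = {v: 0.0 for v in g}
    for root in sorted(g.nodes()):
        parent, depth = _bfs_tree_deterministic(g, root)
        size = {v: 1 for v in parent}
        for v in sorted(parent, key=lambda x: -depth[x]):
            p = parent[v]
            if p is not None:
                size[p] += size[v]
        tree_n = len(parent)
        for v in parent:
            if size[v] > fraction * tree_n:
                scores[v] += 1.0
    return scores


def _radiality(g: nx.Graph) -> dict:
    scores = {v: 0.0 for v in g}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n = sub.number_of_nodes()
        if n < 2:
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(dd.values()) for dd in dist.values())
        for v in sub:
            scores[v] = sum(
                (diam + 1 - d) for w, d in dist[v].items() if w != v
            ) / (n - 1)
    return scores


def _stress_and_paths(g: nx.Graph) -> dict:
    """Stress centrality: number of shortest paths with v as interior node.

    Uses BFS path counts sigma from every source; for undirected graphs each
    unordered (s, t) pair is counted once.
    """
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    for s in nodes:
        si = index[s]
        D[si, si] = 0.0
        S[si, si] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                ui = index[u]
                for w in adj[u]:
                    wi = index[w]
                    if np.isinf(D[si, wi]):
                        D[si, wi] = d + 1
                        nxt.append(w)
                    if D[si, wi] == d + 1:
                        S[si, wi] += S[si, ui]
            frontier = nxt
            d += 1
    stress = {}
    for v in nodes:
        i = index[v]
        through = (D[:, i:i + 1] + D[i:i + 1, :]) == D
        contrib = np.outer(S[:, i], S[i, :]) * through
        contrib[i, :] = 0.0
        contrib[:, i] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = float(contrib.sum()) / 2.0
    return stress


def compute_scores(
    network: nx.Graph | nx.DiGraph, config: CentralityConfig = CentralityConfig()
) -> pd.DataFrame:
    """Node-by-algorithm score matrix for all twelve algorithms."""
    if network.number_of_nodes() == 0:
        raise ValueError("centrality requires a non-empty network")
    g: nx.Graph
    if config.use_undirected_projection and network.is_directed():
        g = nx.Graph(network.to_undirected(as_view=False))
    else:
        g = nx.Graph(network)
    g.remove_edges_from(nx.selfloop_edges(g))

    scores: dict[str, dict] = {}
    scores["MCC"] = _mcc(g)
    scores["MNC"], scores["DMNC"] = _mnc_dmnc(g, config.dmnc_epsilon)
    scores["Degree"] = {v: float(d) for v, d in g.degree()}
    scores["EPC"] = _epc(g, config)
    scores["BottleNeck"] = _bottleneck(g, config.bottleneck_fraction)
    ecc: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ecc.update({v: float(e) for v, e in nx.eccentricity(sub).items()})
    if config.invert_eccentricity:
        m = max(ecc.values()) if ecc else 0.0
        ecc = {v: m - e for v, e in ecc.items()}
    scores["EcCentricity"] = ecc
    scores["Closeness"] = {v: float(c) for v, c in nx.harmonic_centrality(g).items()}
    scores["Radiality"] = _radiality(g)
    scores["Betweenness"] = {
        v: float(b) for v, b in nx.betweenness_centrality(g, normalized=True).items()
    }
    scores["Stress"] = _stress_and_paths(g)
    scores["ClusteringCoefficient"] = {v: float(c) for v, c in nx.clustering(g).items()}

    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {alg: [scores[alg][v] for v in nodes] for alg in ALGORITHMS}, index=nodes
    )


def rank_sum(
    scores: pd.DataFrame,
    nodes: Sequence | None = None,
    top_k: int = 10,
) -> CentralityReport:
    """Rank-sum consensus over the algorithm columns.

    Within each algorithm the highest score receives rank n, the lowest
    rank 1, ties the average of their covered ranks; the per-node rank sum
    across algorithms orders the nodes (ties broken by node id).  ``nodes``
    restricts the ranked set (e.g. to immune traits only).
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one algorithm column")
    sub = scores.loc[list(nodes)] if nodes is not None else scores
    ranks = pd.DataFrame(
        {col: rankdata(sub[col].to_numpy(), method="average") for col in sub.columns},
        index=sub.index,
    )
    sums = ranks.sum(axis=1)
    order = sorted(sums.index, key=lambda v: (-sums[v], str(v)))
    return CentralityReport(
        scores=sub,
        ranks=ranks,
        rank_sums=sums,
        top_k=order[: min(top_k, len(order))],
    )


def report_to_tsv(report: CentralityReport, path: str | Path) -> Path:
    """Node, per-algorithm scores and ranks, rank sum, consensus order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = report.scores.copy()
    for col in report.ranks.columns:
        df[f"rank_{col}"] = report.ranks[col]
    df["rank_sum"] = report.rank_sums
    order = {v: i + 1 for i, v in enumerate(
        sorted(report.rank_sums.index, key=lambda v: (-report.rank_sums[v], str(v)))
    )}
    df["consensus_order"] = [order[v] for v in df.index]
    df.index.name = "node"
    df.to_csv(path, sep="\t")
    return path
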