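"""Directed signed causal networks: per-trait maps, the integrated map, the final map.

Nodes are traits (attribute ``trait_class``); edges point from exposure to
outcome and carry the signed effect, p-value, FDR and source analysis group.
Parallel edges occur only as reciprocal pairs (both directions separately
significant), so a plain directed graph suffices.

Three constructions, in the order the analysis runs:

1. :func:`build_trait_network` — one map per sarcopenia trait: every
   immune <-> focal-trait edge passing the threshold, plus the group-C
   cell/protein edges touching the retained immune traits.
2. :func:`integrate_comprehensive` — the union of all per-trait maps, with
   immune nodes linked to fewer than two distinct sarcopenia traits removed
   unless they sit on a directed path between a retained immune node and a
   sarcopenia trait (the pathway-contribution exemption).
3. :func:`prune_final` — iterated removal of immune nodes with degree < 2
   or with no direct sarcopenia edge, to a fixed point.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .sumstats_io import TraitMeta

__all__ = [
    "build_trait_network",
    "integrate_comprehensive",
    "prune_final",
    "edges_to_csv",
    "to_graphml",
    "to_sif",
    "network_from_edges",
]

_IMMUNE = ("cell", "protein")


def _add_edge_row(g: nx.DiGraph, row, registry: Mapping[str, TraitMeta]) -> None:
    for node in (row.source, row.target):
        if node not in g:
            meta = registry.get(node)
            g.add_node(
                node,
                trait_class=meta.trait_class if meta else "unknown",
                label=meta.label if meta else node,
            )
    g.add_edge(
        row.source,
        row.target,
        sign=row.sign,
        beta=float(row.beta),
        pval=float(row.pval),
        fdr=float(row.fdr),
        group=row.group,
    )


def network_from_edges(
    edges: pd.DataFrame, registry: Mapping[str, TraitMeta]
) -> nx.DiGraph:
    """Edge-candidate table -> directed signed graph (no pruning)."""
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            continue
        _add_edge_row(g, row, registry)
    return g


def build_trait_network(
    edges: pd.DataFrame,
    focal_trait: str,
    registry: Mapping[str, TraitMeta],
    threshold_kind: str = "pval",
) -> nx.DiGraph:
    """Causal map for one sarcopenia trait.

    Contains (i) every immune <-> focal-trait edge in the candidate table and
    (ii) every cell <-> protein (group C) edge with at least one endpoint
    among the immune traits retained by (i).  The candidate table is assumed
    already thresholded (see ``pipeline.extract_edges``); ``threshold_kind``
    is recorded on the graph.  Isolated nodes never arise by construction.
    """
    if focal_trait not in registry:
        raise ValueError(f"focal trait {focal_trait!r} not in registry")
    if registry[focal_trait].trait_class != "sarcopenia":
        raise ValueError(f"focal trait {focal_trait!r} is not a sarcopenia trait")

    g = nx.DiGraph(focal_trait=focal_trait, threshold_kind=threshold_kind)
    focal_edges = edges[
        (edges["source"] == focal_trait) | (edges["target"] == focal_trait)
    ]
    retained: set[str] = set()
    for row in focal_edges.itertuples(index=False):
        other = row.target if row.source == focal_trait else row.source
        if registry.get(other) and registry[other].trait_class in _IMMUNE:
            _add_edge_row(g, row, registry)
            retained.add(other)

    c_edges = edges[edges["group"] == "C"]
    for row in c_edges.itertuples(index=False):
        if row.source in retained or row.target in retained:
            _add_edge_row(g, row, registry)
    return g


def _sarco_link_counts(g: nx.DiGraph) -> dict[str, set[str]]:
    """Immune node -> set of sarcopenia traits it is directly linked to."""
    out: dict[str, set[str]] = {}
    for u, v in g.edges():
        cu = g.nodes[u].get("trait_class")
        cv = g.nodes[v].get("trait_class")
        if cu in _IMMUNE and cv == "sarcopenia":
            out.setdefault(u, set()).add(v)
        elif cu == "sarcopenia" and cv in _IMMUNE:
            out.setdefault(v, set()).add(u)
    return out


def integrate_comprehensive(
    networks: Sequence[nx.DiGraph], exempt_paths: bool = True
) -> nx.DiGraph:
    """Union of the per-trait maps, dropping single-trait immune nodes.

    An immune node directly linked (either direction) to fewer than two
    distinct sarcopenia traits is removed, unless ``exempt_paths`` and it
    lies on a directed path of length >= 2 between a retained immune node
    and a sarcopenia trait (it contributes to a pathway).  Isolated nodes
    are removed afterwards.
    """
    if len(networks) < 2:
        raise ValueError("integration needs at least two per-trait networks")
    g = nx.DiGraph(threshold_kind=networks[0].graph.get("threshold_kind"))
    for net in networks:
        g.add_nodes_from(net.nodes(data=True))
        g.add_edges_from(net.edges(data=True))

    links = _sarco_link_counts(g)
    immune = [n for n, d in g.nodes(data=True) if d.get("trait_class") in _IMMUNE]
    sarco = {n for n, d in g.nodes(data=True) if d.get("trait_class") == "sarcopenia"}
    retained = {n for n in immune if len(links.get(n, ())) >= 2}

    drop = set()
    for v in immune:
        if v in retained:
            continue
        if exempt_paths:
            anc = nx.ancestors(g, v)
            desc = nx.descendants(g, v)
            on_path = (anc & retained and desc & sarco) or (
                anc & sarco and desc & retained
            )
            if on_path:
                continue
        drop.add(v)
    g.remove_nodes_from(drop)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g


def prune_final(network: nx.DiGraph) -> nx.DiGraph:
    """Final map: iterated removal of weakly connected immune nodes.

    Repeatedly removes immune nodes with total degree < 2 OR without any
    direct edge to/from a sarcopenia trait, until no node changes; then
    removes isolated nodes.  The fixed point is order-independent because
    both removal conditions are monotone (removing a node can only lower
    other nodes' degrees and never create sarcopenia links).
    """
    g = network.copy()
    changed = True
    while changed:
        changed = False
        links = _sarco_link_counts(g)
        for v in [n for n, d in g.nodes(data=True) if d.get("trait_class") in _IMMUNE]:
            if g.degree(v) < 2 or not links.get(v):
                g.remove_node(v)
                changed = True
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g


def edges_to_csv(g: nx.DiGraph, path: str | Path) -> Path:
    """Edge list with attributes as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"source": u, "target": v, **d}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def to_graphml(g: nx.DiGraph, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h = g.copy()
    h.graph.clear()  # graph-level attrs may be None; node/edge attrs are typed
    for _, d in h.nodes(data=True):
        for k, v in list(d.items()):
            if v is None:
                d[k] = ""
    nx.write_graphml(h, path)
    return path


def to_sif(g: nx.DiGraph, path: str | Path, relation: str = "causes") -> Path:
    """Simple interaction format: source <relation><sign> target, one edge per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for u, v, d in g.edges(data=True):
            fh.write(f"{u}\t{relation}{d.get('sign', '')}\t{v}\n")
    return path
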