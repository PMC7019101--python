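"""Topology analysis of protein-protein interaction (PPI) networks.

Consumes undirected edge lists (Cytoscape SIF or 2/3-column TSV), merges
subnetworks by node-label union, and computes the per-node metrics used for
hub identification: degree, mean neighbor degree (neighborhood
connectivity), normalized shortest-path betweenness, and Wasserman–Faust
closeness (fraction-reachable scaling, so disconnected graphs are handled).
Disassortative mixing — the hub signature — is diagnosed from the sign of a
least-squares slope of log mean neighborhood connectivity against log
degree over degree classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NodeMetrics",
    "AssortativityFit",
    "read_edge_list",
    "write_sif",
    "merge_networks",
    "node_metrics",
    "assortativity_fit",
    "top_hubs",
]

logger = logging.getLogger(__name__)

SLOPE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class NodeMetrics:
    degree: int
    neighborhood_connectivity: float | None  # None for isolates
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class AssortativityFit:
    slope: float | None
    intercept: float | None
    mixing: str  # disassortative | assortative | neutral/undefined


def read_edge_list(path: str | Path, format: str = "sif") -> nx.Graph:
    """Read an undirected simple graph from SIF or TSV.

    SIF lines are ``source  interaction  target [target ...]``; the
    interaction type is preserved as an edge attribute but ignored by all
    metrics.  TSV lines are ``source  target`` or ``source  interaction
    target``.  Reversed/duplicate edges collapse; self-loops are dropped
    with a warning.  A single-token SIF line declares an isolated node.
    """
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown edge-list format {format!r}")
    graph = nx.Graph()
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if format == "sif":
            if len(tokens) == 1:
                graph.add_node(tokens[0])
                continue
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs 'source interaction target'"
                )
            source, interaction, targets = tokens[0], tokens[1], tokens[2:]
        else:
            if len(tokens) == 2:
                source, interaction, targets = tokens[0], "pp", [tokens[1]]
            elif len(tokens) == 3:
                source, interaction, targets = tokens[0], tokens[1], [tokens[2]]
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(tokens)}"
                )
        for target in targets:
            if target == source:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, source)
                graph.add_node(source)
                continue
            graph.add_edge(source, target, interaction=interaction)
    return graph


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as SIF, one edge per line, isolates as bare nodes."""
    lines = []
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f"{u}\t{data.get('interaction', 'pp')}\t{v}")
    for node in sorted(nx.isolates(graph)):
        lines.append(str(node))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def merge_networks(graphs: Sequence[nx.Graph]) -> nx.Graph:
    """Union of node and edge sets; nodes sharing a label are fused."""
    if not graphs:
        raise ValueError("need at least one graph")
    return nx.compose_all(list(graphs))


def node_metrics(graph: nx.Graph) -> dict[str, NodeMetrics]:
    """Degree, neighborhood connectivity, normalized betweenness and
    Wasserman–Faust closeness for every node.

    Isolates get betweenness 0, closeness 0 and undefined (None)
    neighborhood connectivity.
    """
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    neighbor_degree = nx.average_neighbor_degree(graph)
    return {
        node: NodeMetrics(
            degree=degree[node],
            neighborhood_connectivity=(
                neighbor_degree[node] if degree[node] > 0 else None
            ),
            betweenness=betweenness[node],
            closeness=closeness[node] if degree[node] > 0 else 0.0,
        )
        for node in graph.nodes
    }


def assortativity_fit(graph: nx.Graph) -> AssortativityFit:
    """Sign of the log-log trend of mean neighborhood connectivity vs degree.

    Degree classes k >= 1 are formed; the class mean of the per-node mean
    neighbor degree is regressed (least squares) on log k.  A slope below
    -1e-9 classifies the network as disassortative (hub architecture), above
    +1e-9 assortative, otherwise neutral; fewer than two degree classes give
    mixing "neutral/undefined" with no slope.
    """
    metrics = node_metrics(graph)
    by_degree: dict[int, list[float]] = {}
    for m in metrics.values():
        if m.degree >= 1 and m.neighborhood_connectivity is not None:
            by_degree.setdefault(m.degree, []).append(m.neighborhood_connectivity)
    if len(by_degree) < 2:
        return AssortativityFit(slope=None, intercept=None, mixing="neutral/undefined")
    ks = np.array(sorted(by_degree))
    knn = np.array([np.mean(by_degree[k]) for k in ks])
    slope, intercept = np.polyfit(np.log(ks), np.log(knn), 1)
    if slope < -SLOPE_TOLERANCE:
        mixing = "disassortative"
    elif slope > SLOPE_TOLERANCE:
        mixing = "assortative"
    else:
        mixing = "neutral/undefined"
    return AssortativityFit(slope=float(slope), intercept=float(intercept), mixing=mixing)


def top_hubs(
    metrics: dict[str, NodeMetrics], k: int, key: str = "betweenness"
) -> list[str]:
    """The k highest-centrality nodes, descending by ``key`` (betweenness or
    closeness), ties broken by the other centrality then label ascending."""
    if key not in ("betweenness", "closeness"):
        raise ValueError(f"hub key must be 'betweenness' or 'closeness', got {key!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(metrics):
        logger.warning("requested %d hubs from %d nodes; returning all", k, len(metrics))
    other = "closeness" if key == "betweenness" else "betweenness"
    ordered = sorted(
        metrics,
        key=lambda n: (
            -getattr(metrics[n], key),
            -getattr(metrics[n], other),
            n,
        ),
    )
    return ordered[:k]


def write_node_metrics(metrics: dict[str, NodeMetrics], path: str | Path) -> None:
    """Metrics TSV: node, degree, neighborhood_connectivity, betweenness, closeness."""
    lines = ["node\tdegree\tneighborhood_connectivity\tbetweenness\tcloseness"]
    for node in sorted(metrics):
        m = metrics[node]
        nc = "" if m.neighborhood_connectivity is None else repr(m.neighborhood_connectivity)
        lines.append(f"{node}\t{m.degree}\t{nc}\t{m.betweenness!r}\t{m.closeness!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
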