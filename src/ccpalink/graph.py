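"""Undirected simple-graph handling: edge-list I/O, distances, candidate pairs.

Networks are plain :class:`networkx.Graph` objects with opaque, hashable node
labels; reading an edge-list file always yields string labels and never
coerces them to numbers. Only simple undirected graphs are supported:
self-loops and parallel edges are dropped (or rejected in strict mode) at the
I/O boundary, so every function here may assume set-like, symmetric adjacency.

Hop distances come from breadth-first search — the graphs are unweighted, so
BFS is exact — and a pair with no connecting path gets the distinguished
sentinel :data:`UNREACHABLE` (``math.inf``), never a large finite number, so
callers can branch on disconnection explicitly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable, Union

import networkx as nx

__all__ = [
    "UNREACHABLE",
    "ParseError",
    "ParseReport",
    "SummaryStats",
    "bfs_distances",
    "candidate_pairs",
    "canonical_pair",
    "network_summary",
    "pair_sort_key",
    "read_edge_list",
    "shortest_distance",
    "write_edge_list",
]

Node = Hashable
Pair = "tuple[Node, Node]"

#: Sentinel hop count for node pairs with no connecting path.
UNREACHABLE: float = math.inf

_COMMENT_CHAR = "#"


class ParseError(ValueError):
    """Raised in strict mode when an edge-list line violates the format."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class ParseReport:
    """Tally of what :func:`read_edge_list` kept, repaired or dropped."""

    edges: int = 0
    duplicate_edges: int = 0
    self_loops: int = 0


def canonical_pair(x: Node, y: Node) -> tuple:
    """Return the unordered pair ``{x, y}`` in its canonical tuple form.

    Labels are ordered by their natural comparison when possible, falling
    back to string comparison for unorderable label types, so a pair has
    exactly one representation no matter the argument order.
    """
    if x == y:
        raise ValueError(f"a pair needs two distinct labels, got {x!r} twice")
    try:
        return (x, y) if x <= y else (y, x)
    except TypeError:
        return (x, y) if str(x) <= str(y) else (y, x)


def pair_sort_key(pair: tuple) -> tuple:
    """Deterministic, type-agnostic sort key for canonical pairs."""
    return (str(pair[0]), str(pair[1]))


def _parse(lines: Iterable[str], strict: bool) -> nx.Graph:
    net = nx.Graph()
    report = ParseReport()
    for lineno, raw in enumerate(lines, 1):
        text = raw.split(_COMMENT_CHAR, 1)[0].strip()
        if not text:
            continue  # blank or comment-only line
        tokens = text.split()
        if len(tokens) == 1:
            # single-token line declares an isolated node
            net.add_node(tokens[0])
            continue
        x, y = tokens[0], tokens[1]
        if x == y:
            if strict:
                raise ParseError(f"self-loop on node {x!r}", lineno)
            report.self_loops += 1
            net.add_node(x)
            continue
        if net.has_edge(x, y):
            if strict:
                raise ParseError(f"duplicate edge {x!r} -- {y!r}", lineno)
            report.duplicate_edges += 1
            continue
        net.add_edge(x, y)
        report.edges += 1
    net.graph["parse_report"] = report
    return net


def read_edge_list(
    source: Union[str, Path, Iterable[str]], *, strict: bool = False
) -> nx.Graph:
    """Read an undirected simple graph from edge-list text.

    Format: two whitespace-delimited node labels per line; ``#`` starts a
    comment; blank lines are ignored; a single-token line declares an
    isolated node; extra tokens after the first two are ignored.

    Parameters
    ----------
    source
        A path, or any iterable of lines (an open text file, a list of
        strings, ...).
    strict
        If true, self-loop and duplicate-edge lines raise :class:`ParseError`
        with the offending line number instead of being dropped.

    Returns
    -------
    networkx.Graph
        With string node labels; the drop tallies are attached as
        ``G.graph["parse_report"]`` (a :class:`ParseReport`).
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return _parse(handle, strict)
    return _parse(source, strict)


def _canonical_edges(net: nx.Graph) -> list:
    return sorted((canonical_pair(u, v) for u, v in net.edges), key=pair_sort_key)


def write_edge_list(net: nx.Graph, sink: Union[str, Path, object]) -> None:
    """Write ``net`` as canonical edge-list text: one line per edge, each edge
    exactly once with its labels in canonical order, then one single-token
    line per isolated node (so a write/read round trip reproduces the graph
    exactly for string-labelled networks)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as handle:
            write_edge_list(net, handle)
        return
    for x, y in _canonical_edges(net):
        sink.write(f"{x}\t{y}\n")
    isolated = sorted((v for v in net if net.degree(v) == 0), key=str)
    for v in isolated:
        sink.write(f"{v}\n")


def bfs_distances(net: nx.Graph, source: Node) -> dict:
    """Hop count from ``source`` to every reachable node (source included, 0)."""
    if source not in net:
        raise KeyError(f"unknown node label {source!r}")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in net.adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def shortest_distance(net: nx.Graph, x: Node, y: Node) -> float:
    """BFS hop count between ``x`` and ``y``; 0 when ``x == y``;
    :data:`UNREACHABLE` when no path exists."""
    for node in (x, y):
        if node not in net:
            raise KeyError(f"unknown node label {node!r}")
    if x == y:
        return 0
    dist = {x: 0}
    queue = deque([x])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in net.adj[u]:
            if v not in dist:
                if v == y:
                    return du + 1
                dist[v] = du + 1
                queue.append(v)
    return UNREACHABLE


def candidate_pairs(net: nx.Graph) -> set:
    """All unordered pairs of distinct nodes not joined by an edge.

    This is the candidate (missing-link) set L = U − E, where U is all
    N(N−1)/2 possible pairs; ``len(result) == N(N-1)/2 - M`` always.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("candidate pairs need at least 2 nodes")
    return {
        canonical_pair(u, v)
        for u, v in combinations(list(net), 2)
        if not net.has_edge(u, v)
    }


@dataclass
class SummaryStats:
    """Headline topology numbers: N, M, <k> = 2M/N, and the mean BFS hop
    distance <d> over connected unordered node pairs (disconnected pairs are
    excluded from both numerator and denominator; NaN when no pair is
    connected)."""

    node_count: int
    edge_count: int
    avg_degree: float
    avg_distance: float

    def to_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "avg_degree": self.avg_degree,
            "avg_distance": None if math.isnan(self.avg_distance) else self.avg_distance,
        }


def network_summary(net: nx.Graph) -> SummaryStats:
    """Compute :class:`SummaryStats` for ``net`` (one BFS per node)."""
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("summary needs at least 1 node")
    m = net.number_of_edges()
    total = 0
    pairs = 0
    for source in net:
        dist = bfs_distances(net, source)
        total += sum(dist.values())
        pairs += len(dist) - 1  # ordered connected pairs from this source
    avg_distance = total / pairs if pairs else math.nan
    return SummaryStats(n, m, 2 * m / n, avg_distance)
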