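"""Seeded graph generators and fixed fixtures.

Everything here exists so the scoring and evaluation code can be exercised
without downloading real network datasets: a five-node hand-checkable
fixture, seeded classical random-graph models (Erdős–Rényi,
Barabási–Albert, Watts–Strogatz), and a planted community benchmark whose
held-out "future" edges have high common-neighbor counts by construction —
a desk-scale stand-in for social/biological networks where triadic closure
drives edge formation.

All generated graphs use string node labels (so edge-list round trips are
exact) and are deterministic per seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .graph import canonical_pair, pair_sort_key

__all__ = ["MODELS", "GeneratorSpec", "fixture_g5", "generate", "planted_benchmark"]

MODELS = ("erdos_renyi", "barabasi_albert", "watts_strogatz", "planted_cn")


def fixture_g5() -> nx.Graph:
    """The fixed five-node fixture: nodes {A..E}, edges
    {A–B, A–C, B–C, C–D, D–E} (a triangle with a two-edge tail).

    Degrees are (A:2, B:2, C:3, D:2, E:1) and the five candidate pairs are
    A–D, A–E, B–D, B–E, C–E; all worked examples in the test suite are hand
    evaluations on this graph.
    """
    return nx.Graph([("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E")])


@dataclass(frozen=True)
class GeneratorSpec:
    """A fully-seeded recipe for one random graph.

    ``params`` are model-specific: ``p`` (edge probability) for
    erdos_renyi; ``m`` (attachment count) for barabasi_albert; ``k`` (ring
    neighbors) and ``p`` (rewiring probability) for watts_strogatz;
    ``planted_fraction``, ``p_in``, ``p_out``, ``community_size`` for
    planted_cn. Identical specs generate identical graphs.
    """

    model: str
    n: int
    seed: int = 0
    params: Mapping = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"model": self.model, "n": self.n, "seed": self.seed, "params": dict(self.params)}


def generate(spec: GeneratorSpec) -> nx.Graph:
    """Generate the simple undirected graph described by ``spec``.

    Nodes are relabelled to strings ("0", "1", ...). Raises ``ValueError``
    for unknown models or out-of-range parameters.
    """
    if spec.model not in MODELS:
        raise ValueError(f"unknown model {spec.model!r}; choose from {', '.join(MODELS)}")
    if spec.n < 1:
        raise ValueError(f"node count must be positive, got {spec.n}")
    params = dict(spec.params)
    if spec.model == "erdos_renyi":
        p = float(params.pop("p", 0.1))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"edge probability must lie in [0, 1], got {p}")
        net = nx.gnp_random_graph(spec.n, p, seed=spec.seed)
    elif spec.model == "barabasi_albert":
        m = int(params.pop("m", 3))
        if not 1 <= m < spec.n:
            raise ValueError(f"attachment count must satisfy 1 <= m < n, got m={m}, n={spec.n}")
        net = nx.barabasi_albert_graph(spec.n, m, seed=spec.seed)
    elif spec.model == "watts_strogatz":
        k = int(params.pop("k", 4))
        p = float(params.pop("p", 0.1))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"rewiring probability must lie in [0, 1], got {p}")
        net = nx.watts_strogatz_graph(spec.n, k, p, seed=spec.seed)
    else:  # planted_cn
        fraction = float(params.pop("planted_fraction", 0.2))
        net, _ = planted_benchmark(spec.n, fraction, spec.seed, **params)
        params = {}
    if params:
        raise ValueError(f"unknown parameters for {spec.model}: {sorted(params)}")
    return nx.relabel_nodes(net, {v: str(v) for v in net})


def planted_benchmark(
    n: int,
    planted_fraction: float = 0.2,
    seed: int = 0,
    *,
    p_in: float = 0.6,
    p_out: float = 0.02,
    community_size: int = 12,
) -> "tuple[nx.Graph, frozenset]":
    """Clustered graph with a seeded sample of intra-community edges held out.

    Nodes are split into consecutive communities of ``community_size``;
    within-community pairs connect with probability ``p_in``, others with
    ``p_out``. A fraction ``planted_fraction`` of the realized
    intra-community edges is then removed and returned as the "future" edge
    set. Because communities are dense, a removed edge's endpoints still
    share many neighbors, while uniformly sampled non-edges are
    predominantly inter-community — so common-neighbor-style scorers have a
    known, strong signal to find.

    Returns ``(network, future_edges)``; the future edges are absent from
    the returned network, whose nodes are strings ("0".."n-1").
    """
    if n < 10:
        raise ValueError(f"planted benchmark needs at least 10 nodes, got {n}")
    if not 0.0 < planted_fraction < 1.0:
        raise ValueError(f"planted_fraction must lie in (0, 1), got {planted_fraction}")
    rng = random.Random(seed)
    labels = [str(i) for i in range(n)]
    net = nx.Graph()
    net.add_nodes_from(labels)
    intra = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (i // community_size) == (j // community_size)
            if rng.random() < (p_in if same else p_out):
                net.add_edge(labels[i], labels[j])
                if same:
                    intra.append(canonical_pair(labels[i], labels[j]))
    if not intra:
        raise ValueError("no intra-community edges realized; increase n or p_in")
    intra.sort(key=pair_sort_key)
    count = max(1, round(planted_fraction * len(intra)))
    future = rng.sample(intra, count)
    net.remove_edges_from(future)
    return net, frozenset(future)
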