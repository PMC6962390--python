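"""Topological similarity indices for scoring candidate links.

The headline score is CCPA (common neighbors + closeness, parameterized):

    S_xy = alpha * |Gamma(x) ∩ Gamma(y)|  +  (1 - alpha) * N / d_xy

where Gamma(x) is the neighborhood of x, N the node count of the network
being scored, d_xy the BFS hop distance, and alpha in [0, 1] weighs the two
factors against each other (alpha = 1 reduces to plain common-neighbor
counting, alpha = 0 to the closeness term alone).

Eight classic baselines are provided under their usual initials:

==========  =====================================================
``cn``      common neighbors, |Γ(x)∩Γ(y)|
``cnd``     common neighbors & distance: (CN+1)/2 if CN > 0 else 1/d_xy
``pa``      preferential attachment, k_x · k_y
``aa``      Adamic–Adar, Σ 1/ln k_z over common neighbors z
``ra``      resource allocation, Σ 1/k_z over common neighbors z
``jaccard`` |Γ(x)∩Γ(y)| / |Γ(x)∪Γ(y)|  (alias ``ji``)
``sorensen`` 2|Γ(x)∩Γ(y)| / (k_x + k_y)  (alias ``si``)
``hpi``     hub promoted, |Γ(x)∩Γ(y)| / min(k_x, k_y)
==========  =====================================================

Conventions, applied uniformly: every index is symmetric in (x, y) and
finite; a zero denominator (isolated endpoint, empty neighborhood union)
scores 0 — such pairs are maximally dissimilar, and the evaluation protocol
must still be able to score them; the distance terms N/d and 1/d are 0 for
disconnected pairs (the d → ∞ limit), never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Union

import networkx as nx

from .graph import (
    UNREACHABLE,
    bfs_distances,
    candidate_pairs,
    pair_sort_key,
    shortest_distance,
)

__all__ = [
    "INDEX_NAMES",
    "PairScore",
    "get_scorer",
    "rank_candidates",
    "resolve_method",
    "score_aa",
    "score_ccpa",
    "score_cn",
    "score_cnd",
    "score_hpi",
    "score_jaccard",
    "score_pa",
    "score_ra",
    "score_sorensen",
    "write_scores_tsv",
]

#: Canonical identifiers of the nine implemented indices.
INDEX_NAMES = ("ccpa", "cn", "cnd", "pa", "aa", "ra", "jaccard", "sorensen", "hpi")

_ALIASES = {"ji": "jaccard", "si": "sorensen"}


def resolve_method(method: str) -> str:
    """Normalize a method identifier (case-insensitive, aliases resolved)."""
    name = _ALIASES.get(method.lower(), method.lower())
    if name not in INDEX_NAMES:
        raise ValueError(
            f"unknown similarity method {method!r}; choose from {', '.join(INDEX_NAMES)}"
        )
    return name


def _require_pair(net: nx.Graph, x, y) -> None:
    for node in (x, y):
        if node not in net:
            raise KeyError(f"unknown node label {node!r}")
    if x == y:
        raise ValueError("similarity scores are defined for distinct nodes only")


def _common(net: nx.Graph, x, y):
    return net.adj[x].keys() & net.adj[y].keys()


def score_cn(net: nx.Graph, x, y) -> float:
    """Common-neighbor count |Γ(x)∩Γ(y)|."""
    _require_pair(net, x, y)
    return float(len(_common(net, x, y)))


def score_ccpa(net: nx.Graph, x, y, alpha: float, *, distance: Optional[float] = None) -> float:
    """CCPA score alpha·|Γ(x)∩Γ(y)| + (1−alpha)·N/d_xy.

    ``N`` is the node count of ``net`` (during evaluation that is the
    training network). The closeness term is 0 when x and y are
    disconnected. ``distance`` may carry a precomputed hop distance so bulk
    scorers can reuse BFS results.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    _require_pair(net, x, y)
    cn = len(_common(net, x, y))
    d = shortest_distance(net, x, y) if distance is None else distance
    closeness = 0.0 if d == UNREACHABLE else len(net) / d
    return alpha * cn + (1.0 - alpha) * closeness


def score_cnd(net: nx.Graph, x, y, *, distance: Optional[float] = None) -> float:
    """Common-neighbors-and-distance score: (CN+1)/2 when the pair shares at
    least one neighbor, otherwise 1/d_xy (0 if disconnected)."""
    _require_pair(net, x, y)
    cn = len(_common(net, x, y))
    if cn:
        return (cn + 1) / 2.0
    d = shortest_distance(net, x, y) if distance is None else distance
    return 0.0 if d == UNREACHABLE else 1.0 / d


def score_pa(net: nx.Graph, x, y) -> float:
    """Preferential attachment k_x · k_y."""
    _require_pair(net, x, y)
    return float(net.degree(x) * net.degree(y))


def score_aa(net: nx.Graph, x, y) -> float:
    """Adamic–Adar Σ 1/ln(k_z); every common neighbor of a simple-graph pair
    has degree ≥ 2, so each term is finite."""
    _require_pair(net, x, y)
    return float(sum(1.0 / math.log(net.degree(z)) for z in _common(net, x, y)))


def score_ra(net: nx.Graph, x, y) -> float:
    """Resource allocation Σ 1/k_z over common neighbors."""
    _require_pair(net, x, y)
    return float(sum(1.0 / net.degree(z) for z in _common(net, x, y)))


def score_jaccard(net: nx.Graph, x, y) -> float:
    """Jaccard index |Γ(x)∩Γ(y)| / |Γ(x)∪Γ(y)|; 0 when both neighborhoods
    are empty."""
    _require_pair(net, x, y)
    union = len(net.adj[x].keys() | net.adj[y].keys())
    return len(_common(net, x, y)) / union if union else 0.0


def score_sorensen(net: nx.Graph, x, y) -> float:
    """Sorensen index 2|Γ(x)∩Γ(y)| / (k_x + k_y); 0 when both degrees are 0."""
    _require_pair(net, x, y)
    denom = net.degree(x) + net.degree(y)
    return 2.0 * len(_common(net, x, y)) / denom if denom else 0.0


def score_hpi(net: nx.Graph, x, y) -> float:
    """Hub-promoted index |Γ(x)∩Γ(y)| / min(k_x, k_y); 0 when either
    endpoint is isolated."""
    _require_pair(net, x, y)
    denom = min(net.degree(x), net.degree(y))
    return len(_common(net, x, y)) / denom if denom else 0.0


_PLAIN_SCORES: Mapping[str, Callable] = {
    "cn": score_cn,
    "pa": score_pa,
    "aa": score_aa,
    "ra": score_ra,
    "jaccard": score_jaccard,
    "sorensen": score_sorensen,
    "hpi": score_hpi,
}


class _Distances:
    """Memoized single-source BFS shared across many pair queries on one
    (immutable-while-scoring) network."""

    def __init__(self, net: nx.Graph):
        self._net = net
        self._rows: dict = {}

    def __call__(self, x, y) -> float:
        row = self._rows.get(x)
        if row is None:
            row = self._rows.get(y)
            if row is not None:
                return row.get(x, UNREACHABLE)
            row = self._rows[x] = bfs_distances(self._net, x)
        return row.get(y, UNREACHABLE)


def get_scorer(
    net: nx.Graph,
    method: Union[str, Callable],
    params: Optional[Mapping] = None,
) -> Callable:
    """Build a ``scorer(x, y) -> float`` closure for ``method`` on ``net``.

    ``method`` may be one of :data:`INDEX_NAMES` (or an alias), or any
    callable ``(x, y) -> float`` — the latter lets the evaluation protocol
    benchmark arbitrary scorers. Distance-based indices (ccpa, cnd) share a
    memoized BFS cache across calls. ``ccpa`` requires an ``alpha`` entry in
    ``params``; the other named indices take no parameters.
    """
    if callable(method):
        return method
    name = resolve_method(method)
    extra = dict(params or {})
    if name == "ccpa":
        if "alpha" not in extra:
            raise ValueError("ccpa requires an 'alpha' parameter in [0, 1]")
        alpha = float(extra.pop("alpha"))
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
        if extra:
            raise ValueError(f"unexpected ccpa parameters: {sorted(extra)}")
        dist = _Distances(net)
        return lambda x, y: score_ccpa(net, x, y, alpha, distance=dist(x, y))
    if extra:
        raise ValueError(f"method {name!r} takes no parameters, got {sorted(extra)}")
    if name == "cnd":
        dist = _Distances(net)
        return lambda x, y: score_cnd(net, x, y, distance=dist(x, y))
    fn = _PLAIN_SCORES[name]
    return lambda x, y: fn(net, x, y)


@dataclass(frozen=True)
class PairScore:
    """One scored candidate pair (labels in canonical order)."""

    x: object
    y: object
    score: float
    method: str
    params: Optional[Mapping] = None


def rank_candidates(
    net: nx.Graph,
    method: Union[str, Callable],
    params: Optional[Mapping] = None,
) -> "list[PairScore]":
    """Score every candidate pair (non-edge) of ``net`` and rank descending.

    Ties break lexicographically on the canonical pair labels, so the output
    order is byte-stable across runs.
    """
    scorer = get_scorer(net, method, params)
    name = resolve_method(method) if isinstance(method, str) else getattr(
        method, "__name__", "custom"
    )
    frozen = dict(params) if params else None
    ranked = [
        PairScore(x, y, float(scorer(x, y)), name, frozen)
        for x, y in candidate_pairs(net)
    ]
    ranked.sort(key=lambda s: (-s.score, pair_sort_key((s.x, s.y))))
    return ranked


def write_scores_tsv(scores, sink, *, comment: Optional[str] = None) -> None:
    """Write ranked :class:`PairScore` rows as TSV with a header
    (columns node1, node2, score, method, rank); ``comment`` becomes a
    leading ``#`` line."""
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as handle:
            write_scores_tsv(scores, handle, comment=comment)
        return
    if comment is not None:
        sink.write(f"# {comment}\n")
    sink.write("node1\tnode2\tscore\tmethod\trank\n")
    for rank, s in enumerate(scores, 1):
        sink.write(f"{s.x}\t{s.y}\t{format(s.score, '.12g')}\t{s.method}\t{rank}\n")
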