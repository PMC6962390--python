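"""Train/probe evaluation protocol for link-prediction scorers.

The observed edge set E is split uniformly at random into a training set E^T
(default 80%) and a probe set E^P (the rest); scores are computed on the
training network only, and quality is the AUC of Eq.-style pairwise
comparison: the probability that a random probe edge outscores a random
non-existent link, with half credit for ties,

    AUC = (n1 + 0.5 * n2) / n .

Non-existent links default to U − E (pairs absent from the *full* observed
graph), so probe edges are never counted as negatives; ``negative_pool=
"training"`` switches to U − E^T for comparison with protocols that allow
probe edges among the negatives.

Experiments are repeated over independent splits (default 15) and reported
as mean ± sample standard deviation; the alpha sweep reruns CCPA over a grid
of alpha values (default {0.1, ..., 0.9}) with identical split seeds so that
alpha is the only varying factor. Per-run seeds come from a SplitMix64-style
mix of (base_seed, index), so adding runs never perturbs earlier ones.
"""

from __future__ import annotations

import math
import random
import statistics
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .graph import candidate_pairs, canonical_pair, pair_sort_key
from .similarity import get_scorer, resolve_method

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_RUNS",
    "DEFAULT_SAMPLE_COMPARISONS",
    "DEFAULT_TRAIN_FRACTION",
    "EXHAUSTIVE_LIMIT",
    "TIE_TOLERANCE",
    "AUCEstimate",
    "AlphaSweep",
    "EvaluationError",
    "ExperimentReport",
    "TrainProbeSplit",
    "alpha_sweep",
    "auc_from_scores",
    "derive_seed",
    "estimate_auc",
    "run_experiment",
    "split_train_probe",
]

#: Protocol defaults: 80% of edges train, 15 repeated splits, alpha grid 0.1..0.9.
DEFAULT_TRAIN_FRACTION = 0.8
DEFAULT_RUNS = 15
DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))

#: Two floating-point scores within this distance count as a tie (n2).
TIE_TOLERANCE = 1e-12
#: Compare every (probe, negative) pair exhaustively up to this many comparisons.
EXHAUSTIVE_LIMIT = 10**6
#: Sampled-mode comparison count when the exhaustive product is too large.
DEFAULT_SAMPLE_COMPARISONS = 10**5

_MASK64 = (1 << 64) - 1


class EvaluationError(RuntimeError):
    """Raised when the protocol cannot run (empty probe or negative pool)."""


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-run seed from (base_seed, index).

    SplitMix64 finalizer over ``base_seed + (index+1)·golden``; result is
    folded below 2**31 so it feeds any downstream RNG safely.
    """
    z = (int(base_seed) + (int(index) + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _MASK64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return int(z % (1 << 31))


@dataclass(frozen=True)
class TrainProbeSplit:
    """One random edge split: the training network G^T (full node set, E^T)
    plus the held-out probe edge set E^P."""

    training: nx.Graph
    probe_edges: frozenset
    fraction: float
    seed: int

    def all_edges(self) -> frozenset:
        """The source graph's full edge set E = E^T ∪ E^P (canonical pairs)."""
        train = frozenset(canonical_pair(u, v) for u, v in self.training.edges)
        return train | self.probe_edges


def split_train_probe(
    net: nx.Graph,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> TrainProbeSplit:
    """Randomly partition the edges of ``net`` into training and probe sets.

    Training edges are drawn uniformly at random without replacement;
    |E^T| = round-half-up(fraction · M), capped at M − 1 so at least one
    probe edge remains. All nodes of ``net`` are kept in the training
    network (possibly isolated). Identical (net, fraction, seed) give
    identical splits.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"training fraction must lie in (0, 1), got {fraction}")
    m = net.number_of_edges()
    if m < 2:
        raise ValueError(f"need at least 2 edges to split, got {m}")
    edges = sorted((canonical_pair(u, v) for u, v in net.edges), key=pair_sort_key)
    rng = random.Random(seed)
    rng.shuffle(edges)
    n_train = min(math.floor(fraction * m + 0.5), m - 1)
    training = nx.Graph()
    training.add_nodes_from(net)
    training.add_edges_from(edges[:n_train])
    return TrainProbeSplit(training, frozenset(edges[n_train:]), float(fraction), int(seed))


@dataclass(frozen=True)
class AUCEstimate:
    """AUC value with its comparison tallies: ``auc == (n1 + 0.5*n2)/n``."""

    auc: float
    n: int
    n1: int
    n2: int
    mode: str  # "exhaustive" | "sampled"

    def to_dict(self) -> dict:
        return {"auc": self.auc, "n": self.n, "n1": self.n1, "n2": self.n2, "mode": self.mode}


def auc_from_scores(
    probe_scores: Sequence[float],
    negative_scores: Sequence[float],
    *,
    tol: float = TIE_TOLERANCE,
    mode: str = "exhaustive",
) -> AUCEstimate:
    """Exhaustive AUC over every (probe, negative) score pairing.

    n1 counts pairings where the probe score exceeds the negative score by
    more than ``tol``; n2 counts pairings within ``tol`` (ties).
    """
    probe = np.asarray(probe_scores, dtype=float)
    negative = np.sort(np.asarray(negative_scores, dtype=float))
    if probe.size == 0 or negative.size == 0:
        raise EvaluationError("both probe and negative score sets must be nonempty")
    below = np.searchsorted(negative, probe - tol, side="left")
    upto = np.searchsorted(negative, probe + tol, side="right")
    n1 = int(below.sum())
    n2 = int((upto - below).sum())
    n = int(probe.size) * int(negative.size)
    return AUCEstimate((n1 + 0.5 * n2) / n, n, n1, n2, mode)


def estimate_auc(
    split: TrainProbeSplit,
    method: Union[str, Callable],
    params: Optional[Mapping] = None,
    n_comparisons: Union[int, str, None] = None,
    seed: int = 0,
    *,
    negative_pool: str = "source",
    tol: float = TIE_TOLERANCE,
) -> AUCEstimate:
    """Estimate the link-prediction AUC of ``method`` on one split.

    All scores are computed on the training network only. Negatives come
    from U − E (``negative_pool="source"``, default) or U − E^T
    (``"training"``). ``n_comparisons`` may be ``None`` (exhaustive when the
    probe × negative product is at most :data:`EXHAUSTIVE_LIMIT`, else
    sampled at :data:`DEFAULT_SAMPLE_COMPARISONS`), the string
    ``"exhaustive"``, or an integer sample size; sampling draws independent
    uniform (probe, negative) pairs with ``seed``.
    """
    probes = sorted(split.probe_edges, key=pair_sort_key)
    if not probes:
        raise EvaluationError("probe edge set is empty")
    pool = candidate_pairs(split.training)
    if negative_pool == "source":
        pool -= split.probe_edges
    elif negative_pool != "training":
        raise ValueError(f"negative_pool must be 'source' or 'training', got {negative_pool!r}")
    negatives = sorted(pool, key=pair_sort_key)
    if not negatives:
        raise EvaluationError("no non-existent links to compare against (complete graph)")

    scorer = get_scorer(split.training, method, params)

    if n_comparisons in (None, "auto"):
        exhaustive = len(probes) * len(negatives) <= EXHAUSTIVE_LIMIT
        sample_n = DEFAULT_SAMPLE_COMPARISONS
    elif n_comparisons == "exhaustive":
        exhaustive = True
        sample_n = 0
    else:
        exhaustive = False
        sample_n = int(n_comparisons)
        if sample_n < 1:
            raise ValueError("n_comparisons must be a positive integer")

    if exhaustive:
        probe_scores = [scorer(x, y) for x, y in probes]
        negative_scores = [scorer(x, y) for x, y in negatives]
        return auc_from_scores(probe_scores, negative_scores, tol=tol)

    rng = random.Random(seed)
    cache: dict = {}

    def cached(pair):
        value = cache.get(pair)
        if value is None:
            value = cache[pair] = scorer(*pair)
        return value

    n1 = n2 = 0
    for _ in range(sample_n):
        diff = cached(probes[rng.randrange(len(probes))]) - cached(
            negatives[rng.randrange(len(negatives))]
        )
        if diff > tol:
            n1 += 1
        elif diff >= -tol:
            n2 += 1
    return AUCEstimate((n1 + 0.5 * n2) / sample_n, sample_n, n1, n2, "sampled")


@dataclass(frozen=True)
class ExperimentReport:
    """Per-run AUCs over repeated random splits, with mean and sample SD."""

    method: str
    params: Mapping
    runs: int
    fraction: float
    base_seed: int
    negative_pool: str
    per_run_auc: tuple
    mean_auc: float
    sd_auc: float
    estimates: tuple = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": dict(self.params),
            "runs": self.runs,
            "fraction": self.fraction,
            "base_seed": self.base_seed,
            "negative_pool": self.negative_pool,
            "per_run_auc": list(self.per_run_auc),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "auc_estimates": [e.to_dict() for e in self.estimates],
        }


def run_experiment(
    net: nx.Graph,
    method: Union[str, Callable],
    params: Optional[Mapping] = None,
    runs: int = DEFAULT_RUNS,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    base_seed: int = 0,
    n_comparisons: Union[int, str, None] = None,
    *,
    negative_pool: str = "source",
) -> ExperimentReport:
    """Repeat split → score → AUC ``runs`` times and summarize.

    Run ``r`` uses split seed ``derive_seed(base_seed, 2r)`` and sampling
    seed ``derive_seed(base_seed, 2r+1)``; the report's mean and sample
    standard deviation (n−1 denominator; 0.0 for a single run) are
    recomputable from ``per_run_auc``.
    """
    if runs < 1:
        raise ValueError(f"runs must be at least 1, got {runs}")
    estimates = []
    for r in range(runs):
        split = split_train_probe(net, fraction, derive_seed(base_seed, 2 * r))
        estimates.append(
            estimate_auc(
                split,
                method,
                params,
                n_comparisons,
                derive_seed(base_seed, 2 * r + 1),
                negative_pool=negative_pool,
            )
        )
    aucs = tuple(e.auc for e in estimates)
    name = resolve_method(method) if isinstance(method, str) else getattr(
        method, "__name__", "custom"
    )
    return ExperimentReport(
        method=name,
        params=dict(params or {}),
        runs=runs,
        fraction=float(fraction),
        base_seed=int(base_seed),
        negative_pool=negative_pool,
        per_run_auc=aucs,
        mean_auc=statistics.fmean(aucs),
        sd_auc=statistics.stdev(aucs) if runs > 1 else 0.0,
        estimates=tuple(estimates),
    )


@dataclass(frozen=True)
class AlphaSweep:
    """CCPA experiments over an alpha grid, identical split seeds per alpha."""

    alphas: tuple
    reports: tuple
    best_alpha: float
    best_mean_auc: float

    @property
    def grid_mean_auc(self) -> float:
        """Mean of the per-alpha mean AUCs (the grid-averaged CCPA figure)."""
        return statistics.fmean(r.mean_auc for r in self.reports)

    def to_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "reports": [r.to_dict() for r in self.reports],
            "best_alpha": self.best_alpha,
            "best_mean_auc": self.best_mean_auc,
            "grid_mean_auc": self.grid_mean_auc,
        }

    def to_frame(self):
        """Per-alpha summary as a pandas DataFrame (alpha, mean_auc, sd_auc)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "alpha": list(self.alphas),
                "mean_auc": [r.mean_auc for r in self.reports],
                "sd_auc": [r.sd_auc for r in self.reports],
            }
        )


def alpha_sweep(
    net: nx.Graph,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    runs: int = DEFAULT_RUNS,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    base_seed: int = 0,
    n_comparisons: Union[int, str, None] = None,
    *,
    negative_pool: str = "source",
) -> AlphaSweep:
    """Run the CCPA experiment once per alpha on identical splits.

    Every alpha shares the same base seed, hence the same sequence of
    train/probe splits, so alpha is the only varying factor. Ties for the
    best mean AUC break toward the smaller alpha.
    """
    grid = tuple(float(a) for a in alphas)
    if not grid:
        raise ValueError("alpha grid must be nonempty")
    for a in grid:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {a}")
    reports = tuple(
        run_experiment(
            net,
            "ccpa",
            {"alpha": a},
            runs,
            fraction,
            base_seed,
            n_comparisons,
            negative_pool=negative_pool,
        )
        for a in grid
    )
    best = max(range(len(grid)), key=lambda i: (reports[i].mean_auc, -grid[i]))
    return AlphaSweep(grid, reports, grid[best], reports[best].mean_auc)
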