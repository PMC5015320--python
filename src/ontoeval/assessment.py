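"""Statistical comparison of methods.

Scalar metrics on a single benchmark carry sampling noise from the benchmark
proteins themselves, so methods are compared by resampling proteins with
replacement: percentile confidence intervals for one method, and paired
head-to-head contests (shared bootstrap samples, win counting, mean F_max
difference delta) between two.  Prediction diversity is summarized as a
network whose edges are high Pearson correlations between methods' scores on
shared (protein, term) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import numpy as np

from .annotations import BenchmarkSet
from .metrics import EvaluationSummary
from .predictions import PredictionSet

#: An evaluator maps a multiset of benchmark proteins to a scalar metric.
Evaluator = Callable[[Sequence[str]], float]


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    level: float
    B: int


def _sample_indices(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    return rng.integers(0, n, size=(B, n))


def bootstrap_ci(
    evaluator: Evaluator,
    benchmark: BenchmarkSet,
    B: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap interval for a scalar metric.

    Benchmark proteins are the resampling unit; a fixed seed makes reruns
    bit-identical.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0,1)")
    proteins = benchmark.protein_ids()
    if len(proteins) == 1:
        import warnings

        warnings.warn("benchmark of size 1: bootstrap interval is degenerate")
    rng = np.random.default_rng(seed)
    point = evaluator(proteins)
    idx = _sample_indices(rng, len(proteins), B)
    reps = np.asarray([evaluator([proteins[j] for j in row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(reps, [alpha, 1.0 - alpha])
    return BootstrapCI(float(point), float(lower), float(upper), level, B)


@dataclass
class HeadToHeadResult:
    method1: str
    method2: str
    B: int
    delta: float  # mean F_max(m2) - mean F_max(m1) over bootstrap samples
    wins1: int
    wins2: int
    ties: int
    samples: np.ndarray | None = field(default=None, repr=False)

    @property
    def win_fraction2(self) -> float:
        return self.wins2 / self.B


def head_to_head(
    evaluator1: Evaluator,
    evaluator2: Evaluator,
    benchmark: BenchmarkSet,
    B: int = 10000,
    seed: int | None = None,
    method1: str = "m1",
    method2: str = "m2",
    keep_samples: bool = False,
) -> HeadToHeadResult:
    """Paired bootstrap contest between two methods.

    Both methods are scored on the *same* B resampled benchmark sets; a
    method wins a sample by a strictly higher metric, exact equality is a
    tie.  delta is the difference of the two bootstrap means (method2 minus
    method1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    proteins = benchmark.protein_ids()
    rng = np.random.default_rng(seed)
    idx = _sample_indices(rng, len(proteins), B)
    pairs = np.empty((B, 2))
    for b, row in enumerate(idx):
        sample = [proteins[j] for j in row]
        pairs[b, 0] = evaluator1(sample)
        pairs[b, 1] = evaluator2(sample)
    wins1 = int(np.sum(pairs[:, 0] > pairs[:, 1]))
    wins2 = int(np.sum(pairs[:, 1] > pairs[:, 0]))
    ties = B - wins1 - wins2
    delta = float(pairs[:, 1].mean() - pairs[:, 0].mean())
    return HeadToHeadResult(
        method1, method2, B, delta, wins1, wins2, ties,
        samples=pairs if keep_samples else None,
    )


def select_best_per_pi(
    summaries: Iterable[EvaluationSummary],
    registry: Mapping[str, str],
    key: Callable[[EvaluationSummary], float] = lambda s: s.fmax,
    higher_is_better: bool = True,
) -> list[EvaluationSummary]:
    """Keep one summary per principal investigator: the best by ``key``.

    Ties within a PI go to the lexicographically smallest method id, so the
    selection is deterministic.
    """
    by_pi: dict[str, list[EvaluationSummary]] = {}
    for s in sorted(summaries, key=lambda s: s.method_id):
        try:
            pi = registry[s.method_id]
        except KeyError:
            raise KeyError(f"method {s.method_id} missing from the PI registry")
        by_pi.setdefault(pi, []).append(s)
    sign = 1.0 if higher_is_better else -1.0
    out = []
    for pi in sorted(by_pi):
        best = max(by_pi[pi], key=lambda s: (sign * key(s), ))
        # max() keeps the first on ties; the list is sorted by method id
        out.append(best)
    return out


@dataclass
class SimilarityNetwork:
    """Pairwise Pearson similarity between methods' prediction scores."""

    methods: list[str]
    matrix: np.ndarray  # correlation, NaN where undefined
    cutoff: float
    flags: dict[str, str] = field(default_factory=dict)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i, mi in enumerate(self.methods):
            for j in range(i + 1, len(self.methods)):
                r = self.matrix[i, j]
                if not np.isnan(r) and r >= self.cutoff:
                    out.append((mi, self.methods[j], float(r)))
        return out

    def components(self) -> list[frozenset[str]]:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.methods)
        g.add_edges_from((a, b) for a, b, _ in self.edges())
        return sorted(
            (frozenset(c) for c in nx.connected_components(g)),
            key=lambda c: (-len(c), sorted(c)[0]),
        )

    def top_in_largest_component(self, ranked_methods: Sequence[str], k: int) -> int:
        comps = self.components()
        if not comps:
            return 0
        largest = comps[0]
        return sum(1 for m in ranked_methods[:k] if m in largest)

    def write_edge_tsv(self, handle: TextIO) -> None:
        handle.write("method1\tmethod2\tpearson_r\n")
        for a, b, r in self.edges():
            handle.write(f"{a}\t{b}\t{r:.10g}\n")


def similarity_network(
    predictions: Sequence[PredictionSet],
    cutoff: float = 0.75,
    policy: str = "pairwise",
    flags: Mapping[str, str] | None = None,
) -> SimilarityNetwork:
    """Correlation network over methods.

    ``policy`` selects which (protein, term) pairs enter each correlation:
    ``pairwise`` (default) intersects the pairs the two methods scored;
    ``union_zero`` takes their union with missing scores as 0; ``global``
    intersects across all methods at once.
    """
    if len(predictions) < 2:
        raise ValueError("at least two methods are required")
    if policy not in ("pairwise", "union_zero", "global"):
        raise ValueError(f"unknown common-pair policy {policy!r}")
    methods = [p.method_id for p in predictions]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate method ids")
    maps: list[dict[tuple[str, str], float]] = []
    for p in predictions:
        flat = {
            (protein, term): score
            for protein, terms in p.scores.items()
            for term, score in terms.items()
        }
        maps.append(flat)

    global_keys: set[tuple[str, str]] | None = None
    if policy == "global":
        global_keys = set(maps[0])
        for m in maps[1:]:
            global_keys &= set(m)

    k = len(predictions)
    matrix = np.full((k, k), np.nan)
    np.fill_diagonal(matrix, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            if policy == "pairwise":
                keys = sorted(set(maps[i]) & set(maps[j]))
            elif policy == "union_zero":
                keys = sorted(set(maps[i]) | set(maps[j]))
            else:
                keys = sorted(global_keys)  # type: ignore[arg-type]
            if len(keys) < 2:
                continue
            x = np.asarray([maps[i].get(key, 0.0) for key in keys])
            y = np.asarray([maps[j].get(key, 0.0) for key in keys])
            if x.std() == 0.0 or y.std() == 0.0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            matrix[i, j] = matrix[j, i] = r
    return SimilarityNetwork(methods, matrix, cutoff, dict(flags or {}))
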