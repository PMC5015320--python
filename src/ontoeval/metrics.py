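"""Protein-centric and term-centric evaluation metrics.

Protein-centric evaluation treats prediction as hierarchical multi-label
classification: at a score threshold tau each method asserts a term set
P_i(tau) for protein i, compared against the ground-truth set T_i.

*  Precision pr(tau) averages |P∩T|/|P| over the m(tau) proteins with a
   non-empty prediction at tau; recall rc(tau) averages |P∩T|/|T| over the
   n_e evaluated proteins.  F_max is the best harmonic mean over the grid.
*  Remaining uncertainty ru(tau) and misinformation mi(tau) weight missed and
   over-predicted terms by information content; S_min is the minimum
   Euclidean norm of (ru, mi) — the semantic distance of the best threshold.
*  Weighted precision/recall and normalized ru/mi are the secondary,
   information-content-rescaled variants of the two curve families.

In *full* mode n_e = n, so a method is penalized on benchmark proteins it
ignored; in *partial* mode n_e = m(0) and only self-selected targets count.
Term-centric evaluation ranks proteins per term by score (unpredicted
proteins count as score 0) and reports the ROC AUC, computed from midranks.

All thresholds live on the 0.01..1.00 grid; scores are expected to be
validated (two decimals) and max-propagated before any metric is computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy.stats import rankdata

from .annotations import BenchmarkSet
from .ontology import InformationContentTable, Ontology
from .predictions import DEFAULT_GRID, PredictionSet, ThresholdGrid


@dataclass
class Curve:
    """A threshold-indexed metric curve.

    ``coord1``/``coord2`` hold (pr, rc) for precision-recall-type curves and
    (ru, mi) for semantic-distance-type curves; ``m`` counts proteins with at
    least one prediction at each threshold.  Undefined precision (m(tau)=0)
    is NaN.
    """

    kind: str  # "pr" | "rumi" | "wpr" | "nrumi"
    mode: str
    tau: np.ndarray
    coord1: np.ndarray
    coord2: np.ndarray
    m: np.ndarray
    n: int
    n_e: int

    def to_tsv(self, handle: TextIO) -> None:
        c1, c2 = ("pr", "rc") if self.kind in ("pr", "wpr") else ("ru", "mi")
        handle.write(f"tau\t{c1}\t{c2}\tm\n")
        for i in range(len(self.tau)):
            v1 = "NA" if np.isnan(self.coord1[i]) else f"{self.coord1[i]:.10g}"
            handle.write(
                f"{self.tau[i]:.2f}\t{v1}\t{self.coord2[i]:.10g}\t{int(self.m[i])}\n"
            )


class _ProteinCurves:
    """Per-protein counts and information totals across the threshold grid."""

    __slots__ = (
        "has_pred", "n_truth", "ic_truth", "tp", "npred", "ic_tp", "ic_pred", "ru"
    )

    def __init__(
        self,
        scores: Mapping[str, float],
        truth: frozenset[str],
        grid: np.ndarray,
        ic: InformationContentTable | None,
    ):
        self.n_truth = len(truth)
        self.has_pred = bool(scores)
        terms = list(scores)
        vals = np.asarray([scores[t] for t in terms])
        order = np.argsort(vals, kind="stable")
        vals = vals[order]
        in_truth = np.asarray([terms[j] in truth for j in order], dtype=bool)
        # count of scores >= tau, via the ascending-sorted score array
        idx = np.searchsorted(vals, grid, side="left")
        self.npred = len(vals) - idx
        truth_vals = vals[in_truth]
        self.tp = len(truth_vals) - np.searchsorted(truth_vals, grid, side="left")
        if ic is not None:
            predicted_terms = set(terms)
            missing_ic = float(sum(ic[t] for t in sorted(truth - predicted_terms)))
            w = np.asarray([ic[terms[j]] for j in order])
            cum = np.concatenate(([0.0], np.cumsum(w)))
            self.ic_pred = cum[-1] - cum[idx]
            w_truth = w[in_truth]
            cum_t = np.concatenate(([0.0], np.cumsum(w_truth)))
            idx_t = np.searchsorted(truth_vals, grid, side="left")
            self.ic_tp = cum_t[-1] - cum_t[idx_t]
            self.ic_truth = missing_ic + float(cum_t[-1])
            # ru built without cancellation so exact zeros stay exact
            self.ru = missing_ic + cum_t[idx_t]
        else:
            self.ic_truth = 0.0
            self.ic_pred = np.zeros(len(grid))
            self.ic_tp = np.zeros(len(grid))
            self.ru = np.zeros(len(grid))


class CurveEvaluator:
    """Precomputed per-protein curve ingredients for one (method, benchmark).

    Bootstrap resampling re-evaluates the same benchmark under many protein
    multisets; precomputing each protein's threshold profile once makes each
    replicate a cheap sum.
    """

    def __init__(
        self,
        predictions: PredictionSet,
        benchmark: BenchmarkSet,
        ic: InformationContentTable | None = None,
        grid: ThresholdGrid = DEFAULT_GRID,
        mode: str = "full",
    ):
        if mode not in ("full", "partial"):
            raise ValueError(f"unknown evaluation mode {mode!r}")
        if benchmark.n == 0:
            raise ValueError("empty benchmark set")
        self.predictions = predictions
        self.benchmark = benchmark
        self.ic = ic
        self.grid = grid
        self.mode = mode
        self._tau = grid.as_array()
        self._per_protein: dict[str, _ProteinCurves] = {}
        dropped = 0
        for protein, truth in benchmark.proteins.items():
            if not truth:
                dropped += 1
                continue
            self._per_protein[protein] = _ProteinCurves(
                predictions.protein_scores(protein), truth, self._tau, ic
            )
        if dropped:
            warnings.warn(
                f"{dropped} benchmark proteins had empty truth sets and were dropped"
            )
        if not self._per_protein:
            raise ValueError("benchmark has no proteins with non-empty truth sets")

    # -- protein selections ------------------------------------------------

    def default_proteins(self) -> list[str]:
        """Proteins entering the evaluation under the current mode."""
        proteins = sorted(self._per_protein)
        if self.mode == "partial":
            proteins = [p for p in proteins if self._per_protein[p].has_pred]
        return proteins

    def _resolve(self, proteins: Sequence[str] | None) -> list[_ProteinCurves]:
        if proteins is None:
            proteins = self.default_proteins()
        else:
            if self.mode == "partial":
                proteins = [
                    p for p in proteins if self._per_protein[p].has_pred
                ]
        return [self._per_protein[p] for p in proteins]

    @property
    def n(self) -> int:
        return len(self._per_protein)

    @property
    def m0(self) -> int:
        return sum(1 for pc in self._per_protein.values() if pc.has_pred)

    @property
    def coverage(self) -> float:
        return self.m0 / self.n

    # -- curves ------------------------------------------------------------

    def pr_curve(self, proteins: Sequence[str] | None = None) -> Curve:
        rows = self._resolve(proteins)
        if not rows:
            raise ValueError("no proteins to evaluate")
        K = len(self._tau)
        m = np.zeros(K, dtype=int)
        pr_sum = np.zeros(K)
        rc_sum = np.zeros(K)
        for pc in rows:
            predicted = pc.npred > 0
            m += predicted
            with np.errstate(invalid="ignore", divide="ignore"):
                pr_sum += np.where(predicted, pc.tp / np.maximum(pc.npred, 1), 0.0)
            rc_sum += pc.tp / pc.n_truth
        n_e = len(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = np.where(m > 0, pr_sum / np.maximum(m, 1), np.nan)
        rc = rc_sum / n_e
        return Curve("pr", self.mode, self._tau, pr, rc, m, self.n, n_e)

    def rumi_curve(self, proteins: Sequence[str] | None = None) -> Curve:
        self._require_ic()
        rows = self._resolve(proteins)
        if not rows:
            raise ValueError("no proteins to evaluate")
        K = len(self._tau)
        m = np.zeros(K, dtype=int)
        ru_sum = np.zeros(K)
        mi_sum = np.zeros(K)
        for pc in rows:
            m += pc.npred > 0
            ru_sum += pc.ru
            mi_sum += pc.ic_pred - pc.ic_tp
        n_e = len(rows)
        return Curve(
            "rumi", self.mode, self._tau, ru_sum / n_e, mi_sum / n_e, m, self.n, n_e
        )

    def weighted_pr_curve(self, proteins: Sequence[str] | None = None) -> Curve:
        self._require_ic()
        rows = self._resolve(proteins)
        if not rows:
            raise ValueError("no proteins to evaluate")
        K = len(self._tau)
        m = np.zeros(K, dtype=int)
        pr_sum = np.zeros(K)
        rc_sum = np.zeros(K)
        zero_ic = 0
        for pc in rows:
            predicted = pc.npred > 0
            m += predicted
            with np.errstate(invalid="ignore", divide="ignore"):
                contrib = np.where(
                    predicted & (pc.ic_pred > 0), pc.ic_tp / np.where(pc.ic_pred > 0, pc.ic_pred, 1.0), 0.0
                )
            pr_sum += contrib
            if pc.ic_truth > 0:
                rc_sum += pc.ic_tp / pc.ic_truth
            else:
                zero_ic += 1
        if zero_ic:
            warnings.warn(
                f"{zero_ic} proteins with zero total truth information contribute 0"
            )
        n_e = len(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = np.where(m > 0, pr_sum / np.maximum(m, 1), np.nan)
        return Curve("wpr", self.mode, self._tau, pr, rc_sum / n_e, m, self.n, n_e)

    def normalized_rumi_curve(self, proteins: Sequence[str] | None = None) -> Curve:
        self._require_ic()
        rows = self._resolve(proteins)
        if not rows:
            raise ValueError("no proteins to evaluate")
        K = len(self._tau)
        m = np.zeros(K, dtype=int)
        ru_sum = np.zeros(K)
        mi_sum = np.zeros(K)
        for pc in rows:
            m += pc.npred > 0
            # ic of the union T ∪ P(tau) normalizes both coordinates into [0,1]
            denom = pc.ru + pc.ic_pred
            safe = np.where(denom > 0, denom, 1.0)
            ru_sum += np.where(denom > 0, pc.ru / safe, 0.0)
            mi_sum += np.where(denom > 0, (pc.ic_pred - pc.ic_tp) / safe, 0.0)
        n_e = len(rows)
        return Curve(
            "nrumi", self.mode, self._tau, ru_sum / n_e, mi_sum / n_e, m, self.n, n_e
        )

    def fmax_on(self, proteins: Sequence[str] | None = None) -> float:
        return fmax(self.pr_curve(proteins))[0]

    def smin_on(self, proteins: Sequence[str] | None = None) -> float:
        return smin(self.rumi_curve(proteins))[0]

    def _require_ic(self) -> None:
        if self.ic is None:
            raise ValueError("an information-content table is required for this curve")


# -- functional surface ----------------------------------------------------


def precision_recall_curve(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    grid: ThresholdGrid = DEFAULT_GRID,
    mode: str = "full",
) -> Curve:
    return CurveEvaluator(predictions, benchmark, grid=grid, mode=mode).pr_curve()


def ru_mi_curve(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    ic: InformationContentTable,
    grid: ThresholdGrid = DEFAULT_GRID,
    mode: str = "full",
) -> Curve:
    return CurveEvaluator(predictions, benchmark, ic=ic, grid=grid, mode=mode).rumi_curve()


def weighted_precision_recall_curve(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    ic: InformationContentTable,
    grid: ThresholdGrid = DEFAULT_GRID,
    mode: str = "full",
) -> Curve:
    return CurveEvaluator(
        predictions, benchmark, ic=ic, grid=grid, mode=mode
    ).weighted_pr_curve()


def normalized_ru_mi_curve(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    ic: InformationContentTable,
    grid: ThresholdGrid = DEFAULT_GRID,
    mode: str = "full",
) -> Curve:
    return CurveEvaluator(
        predictions, benchmark, ic=ic, grid=grid, mode=mode
    ).normalized_rumi_curve()


def fmax(curve: Curve) -> tuple[float, float | None]:
    """Maximum harmonic mean of precision and recall over the grid.

    Thresholds with no predictions (undefined precision) are skipped; an
    all-undefined curve scores 0.  Ties go to the smallest threshold.
    """
    best, best_tau = 0.0, None
    found = False
    for i in range(len(curve.tau)):
        p, r = curve.coord1[i], curve.coord2[i]
        if np.isnan(p):
            continue
        f = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
        if not found or f > best:
            best, best_tau, found = f, float(curve.tau[i]), True
    if not found:
        return 0.0, None
    return float(best), best_tau


def smin(curve: Curve) -> tuple[float, float | None]:
    """Minimum Euclidean norm of (ru, mi) over the grid; ties to smallest tau."""
    best, best_tau = math.inf, None
    for i in range(len(curve.tau)):
        s = math.hypot(curve.coord1[i], curve.coord2[i])
        if s < best:
            best, best_tau = s, float(curve.tau[i])
    return float(best), best_tau


def coverage(predictions: PredictionSet, benchmark: BenchmarkSet) -> float:
    """Fraction m(0)/n of benchmark proteins with at least one prediction."""
    if benchmark.n == 0:
        raise ValueError("empty benchmark set")
    m0 = sum(
        1 for p in benchmark.proteins if predictions.protein_scores(p)
    )
    return m0 / benchmark.n


@dataclass
class EvaluationSummary:
    """Scalar evaluation record for one (method, benchmark, mode)."""

    method_id: str
    benchmark: str
    mode: str
    n: int
    n_e: int
    m0: int
    coverage: float
    fmax: float
    fmax_tau: float | None
    smin: float | None = None
    smin_tau: float | None = None
    weighted_fmax: float | None = None
    weighted_fmax_tau: float | None = None
    normalized_smin: float | None = None
    normalized_smin_tau: float | None = None
    curves: dict[str, Curve] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict[str, object]:
        out = {
            k: v for k, v in self.__dict__.items() if k != "curves"
        }
        return out


def evaluate(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    ic: InformationContentTable | None = None,
    grid: ThresholdGrid = DEFAULT_GRID,
    mode: str = "full",
    benchmark_id: str | None = None,
    keep_curves: bool = True,
) -> EvaluationSummary:
    """Full scalar evaluation: F_max, coverage and, given an information-content
    table, S_min plus the weighted/normalized secondary metrics."""
    ev = CurveEvaluator(predictions, benchmark, ic=ic, grid=grid, mode=mode)
    pr = ev.pr_curve()
    f, f_tau = fmax(pr)
    summary = EvaluationSummary(
        method_id=predictions.method_id,
        benchmark=benchmark_id or f"{benchmark.namespace}-{benchmark.knowledge}",
        mode=mode,
        n=ev.n,
        n_e=pr.n_e,
        m0=ev.m0,
        coverage=ev.coverage,
        fmax=f,
        fmax_tau=f_tau,
    )
    curves = {"pr": pr}
    if ic is not None:
        rumi = ev.rumi_curve()
        summary.smin, summary.smin_tau = smin(rumi)
        wpr = ev.weighted_pr_curve()
        summary.weighted_fmax, summary.weighted_fmax_tau = fmax(wpr)
        nrumi = ev.normalized_rumi_curve()
        summary.normalized_smin, summary.normalized_smin_tau = smin(nrumi)
        curves.update({"rumi": rumi, "wpr": wpr, "nrumi": nrumi})
    if keep_curves:
        summary.curves = curves
    return summary


# -- term-centric evaluation ----------------------------------------------


@dataclass(frozen=True)
class TermAUCRecord:
    term: str
    positives: int
    negatives: int
    auc: float


def term_auc(
    predictions: PredictionSet, benchmark: BenchmarkSet, term: str
) -> TermAUCRecord:
    """ROC AUC for one term: rank benchmark proteins by its predicted score.

    Positives are the proteins truly annotated with the term, all remaining
    benchmark proteins are negatives, and unpredicted proteins enter with
    score 0.  Computed from midranks, i.e. the Mann-Whitney U statistic
    normalized by n1*n2; ties contribute 1/2.
    """
    proteins = sorted(benchmark.proteins)
    labels = np.asarray([term in benchmark.proteins[p] for p in proteins], dtype=bool)
    scores = np.asarray(
        [predictions.protein_scores(p).get(term, 0.0) for p in proteins]
    )
    n1 = int(labels.sum())
    n2 = len(proteins) - n1
    if n1 == 0:
        raise ValueError(f"term {term} has no positive benchmark proteins")
    if n2 == 0:
        raise ValueError(f"term {term} has no negative benchmark proteins")
    ranks = rankdata(scores)
    u = float(ranks[labels].sum()) - n1 * (n1 + 1) / 2.0
    return TermAUCRecord(term, n1, n2, u / (n1 * n2))


@dataclass
class AverageAUC:
    mean: float
    se: float
    records: list[TermAUCRecord]


def average_auc(
    predictions: PredictionSet,
    benchmark: BenchmarkSet,
    min_positives: int = 10,
) -> AverageAUC:
    """Unweighted mean AUC over terms with at least ``min_positives`` positives.

    The standard error is sd/sqrt(#terms) over the qualifying terms.
    """
    terms: set[str] = set()
    for truth in benchmark.proteins.values():
        terms |= truth
    counts = {
        t: sum(1 for truth in benchmark.proteins.values() if t in truth)
        for t in terms
    }
    records = [
        term_auc(predictions, benchmark, t)
        for t in sorted(terms)
        if counts[t] >= min_positives and counts[t] < benchmark.n
    ]
    if not records:
        raise ValueError(
            f"no term with >= {min_positives} positives and >= 1 negative"
        )
    aucs = np.asarray([r.auc for r in records])
    se = float(np.std(aucs, ddof=1) / math.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    return AverageAUC(float(aucs.mean()), se, records)


def top_terms_nonoverlapping(
    aucs: Mapping[str, float], ontology: Ontology, k: int
) -> list[tuple[str, float]]:
    """Greedy top-k terms by AUC whose ancestries (self included, root
    excluded) are mutually disjoint — a ranked set of independently
    well-predicted branches of the ontology."""
    accepted: list[tuple[str, float]] = []
    used: set[str] = set()
    ranking = sorted(aucs.items(), key=lambda kv: (-kv[1], kv[0]))
    for term, auc in ranking:
        if len(accepted) >= k:
            break
        lineage = (ontology.propagate({term})) - ontology.roots
        if lineage & used:
            continue
        accepted.append((term, auc))
        used |= lineage
    return accepted


def write_term_auc_tsv(records: Iterable[TermAUCRecord], handle: TextIO) -> None:
    handle.write("term\tpositives\tnegatives\tauc\n")
    for r in records:
        handle.write(f"{r.term}\t{r.positives}\t{r.negatives}\t{r.auc:.10g}\n")
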