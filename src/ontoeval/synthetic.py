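"""Seeded generators for toy ontologies, annotation snapshots, and predictions.

Every pipeline stage can be exercised without downloading a real ontology or
annotation database: the generators emit the same in-memory objects (and,
through the writers, the same file formats) the real pipeline consumes.
Given a spec and seed the output is deterministic, so golden-file and
regression tests are stable.

The generative model is deliberately simple: a rooted mostly-tree ontology
with a controlled fraction of diamond (two-parent) nodes; proteins annotated
by sampling leaf terms and closing under propagation; an annotation-growth
phase in which designated cohorts gain their first terms in some namespaces
(future no-knowledge / limited-knowledge benchmark proteins); and predictors
of tunable quality q (probability of recovering a truth leaf) and noise rate
(spurious leaves per protein) whose kept-term scores are drawn high
(Beta(5,1)) and noise scores low (Beta(1,5)), producing threshold-sensitive
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import AnnotationSnapshot, BenchmarkSet, GO_NAMESPACES
from .ontology import Ontology, Term
from .predictions import PredictionSet, from_score_map, round_to_grid

_PREFIX = {"MFO": "MF", "BPO": "BP", "CCO": "CC", "HPO": "HP"}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic generators; same spec + seed => same fixture."""

    seed: int = 0
    depth: int = 3
    branching: int = 2
    part_of_fraction: float = 0.2
    diamond_fraction: float = 0.2
    corpus_size: int = 100
    leaves_per_protein: float = 2.0  # mean of 1 + Poisson(mean - 1)
    nk_fraction: float = 0.2
    lk_fraction: float = 0.2
    growth_rate: float = 1.0  # probability an eligible protein gains terms
    quality: float = 0.8  # probability a truth leaf is recovered
    noise_rate: float = 1.0  # mean number of spurious leaves per protein

    def __post_init__(self):
        for name in (
            "part_of_fraction",
            "diamond_fraction",
            "nk_fraction",
            "lk_fraction",
            "growth_rate",
            "quality",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be >= 1")


def make_ontology(
    spec: FixtureSpec, namespace: str = "MFO", seed_offset: int = 0
) -> Ontology:
    """A rooted DAG: a full ``branching``-ary tree of the given depth, with a
    fraction of depth>=2 nodes acquiring a second parent one level up."""
    rng = np.random.default_rng(spec.seed + seed_offset)
    prefix = _PREFIX.get(namespace, "TM")
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}:{counter:07d}"

    root = next_id()
    terms: dict[str, Term] = {
        root: Term(root, f"{namespace} root", namespace, {})
    }
    levels: list[list[str]] = [[root]]
    for depth in range(1, spec.depth + 1):
        level: list[str] = []
        for parent_pos, parent in enumerate(levels[-1]):
            for _ in range(spec.branching):
                tid = next_id()
                parents: dict[str, set[str]] = {}
                relation = (
                    "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                )
                parents[relation] = {parent}
                # diamond: a second parent from the same shallower level
                if (
                    depth >= 2
                    and len(levels[-1]) > 1
                    and rng.random() < spec.diamond_fraction
                ):
                    others = [p for p in levels[-1] if p != parent]
                    second = others[int(rng.integers(len(others)))]
                    relation2 = (
                        "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                    )
                    parents.setdefault(relation2, set()).add(second)
                terms[tid] = Term(
                    tid,
                    f"term {tid}",
                    namespace,
                    {rel: frozenset(ids) for rel, ids in parents.items()},
                )
                level.append(tid)
        levels.append(level)
    return Ontology(terms, namespace=namespace)


def make_go_ontologies(spec: FixtureSpec) -> dict[str, Ontology]:
    """Three independent namespace DAGs standing in for MFO/BPO/CCO."""
    return {
        ns: make_ontology(spec, ns, seed_offset=i + 1)
        for i, ns in enumerate(GO_NAMESPACES)
    }


def _sample_closed_set(
    rng: np.random.Generator, ontology: Ontology, spec: FixtureSpec
) -> frozenset[str]:
    leaves = sorted(ontology.leaves())
    k = 1 + int(rng.poisson(max(spec.leaves_per_protein - 1.0, 0.0)))
    k = min(k, len(leaves))
    chosen = rng.choice(len(leaves), size=k, replace=False)
    picked = [leaves[i] for i in sorted(chosen)]
    return ontology.propagate(picked) - ontology.roots


def make_snapshots(
    spec: FixtureSpec, ontologies: dict[str, Ontology]
) -> tuple[AnnotationSnapshot, AnnotationSnapshot]:
    """Annotation snapshots at t0 and t1 (t1 extends t0 per protein).

    Proteins fall into three cohorts: a no-knowledge cohort (no t0
    annotation anywhere), a limited-knowledge cohort (t0 annotations in a
    proper, non-empty subset of the namespaces), and a fully-annotated rest.
    During growth, each NK/LK protein gains terms in (some of) its missing
    namespaces with probability ``growth_rate``.
    """
    rng = np.random.default_rng(spec.seed + 101)
    namespaces = sorted(ontologies)
    t0: dict[str, dict[str, frozenset[str]]] = {ns: {} for ns in namespaces}
    t1: dict[str, dict[str, frozenset[str]]] = {ns: {} for ns in namespaces}
    for i in range(spec.corpus_size):
        protein = f"P{i + 1:05d}"
        u = rng.random()
        if u < spec.nk_fraction:
            annotated_t0: list[str] = []
        elif u < spec.nk_fraction + spec.lk_fraction and len(namespaces) > 1:
            n_t0 = int(rng.integers(1, len(namespaces)))
            annotated_t0 = list(
                rng.choice(namespaces, size=n_t0, replace=False)
            )
        else:
            annotated_t0 = list(namespaces)
        for ns in annotated_t0:
            terms = _sample_closed_set(rng, ontologies[ns], spec)
            t0[ns][protein] = terms
            t1[ns][protein] = terms
        missing = [ns for ns in namespaces if ns not in annotated_t0]
        if missing and rng.random() < spec.growth_rate:
            n_gain = int(rng.integers(1, len(missing) + 1))
            gained = rng.choice(missing, size=n_gain, replace=False)
            for ns in gained:
                t1[ns][protein] = _sample_closed_set(rng, ontologies[ns], spec)
    snap0 = AnnotationSnapshot(label="t0", terms=t0, source="synthetic")
    snap1 = AnnotationSnapshot(label="t1", terms=t1, source="synthetic")
    return snap0, snap1


def make_predictions(
    spec: FixtureSpec,
    truth: BenchmarkSet,
    ontology: Ontology,
    quality: float | None = None,
    noise_rate: float | None = None,
    method_id: str = "synthetic",
    seed_offset: int = 0,
) -> PredictionSet:
    """A predictor of tunable quality over a benchmark's truth sets.

    Each leaf of a protein's truth set is recovered with probability q at a
    high score (Beta(5,1)); spurious leaves are added at low scores
    (Beta(1,5)).  Scores are rounded to the grid (floored at 0.01 so kept
    terms stay expressible) and max-propagated, so q=1 with no noise is a
    perfect predictor at threshold 0.01.
    """
    q = spec.quality if quality is None else quality
    noise = spec.noise_rate if noise_rate is None else noise_rate
    if not 0.0 <= q <= 1.0 or noise < 0.0:
        raise ValueError("quality must be in [0,1] and noise_rate >= 0")
    rng = np.random.default_rng(spec.seed + 1000 + seed_offset)
    all_leaves = sorted(ontology.leaves())
    roots = ontology.roots
    scores: dict[str, dict[str, float]] = {}
    for protein in sorted(truth.proteins):
        t_set = truth.proteins[protein]
        truth_leaves = sorted(
            t for t in t_set if not (ontology.children(t) & t_set)
        )
        per: dict[str, float] = {}
        for leaf in truth_leaves:
            if rng.random() < q:
                score = max(round_to_grid(float(rng.beta(5.0, 1.0))), 0.01)
                for term in ontology.propagate({leaf}) - roots:
                    per[term] = max(per.get(term, 0.0), score)
        n_noise = int(rng.poisson(noise))
        for _ in range(n_noise):
            leaf = all_leaves[int(rng.integers(len(all_leaves)))]
            if leaf in t_set:
                continue
            score = max(round_to_grid(float(rng.beta(1.0, 5.0))), 0.01)
            for term in ontology.propagate({leaf}) - roots:
                per[term] = max(per.get(term, 0.0), score)
        if per:
            scores[protein] = per
    p = from_score_map(method_id, scores)
    p.validated = True
    p.propagated = True
    return p


def perfect_predictions(
    truth: BenchmarkSet, method_id: str = "perfect", score: float = 1.0
) -> PredictionSet:
    """The analytic limit case: predict exactly the truth set at one score."""
    scores = {
        protein: {term: score for term in terms}
        for protein, terms in truth.proteins.items()
    }
    p = from_score_map(method_id, scores)
    p.validated = True
    p.propagated = True
    return p
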