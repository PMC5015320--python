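"""Control predictors: Naive term frequency and BLAST annotation transfer.

Naive scores every term by its relative annotation frequency in the training
corpus, identically for every target — the floor any informed method should
clear.  BLAST transfers the annotations of alignment hits, scoring each term
with the highest sequence identity among the hits that carry it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from .annotations import AnnotationSnapshot
from .predictions import PredictionSet, from_score_map, round_to_grid


def train_naive(
    training: AnnotationSnapshot | Mapping[str, frozenset[str]],
    namespace: str | None = None,
) -> dict[str, float]:
    """Per-term annotation frequencies in the training corpus.

    Scores are rounded to the two-decimal grid; terms whose frequency rounds
    to 0.00 are unexpressible in a submission and omitted.
    """
    if isinstance(training, AnnotationSnapshot):
        if namespace is None:
            raise ValueError("a namespace is required with a snapshot input")
        term_sets = training.term_sets(namespace)
    else:
        term_sets = dict(training)
    if not term_sets:
        raise ValueError("empty training corpus")
    counts: dict[str, int] = {}
    for terms in term_sets.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n = len(term_sets)
    out: dict[str, float] = {}
    for term, c in counts.items():
        score = round_to_grid(c / n)
        if score >= 0.01:
            out[term] = score
    return out


def naive_predictions(
    term_scores: Mapping[str, float],
    targets: Iterable[str],
    method_id: str = "naive",
) -> PredictionSet:
    """Emit the same frequency map for every requested target."""
    scores = {t: dict(term_scores) for t in targets}
    p = from_score_map(method_id, scores)
    p.validated = True
    p.propagated = True  # frequencies of closed sets are monotone up the DAG
    return p


@dataclass(frozen=True)
class BlastHit:
    """One alignment hit of a query against a training protein."""

    query: str
    subject: str
    identity: float  # fraction in (0,1]

    def __post_init__(self):
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(
                f"identity {self.identity} for {self.query}->{self.subject} "
                "outside (0,1]"
            )


def read_blast_tabular(
    handle: TextIO, percent_scale: bool = True
) -> list[BlastHit]:
    """Read BLAST outfmt-6 rows (qseqid sseqid pident ...).

    ``percent_scale`` divides the identity column by 100, matching BLAST's
    native output; pass False if the table already holds fractions.
    """
    hits = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BLAST tabular row with <3 columns: {line!r}")
        ident = float(fields[2])
        if percent_scale:
            ident /= 100.0
        hits.append(BlastHit(fields[0], fields[1], ident))
    return hits


def blast_transfer(
    hits: Sequence[BlastHit],
    training: AnnotationSnapshot | Mapping[str, frozenset[str]],
    namespace: str | None = None,
    method_id: str = "blast",
) -> PredictionSet:
    """Transfer annotations from hit subjects: score(term) is the highest
    identity among the hit subjects annotated with that term.

    Hits whose subject carries no training annotation are ignored; queries
    without usable hits stay unpredicted.  With propagation-closed training
    sets, the output is DAG-consistent by construction.
    """
    if isinstance(training, AnnotationSnapshot):
        if namespace is None:
            raise ValueError("a namespace is required with a snapshot input")
        term_sets = training.term_sets(namespace)
    else:
        term_sets = dict(training)
    scores: dict[str, dict[str, float]] = {}
    for hit in hits:
        subject_terms = term_sets.get(hit.subject)
        if not subject_terms:
            continue
        per_query = scores.setdefault(hit.query, {})
        score = round_to_grid(hit.identity)
        if score < 0.01:
            continue
        for term in subject_terms:
            if score > per_query.get(term, 0.0):
                per_query[term] = score
    scores = {q: m for q, m in scores.items() if m}
    p = from_score_map(method_id, scores)
    p.validated = True
    p.propagated = True
    return p
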