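"""Prediction submissions: parsing, validation, and DAG-consistent score maps.

A submission assigns each (target protein, term) pair it chooses a confidence
score in (0,1].  Scores are kept to two decimals, matching the evaluation
threshold grid of 0.01..1.00 in steps of 0.01, and are max-propagated up the
ontology before evaluation so that every thresholded prediction set is a
consistent subgraph (parent score >= child score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np

from .ontology import Ontology


def round_to_grid(score: float) -> float:
    """Round half-up to two decimals, onto the canonical float for k/100."""
    return math.floor(score * 100.0 + 0.5) / 100.0


@dataclass(frozen=True)
class ThresholdGrid:
    """The ordered decision thresholds tau_1 < ... < tau_K."""

    values: tuple[float, ...]

    def __post_init__(self):
        if not self.values:
            raise ValueError("empty threshold grid")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)

    @classmethod
    def default(cls) -> "ThresholdGrid":
        return cls(tuple(k / 100.0 for k in range(1, 101)))


DEFAULT_GRID = ThresholdGrid.default()


@dataclass
class ValidationReport:
    rounded: int = 0
    dropped_zero: int = 0
    rejected_range: int = 0
    duplicates: int = 0
    unknown_terms: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class PredictionSet:
    """Per-protein, per-term confidence scores for one method."""

    method_id: str
    scores: dict[str, dict[str, float]]
    metadata: dict[str, object] = field(default_factory=dict)
    propagated: bool = False
    validated: bool = False

    def proteins(self) -> frozenset[str]:
        return frozenset(self.scores)

    def protein_scores(self, protein: str) -> dict[str, float]:
        return self.scores.get(protein, {})

    def threshold_set(self, protein: str, tau: float) -> frozenset[str]:
        """P_i(tau): terms scored at or above tau; empty if unpredicted."""
        if not 0.0 < tau <= 1.0:
            raise ValueError(f"threshold {tau} outside (0,1]")
        return frozenset(
            t for t, s in self.scores.get(protein, {}).items() if s >= tau
        )

    def n_pairs(self) -> int:
        return sum(len(m) for m in self.scores.values())


class SubmissionFormatError(ValueError):
    pass


def parse_cafa_submission(handle: TextIO, method_id: str | None = None) -> PredictionSet:
    """Parse a CAFA-style submission flat file.

    Layout: ``AUTHOR``/``MODEL``/``KEYWORDS`` header lines, whitespace-separated
    body rows ``target term score``, and a terminal ``END``.  ``ACCURACY``
    lines are tolerated and ignored.  Duplicate (target, term) rows keep the
    maximum score and are counted.
    """
    header: dict[str, str] = {}
    scores: dict[str, dict[str, float]] = {}
    duplicates = 0
    ended = False
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        key = line.split(maxsplit=1)[0]
        if key in {"AUTHOR", "MODEL", "KEYWORDS", "ACCURACY"}:
            header.setdefault(key, line.split(maxsplit=1)[1] if " " in line else "")
            continue
        if key == "END":
            ended = True
            break
        fields = line.split()
        if len(fields) != 3:
            raise SubmissionFormatError(
                f"line {lineno}: expected 'target term score', got {line!r}"
            )
        target, term, raw_score = fields
        try:
            score = float(raw_score)
        except ValueError:
            raise SubmissionFormatError(
                f"line {lineno}: non-numeric score {raw_score!r}"
            ) from None
        per_target = scores.setdefault(target, {})
        if term in per_target:
            duplicates += 1
            per_target[term] = max(per_target[term], score)
        else:
            per_target[term] = score
    if "AUTHOR" not in header or "MODEL" not in header:
        raise SubmissionFormatError("missing AUTHOR/MODEL header")
    if not ended:
        raise SubmissionFormatError("missing END sentinel")
    mid = method_id or f"{header.get('AUTHOR', 'anonymous')}-{header.get('MODEL', '1')}"
    metadata: dict[str, object] = dict(header)
    metadata["duplicates"] = duplicates
    return PredictionSet(method_id=mid, scores=scores, metadata=metadata)


def write_cafa_submission(p: PredictionSet, handle: TextIO) -> None:
    handle.write(f"AUTHOR {p.metadata.get('AUTHOR', p.method_id)}\n")
    handle.write(f"MODEL {p.metadata.get('MODEL', '1')}\n")
    handle.write(f"KEYWORDS {p.metadata.get('KEYWORDS', '')}\n")
    for protein in sorted(p.scores):
        for term in sorted(p.scores[protein]):
            handle.write(f"{protein}\t{term}\t{p.scores[protein][term]:.2f}\n")
    handle.write("END\n")


def validate_scores(
    p: PredictionSet, strict: bool = False
) -> tuple[PredictionSet, ValidationReport]:
    """Round scores to the 0.01 grid and enforce the (0,1] range.

    Scores rounding to 0.00 are unexpressible on the grid and dropped; scores
    outside (0,1] are rejected (raised in strict mode, counted otherwise).
    """
    report = ValidationReport(duplicates=int(p.metadata.get("duplicates", 0)))
    out: dict[str, dict[str, float]] = {}
    for protein, term_scores in p.scores.items():
        kept: dict[str, float] = {}
        for term, score in term_scores.items():
            if not 0.0 < score <= 1.0:
                report.rejected_range += 1
                continue
            rounded = round_to_grid(score)
            if rounded < 0.01:  # rounds to 0.00: unexpressible on the grid
                report.dropped_zero += 1
                continue
            if rounded != score:
                report.rounded += 1
            kept[term] = rounded
        if kept:
            out[protein] = kept
    if strict and report.rejected_range:
        raise ValueError(
            f"{report.rejected_range} scores outside (0,1] in {p.method_id}"
        )
    validated = PredictionSet(
        method_id=p.method_id,
        scores=out,
        metadata=dict(p.metadata),
        propagated=p.propagated,
        validated=True,
    )
    return validated, report


def propagate_scores(
    p: PredictionSet, ontology: Ontology
) -> tuple[PredictionSet, ValidationReport]:
    """Make score maps DAG-consistent by max-propagation toward the root.

    Every ancestor receives at least the maximum score of its descendants, so
    each thresholded set is a propagation-closed subgraph.  Namespace roots
    are removed (scoring the root is vacuous); unknown terms are dropped and
    counted.  Idempotent, and never lowers a score.
    """
    report = ValidationReport()
    roots = ontology.roots
    out: dict[str, dict[str, float]] = {}
    for protein, term_scores in p.scores.items():
        merged: dict[str, float] = {}
        for term, score in term_scores.items():
            canonical = ontology.canonical_id(term)
            if canonical is None:
                report.unknown_terms += 1
                continue
            for anc in ontology.propagate({canonical}):
                if anc in roots:
                    continue
                if score > merged.get(anc, 0.0):
                    merged[anc] = score
        if merged:
            out[protein] = merged
    propagated = PredictionSet(
        method_id=p.method_id,
        scores=out,
        metadata=dict(p.metadata),
        propagated=True,
        validated=p.validated,
    )
    return propagated, report


def prepare_predictions(
    p: PredictionSet,
    ontology: Ontology,
    strict: bool = False,
    propagate: bool = True,
) -> tuple[PredictionSet, ValidationReport]:
    """Validation followed by (optional) max-propagation: the standard path
    every submission takes before any metric sees it."""
    validated, report = validate_scores(p, strict=strict)
    if propagate:
        validated, prop_report = propagate_scores(validated, ontology)
        report.unknown_terms = prop_report.unknown_terms
    return validated, report


def from_score_map(
    method_id: str,
    scores: Mapping[str, Mapping[str, float]],
    **metadata: object,
) -> PredictionSet:
    """Build a PredictionSet from nested mappings (testing and baselines)."""
    return PredictionSet(
        method_id=method_id,
        scores={p: dict(m) for p, m in scores.items() if m},
        metadata=dict(metadata),
    )
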