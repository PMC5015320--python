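"""Annotation snapshots and time-delayed benchmark construction.

A time-delayed assessment freezes the experimentally supported annotations at
submission close (t0), waits for curation to accumulate, and scores methods
against the annotations gained by a later snapshot (t1).  Proteins enter a
benchmark either with *no knowledge* (no experimental GO annotation anywhere
at t0) or with *limited knowledge* (annotated in one or two GO namespaces at
t0, but not in the one being evaluated).  Phenotype-ontology benchmarks are
built independently of GO status and come in the no-knowledge flavour only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .ontology import Ontology

#: Evidence codes accepted as experimental support for ground truth.
EXPERIMENTAL_EVIDENCE_CODES: frozenset[str] = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)

GO_NAMESPACES: tuple[str, ...] = ("MFO", "BPO", "CCO")

_GAF_ASPECT = {"F": "MFO", "P": "BPO", "C": "CCO"}


class AnnotationRecord(NamedTuple):
    """One (protein, term) annotation with provenance."""

    protein: str
    term: str
    evidence: str
    namespace: str
    taxon: str = ""


def filter_experimental(
    records: Iterable[AnnotationRecord],
    codes: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> list[AnnotationRecord]:
    """Keep only records whose evidence code is in ``codes``."""
    return [r for r in records if r.evidence in codes]


def read_annotation_tsv(handle: TextIO) -> list[AnnotationRecord]:
    """Read the native 5-column TSV: protein, term, evidence, namespace, taxon."""
    records = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"annotation row has {len(fields)} fields: {line!r}")
        taxon = fields[4] if len(fields) > 4 else ""
        records.append(AnnotationRecord(fields[0], fields[1], fields[2], fields[3], taxon))
    return records


def write_annotation_tsv(records: Iterable[AnnotationRecord], handle: TextIO) -> None:
    for r in records:
        handle.write(f"{r.protein}\t{r.term}\t{r.evidence}\t{r.namespace}\t{r.taxon}\n")


def read_gaf(handle: TextIO) -> list[AnnotationRecord]:
    """Read a GAF 2.x file onto the native record type.

    NOT-qualified rows are dropped; the aspect column is mapped onto the
    namespace tags (F/P/C -> MFO/BPO/CCO); the first taxon id is kept.
    """
    records = []
    for line in handle:
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 13:
            raise ValueError("GAF row with fewer than 13 columns")
        if "NOT" in fields[3].split("|"):
            continue
        aspect = _GAF_ASPECT.get(fields[8])
        if aspect is None:
            continue
        taxon = fields[12].split("|")[0].removeprefix("taxon:")
        records.append(AnnotationRecord(fields[1], fields[4], fields[6], aspect, taxon))
    return records


@dataclass
class AnnotationSnapshot:
    """Propagation-closed, root-excluded per-protein term sets at one time point."""

    label: str
    terms: dict[str, dict[str, frozenset[str]]]  # namespace -> protein -> set
    taxa: dict[str, str] = field(default_factory=dict)
    skipped_unknown: int = 0
    skipped_obsolete: int = 0
    source: str = ""

    def namespaces(self) -> frozenset[str]:
        return frozenset(self.terms)

    def proteins(self, namespace: str | None = None) -> frozenset[str]:
        if namespace is not None:
            return frozenset(self.terms.get(namespace, {}))
        out: set[str] = set()
        for per_ns in self.terms.values():
            out |= set(per_ns)
        return frozenset(out)

    def get(self, protein: str, namespace: str) -> frozenset[str]:
        return self.terms.get(namespace, {}).get(protein, frozenset())

    def annotated_namespaces(self, protein: str) -> frozenset[str]:
        return frozenset(
            ns for ns, per_ns in self.terms.items() if per_ns.get(protein)
        )

    def term_sets(self, namespace: str) -> dict[str, frozenset[str]]:
        return dict(self.terms.get(namespace, {}))


def build_snapshot(
    records: Iterable[AnnotationRecord],
    ontologies: Mapping[str, Ontology],
    label: str = "",
    source: str = "",
) -> AnnotationSnapshot:
    """Aggregate records into closed per-protein, per-namespace term sets.

    Terms are resolved through alt_id mapping, propagated to ancestors, and
    the namespace root is removed (a root-only annotation says nothing).
    Records naming unknown or obsolete terms are skipped and counted.
    """
    raw: dict[str, dict[str, set[str]]] = {ns: {} for ns in ontologies}
    taxa: dict[str, str] = {}
    skipped_unknown = 0
    for rec in records:
        ontology = ontologies.get(rec.namespace)
        if ontology is None:
            skipped_unknown += 1
            continue
        canonical = ontology.canonical_id(rec.term)
        if canonical is None:
            skipped_unknown += 1
            continue
        raw[rec.namespace].setdefault(rec.protein, set()).add(canonical)
        if rec.taxon:
            taxa.setdefault(rec.protein, rec.taxon)

    closed: dict[str, dict[str, frozenset[str]]] = {}
    for ns, per_protein in raw.items():
        roots = ontologies[ns].roots
        ns_out: dict[str, frozenset[str]] = {}
        for protein, terms in per_protein.items():
            full = ontologies[ns].propagate(terms) - roots
            if full:
                ns_out[protein] = full
        closed[ns] = ns_out
    return AnnotationSnapshot(
        label=label,
        terms=closed,
        taxa=taxa,
        skipped_unknown=skipped_unknown,
        source=source,
    )


@dataclass
class BenchmarkSet:
    """Ground truth for one namespace and knowledge type.

    ``proteins`` maps each benchmark protein to its truth set T_i
    (propagation-closed, root-excluded, non-empty).
    """

    namespace: str
    knowledge: str
    proteins: dict[str, frozenset[str]]
    taxa: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def protein_ids(self) -> list[str]:
        return sorted(self.proteins)

    def subset(self, proteins: Iterable[str], knowledge: str | None = None) -> "BenchmarkSet":
        keep = [p for p in proteins if p in self.proteins]
        return BenchmarkSet(
            namespace=self.namespace,
            knowledge=knowledge or self.knowledge,
            proteins={p: self.proteins[p] for p in keep},
            taxa={p: self.taxa[p] for p in keep if p in self.taxa},
        )

    def write_list(self, handle: TextIO) -> None:
        for protein in sorted(self.proteins):
            handle.write(f"{protein}\t{self.knowledge}\n")

    def write_truth(self, handle: TextIO) -> None:
        for protein in sorted(self.proteins):
            for term in sorted(self.proteins[protein]):
                handle.write(f"{protein}\t{term}\n")


def build_benchmarks(
    t0: AnnotationSnapshot,
    t1: AnnotationSnapshot,
    namespace: str,
) -> dict[str, BenchmarkSet]:
    """Construct the no-knowledge / limited-knowledge benchmarks for one namespace.

    For a GO namespace: NK members had no experimental annotation in *any* of
    the three GO namespaces at t0 and gained terms in this namespace by t1;
    LK members had t0 annotations in one or two of the *other* GO namespaces,
    none in this one, and gained terms here by t1.  The truth set is the t1
    term set as stored (curation retractions between snapshots are ignored).
    HPO status is judged against HPO t0 annotations only, and only the NK set
    is produced.
    """
    if namespace not in t1.namespaces():
        raise ValueError(f"t1 snapshot has no annotations for namespace {namespace}")
    t0_universe = t0.proteins()
    t1_universe = t1.proteins()
    missing = t0_universe - t1_universe
    if missing:
        raise ValueError(
            f"{len(missing)} proteins annotated at t0 are absent from t1 "
            f"(e.g. {sorted(missing)[:3]}); snapshots are inconsistent"
        )

    gainers = {
        protein: terms
        for protein, terms in t1.term_sets(namespace).items()
        if terms and not t0.get(protein, namespace)
    }

    nk: dict[str, frozenset[str]] = {}
    lk: dict[str, frozenset[str]] = {}
    if namespace == "HPO":
        # Phenotype benchmarks are selected independently of GO status.
        for protein, terms in gainers.items():
            if not t0.get(protein, "HPO"):
                nk[protein] = terms
        out = {"NK": BenchmarkSet("HPO", "NK", nk)}
    else:
        for protein, terms in gainers.items():
            t0_go = frozenset(
                ns for ns in GO_NAMESPACES if t0.get(protein, ns)
            )
            if not t0_go:
                nk[protein] = terms
            elif namespace not in t0_go:  # one or two other namespaces annotated
                lk[protein] = terms
        out = {
            "NK": BenchmarkSet(namespace, "NK", nk),
            "LK": BenchmarkSet(namespace, "LK", lk),
        }
    for bench in out.values():
        bench.taxa = {
            p: t1.taxa.get(p, t0.taxa.get(p, ""))
            for p in bench.proteins
            if t1.taxa.get(p) or t0.taxa.get(p)
        }
    return out


def split_easy_difficult(
    benchmark: BenchmarkSet,
    identity: Mapping[str, float],
    cutoff: float = 0.60,
) -> dict[str, BenchmarkSet]:
    """Split a benchmark by maximal sequence identity to the training set.

    Proteins at or above ``cutoff`` are *easy* (a close homolog existed in the
    training database); the rest, including proteins with no identity value
    at all, are *difficult*.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"identity cutoff must be in (0,1), got {cutoff}")
    easy = [p for p in benchmark.proteins if identity.get(p, 0.0) >= cutoff]
    difficult = [p for p in benchmark.proteins if identity.get(p, 0.0) < cutoff]
    return {
        "easy": benchmark.subset(easy),
        "difficult": benchmark.subset(difficult),
    }


def taxon_subsets(
    benchmark: BenchmarkSet,
    taxon_map: Mapping[str, str] | None = None,
    min_size: int = 15,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, BenchmarkSet]:
    """Per-species benchmark subsets, keeping only those with >= min_size proteins.

    ``groups`` optionally defines coarser categories (e.g. eukarya/prokarya)
    as taxon collections; group subsets obey the same size floor.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    taxa = dict(benchmark.taxa)
    if taxon_map:
        taxa.update({p: t for p, t in taxon_map.items() if p in benchmark.proteins})
    by_taxon: dict[str, list[str]] = {}
    for protein in benchmark.proteins:
        taxon = taxa.get(protein)
        if taxon:
            by_taxon.setdefault(taxon, []).append(protein)
    out: dict[str, BenchmarkSet] = {}
    for taxon, proteins in sorted(by_taxon.items()):
        if len(proteins) >= min_size:
            out[taxon] = benchmark.subset(proteins)
    if groups:
        for name, members in groups.items():
            member_set = frozenset(members)
            proteins = [p for p, t in taxa.items() if t in member_set]
            if len(proteins) >= min_size:
                out[name] = benchmark.subset(proteins)
    return out


# -- sequence identity (easy/difficult machinery) --------------------------


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(seq1: str, seq2: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: identical columns / alignment length (with gaps)."""
    aligner = aligner or _global_aligner()
    alignment = aligner.align(seq1, seq2)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def max_global_identity(
    queries: Mapping[str, str],
    training: Mapping[str, str],
) -> dict[str, float]:
    """For each query, the maximal global identity over the training sequences."""
    if not training:
        raise ValueError("empty training sequence set")
    aligner = _global_aligner()
    out: dict[str, float] = {}
    for qid, qseq in queries.items():
        out[qid] = max(global_identity(qseq, tseq, aligner) for tseq in training.values())
    return out


def read_fasta(handle: TextIO) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def read_identity_table(handle: TextIO) -> dict[str, float]:
    """Precomputed 2-column TSV (protein, max identity) bypassing alignment."""
    out: dict[str, float] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        protein, value = line.split("\t")[:2]
        ident = float(value)
        if not 0.0 <= ident <= 1.0:
            raise ValueError(f"identity {ident} for {protein} outside [0,1]")
        out[protein] = ident
    return out
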