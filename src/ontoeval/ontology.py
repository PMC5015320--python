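"""Ontology handling: OBO parsing, DAG queries and information content.

The evaluation framework treats an annotation ontology (Gene Ontology or the
Human Phenotype Ontology) as a rooted directed acyclic graph whose edges are
the ``is_a`` and ``part_of`` relations.  Annotating a protein with a term
implies annotation with every ancestor of that term (the true-path rule), so
all downstream machinery works with propagation-closed term sets.

Per-term information content ic(f) is estimated from an annotation corpus as
the negative binary logarithm of the conditional probability that f is
present in a protein's (closed) annotation given that all parents of f are
present.  Roots carry zero information by construction.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

#: Relations that participate in ancestry and propagation.  Other OBO
#: relationship types (regulates, occurs_in, ...) are deliberately ignored.
PROPAGATION_RELATIONS: tuple[str, ...] = ("is_a", "part_of")

#: Canonical namespace tags used throughout the package.
NAMESPACES: tuple[str, ...] = ("MFO", "BPO", "CCO", "HPO")

_NAMESPACE_ALIASES = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "human_phenotype": "HPO",
    "phenotypic_abnormality": "HPO",
    "MFO": "MFO",
    "BPO": "BPO",
    "CCO": "CCO",
    "HPO": "HPO",
}


class OntologyError(ValueError):
    """Raised for structural problems: cycles, unknown terms, bad namespaces."""


def normalize_namespace(ns: str) -> str:
    try:
        return _NAMESPACE_ALIASES[ns]
    except KeyError:
        raise OntologyError(f"unknown namespace {ns!r}") from None


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` maps a relation name (``is_a`` / ``part_of``) to the set of
    parent term ids reached through that relation.
    """

    id: str
    name: str
    namespace: str
    parents: Mapping[str, frozenset[str]] = field(default_factory=dict)
    obsolete: bool = False

    @property
    def parent_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.parents.values():
            out |= ids
        return frozenset(out)


class Ontology:
    """A rooted DAG of terms connected by is_a / part_of edges.

    Parameters
    ----------
    terms:
        Mapping of term id to :class:`Term`.  Parent references must resolve
        within this mapping; a cycle is a hard error.
    namespace:
        The sub-ontology this graph represents (``None`` for a mixed graph,
        e.g. full GO before splitting by namespace).
    alt_ids:
        Mapping of secondary accession to canonical term id.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        namespace: str | None = None,
        alt_ids: Mapping[str, str] | None = None,
    ):
        self.terms: dict[str, Term] = dict(terms)
        self.namespace = namespace
        self.alt_ids: dict[str, str] = dict(alt_ids or {})

        graph = nx.DiGraph()  # edges point child -> parent
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for relation, parents in term.parents.items():
                if relation not in PROPAGATION_RELATIONS:
                    continue
                for parent in parents:
                    if parent not in self.terms:
                        raise OntologyError(
                            f"term {term.id} references unknown parent {parent}"
                        )
                    graph.add_edge(term.id, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"ontology graph contains a cycle: {path}")
        self._graph = graph
        self.roots: frozenset[str] = frozenset(
            t for t in self.terms if graph.out_degree(t) == 0
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic queries -----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def root(self) -> str:
        """The unique root, when there is one."""
        if len(self.roots) != 1:
            raise OntologyError(
                f"ontology has {len(self.roots)} roots; a single root was expected"
            )
        return next(iter(self.roots))

    def canonical_id(self, term_id: str) -> str | None:
        """Resolve alt_ids to the canonical accession; None if unknown."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via is_a/part_of, excluding itself."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id}")
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term_id))
            self._ancestor_cache[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms from which ``term_id`` is reachable, excluding itself."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id}")
        return frozenset(nx.ancestors(self._graph, term_id))

    def children(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id}")
        return frozenset(self._graph.predecessors(term_id))

    def leaves(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if self._graph.in_degree(t) == 0)

    def propagate(self, term_ids: Iterable[str]) -> frozenset[str]:
        """Propagation closure: the input terms plus all their ancestors."""
        out: set[str] = set()
        for term in term_ids:
            if term not in self.terms:
                raise OntologyError(f"unknown term {term}")
            out.add(term)
            out |= self.ancestors(term)
        return frozenset(out)

    def is_closed(self, term_ids: Iterable[str]) -> bool:
        ts = frozenset(term_ids)
        return self.propagate(ts) == ts

    # -- derived ontologies ------------------------------------------------

    def extract_subontology(self, root: str, namespace: str | None = None) -> "Ontology":
        """Restrict to ``root`` and its descendants, dropping edges that leave
        the subtree.  Used to carve the phenotypic-abnormality subtree out of
        HPO, or any rooted sub-DAG of interest.
        """
        if root not in self.terms:
            raise OntologyError(f"unknown root {root}")
        keep = {root} | set(self.descendants(root))
        terms = {
            tid: _restrict_term(self.terms[tid], keep) for tid in keep
        }
        alt = {a: c for a, c in self.alt_ids.items() if c in keep}
        return Ontology(terms, namespace=namespace or self.namespace, alt_ids=alt)

    def split_namespaces(self) -> dict[str, "Ontology"]:
        """Partition a mixed graph (e.g. full GO) into per-namespace ontologies."""
        by_ns: dict[str, dict[str, Term]] = {}
        for term in self.terms.values():
            by_ns.setdefault(term.namespace, {})[term.id] = term
        out: dict[str, Ontology] = {}
        for ns, terms in by_ns.items():
            keep = set(terms)
            restricted = {tid: _restrict_term(t, keep) for tid, t in terms.items()}
            alt = {a: c for a, c in self.alt_ids.items() if c in keep}
            out[ns] = Ontology(restricted, namespace=ns, alt_ids=alt)
        return out


def _restrict_term(term: Term, keep: set[str]) -> Term:
    parents = {
        rel: frozenset(p for p in ids if p in keep)
        for rel, ids in term.parents.items()
    }
    parents = {rel: ids for rel, ids in parents.items() if ids}
    return Term(term.id, term.name, term.namespace, parents, term.obsolete)


# -- OBO parsing -----------------------------------------------------------


def parse_obo(
    source: str | TextIO,
    namespace: str | None = None,
    default_namespace: str | None = None,
) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Parameters
    ----------
    source:
        Path or open text stream.
    namespace:
        Namespace tag for the returned graph; inferred when every term agrees.
    default_namespace:
        Namespace assigned to stanzas lacking one (HPO releases often omit it).

    Only ``is_a`` and ``relationship: part_of`` edges are retained.  Obsolete
    terms are dropped; ``alt_id`` accessions are kept as a mapping onto their
    canonical ids.
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as handle:
            text = handle.read()
    else:
        text = source.read()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    seen_ns: set[str] = set()
    for tid, data in graph.nodes(data=True):
        if not data:
            continue  # implicit node from a dangling edge; caught below
        if str(data.get("is_obsolete", "false")).lower() == "true":
            continue
        raw_ns = data.get("namespace", default_namespace)
        if raw_ns is None:
            raise OntologyError(f"term {tid} has no namespace and no default given")
        ns = normalize_namespace(raw_ns)
        seen_ns.add(ns)
        parents: dict[str, set[str]] = {}
        for parent in data.get("is_a", []):
            parents.setdefault("is_a", set()).add(parent.split("!")[0].strip())
        for rel_line in data.get("relationship", []):
            parts = rel_line.split("!")[0].split()
            if len(parts) >= 2 and parts[0] == "part_of":
                parents.setdefault("part_of", set()).add(parts[1])
        terms[tid] = Term(
            id=tid,
            name=data.get("name", tid),
            namespace=ns,
            parents={rel: frozenset(ids) for rel, ids in parents.items()},
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid

    # Parents pointing at obsolete (dropped) stanzas are a hard error, same
    # as parents never declared: the graph would silently lose paths to root.
    for term in terms.values():
        for parent in term.parent_ids:
            if parent not in terms:
                raise OntologyError(
                    f"term {term.id} references unknown parent {parent}"
                )

    if namespace is None and len(seen_ns) == 1:
        namespace = next(iter(seen_ns))
    return Ontology(terms, namespace=namespace, alt_ids=alt_ids)


def write_obo(ontology: Ontology, handle: TextIO) -> None:
    """Serialize an ontology back to a minimal OBO 1.2 flat file.

    Deterministic: terms and parents are written in sorted order, so equal
    ontologies produce byte-identical files.
    """
    _ns_obo = {"MFO": "molecular_function", "BPO": "biological_process",
               "CCO": "cellular_component", "HPO": "human_phenotype"}
    handle.write("format-version: 1.2\n")
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        handle.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
        handle.write(f"namespace: {_ns_obo.get(term.namespace, term.namespace)}\n")
        for parent in sorted(term.parents.get("is_a", ())):
            handle.write(f"is_a: {parent}\n")
        for parent in sorted(term.parents.get("part_of", ())):
            handle.write(f"relationship: part_of {parent}\n")


def intersect_ontologies(o1: Ontology, o2: Ontology) -> Ontology:
    """Intersection of two snapshots of the same sub-ontology.

    Keeps the terms present in both and the edges present in both; used to
    build a common ontology version when comparing assessments made against
    different releases, so ontology drift does not contaminate the comparison.
    """
    if o1.namespace != o2.namespace:
        raise OntologyError(
            f"namespace mismatch: {o1.namespace!r} vs {o2.namespace!r}"
        )
    keep = set(o1.terms) & set(o2.terms)
    terms: dict[str, Term] = {}
    for tid in keep:
        t1, t2 = o1.terms[tid], o2.terms[tid]
        parents: dict[str, frozenset[str]] = {}
        for rel in PROPAGATION_RELATIONS:
            common = (
                frozenset(p for p in t1.parents.get(rel, ()) if p in keep)
                & frozenset(t2.parents.get(rel, frozenset()))
            )
            if common:
                parents[rel] = common
        terms[tid] = Term(tid, t1.name, t1.namespace, parents)
    alt = {a: c for a, c in o1.alt_ids.items() if c in keep and o2.alt_ids.get(a) == c}
    return Ontology(terms, namespace=o1.namespace, alt_ids=alt)


# -- information content ---------------------------------------------------


@dataclass
class InformationContentTable:
    """Per-term information content, in bits, estimated from a corpus.

    ``capped`` lists terms whose conditional frequency could not be estimated
    (never observed, or parents never co-observed); they carry the ceiling
    value ``-log2(1/(corpus_size+1))`` so semantic-distance metrics stay
    finite.
    """

    ic: dict[str, float]
    corpus_size: int
    capped: frozenset[str] = frozenset()

    @property
    def cap(self) -> float:
        return -math.log2(1.0 / (self.corpus_size + 1))

    def __getitem__(self, term: str) -> float:
        value = self.ic.get(term)
        if value is None:
            return self.cap
        return value

    def get(self, term: str, default: float | None = None) -> float:
        if default is None:
            return self[term]
        return self.ic.get(term, default)

    def total(self, terms: Iterable[str]) -> float:
        return sum(self[t] for t in terms)

    def to_tsv(self, handle: TextIO) -> None:
        for term in sorted(self.ic):
            flag = "\tcapped" if term in self.capped else ""
            handle.write(f"{term}\t{self.ic[term]:.10g}{flag}\n")

    @classmethod
    def from_tsv(cls, handle: TextIO, corpus_size: int) -> "InformationContentTable":
        ic: dict[str, float] = {}
        capped: set[str] = set()
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if not fields[0]:
                continue
            ic[fields[0]] = float(fields[1])
            if len(fields) > 2 and fields[2] == "capped":
                capped.add(fields[0])
        return cls(ic, corpus_size, frozenset(capped))


def estimate_information_content(
    ontology: Ontology,
    corpus: Iterable[Iterable[str]],
) -> InformationContentTable:
    """Estimate ic(f) = -log2 P(f | all parents of f) from closed term sets.

    Every corpus term set must already be propagation-closed (the numerator
    count for f is then simply the number of proteins carrying f).  Terms
    whose parents never co-occur in the corpus, or which are never observed,
    get the cap value and are flagged.
    """
    closed_sets = [frozenset(s) for s in corpus]
    if not closed_sets:
        raise ValueError("empty annotation corpus")
    for s in closed_sets:
        if not ontology.is_closed(s):
            raise ValueError(
                "corpus term set is not propagation-closed; propagate before "
                "estimating information content"
            )

    n_with: dict[str, int] = {}
    for s in closed_sets:
        for term in s:
            n_with[term] = n_with.get(term, 0) + 1

    size = len(closed_sets)
    table: dict[str, float] = {}
    capped: set[str] = set()
    cap = -math.log2(1.0 / (size + 1))
    for tid, term in ontology.terms.items():
        if tid in ontology.roots:
            table[tid] = 0.0
            continue
        parents = term.parent_ids
        numerator = n_with.get(tid, 0)
        denominator = sum(1 for s in closed_sets if parents <= s)
        if numerator == 0 or denominator == 0:
            table[tid] = cap
            capped.add(tid)
        else:
            table[tid] = -math.log2(numerator / denominator)
    return InformationContentTable(table, size, frozenset(capped))
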