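import pytest

from ontoeval.ontology import Ontology, Term


def _term(tid, ns, is_a=(), part_of=()):
    parents = {}
    if is_a:
        parents["is_a"] = frozenset(is_a)
    if part_of:
        parents["part_of"] = frozenset(part_of)
    return Term(tid, tid, ns, parents)


@pytest.fixture
def chain_ontology():
    """root <- a <- b, single namespace."""
    terms = {
        "T:root": _term("T:root", "MFO"),
        "T:a": _term("T:a", "MFO", is_a=["T:root"]),
        "T:b": _term("T:b", "MFO", is_a=["T:a"]),
    }
    return Ontology(terms, namespace="MFO")


@pytest.fixture
def diamond_ontology():
    """root <- {a, b} <- c: c has two parents, plus a spare leaf d under a."""
    terms = {
        "T:root": _term("T:root", "MFO"),
        "T:a": _term("T:a", "MFO", is_a=["T:root"]),
        "T:b": _term("T:b", "MFO", part_of=["T:root"]),
        "T:c": _term("T:c", "MFO", is_a=["T:a"], part_of=["T:b"]),
        "T:d": _term("T:d", "MFO", is_a=["T:a"]),
    }
    return Ontology(terms, namespace="MFO")


TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: a
namespace: molecular_function
alt_id: GO:0000099
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
namespace: molecular_function
is_a: GO:0000002 ! a
relationship: part_of GO:0000001 ! root
relationship: regulates GO:0000002 ! ignored

[Term]
id: GO:0000004
name: gone
namespace: molecular_function
is_obsolete: true
"""


@pytest.fixture
def toy_obo_text():
    return TOY_OBO
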