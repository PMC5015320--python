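"""Seeded random small instances shared by oracle-equivalence tests."""

import numpy as np

from ontoeval.annotations import BenchmarkSet
from ontoeval.ontology import estimate_information_content, Ontology
from ontoeval.predictions import from_score_map, prepare_predictions
from ontoeval.synthetic import FixtureSpec, make_ontology


def random_instance(seed, max_proteins=10):
    """A random (ontology, benchmark, propagated predictions, ic table) tuple.

    The ontology has at most 13 terms (depth 2, branching 3, diamonds);
    truth sets are random closed leaf selections; raw predictions score a
    random term subset on the 0.01 grid, with some proteins left unpredicted,
    then go through the standard validate+propagate path.
    """
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        seed=int(seed) % 2**31, depth=2, branching=3, diamond_fraction=0.3
    )
    ontology = make_ontology(spec)
    terms = sorted(set(ontology.terms) - ontology.roots)
    leaves = sorted(ontology.leaves())

    n = int(rng.integers(1, max_proteins + 1))
    truth = {}
    for i in range(n):
        k = int(rng.integers(1, 4))
        picked = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        truth[f"P{i}"] = ontology.propagate([leaves[j] for j in picked]) - ontology.roots
    benchmark = BenchmarkSet("MFO", "NK", truth)

    raw = {}
    for i in range(n):
        if rng.random() < 0.2:
            continue  # unpredicted protein
        k = int(rng.integers(1, len(terms) + 1))
        picked = rng.choice(len(terms), size=k, replace=False)
        raw[f"P{i}"] = {
            terms[j]: int(rng.integers(1, 101)) / 100.0 for j in picked
        }
    predictions, _ = prepare_predictions(from_score_map("rand", raw), ontology)

    corpus_n = int(rng.integers(3, 20))
    corpus = []
    for _ in range(corpus_n):
        k = int(rng.integers(1, 4))
        picked = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        corpus.append(ontology.propagate([leaves[j] for j in picked]))
    ic = estimate_information_content(ontology, corpus)
    return ontology, benchmark, predictions, ic
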