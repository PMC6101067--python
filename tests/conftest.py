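"""Shared test fixtures.

``four_disease`` is the small hand-built corpus used for closed-form
checks: 4 diseases, a root with two branches.  Terms A and B are siblings
under M; C is a second child of the root.

    root ── M ── A   (disease d1)
      │     └── B    (disease d2)
      └─── C         (diseases d3, d4)

After propagation |D_A| = |D_B| = 1, |D_M| = |D_C| = 2, |D_root| = 4, so
IC(A) = IC(B) = ln 4, IC(M) = ln 2 and the sibling pair (A, B) has the
hand-computable scores asserted across the suite.
"""

import math

import pytest

from phenokit.fixtures import FixtureSpec, generate_corpus, generate_ontology
from phenokit.ontology import (
    AnnotationCorpus,
    OntologyGraph,
    Term,
    compute_ic,
    propagate,
)

ROOT, M, A, B, C = "HP:0000001", "HP:0000002", "HP:0000003", "HP:0000004", "HP:0000005"

LN2 = math.log(2.0)
LN4 = math.log(4.0)


def build_four_disease():
    terms = {
        ROOT: Term(id=ROOT, name="phenotypic abnormality"),
        M: Term(id=M, name="abnormal kidney morphology", synonyms=("kidney anomaly",)),
        A: Term(id=A, name="renal agenesis"),
        B: Term(id=B, name="renal cyst"),
        C: Term(id=C, name="abnormal heart"),
    }
    edges = [(M, ROOT), (A, M), (B, M), (C, ROOT)]
    g = OntologyGraph(terms, edges)
    corpus = AnnotationCorpus(
        entity_kind="disease",
        direct={
            "DIS:0001": frozenset({A}),
            "DIS:0002": frozenset({B}),
            "DIS:0003": frozenset({C}),
            "DIS:0004": frozenset({C}),
        },
    )
    corpus = propagate(g, corpus)
    return g, corpus, compute_ic(g, corpus)


@pytest.fixture(scope="session")
def four_disease():
    return build_four_disease()


def make_random_world(seed, n_terms=40, max_parents=3, n_entities=12,
                      annotations=(2, 4), entity_kind="gene"):
    """Random ontology + propagated corpus + IC table for oracle tests."""
    spec = FixtureSpec(
        n_terms=n_terms,
        max_parents=max_parents,
        n_entities=n_entities,
        annotations_per_entity=annotations,
        seed=seed,
    )
    g = generate_ontology(spec)
    corpus = propagate(g, generate_corpus(g, spec, entity_kind=entity_kind))
    return g, corpus, compute_ic(g, corpus)


@pytest.fixture(scope="session")
def random_world():
    return make_random_world(seed=11)


def brute_force_ancestors(g: OntologyGraph, t: str) -> set[str]:
    """Exhaustive DFS reachability along child->parent edges (oracle)."""
    seen: set[str] = set()
    stack = [t]
    while stack:
        node = stack.pop()
        for parent in g.dag.successors(node):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen
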