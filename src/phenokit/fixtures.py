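"""Seeded synthetic ontologies, annotation corpora and noisy profiles.

Everything in the test suite runs on synthetic data from this module, so
no ontology download is required.  The generator emulates the gross shape
of an HPO-style resource: a single-rooted ``is_a`` DAG (each new term
attaches to one or more earlier terms, which guarantees acyclicity), and
entities annotated preferentially to leaves (annotations in real corpora
are made at the most specific term available; the leaf bias defaults to
0.7).  A master seed fans out to per-component child seeds through a
fixed spawn rule, so adding a new fixture never perturbs existing ones
and regeneration is byte-identical per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ontology import AnnotationCorpus, OntologyGraph, Term
from .phenosim import PatientProfile

__all__ = [
    "FixtureSpec",
    "generate_ontology",
    "generate_corpus",
    "generate_noisy_profile",
    "write_annotations_tsv",
]

# fixed spawn keys: one lane per component
_ONTOLOGY_LANE = 0
_CORPUS_LANE = 1
_PROFILE_LANE = 2

DEFAULT_LEAF_BIAS = 0.7


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_terms: int = 40
    max_parents: int = 3
    n_entities: int = 20
    annotations_per_entity: tuple[int, int] = (2, 4)
    n_noise_terms: int = 2
    seed: int = 0
    leaf_bias: float = DEFAULT_LEAF_BIAS

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")
        lo, hi = self.annotations_per_entity
        if not (1 <= lo <= hi):
            raise ValueError("annotations_per_entity must satisfy 1 <= lo <= hi")
        if self.n_noise_terms < 0:
            raise ValueError("n_noise_terms must be >= 0")
        if not 0.0 <= self.leaf_bias <= 1.0:
            raise ValueError("leaf_bias must lie in [0, 1]")


def _lane_rng(seed: int, lane: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(lane,)))


def _term_id(i: int) -> str:
    return f"FP:{i:07d}"


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Single-rooted random DAG; term 0 is the root.

    Each later term attaches to 1..max_parents uniformly chosen earlier
    terms, so the graph is acyclic by construction and every node reaches
    the root.  With ``max_parents=1`` the output is a tree.
    """
    rng = _lane_rng(spec.seed, _ONTOLOGY_LANE)
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str]] = []
    for i in range(spec.n_terms):
        tid = _term_id(i)
        terms[tid] = Term(
            id=tid,
            name=f"term {i:04d}",
            synonyms=(f"syn {i:04d} a",),
        )
        if i == 0:
            continue
        n_parents = int(rng.integers(1, min(spec.max_parents, i) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in sorted(int(x) for x in parents):
            edges.append((tid, _term_id(p)))
    return OntologyGraph(terms, edges)


def generate_corpus(
    g: OntologyGraph, spec: FixtureSpec, entity_kind: str = "gene"
) -> AnnotationCorpus:
    """Random direct annotations, biased toward leaves.

    Each of ``n_entities`` entities draws a uniform count in
    ``annotations_per_entity`` of distinct non-root terms; each draw picks
    a leaf with probability ``leaf_bias``, otherwise an internal non-root
    term (or a leaf again if none exist).
    """
    rng = _lane_rng(spec.seed, _CORPUS_LANE)
    leaves = [t for t in g.leaves() if t != g.root]
    internal = [t for t in g.active_terms() if t != g.root and t not in set(leaves)]
    available = len(leaves) + len(internal)
    lo, hi = spec.annotations_per_entity
    if hi > available:
        raise ValueError(
            f"annotations_per_entity upper bound {hi} exceeds the "
            f"{available} available non-root terms"
        )
    prefix = "GENE" if entity_kind == "gene" else "DIS"
    direct: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for e in range(1, spec.n_entities + 1):
        eid = f"{prefix}:{e:04d}"
        names[eid] = f"{entity_kind} {e:04d}"
        count = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < count:
            pool = leaves if (rng.random() < spec.leaf_bias or not internal) else internal
            chosen.add(pool[int(rng.integers(len(pool)))])
        direct[eid] = frozenset(chosen)
    return AnnotationCorpus(entity_kind=entity_kind, direct=direct, entity_names=names)


def generate_noisy_profile(
    g: OntologyGraph,
    corpus: AnnotationCorpus,
    entity: str,
    n_noise: int,
    seed: int,
) -> tuple[PatientProfile, frozenset[str]]:
    """A patient profile: one entity's annotations plus planted noise terms.

    Noise terms are drawn uniformly without replacement from the active
    terms outside the entity's direct annotation set; the planted set is
    returned for recovery scoring.
    """
    if entity not in corpus.direct or not corpus.direct[entity]:
        raise ValueError(f"entity {entity!r} has no direct annotations")
    true_terms = corpus.direct[entity]
    outside = sorted(set(g.active_terms()) - true_terms)
    if n_noise > len(outside):
        raise ValueError(
            f"n_noise={n_noise} exceeds the {len(outside)} terms outside the profile"
        )
    rng = _lane_rng(seed, _PROFILE_LANE)
    noise = frozenset(
        str(t) for t in rng.choice(np.array(outside), size=n_noise, replace=False)
    )
    profile = PatientProfile(terms=true_terms | noise, label=f"{entity}+{n_noise}noise")
    return profile, noise


def write_annotations_tsv(corpus: AnnotationCorpus, path) -> None:
    """3-column annotation TSV (entity_id, entity_name, term_id), sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic {corpus.entity_kind} annotations\n")
        for eid in sorted(corpus.direct):
            name = corpus.entity_names.get(eid, eid)
            for term in sorted(corpus.direct[eid]):
                fh.write(f"{eid}\t{name}\t{term}\n")
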