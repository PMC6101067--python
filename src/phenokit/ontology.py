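"""Ontology DAG, annotation corpus, information content and MICA.

The Human Phenotype Ontology (and any HPO-shaped OBO ontology) is a rooted
``is_a`` directed acyclic graph.  Terms describe phenotypic abnormalities;
diseases or genes are *annotated* to terms.  Under the true-path rule an
annotation to a term implies annotation to every ancestor, so annotation
sets grow monotonically toward the root.  The information content of a term
``t`` with respect to an annotation corpus is

    IC(t) = -log(|D_t| / |D|)

where ``D_t`` is the set of entities annotated (after propagation) to ``t``
and ``D`` the set annotated to the root, i.e. all annotated entities.  The
Most Informative Common Ancestor (MICA) of two terms is the common ancestor
with maximal IC; it is the shared quantity behind all the IC-based
similarity measures in :mod:`phenokit.term_similarity`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "OntologyGraph",
    "AnnotationCorpus",
    "ICTable",
    "OntologyError",
    "UnknownTermError",
    "load_obo",
    "write_obo",
    "read_annotations",
    "propagate",
    "compute_ic",
    "mica",
]


class OntologyError(ValueError):
    """Raised for structural ontology problems (cycles, multiple roots)."""


class UnknownTermError(KeyError):
    """Raised when a term id cannot be resolved to a usable ontology term."""

    def __init__(self, term_id: str, reason: str = "unknown term"):
        super().__init__(f"{reason}: {term_id!r}")
        self.term_id = term_id


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    synonyms: tuple[str, ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False


class OntologyGraph:
    """Rooted ``is_a`` DAG of terms.

    Edges run child -> parent.  Obsolete terms are retained for id lookup
    but excluded from the DAG and from every similarity computation.
    Construction validates acyclicity and single-rootedness.
    """

    def __init__(self, terms: dict[str, Term], edges: list[tuple[str, str]]):
        self.terms: dict[str, Term] = dict(terms)
        self.alt_to_primary: dict[str, str] = {}
        for t in self.terms.values():
            for alt in t.alt_ids:
                if alt in self.alt_to_primary and self.alt_to_primary[alt] != t.id:
                    raise OntologyError(
                        f"alt_id {alt!r} maps to both "
                        f"{self.alt_to_primary[alt]!r} and {t.id!r}"
                    )
                self.alt_to_primary[alt] = t.id

        self.dag = nx.DiGraph()
        for t in self.terms.values():
            if not t.obsolete:
                self.dag.add_node(t.id)
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyError(f"edge ({child!r}, {parent!r}) references unknown term")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                continue  # obsolete terms carry no edges
            self.dag.add_edge(child, parent)

        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise OntologyError(f"is_a cycle detected involving {cycle[0][0]!r}")

        roots = sorted(n for n in self.dag.nodes if self.dag.out_degree(n) == 0)
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {roots!r}")
        self.root: str = roots[0]
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- lookup ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an id (possibly an alt_id) to its primary id.

        Raises :class:`UnknownTermError` for unknown ids.  Obsolete ids
        resolve (they exist) but are rejected by DAG operations.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_to_primary:
            return self.alt_to_primary[term_id]
        raise UnknownTermError(term_id)

    def active(self, term_id: str) -> str:
        """Resolve to a primary, non-obsolete id or raise."""
        primary = self.resolve(term_id)
        if self.terms[primary].obsolete:
            raise UnknownTermError(term_id, "obsolete term")
        return primary

    def active_terms(self) -> list[str]:
        return sorted(self.dag.nodes)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.dag.nodes if self.dag.in_degree(n) == 0)

    # -- DAG operations -------------------------------------------------

    def ancestors(self, term_id: str, inclusive: bool = False) -> frozenset[str]:
        """All terms reachable from ``term_id`` via child->parent edges."""
        t = self.active(term_id)
        cached = self._ancestor_cache.get(t)
        if cached is None:
            # reachable along the child->parent direction
            cached = frozenset(nx.descendants(self.dag, t)) | {t}
            self._ancestor_cache[t] = cached
        return cached if inclusive else cached - {t}

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self.dag.successors(self.active(term_id)))

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self.dag.predecessors(self.active(term_id)))


@dataclass(frozen=True)
class AnnotationCorpus:
    """Entity (disease or gene) -> phenotype-term annotation sets.

    ``direct`` holds the annotations as given; ``propagated`` the closure
    under ancestors (the true-path rule), or ``None`` until
    :func:`propagate` has run.
    """

    entity_kind: str  # "disease" | "gene"
    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] | None = None
    entity_names: dict[str, str] = field(default_factory=dict)

    def entities(self) -> list[str]:
        return sorted(self.direct)

    @property
    def n_entities(self) -> int:
        return len(self.direct)

    def annotated_terms(self) -> list[str]:
        """Terms with at least one direct annotation, sorted."""
        out: set[str] = set()
        for ts in self.direct.values():
            out |= ts
        return sorted(out)


@dataclass(frozen=True)
class ICTable:
    """Per-term information content plus the annotation counts behind it.

    ``counts[t]`` is |D_t| after propagation (0 for never-annotated terms);
    IC values use ``max(|D_t|, 1)`` so every term gets a finite IC equal to
    the maximum observed specificity.  ``base`` records the logarithm base.
    """

    ic: dict[str, float]
    counts: dict[str, int]
    n_entities: int
    base: float = math.e

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


# ---------------------------------------------------------------------------
# OBO I/O
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'"(.*?)"')


def _parse_synonyms(raw: list[str] | None) -> tuple[str, ...]:
    if not raw:
        return ()
    out = []
    for s in raw:
        m = _SYNONYM_RE.search(s)
        out.append(m.group(1) if m else s)
    return tuple(out)


def load_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Only ``is_a`` relations become DAG edges; obsolete terms are retained
    for lookup but excluded from the DAG.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, Term] = {}
    for node, data in multigraph.nodes(data=True):
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            synonyms=_parse_synonyms(data.get("synonym")),
            alt_ids=tuple(data.get("alt_id", ())),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key == "is_a"
    ]
    return OntologyGraph(terms, edges)


def write_obo(graph: OntologyGraph, path) -> None:
    """Write a minimal, deterministic OBO 1.2 file (fixture round-trips)."""
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(graph.terms):
        t = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        if t.name:
            lines.append(f"name: {t.name}")
        for alt in t.alt_ids:
            lines.append(f"alt_id: {alt}")
        for syn in t.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if t.obsolete:
            lines.append("is_obsolete: true")
        else:
            for parent in sorted(graph.dag.successors(t.id)):
                lines.append(f"is_a: {parent} ! {graph.terms[parent].name}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path,
    graph: OntologyGraph,
    entity_kind: str = "disease",
    columns: tuple[int, int, int] = (0, 1, 2),
) -> AnnotationCorpus:
    """Read a 3-column annotation TSV (entity_id, entity_name, term_id).

    ``#`` comment lines are skipped.  ``columns`` maps the (entity_id,
    entity_name, term_id) roles onto 0-based column indices, covering
    HPOA-like and genes_to_phenotype-like dialects.  Records annotating
    unknown or obsolete terms are skipped with a logged warning; alt_ids
    are resolved to primary ids.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    eid_col, name_col, term_col = columns
    direct: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        eid = row[eid_col]
        term = row[term_col]
        try:
            primary = graph.active(term)
        except UnknownTermError as exc:
            logger.warning("skipping annotation %s -> %s (%s)", eid, term, exc)
            skipped += 1
            continue
        direct.setdefault(eid, set()).add(primary)
        names.setdefault(eid, row[name_col])
    if skipped:
        logger.warning("%d annotation records skipped", skipped)
    return AnnotationCorpus(
        entity_kind=entity_kind,
        direct={e: frozenset(ts) for e, ts in direct.items()},
        entity_names=names,
    )


def propagate(graph: OntologyGraph, corpus: AnnotationCorpus) -> AnnotationCorpus:
    """Close each entity's annotation set under ancestors (true-path rule).

    Idempotent; ``direct`` is carried through unchanged.
    """
    propagated = {
        e: frozenset().union(*(graph.ancestors(t, inclusive=True) for t in ts))
        if ts
        else frozenset()
        for e, ts in corpus.direct.items()
    }
    return replace(corpus, propagated=propagated)


# ---------------------------------------------------------------------------
# Information content / MICA
# ---------------------------------------------------------------------------

def compute_ic(
    graph: OntologyGraph, corpus: AnnotationCorpus, base: float = math.e
) -> ICTable:
    """IC(t) = -log(max(|D_t|,1)/|D|) for every non-obsolete term."""
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated before computing IC")
    n = corpus.n_entities
    if n < 1:
        raise ValueError("empty corpus: no annotated entities")
    counts: dict[str, int] = {t: 0 for t in graph.dag.nodes}
    for terms in corpus.propagated.values():
        for t in terms:
            counts[t] += 1
    log = math.log
    scale = log(base)
    # "+ 0.0" normalizes IEEE negative zero from -log(1.0)
    ic = {t: -log(max(c, 1) / n) / scale + 0.0 for t, c in counts.items()}
    return ICTable(ic=ic, counts=counts, n_entities=n, base=base)


def mica(graph: OntologyGraph, ic: ICTable, a: str, b: str) -> str:
    """Most informative common ancestor of ``a`` and ``b`` (inclusive).

    Ties on IC break to the lexicographically smallest id.
    """
    common = graph.ancestors(a, inclusive=True) & graph.ancestors(b, inclusive=True)
    if not common:  # cannot happen in a single-rooted DAG with valid terms
        raise OntologyError(f"no common ancestor for {a!r}, {b!r}")
    best = max(ic.ic[t] for t in common)
    return min(t for t in common if ic.ic[t] == best)
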