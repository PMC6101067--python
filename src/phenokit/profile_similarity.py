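"""Phenotype-set, gene and disease similarity; candidate ranking;
permutation p-values.

Set similarity aggregates a pairwise term measure ``s`` over two term sets
A and B.  The default aggregation is the symmetric best-match average

    BMA(A, B) = 1/2 * ( mean_{a in A} max_{b in B} s(a,b)
                      + mean_{b in B} max_{a in A} s(a,b) ),

the standard choice for Phenomizer-style profile comparison; ``max`` and
``avg`` (grand mean over all cross pairs) are also available.  Gene and
disease similarity is set similarity over the entities' direct annotation
sets.

Significance is assessed by permutation: the null redraws the query as a
uniform random term set of the same size from the annotated-term universe,
and the p-value uses the add-one estimator

    p = (1 + #{null >= observed}) / (M + 1),

which is bounded below by 1/(M+1) and never exactly zero.  Rankings also
report Benjamini-Hochberg q-values across candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationCorpus, ICTable, OntologyGraph
from .phenosim import PatientProfile
from .term_similarity import get_measure

logger = logging.getLogger(__name__)

__all__ = [
    "SetSimilarityResult",
    "Ranking",
    "set_similarity",
    "entity_similarity",
    "predict_associations",
    "empirical_pvalue",
]

AGGREGATIONS = ("bma", "max", "avg")
DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class SetSimilarityResult:
    score: float
    method: str
    aggregation: str
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class Ranking:
    """Ranked candidate entities for a query profile.

    ``candidates`` rows: (entity id, score, p_value or None, q_value or None),
    sorted by descending score with lexicographic tie-break.
    """

    query: PatientProfile
    candidates: list[tuple[str, float, float | None, float | None]]
    target_kind: str
    skipped: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tentity\tscore\tp_value\tq_value\n")
            for rank, (entity, score, p, q) in enumerate(self.candidates, start=1):
                p_s = "NA" if p is None else repr(p)
                q_s = "NA" if q is None else repr(q)
                fh.write(f"{rank}\t{entity}\t{score!r}\t{p_s}\t{q_s}\n")


def _aggregate(
    A: Sequence[str], B: Sequence[str], s: Callable[[str, str], float], aggregation: str
) -> float:
    cross = np.array([[s(a, b) for b in B] for a in A])
    if aggregation == "bma":
        return float((cross.max(axis=1).mean() + cross.max(axis=0).mean()) / 2.0)
    if aggregation == "max":
        return float(cross.max())
    if aggregation == "avg":
        return float(cross.mean())
    raise ValueError(f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}")


def set_similarity(
    A: Iterable[str],
    B: Iterable[str],
    g: OntologyGraph,
    ic: ICTable,
    measure: str | Callable[[str, str], float] = "lin",
    aggregation: str = "bma",
) -> SetSimilarityResult:
    """Aggregate a pairwise term measure over two phenotype-term sets."""
    A = sorted({g.active(t) for t in A})
    B = sorted({g.active(t) for t in B})
    if not A or not B:
        raise ValueError("both term sets must be non-empty after validation")
    if callable(measure):
        s, name = measure, getattr(measure, "__name__", "custom")
    else:
        s, name = get_measure(measure, g, ic), measure
    return SetSimilarityResult(
        score=_aggregate(A, B, s, aggregation), method=name, aggregation=aggregation
    )


def entity_similarity(
    e1: str,
    e2: str,
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    ic: ICTable,
    measure: str | Callable[[str, str], float] = "lin",
    aggregation: str = "bma",
) -> SetSimilarityResult:
    """Set similarity over two entities' direct annotation sets."""
    for e in (e1, e2):
        if e not in corpus.direct or not corpus.direct[e]:
            raise ValueError(
                f"{corpus.entity_kind} {e!r} is not annotated by any ontology term"
            )
    return set_similarity(
        corpus.direct[e1], corpus.direct[e2], g, ic, measure, aggregation
    )


def empirical_pvalue(
    observed: float,
    q_size: int,
    entity_terms: Iterable[str],
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    ic: ICTable,
    measure: str | Callable[[str, str], float] = "lin",
    aggregation: str = "bma",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed=0,
) -> float:
    """Add-one permutation p-value against size-matched random term sets.

    Null queries are drawn uniformly without replacement from the universe
    of terms carrying at least one direct annotation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    universe = np.array(corpus.annotated_terms())
    if q_size > len(universe):
        raise ValueError(
            f"query size {q_size} exceeds the annotated-term universe ({len(universe)})"
        )
    entity_terms = sorted(set(entity_terms))
    if callable(measure):
        s = measure
    else:
        s = get_measure(measure, g, ic)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        null_query = rng.choice(universe, size=q_size, replace=False)
        null_score = _aggregate(sorted(null_query), entity_terms, s, aggregation)
        if null_score >= observed:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def predict_associations(
    q: PatientProfile,
    candidates: Sequence[str] | None,
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    ic: ICTable,
    measure: str | Callable[[str, str], float] = "lin",
    aggregation: str = "bma",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> Ranking:
    """Rank candidate entities by profile similarity to the query.

    ``candidates=None`` scores every annotated entity in the corpus.
    Unknown candidates land in the skipped-entities report.  Pure function
    of (query, corpus, config, seed): reruns are identical.
    Set ``n_permutations=0`` to skip p-values.
    """
    if candidates is None:
        pool = [e for e in corpus.entities() if corpus.direct[e]]
        skipped: list[str] = []
    else:
        pool, skipped = [], []
        for e in candidates:
            if e in corpus.direct and corpus.direct[e]:
                pool.append(e)
            else:
                skipped.append(e)
        if skipped:
            logger.warning("candidates absent from corpus skipped: %s", ", ".join(skipped))
    if callable(measure):
        s = measure
    else:
        s = get_measure(measure, g, ic)

    query_terms = sorted({g.active(t) for t in q.terms})
    scored = [
        (e, _aggregate(query_terms, sorted(corpus.direct[e]), s, aggregation))
        for e in pool
    ]
    scored.sort(key=lambda row: (-row[1], row[0]))

    p_values: list[float | None]
    q_values: list[float | None]
    if n_permutations >= 1 and scored:
        child_seeds = np.random.SeedSequence(seed).spawn(len(scored))
        p_values = [
            empirical_pvalue(
                score,
                len(query_terms),
                corpus.direct[e],
                corpus,
                g,
                ic,
                s,
                aggregation,
                n_permutations,
                child,
            )
            for (e, score), child in zip(scored, child_seeds)
        ]
        q_values = list(
            multipletests(np.array(p_values), method="fdr_bh")[1].astype(float)
        )
    else:
        p_values = [None] * len(scored)
        q_values = [None] * len(scored)

    rows = [
        (e, score, p, qv)
        for (e, score), p, qv in zip(scored, p_values, q_values)
    ]
    return Ranking(query=q, candidates=rows, target_kind=corpus.entity_kind, skipped=skipped)


def write_run_metadata(path, **fields) -> None:
    """JSON sidecar describing a run (method, seed, parameters, checksums)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
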