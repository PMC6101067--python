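"""Pairwise IC-based term similarity measures and matrices.

Four classical measures, all built on the MICA:

* Resnik:    sim = IC(MICA)                       (unnormalized, >= 0)
* Lin:       sim = 2*IC(MICA) / (IC(a) + IC(b))   in [0, 1]
* Schlicker: Lin * (1 - |D_MICA| / |D|)           in [0, 1]
* Jiang-Conrath: sim = 1 / (dist + 1) with
  dist = IC(a) + IC(b) - 2*IC(MICA)               in (0, 1]

Lin, Schlicker and JC are ratios/differences of ICs and therefore invariant
under the logarithm base; Resnik scales with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .ontology import AnnotationCorpus, ICTable, OntologyGraph, mica

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "sim_resnik",
    "sim_lin",
    "sim_schlicker",
    "sim_jc",
    "get_measure",
    "pairwise_matrix",
    "MEASURES",
]

MEASURES = ("resnik", "lin", "schlicker", "jc", "phenosim")


def sim_resnik(a: str, b: str, g: OntologyGraph, ic: ICTable) -> float:
    """IC of the most informative common ancestor."""
    return ic.ic[mica(g, ic, a, b)]


def sim_lin(a: str, b: str, g: OntologyGraph, ic: ICTable) -> float:
    """2*IC(MICA)/(IC(a)+IC(b)); 0 when both ICs vanish (root/root)."""
    denom = ic.ic[g.active(a)] + ic.ic[g.active(b)]
    if denom == 0.0:
        return 0.0
    return 2.0 * ic.ic[mica(g, ic, a, b)] / denom


def sim_schlicker(a: str, b: str, g: OntologyGraph, ic: ICTable) -> float:
    """Lin similarity damped by the MICA's annotation frequency."""
    m = mica(g, ic, a, b)
    denom = ic.ic[g.active(a)] + ic.ic[g.active(b)]
    if denom == 0.0:
        return 0.0
    lin = 2.0 * ic.ic[m] / denom
    return lin * (1.0 - ic.counts[m] / ic.n_entities)


def sim_jc(a: str, b: str, g: OntologyGraph, ic: ICTable) -> float:
    """1/(dist+1) with dist the Jiang-Conrath semantic distance."""
    m = mica(g, ic, a, b)
    dist = ic.ic[g.active(a)] + ic.ic[g.active(b)] - 2.0 * ic.ic[m]
    return 1.0 / (dist + 1.0)


def get_measure(
    name: str, g: OntologyGraph, ic: ICTable, normalize_resnik: bool = False
) -> Callable[[str, str], float]:
    """Return a cached ``(a, b) -> score`` callable for a measure name.

    ``normalize_resnik`` divides Resnik scores by the maximum IC in the
    table (useful for comparability when thresholding networks); off by
    default, matching the raw definition.
    """
    if name == "resnik":
        if normalize_resnik:
            max_ic = max(ic.ic.values()) or 1.0
            fn = lambda a, b: sim_resnik(a, b, g, ic) / max_ic  # noqa: E731
        else:
            fn = lambda a, b: sim_resnik(a, b, g, ic)  # noqa: E731
    elif name == "lin":
        fn = lambda a, b: sim_lin(a, b, g, ic)  # noqa: E731
    elif name == "schlicker":
        fn = lambda a, b: sim_schlicker(a, b, g, ic)  # noqa: E731
    elif name == "jc":
        fn = lambda a, b: sim_jc(a, b, g, ic)  # noqa: E731
    elif name == "phenosim":
        from .phenosim import sim_phenosim

        fn = lambda a, b: sim_phenosim(a, b, g, ic)  # noqa: E731
    else:
        raise ValueError(f"unknown similarity measure {name!r}; choose from {MEASURES}")

    cache: dict[tuple[str, str], float] = {}

    def cached(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        score = cache.get(key)
        if score is None:
            score = fn(*key)
            cache[key] = score
        return score

    return cached


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity matrix with method metadata."""

    method: str
    terms: list[str]
    scores: np.ndarray
    log_base: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        k = len(self.terms)
        if self.scores.shape != (k, k):
            raise ValueError("scores shape must be |terms| x |terms|")

    def pair_score(self, a: str, b: str) -> float:
        i, j = self.terms.index(a), self.terms.index(b)
        return float(self.scores[i, j])

    def iter_pairs(self):
        """Yield (term_a, term_b, score) for each unordered pair, a < b order."""
        for i in range(len(self.terms)):
            for j in range(i + 1, len(self.terms)):
                yield self.terms[i], self.terms[j], float(self.scores[i, j])

    def to_long_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term_a\tterm_b\tscore\tmethod\n")
            for a, b, s in self.iter_pairs():
                fh.write(f"{a}\t{b}\t{s!r}\t{self.method}\n")

    def to_square_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\t" + "\t".join(self.terms) + "\n")
            for i, t in enumerate(self.terms):
                row = "\t".join(repr(float(v)) for v in self.scores[i])
                fh.write(f"{t}\t{row}\n")


def pairwise_matrix(
    terms: list[str],
    method: str,
    g: OntologyGraph,
    ic: ICTable,
    normalize_resnik: bool = False,
) -> SimilarityMatrix:
    """Assemble the symmetric pairwise matrix for a list of term ids.

    Unknown ids are reported (warning) and dropped; duplicates collapse
    with a warning, preserving first-seen order.  Fewer than two valid
    terms is an input failure.
    """
    valid: list[str] = []
    seen: set[str] = set()
    invalid: list[str] = []
    for t in terms:
        try:
            primary = g.active(t)
        except KeyError:
            invalid.append(t)
            continue
        if primary in seen:
            logger.warning("duplicate input term %s collapsed", t)
            continue
        seen.add(primary)
        valid.append(primary)
    if invalid:
        logger.warning("unknown/obsolete input terms skipped: %s", ", ".join(invalid))
    if len(valid) < 2:
        raise ValueError(
            f"need at least 2 valid terms, got {len(valid)} "
            f"(invalid: {invalid!r})"
        )
    measure = get_measure(method, g, ic, normalize_resnik=normalize_resnik)
    k = len(valid)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            scores[i, j] = scores[j, i] = measure(valid[i], valid[j])
    return SimilarityMatrix(method=method, terms=valid, scores=scores, log_base=ic.base)
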