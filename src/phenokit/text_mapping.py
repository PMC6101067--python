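"""Free text -> ontology term mapping by local dictionary matching.

Clinical phenotype descriptions usually arrive as prose, not term ids.
This module builds a lexicon from every non-obsolete term's name and
synonyms (normalized: case-fold, punctuation stripped, whitespace
collapsed) and scans text with a greedy left-to-right longest-match over
word boundaries.  Matching is exact after normalization — no stemming and
no fuzzy distance — so the mapping is deterministic and auditable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .ontology import ICTable, OntologyGraph

logger = logging.getLogger(__name__)

__all__ = ["TextMatch", "Lexicon", "build_lexicon", "map_text", "normalize_label"]

_WORD_RE = re.compile(r"\w+", re.UNICODE)
_NON_WORD_RE = re.compile(r"[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class TextMatch:
    """One matched span: half-open 0-based character offsets."""

    start: int
    end: int
    surface: str
    term: str
    via: str  # "name" | "synonym"


def normalize_label(label: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return " ".join(_NON_WORD_RE.sub(" ", label.casefold()).split())


@dataclass
class Lexicon:
    """Normalized label -> (term id, via) with the longest phrase length."""

    entries: dict[str, tuple[str, str]]
    max_phrase_words: int

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries


def build_lexicon(g: OntologyGraph, ic: ICTable | None = None) -> Lexicon:
    """Index every active term's name and synonyms.

    Collisions between distinct terms resolve toward the higher-IC (more
    specific) term when an IC table is given, breaking remaining ties to
    the lexicographically smaller id; collisions are logged.  A term's own
    name beats its synonym for the same key.
    """
    entries: dict[str, tuple[str, str]] = {}

    def specificity(term_id: str) -> tuple[float, str]:
        ic_v = ic.ic.get(term_id, 0.0) if ic is not None else 0.0
        return (ic_v, term_id)

    def insert(key: str, term_id: str, via: str) -> None:
        if not key:
            return
        current = entries.get(key)
        if current is None:
            entries[key] = (term_id, via)
            return
        cur_term, cur_via = current
        if cur_term == term_id:
            if via == "name" and cur_via == "synonym":
                entries[key] = (term_id, via)
            return
        cur_ic, cur_id = specificity(cur_term)
        new_ic, new_id = specificity(term_id)
        # prefer higher IC; tie -> lexicographically smaller id
        if (new_ic, ) > (cur_ic, ) or (new_ic == cur_ic and new_id < cur_id):
            logger.warning(
                "lexicon collision on %r: %s replaces %s", key, term_id, cur_term
            )
            entries[key] = (term_id, via)
        else:
            logger.warning(
                "lexicon collision on %r: keeping %s over %s", key, cur_term, term_id
            )

    for term_id in g.active_terms():
        term = g.terms[term_id]
        insert(normalize_label(term.name), term_id, "name")
        for syn in term.synonyms:
            insert(normalize_label(syn), term_id, "synonym")

    max_words = max((len(k.split()) for k in entries), default=1)
    return Lexicon(entries=entries, max_phrase_words=max_words)


def map_text(text: str, lexicon: Lexicon) -> list[TextMatch]:
    """Greedy left-to-right longest-match of lexicon phrases in ``text``.

    Matches respect word boundaries, never overlap, and are returned in
    text order.  No matches is an empty list, not an error.
    """
    if not text:
        raise ValueError("text must be non-empty")
    tokens = [(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    norm = [normalize_label(tok) for tok, _, _ in tokens]
    matches: list[TextMatch] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(lexicon.max_phrase_words, n - i), 0, -1):
            key = " ".join(norm[i : i + length])
            hit = lexicon.entries.get(key)
            if hit is not None:
                term, via = hit
                start = tokens[i][1]
                end = tokens[i + length - 1][2]
                matches.append(
                    TextMatch(start=start, end=end, surface=text[start:end], term=term, via=via)
                )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return matches


def write_matches_tsv(matches: list[TextMatch], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("start\tend\tsurface\tterm_id\tvia\n")
        for m in matches:
            fh.write(f"{m.start}\t{m.end}\t{m.surface}\t{m.term}\t{m.via}\n")
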