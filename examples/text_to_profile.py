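"""Map a free-text clinical description to ontology terms.

Uses a tiny hand-built kidney/heart ontology; the lexicon indexes every
term name and synonym, and the scanner takes the longest non-overlapping
match at each position.
"""

from phenokit.ontology import AnnotationCorpus, OntologyGraph, Term, compute_ic, propagate
from phenokit.text_mapping import build_lexicon, map_text

terms = {
    "HP:0000001": Term(id="HP:0000001", name="phenotypic abnormality"),
    "HP:0000002": Term(id="HP:0000002", name="abnormal kidney morphology",
                       synonyms=("kidney anomaly",)),
    "HP:0000003": Term(id="HP:0000003", name="renal agenesis"),
    "HP:0000004": Term(id="HP:0000004", name="renal cyst"),
    "HP:0000005": Term(id="HP:0000005", name="abnormal heart"),
}
graph = OntologyGraph(terms, [("HP:0000002", "HP:0000001"),
                              ("HP:0000003", "HP:0000002"),
                              ("HP:0000004", "HP:0000002"),
                              ("HP:0000005", "HP:0000001")])
corpus = propagate(graph, AnnotationCorpus("disease", {
    "DIS:0001": frozenset({"HP:0000003"}),
    "DIS:0002": frozenset({"HP:0000004"}),
    "DIS:0003": frozenset({"HP:0000005"}),
}))
lexicon = build_lexicon(graph, compute_ic(graph, corpus))

text = ("Newborn with Renal Agenesis on the left; ultrasound also suggests "
        "abnormal kidney morphology and a possible abnormal heart.")
print(f"text: {text}\n")
for m in map_text(text, lexicon):
    print(f"  [{m.start:3d},{m.end:3d}) {m.surface!r:38s} -> {m.term} (via {m.via})")

print(
    "\nEach line is one non-overlapping longest match; offsets are 0-based"
    "\nhalf-open character positions into the original text."
)
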