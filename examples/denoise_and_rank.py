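"""Denoise a noisy patient profile and rank candidate genes.

Simulates a patient whose profile is one gene's 8 phenotype annotations
plus 2 random noise terms, removes the lowest-PageRank 20% of the
profile, and ranks all genes against the cleaned profile with permutation
p-values.
"""

from phenokit.fixtures import (
    FixtureSpec,
    generate_corpus,
    generate_noisy_profile,
    generate_ontology,
)
from phenokit.ontology import compute_ic, propagate
from phenokit.phenosim import build_network, denoise_profile
from phenokit.profile_similarity import predict_associations

spec = FixtureSpec(n_terms=120, max_parents=2, n_entities=30,
                   annotations_per_entity=(8, 8), seed=42)
graph = generate_ontology(spec)
corpus = propagate(graph, generate_corpus(graph, spec, entity_kind="gene"))
ic = compute_ic(graph, corpus)
network = build_network(graph, corpus)

true_gene = "GENE:0005"
profile, planted = generate_noisy_profile(graph, corpus, true_gene, 2, seed=1)
print(f"profile: {len(profile.terms)} terms ({len(planted)} planted noise)")

cleaned, removed = denoise_profile(network, profile, drop_fraction=0.2, ic=ic)
print(f"removed by PageRank denoising: {[t for t, _ in removed]}")
print(f"planted noise terms:          {sorted(planted)}")

ranking = predict_associations(cleaned, None, corpus, graph, ic,
                               measure="lin", aggregation="bma",
                               n_permutations=200, seed=3)
print("\ntop 5 candidate genes (score = BMA-Lin similarity to the profile):")
for rank, (gene, score, p, q) in enumerate(ranking.candidates[:5], start=1):
    marker = "  <-- source gene" if gene == true_gene else ""
    print(f"  {rank}. {gene}  score={score:.4f}  p={p:.4g}  q={q:.4g}{marker}")

print(
    "\nA p-value near 1/(M+1) means no random same-size phenotype set"
    "\nmatched the gene as well as the patient profile did."
)
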