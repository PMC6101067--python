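"""Phenotype network, personalized PageRank, denoising, path-constrained IC."""

import numpy as np
import networkx as nx
import pytest

from conftest import A, B, C, M, ROOT, LN2, make_random_world
from phenokit.fixtures import FixtureSpec, generate_corpus, generate_noisy_profile, generate_ontology
from phenokit.ontology import AnnotationCorpus, propagate, compute_ic
from phenokit.phenosim import (
    PatientProfile,
    PhenotypeNetwork,
    build_network,
    denoise_profile,
    personalized_pagerank,
    read_edge_list,
    sim_phenosim,
    write_edge_list,
)
from phenokit.term_similarity import sim_resnik


def gene_corpus(g, direct):
    return propagate(g, AnnotationCorpus(entity_kind="gene",
                                         direct={k: frozenset(v) for k, v in direct.items()}))


class TestBuildNetwork:
    def test_shared_singleton_gene_gives_weight_one(self, four_disease):
        g, _, _ = four_disease
        corpus = gene_corpus(g, {"GENE:0001": {A, B}})
        net = build_network(g, corpus)
        assert net.graph[A][B]["weight"] == 1.0
        assert net.graph[A][B]["provenance"] == "co-annotation"

    def test_no_shared_gene_no_coannotation_edge(self, four_disease):
        g, _, _ = four_disease
        corpus = gene_corpus(g, {"GENE:0001": {A}, "GENE:0002": {C}})
        net = build_network(g, corpus)
        assert not net.graph.has_edge(A, C)

    def test_hand_computed_jaccard_weights(self, four_disease):
        """3 genes x 3 terms: weights equal brute-force Jaccard indices."""
        g, _, _ = four_disease
        corpus = gene_corpus(g, {
            "GENE:0001": {A, B},
            "GENE:0002": {A, C},
            "GENE:0003": {A},
        })
        net = build_network(g, corpus)
        # entities(A)={1,2,3}, entities(B)={1}, entities(C)={2}
        assert net.graph[A][B]["weight"] == pytest.approx(1 / 3)
        assert net.graph[A][C]["weight"] == pytest.approx(1 / 3)
        assert not net.graph.has_edge(B, C)
        # ontology backbone included with unit weight
        assert net.graph[A][M]["weight"] == 1.0
        assert net.graph[A][M]["provenance"] == "ontology"
        assert net.nodes == {A, B, C, M, ROOT}

    def test_nodes_are_annotated_terms_plus_ancestors(self, four_disease):
        g, _, _ = four_disease
        corpus = gene_corpus(g, {"GENE:0001": {A}})
        net = build_network(g, corpus)
        assert net.nodes == {A, M, ROOT}

    def test_no_self_loops_positive_weights(self, random_world):
        g, corpus, _ = random_world
        net = build_network(g, corpus)
        assert all(u != v for u, v in net.graph.edges)
        assert all(d["weight"] > 0 for _, _, d in net.graph.edges(data=True))

    def test_empty_corpus_rejected(self, four_disease):
        g, _, _ = four_disease
        with pytest.raises(ValueError):
            build_network(g, propagate(g, AnnotationCorpus("gene", {})))

    def test_edge_list_round_trip(self, random_world, tmp_path):
        g, corpus, _ = random_world
        net = build_network(g, corpus)
        p = tmp_path / "net.tsv"
        write_edge_list(net, p)
        again = read_edge_list(p)
        assert again.edge_records() == net.edge_records()


def dense_pagerank_oracle(net, restart, damping):
    """Direct solution of the stationarity linear system."""
    nodes = sorted(net.graph.nodes)
    idx = {t: i for i, t in enumerate(nodes)}
    k = len(nodes)
    adj = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    deg = adj.sum(axis=1)
    dangling = deg == 0
    W = np.zeros((k, k))
    nz = ~dangling
    W[:, nz] = adj[:, nz] / deg[nz]  # column-stochastic
    v = np.zeros(k)
    v[[idx[t] for t in sorted(restart)]] = 1.0 / len(restart)
    e_dang = dangling.astype(float)
    lhs = np.eye(k) - damping * W - damping * np.outer(v, e_dang)
    x = np.linalg.solve(lhs, (1.0 - damping) * v)
    return {t: x[idx[t]] / x.sum() for t in nodes}


class TestPersonalizedPageRank:
    def test_single_node_network(self):
        graph = nx.Graph()
        graph.add_node("FP:0000001")
        scores = personalized_pagerank(PhenotypeNetwork(graph), {"FP:0000001"})
        assert scores.score["FP:0000001"] == pytest.approx(1.0, abs=1e-12)

    def test_scores_sum_to_one(self, random_world):
        g, corpus, _ = random_world
        net = build_network(g, corpus)
        restart = set(sorted(net.graph.nodes)[:3])
        scores = personalized_pagerank(net, restart)
        assert sum(scores.score.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(s >= 0 for s in scores.score.values())

    def test_empty_restart_rejected(self, random_world):
        g, corpus, _ = random_world
        net = build_network(g, corpus)
        with pytest.raises(ValueError):
            personalized_pagerank(net, set())
        with pytest.raises(ValueError):
            personalized_pagerank(net, {"FP:9999999"})

    def test_bad_damping_rejected(self, random_world):
        g, corpus, _ = random_world
        net = build_network(g, corpus)
        node = next(iter(net.graph.nodes))
        for bad in (0.0, 1.0, -0.3, 1.7):
            with pytest.raises(ValueError):
                personalized_pagerank(net, {node}, damping=bad)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_linear_solve(self, seed):
        """Power iteration equals the direct stationarity solution."""
        g, corpus, _ = make_random_world(seed=seed, n_terms=30, n_entities=8)
        net = build_network(g, corpus)
        rng = np.random.default_rng(seed)
        nodes = sorted(net.graph.nodes)
        restart = set(rng.choice(nodes, size=min(4, len(nodes)), replace=False))
        scores = personalized_pagerank(net, restart)
        oracle = dense_pagerank_oracle(net, restart & set(nodes), 0.85)
        for t in nodes:
            assert scores.score[t] == pytest.approx(oracle[t], abs=1e-8)

    def test_isolated_node_in_network(self):
        """Dangling nodes teleport their mass back to the restart set."""
        graph = nx.Graph()
        graph.add_edge("FP:0000001", "FP:0000002", weight=1.0)
        graph.add_node("FP:0000003")  # isolated
        net = PhenotypeNetwork(graph)
        scores = personalized_pagerank(net, {"FP:0000001", "FP:0000003"})
        oracle = dense_pagerank_oracle(net, {"FP:0000001", "FP:0000003"}, 0.85)
        for t in scores.score:
            assert scores.score[t] == pytest.approx(oracle[t], abs=1e-10)


class TestDenoiseProfile:
    def test_drop_fraction_zero_is_identity(self, random_world):
        g, corpus, ic = random_world
        net = build_network(g, corpus)
        p = PatientProfile(terms=frozenset(sorted(net.graph.nodes)[:5]))
        cleaned, report = denoise_profile(net, p, drop_fraction=0.0, ic=ic)
        assert cleaned.terms == p.terms
        assert report == []

    def test_floor_arithmetic(self, random_world):
        g, corpus, ic = random_world
        net = build_network(g, corpus)
        p = PatientProfile(terms=frozenset(sorted(net.graph.nodes)[:5]))
        cleaned, report = denoise_profile(net, p, drop_fraction=0.2, ic=ic)
        assert len(cleaned.terms) == 4 and len(report) == 1
        assert cleaned.terms < p.terms

    def test_never_removes_everything(self, random_world):
        g, corpus, ic = random_world
        net = build_network(g, corpus)
        p = PatientProfile(terms=frozenset(sorted(net.graph.nodes)[:2]))
        cleaned, _ = denoise_profile(net, p, drop_fraction=0.99, ic=ic)
        assert len(cleaned.terms) == 1

    def test_terms_outside_network_removed_first(self, four_disease, caplog):
        g, _, ic = four_disease
        corpus = gene_corpus(g, {"GENE:0001": {A, B}})
        net = build_network(g, corpus)
        p = PatientProfile(terms=frozenset({A, B, "HP:0000005"}))  # C not in net
        with caplog.at_level("WARNING"):
            cleaned, report = denoise_profile(net, p, drop_fraction=0.4, ic=ic)
        assert [t for t, _ in report] == ["HP:0000005"]
        assert cleaned.terms == {A, B}

    def test_planted_noise_recovery_beats_chance(self):
        """Profiles = 8 true terms + 2 random ones; the removed pair should
        be enriched for the planted noise well beyond the 0.2 chance rate."""
        spec = FixtureSpec(n_terms=120, max_parents=2, n_entities=30,
                           annotations_per_entity=(8, 8), seed=42)
        g = generate_ontology(spec)
        corpus = propagate(g, generate_corpus(g, spec, entity_kind="gene"))
        ic = compute_ic(g, corpus)
        net = build_network(g, corpus)
        entities = corpus.entities()
        removed_total = removed_planted = 0
        for seed in range(30):
            entity = entities[seed % len(entities)]
            profile, noise = generate_noisy_profile(g, corpus, entity, 2, seed)
            if len(profile.terms) != 10:
                continue  # rare collision with ancestors; skip malformed draw
            cleaned, report = denoise_profile(net, profile, drop_fraction=0.2, ic=ic)
            removed = {t for t, _ in report}
            removed_total += len(removed)
            removed_planted += len(removed & noise)
        assert removed_total > 0
        assert removed_planted / removed_total > 0.2


class TestSimPhenosim:
    def test_self_equals_resnik(self, four_disease):
        g, _, ic = four_disease
        for t in (A, B, M, ROOT):
            assert sim_phenosim(t, t, g, ic) == sim_resnik(t, t, g, ic)

    def test_sibling_chain_value(self, four_disease):
        """MICA = M (IC ln2), one hop from each sibling: ln2 / (1+2)."""
        g, _, ic = four_disease
        assert sim_phenosim(A, B, g, ic) == pytest.approx(LN2 / 3.0, abs=1e-12)

    def test_symmetric_and_bounded_by_resnik(self, random_world):
        g, _, ic = random_world
        terms = g.active_terms()
        for a in terms[::3]:
            for b in terms[::4]:
                s = sim_phenosim(a, b, g, ic)
                assert s == pytest.approx(sim_phenosim(b, a, g, ic), abs=1e-12)
                assert s <= sim_resnik(a, b, g, ic) + 1e-12
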