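"""PhenoSim-style pipeline: phenotype network, PageRank denoising,
path-constrained IC similarity.

The pipeline has three stages.  First, a weighted *phenotype network* is
built from the ontology backbone (every ``is_a`` edge) plus co-annotation
edges between terms whose direct entity sets overlap, weighted by the
Jaccard index of those entity sets.  Second, a patient's phenotype profile
is denoised: a personalized PageRank walk restarted on the profile scores
every network node by relevance to the profile as a whole, and the
lowest-scoring fraction of the profile is dropped as likely noise.  Third,
term similarity is computed with a path-constrained IC measure,

    sim(a, b) = IC(MICA) / (1 + L(a, b)),

where L(a, b) is the smallest total edge count of DAG paths from ``a`` and
``b`` up to a common ancestor achieving the maximal IC.  The measure
equals Resnik at L = 0 (a == b) and discounts term pairs whose MICA is
topologically remote.

The network weights (ontology weight 1.0, Jaccard co-annotation), damping
0.85, tolerance 1e-10, 200 iterations, drop fraction 0.2 and the 1/(1+L)
penalty are this package's defaults; each is a keyword argument so other
constants can be substituted without code change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .ontology import ICTable, AnnotationCorpus, OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeNetwork",
    "PatientProfile",
    "PageRankScores",
    "build_network",
    "personalized_pagerank",
    "denoise_profile",
    "sim_phenosim",
    "write_edge_list",
    "read_edge_list",
]

DEFAULT_ONTOLOGY_WEIGHT = 1.0
DEFAULT_DAMPING = 0.85
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 200
DEFAULT_DROP_FRACTION = 0.2


@dataclass
class PhenotypeNetwork:
    """Undirected weighted graph over phenotype terms.

    Edge attributes: ``weight`` (> 0) and ``provenance``
    ({"ontology", "co-annotation"}).  No self-loops.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_records(self) -> list[tuple[str, str, float, str]]:
        """Sorted (term_a, term_b, weight, provenance) with term_a < term_b."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            out.append((a, b, float(data["weight"]), data["provenance"]))
        return sorted(out)


@dataclass(frozen=True)
class PatientProfile:
    """A set of phenotype terms describing one patient."""

    terms: frozenset[str]
    label: str = ""

    def __post_init__(self):
        if not self.terms:
            raise ValueError("patient profile must be non-empty")


@dataclass
class PageRankScores:
    """Stationary distribution of a personalized random walk."""

    score: dict[str, float]
    damping: float
    iterations: int
    residual: float


def build_network(
    g: OntologyGraph,
    corpus: AnnotationCorpus,
    ontology_weight: float = DEFAULT_ONTOLOGY_WEIGHT,
) -> PhenotypeNetwork:
    """Phenotype network from ontology edges and co-annotation Jaccard.

    Nodes are every directly annotated term plus all of their ancestors.
    Two edge sources: (i) each ``is_a`` edge inside the node set, with a
    fixed ontology weight; (ii) an edge between two terms whenever their
    direct-annotation entity sets intersect, weighted by the Jaccard index
    of those sets.  Parallel edges collapse to the maximum weight; the
    provenance tag follows the winning weight.
    """
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated before building the network")
    if corpus.n_entities == 0:
        raise ValueError("empty corpus")

    nodes: set[str] = set()
    for terms in corpus.propagated.values():
        nodes |= terms
    net = nx.Graph()
    net.add_nodes_from(sorted(nodes))

    for child, parent in g.dag.edges:
        if child in nodes and parent in nodes:
            net.add_edge(child, parent, weight=ontology_weight, provenance="ontology")

    # invert: term -> entities directly annotated to it
    term_entities: dict[str, set[str]] = {}
    for entity, terms in corpus.direct.items():
        for t in terms:
            term_entities.setdefault(t, set()).add(entity)

    # only terms sharing >=1 entity get a co-annotation edge; enumerate via entities
    candidate_pairs: set[tuple[str, str]] = set()
    for entity, terms in corpus.direct.items():
        for u, v in combinations(sorted(terms), 2):
            candidate_pairs.add((u, v))
    for u, v in sorted(candidate_pairs):
        eu, ev = term_entities[u], term_entities[v]
        inter = len(eu & ev)
        if inter == 0:
            continue
        w = inter / len(eu | ev)
        if net.has_edge(u, v):
            if w > net[u][v]["weight"]:
                net[u][v].update(weight=w, provenance="co-annotation")
        else:
            net.add_edge(u, v, weight=w, provenance="co-annotation")
    return PhenotypeNetwork(graph=net)


def personalized_pagerank(
    n: PhenotypeNetwork,
    restart_set: set[str],
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PageRankScores:
    """Stationary vector of the weighted walk with teleport to ``restart_set``.

    Power iteration: x <- d * W x + (d * dangling_mass + 1 - d) * v, where W
    is the column-stochastic weighted transition operator of the undirected
    graph and v is uniform over the restart set.  Iterates until the L1
    residual drops below ``tol`` or ``max_iter`` is hit; the result always
    sums to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must lie in (0, 1), got {damping}")
    nodes = sorted(n.graph.nodes)
    index = {t: i for i, t in enumerate(nodes)}
    restart = sorted(set(restart_set) & set(nodes))
    if not restart:
        raise ValueError("restart set is empty or disjoint from the network")

    k = len(nodes)
    v = np.zeros(k)
    v[[index[t] for t in restart]] = 1.0 / len(restart)

    adj = nx.to_scipy_sparse_array(n.graph, nodelist=nodes, weight="weight", format="csr")
    degree = np.asarray(adj.sum(axis=1)).ravel()
    dangling = degree == 0.0
    inv_degree = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, degree))
    # column-stochastic operator applied as x @ row-normalized adjacency
    x = v.copy()
    residual = math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        spread = (x * inv_degree) @ adj  # symmetric adj: row == column view
        dangling_mass = float(x[dangling].sum())
        x_next = damping * (spread + dangling_mass * v) + (1.0 - damping) * v
        residual = float(np.abs(x_next - x).sum())
        x = x_next
        if residual < tol:
            break
    x = x / x.sum()
    return PageRankScores(
        score={t: float(x[index[t]]) for t in nodes},
        damping=damping,
        iterations=iterations,
        residual=residual,
    )


def denoise_profile(
    n: PhenotypeNetwork,
    p: PatientProfile,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
    damping: float = DEFAULT_DAMPING,
    ic: ICTable | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[PatientProfile, list[tuple[str, float]]]:
    """Drop the lowest-PageRank fraction of a profile as presumed noise.

    The walk restarts on the profile members present in the network;
    profile terms absent from the network are treated as isolated nodes
    (score 0, removed first).  Exactly ``floor(drop_fraction * |p|)``
    terms are removed, never all of them.  Ties on score retain the
    higher-IC term first, then the lexicographically smaller id.

    Returns the cleaned profile and the removal report
    ``[(term, score), ...]`` in removal order.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError(f"drop_fraction must lie in [0, 1), got {drop_fraction}")
    members = sorted(p.terms)
    k_drop = int(drop_fraction * len(members))
    k_drop = min(k_drop, len(members) - 1)
    if k_drop == 0:
        return p, []

    in_network = set(members) & set(n.graph.nodes)
    scores: dict[str, float] = {t: 0.0 for t in members}
    if in_network:
        pr = personalized_pagerank(
            n, in_network, damping=damping, tol=tol, max_iter=max_iter
        )
        for t in in_network:
            scores[t] = pr.score[t]
    missing = set(members) - in_network
    if missing:
        logger.warning(
            "profile terms absent from network, treated as isolated: %s",
            ", ".join(sorted(missing)),
        )

    def retention_key(t: str):
        ic_t = ic.ic.get(t, 0.0) if ic is not None else 0.0
        return (-scores[t], -ic_t, t)

    ordered = sorted(members, key=retention_key)
    removed = ordered[len(ordered) - k_drop :]
    kept = frozenset(ordered[: len(ordered) - k_drop])
    report = [(t, scores[t]) for t in removed]
    return PatientProfile(terms=kept, label=p.label), report


def sim_phenosim(a: str, b: str, g: OntologyGraph, ic: ICTable) -> float:
    """Path-constrained IC similarity: IC(MICA) / (1 + L(a, b)).

    L(a, b) minimizes, over common ancestors c achieving the maximal IC,
    the shortest-path edge count from ``a`` to c plus from ``b`` to c
    along child->parent edges.  Symmetric; equals Resnik when a == b.
    """
    a = g.active(a)
    b = g.active(b)
    common = g.ancestors(a, inclusive=True) & g.ancestors(b, inclusive=True)
    best_ic = max(ic.ic[t] for t in common)
    best_ancestors = [t for t in common if ic.ic[t] == best_ic]
    da = nx.single_source_shortest_path_length(g.dag, a)
    db = nx.single_source_shortest_path_length(g.dag, b)
    path_len = min(da[c] + db[c] for c in best_ancestors)
    return best_ic / (1.0 + path_len)


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def write_edge_list(n: PhenotypeNetwork, path) -> None:
    """Weighted edge-list TSV: term_a, term_b, weight, provenance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_a\tterm_b\tweight\tprovenance\n")
        for a, b, w, prov in n.edge_records():
            fh.write(f"{a}\t{b}\t{w!r}\t{prov}\n")


def read_edge_list(path) -> PhenotypeNetwork:
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term_a"):
            raise ValueError("expected edge-list header 'term_a\\tterm_b\\t...'")
        for line in fh:
            a, b, w, prov = line.rstrip("\n").split("\t")
            graph.add_edge(a, b, weight=float(w), provenance=prov)
    return PhenotypeNetwork(graph=graph)


def write_graphml(n: PhenotypeNetwork, path) -> None:
    nx.write_graphml(n.graph, path)


def read_graphml(path) -> PhenotypeNetwork:
    return PhenotypeNetwork(graph=nx.read_graphml(path))
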