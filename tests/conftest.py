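"""Shared fixtures: tiny graphs, random instances, and oracle helpers."""

from __future__ import annotations

import io

import networkx as nx
import numpy as np
import pytest

from ontarget import (
    GeneratorConfig,
    OntologyGraph,
    TrainingSet,
    generate_benchmark,
    parse_obo,
    read_drug_table,
    read_interactions,
)

# ---------------------------------------------------------------------------
# independent distance oracle (min-plus Floyd–Warshall, no BFS involved)


def floyd_warshall_oracle(n_nodes: int, edges) -> np.ndarray:
    """All-pairs hop distances by min-plus relaxation; inf = unreachable."""
    dist = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in edges:
        dist[u, v] = dist[v, u] = 1.0
    for k in range(n_nodes):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return dist


def random_graph_instance(seed: int, max_nodes: int = 50):
    """A random undirected graph plus its OntologyGraph view.

    Returns (graph, node names, integer edge list, n).  Node i is named
    ``T{i}``; edge probability is drawn wide enough to cover sparse
    (disconnected) and dense cases.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.25))
    gnx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    named = nx.relabel_nodes(gnx, {i: f"T{i}" for i in range(n)})
    return OntologyGraph(named), [f"T{i}" for i in range(n)], list(gnx.edges()), n


# ---------------------------------------------------------------------------
# tiny hand-built graphs


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """A–B–C path graph."""
    g = nx.Graph()
    g.add_edge("A", "B")
    g.add_edge("B", "C")
    return OntologyGraph(g)


def make_obo(*stanzas: str) -> io.StringIO:
    return io.StringIO("format-version: 1.2\nontology: test\n\n" + "\n\n".join(stanzas) + "\n")


# ---------------------------------------------------------------------------
# neighbor-scenario builder: a query term, equidistant neighbor terms, and
# strictly farther distractor terms, all expressed as OBO text


def neighbor_scenario_obo(query_term: str, near_terms, far_terms) -> str:
    """OBO where every near term is 2 hops from the query, far terms 3 hops.

    Layout: query is_a HUB; near terms is_a HUB; FARHUB is_a HUB; far terms
    is_a FARHUB.
    """
    lines = ["format-version: 1.2", "ontology: scenario", "",
             "[Term]", "id: HUB", "",
             "[Term]", "id: FARHUB", "is_a: HUB", "",
             "[Term]", f"id: {query_term}", "is_a: HUB"]
    for t in near_terms:
        lines += ["", "[Term]", f"id: {t}", "is_a: HUB"]
    for t in far_terms:
        lines += ["", "[Term]", f"id: {t}", "is_a: FARHUB"]
    return "\n".join(lines) + "\n"


def training_set_from_rows(rows) -> TrainingSet:
    """Rows of (drug_id, group, term or iterable-of-terms) → TrainingSet."""
    from ontarget import DrugRecord

    records = []
    for drug_id, group, terms in rows:
        if isinstance(terms, str):
            terms = {terms}
        records.append(DrugRecord(drug_id, group, frozenset(terms)))
    return TrainingSet(records)


# ---------------------------------------------------------------------------
# the default synthetic benchmark, generated once per session


@pytest.fixture(scope="session")
def default_benchmark():
    """Default-config synthetic benchmark: (cfg, graph, dataset, table, truth)."""
    cfg = GeneratorConfig()
    obo_text, drug_table, interactions, truth = generate_benchmark(cfg)
    graph = parse_obo(io.StringIO(obo_text))
    dataset = read_drug_table(io.StringIO(drug_table))
    table = read_interactions(io.StringIO(interactions))
    return cfg, graph, dataset, table, truth
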