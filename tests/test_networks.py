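"""Per-trial networks: edges, components, component-weighted CC and M, hops.

The component-weighted statistics are checked against independently written
brute-force oracles (union-find for components, neighbor-pair triangle
counting for clustering, endpoint-degree correlation for assortativity).
"""

import math

import networkx as nx
import numpy as np
import pytest

from phonofluency import (
    Production,
    Trial,
    build_network,
    classify_productions,
    count_components,
    hop_distribution,
    local_clustering,
    weighted_assortativity,
    weighted_mean_clustering,
)
from phonofluency.networks import DISCONNECTED, build_graph, export_edge_list, export_graphml


# --- independent oracles ----------------------------------------------------

def oracle_components(g):
    """Union-find component count."""
    parent = {n: n for n in g.nodes()}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in g.edges():
        parent[find(u)] = find(v)
    return len({find(n) for n in g.nodes()})


def oracle_weighted_cc(g):
    """Per-component mean of brute-force local CC, node-count weighted."""
    if g.number_of_nodes() == 0:
        return math.nan

    def local(n):
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        if k < 2:
            return 0.0
        links = sum(
            g.has_edge(a, b) for i, a in enumerate(nbrs) for b in nbrs[i + 1 :]
        )
        return links / (k * (k - 1) / 2)

    total = 0.0
    for comp in nx.connected_components(g):
        comp = list(comp)
        total += len(comp) * (sum(local(n) for n in comp) / len(comp))
    return total / g.number_of_nodes()


def oracle_weighted_m(g):
    """Per-component endpoint-degree Pearson correlation, weighted; 0 when undefined."""
    if g.number_of_nodes() == 0:
        return math.nan
    total = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        xs, ys = [], []
        for u, v in sub.edges():
            xs += [sub.degree(u), sub.degree(v)]
            ys += [sub.degree(v), sub.degree(u)]
        r = 0.0
        if xs and len(set(xs)) > 1:
            x, y = np.asarray(xs, float), np.asarray(ys, float)
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            r = num / den if den else 0.0
        total += len(comp) * r
    return total / g.number_of_nodes()


def random_graph(n, rng):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < rng.uniform(0.05, 0.6):
                g.add_edge(i, j)
    return g


# --- worked examples --------------------------------------------------------

def test_k9_plus_isolate_weighted_cc_is_0_9():
    """A fully clustered 9-node component diluted by one isolate: 0.9."""
    g = nx.complete_graph(9)
    g.add_node("isolate")
    assert weighted_mean_clustering(g) == pytest.approx(0.9)
    assert count_components(g) == 2


def test_local_clustering_conventions():
    tri = nx.complete_graph(3)
    assert local_clustering(tri, 0) == 1.0
    star = nx.star_graph(3)
    assert local_clustering(star, 0) == 0.0  # hub: no neighbor-neighbor edges
    assert local_clustering(star, 1) == 0.0  # degree 1: set to zero by convention
    assert all(local_clustering(nx.complete_graph(9), n) == 1.0 for n in range(9))


def test_star_is_maximally_disassortative():
    assert weighted_assortativity(nx.star_graph(4)) == pytest.approx(-1.0)


def test_symmetric_components_cancel():
    """Two equal-size components with opposite M average to ~0."""
    a = nx.lollipop_graph(4, 2)  # 6 nodes, mixed degrees
    b = nx.relabel_nodes(a, {n: n + 10 for n in a.nodes()})
    ma = weighted_assortativity(a)
    g = nx.union(a, b)
    assert weighted_assortativity(g) == pytest.approx(ma)  # equal components keep M
    # and a graph of two opposite-M components of equal size averages them
    star = nx.star_graph(5)           # M = -1, 6 nodes
    ladder = nx.cycle_graph(6)        # zero degree variance -> contributes 0
    g2 = nx.union(star, nx.relabel_nodes(ladder, {n: n + 20 for n in ladder.nodes()}))
    assert weighted_assortativity(g2) == pytest.approx(-0.5)


def test_all_isolates():
    g = nx.empty_graph(5)
    assert weighted_mean_clustering(g) == 0.0
    assert weighted_assortativity(g) == 0.0
    assert count_components(g) == 5


def test_adding_isolate_dilutes_cc():
    g = nx.complete_graph(6)
    before = weighted_mean_clustering(g)
    g.add_node("x")
    assert weighted_mean_clustering(g) < before


# --- oracle equivalence -----------------------------------------------------

def test_oracle_equivalence_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        g = random_graph(int(rng.integers(2, 13)), rng)
        assert count_components(g) == oracle_components(g)
        assert weighted_mean_clustering(g) == pytest.approx(oracle_weighted_cc(g))
        assert weighted_assortativity(g) == pytest.approx(oracle_weighted_m(g))


def test_assortativity_matches_networkx_on_connected_graphs():
    """Dual route: our M equals nx.degree_pearson_correlation_coefficient
    on single-component graphs where the latter is defined."""
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 20:
        g = random_graph(8, rng)
        if not nx.is_connected(g):
            continue
        ref = nx.degree_pearson_correlation_coefficient(g)
        if not np.isfinite(ref):
            continue
        assert weighted_assortativity(g) == pytest.approx(ref, abs=1e-9)
        checked += 1


# --- trial networks ---------------------------------------------------------

def make_classified(parse, lexicon, stimulus, responses):
    trial = Trial("P1", "T1", parse(stimulus),
                  [Production(i, parse(r)) for i, r in enumerate(responses)])
    return classify_productions(trial, lexicon)


def test_build_network_edges_and_dedup(parse, lexicon):
    trial = make_classified(parse, lexicon, "wai4", ["zai1", "zai3", "zai4", "zai1"])
    net = build_network(trial)
    assert net.n_nodes == 3  # repetition deduplicated
    assert net.graph.number_of_edges() == 3  # tone substitutions form a triangle
    assert net.NC == 1
    assert net.CC == pytest.approx(1.0)


def test_network_excludes_errors_and_stimulus(parse, lexicon):
    trial = make_classified(parse, lexicon, "wai4", ["zai4", "zai2", "du2"])
    net = build_network(trial)
    labels = {d["label"] for _, d in net.graph.nodes(data=True)}
    assert labels == {"zai4", "du2"}  # zai2 is a nonword; stimulus not a node
    assert net.NC == 2


def test_include_stimulus_switch(parse, lexicon):
    trial = make_classified(parse, lexicon, "wai4", ["shuai4", "wan4"])
    # shuai4 and wan4 are both edit 1 from wai4 but edit 2 from each other
    assert build_network(trial).NC == 2
    assert build_network(trial, include_stimulus=True).NC == 1


def test_empty_network_measures_missing(parse, lexicon):
    trial = make_classified(parse, lexicon, "wai4", ["zai2"])
    net = build_network(trial)
    assert net.NC is None and math.isnan(net.CC) and math.isnan(net.M)


def test_single_correct_response(parse, lexicon):
    net = build_network(make_classified(parse, lexicon, "wai4", ["zai4"]))
    assert (net.n_nodes, net.graph.number_of_edges(), net.NC) == (1, 0, 1)


def test_hop_distribution(parse, lexicon):
    # shuai4 and wan4 are edit 1 from wai4 (hop 1); shuan4 reaches the
    # stimulus only through them (hop 2); du2 shares no edge with anything
    trial = make_classified(parse, lexicon, "wai4",
                            ["shuai4", "wan4", "shuan4", "du2"])
    net = build_network(trial)
    assert net.hops == {1: 2, 2: 1, DISCONNECTED: 1}
    # the hop-1 bin is exactly the stimulus's immediate neighbors among nodes
    from phonofluency import edit_distance

    stim = parse("wai4")
    n_immediate = sum(
        edit_distance(stim, d["syllable"]) == 1 for _, d in net.graph.nodes(data=True)
    )
    assert net.hop_count(1) == n_immediate


def test_exports(parse, lexicon, tmp_path):
    trial = make_classified(parse, lexicon, "wai4", ["shuai4", "shuan4", "du2"])
    net = build_network(trial)
    edge_path = tmp_path / "edges.tsv"
    export_edge_list(net, edge_path)
    text = edge_path.read_text()
    assert "shuai4\tshuan4" in text or "shuan4\tshuai4" in text
    gml = tmp_path / "net.graphml"
    export_graphml(net, gml)
    back = nx.read_graphml(gml)
    assert set(back.nodes()) == {"shuai4", "shuan4", "du2"}
    assert back.nodes["du2"]["hop"] == -1  # disconnected marker
    assert back.nodes["shuai4"]["hop"] == 1
    assert back.nodes["shuan4"]["hop"] == 2
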