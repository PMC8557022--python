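"""Cross-source network construction, centralities, hubs and enrichment."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methnet import netint
from methnet.errors import EmptyNetworkError, InvalidArgumentError


def _ppi(edges):
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence"])


# ------------------------------------------------- integrated network

def test_cross_source_edge_rule():
    ppi = _ppi([("a1", "b1", 0.9), ("a1", "a2", 0.9)])
    net = netint.build_integrated_network(
        ppi, deg={"a1", "a2"}, dmr_genes={"b1"}, fem_genes=set()
    )
    assert set(net.edges) == {("a1", "b1")} or set(net.edges) == {("b1", "a1")}


def test_confidence_below_cutoff_dropped():
    ppi = _ppi([("a", "b", 0.69), ("a", "c", 0.70)])
    net = netint.build_integrated_network(
        ppi, deg={"a"}, dmr_genes={"b", "c"}, fem_genes=set()
    )
    assert net.has_edge("a", "c") and not net.has_edge("a", "b")


def test_major_component_retained():
    edges = [("a", "b", 0.9), ("b", "c", 0.9), ("c", "d", 0.9), ("d", "e", 0.9),
             ("x", "y", 0.9), ("y", "z", 0.9)]
    deg = {"a", "c", "e", "x", "z"}
    dmr = {"b", "d", "y"}
    net = netint.build_integrated_network(_ppi(edges), deg, dmr, set())
    assert set(net.nodes) == {"a", "b", "c", "d", "e"}


def test_multi_label_nodes_qualify_edges():
    ppi = _ppi([("a", "b", 0.9)])
    net = netint.build_integrated_network(
        ppi, deg={"a", "b"}, dmr_genes={"b"}, fem_genes=set()
    )
    assert net.has_edge("a", "b")
    assert net.nodes["b"]["sources"] == ["DEG", "DMR"]


def test_every_retained_edge_joins_distinct_labels(bundle):
    from methnet import diffmeth, exprde, fem, methqc

    beta, sheet, man = bundle["beta"], bundle["sheet"], bundle["manifest"]
    dms = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ["age"], ann=man)
    dmrs = diffmeth.call_dmrs(dms, man)
    dmr_genes = set(diffmeth.map_dmrs_to_genes(dmrs, man))
    degs = exprde.deg_genes(exprde.simple_de(bundle["counts"], sheet))
    stats = fem.gene_stats(dms, man)
    fem_genes = fem.module_genes(
        fem.detect_modules(stats, bundle["ppi"], n_perm=49, seed=0)
    )
    net = netint.build_integrated_network(
        bundle["ppi"], degs, dmr_genes, fem_genes
    )
    assert nx.is_connected(net)
    for a, b in net.edges:
        la = set(net.nodes[a]["sources"])
        lb = set(net.nodes[b]["sources"])
        assert len(la | lb) >= 2  # never both single identical label


def test_empty_inputs_raise():
    with pytest.raises(InvalidArgumentError):
        netint.build_integrated_network(_ppi([]), set(), set(), set())
    with pytest.raises(EmptyNetworkError):
        netint.build_integrated_network(
            _ppi([("a", "b", 0.5)]), {"a"}, {"b"}, set()
        )


def test_dedupe_keeps_max_confidence_and_drops_self_loops():
    ppi = _ppi([("a", "b", 0.5), ("b", "a", 0.8), ("a", "a", 0.99)])
    out = netint.dedupe_ppi(ppi)
    assert len(out) == 1
    assert out.loc[0, "confidence"] == 0.8


# -------------------------------------------------------- centralities

def test_triangle_graph_hand_values():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    ct = netint.compute_centralities(g)
    assert (ct["degree"] == 2).all()
    assert np.allclose(ct["clustering_coeff"], 1.0)
    assert np.allclose(ct["betweenness"], 0.0)
    assert np.allclose(ct["eigenvector"], 1 / np.sqrt(3), atol=1e-10)


def test_path_graph_hand_values():
    g = nx.Graph([("A", "B"), ("B", "C")])
    ct = netint.compute_centralities(g)
    assert ct.loc["B", "betweenness"] == pytest.approx(1.0)
    assert ct.loc["B", "closeness"] == pytest.approx(1.0)
    assert ct.loc["A", "closeness"] == pytest.approx(2.0 / 3.0)


def test_star_graph_hand_values():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    ct = netint.compute_centralities(g)
    assert ct.loc["n0", "degree"] == 4
    assert ct.loc["n1", "neighbor_degree"] == pytest.approx(4.0)
    assert ct.loc["n0", "clustering_coeff"] == 0.0


# ---- independent oracle: BFS distances, shortest-path enumeration, ----
# ---- power iteration, Katz series, triple-loop triangle counting   ----

def _bfs_dist(adj, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate all shortest s-t paths by DFS bounded by the BFS distance."""
    target = dist[t]
    out = []
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t and len(path) - 1 == target:
            out.append(path)
            continue
        if len(path) - 1 >= target:
            continue
        for v in adj[u]:
            if v not in path:
                stack.append((v, path + [v]))
    return out


def _oracle(g):
    nodes = sorted(g.nodes)
    n = len(nodes)
    adj = {u: sorted(g.neighbors(u)) for u in nodes}
    a = nx.to_numpy_array(g, nodelist=nodes)

    closeness, betweenness = {}, dict.fromkeys(nodes, 0.0)
    dists = {u: _bfs_dist(adj, u) for u in nodes}
    for u in nodes:
        closeness[u] = (n - 1) / sum(dists[u][v] for v in nodes if v != u)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t, dists[s])
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            betweenness[v] += frac
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    betweenness = {v: b * norm for v, b in betweenness.items()}

    # power iteration on A + I: same principal eigenvector, but the shift
    # guarantees dominance (plain A oscillates on bipartite graphs)
    x = np.ones(n)
    for _ in range(100000):
        y = (a @ x) + x
        y = y / np.linalg.norm(y)
        if np.linalg.norm(y - x) < 1e-13:
            break
        x = y
    eig = y

    lam = max(np.linalg.eigvalsh(a))
    alpha = 0.9 / lam
    katz = np.zeros(n)
    term = np.ones(n)
    for _ in range(10000):
        term = alpha * (a @ term)
        katz += term
        if np.linalg.norm(term) < 1e-15:
            break
    katz += np.ones(n)  # beta = 1 contribution of the zeroth term
    katz = katz / np.linalg.norm(katz)

    clustering = {}
    nbr_deg = {}
    for u in nodes:
        nbrs = adj[u]
        k = len(nbrs)
        tri = sum(
            g.has_edge(v, w) for v, w in itertools.combinations(nbrs, 2)
        )
        clustering[u] = 2 * tri / (k * (k - 1)) if k > 1 else 0.0
        nbr_deg[u] = np.mean([len(adj[v]) for v in nbrs])

    return pd.DataFrame(
        {
            "degree": [len(adj[u]) for u in nodes],
            "neighbor_degree": [nbr_deg[u] for u in nodes],
            "closeness": [closeness[u] for u in nodes],
            "eigenvector": eig,
            "katz": katz,
            "betweenness": [betweenness[u] for u in nodes],
            "clustering_coeff": [clustering[u] for u in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def test_centralities_match_bruteforce_oracle_on_random_graphs():
    """All seven metrics agree with an exhaustive oracle on 200 graphs."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 200:
        n = int(rng.integers(3, 9))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if not nx.is_connected(g) or g.number_of_edges() == 0:
            continue
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        ct = netint.compute_centralities(g)
        ref = _oracle(g)
        for col in netint.METRICS:
            assert np.allclose(ct[col], ref[col], atol=1e-8), col
        checked += 1


def test_disconnected_graph_rejected():
    g = nx.Graph([("a", "b"), ("c", "d")])
    with pytest.raises(InvalidArgumentError):
        netint.compute_centralities(g)


# ----------------------------------------------------------- hubs

def test_percentile_threshold_on_1_to_100():
    ct = pd.DataFrame(
        {m: np.arange(1, 101) for m in netint.METRICS},
        index=pd.Index([f"n{i}" for i in range(1, 101)], name="node"),
    )
    hubs, prov = netint.select_hubs(ct, 95.0)
    assert hubs == {f"n{i}" for i in range(96, 101)}
    assert set(prov["n100"]) == set(netint.METRICS)


def test_all_equal_values_select_everything():
    ct = pd.DataFrame(
        {m: np.ones(10) for m in netint.METRICS},
        index=pd.Index([f"n{i}" for i in range(10)], name="node"),
    )
    hubs, _ = netint.select_hubs(ct, 95.0)
    assert len(hubs) == 10


def test_single_metric_provenance_and_monotone_relaxation():
    rng = np.random.default_rng(0)
    ct = pd.DataFrame(
        {m: rng.random(50) for m in netint.METRICS},
        index=pd.Index([f"n{i}" for i in range(50)], name="node"),
    )
    hubs95, prov = netint.select_hubs(ct, 95.0)
    hubs90, _ = netint.select_hubs(ct, 90.0)
    assert hubs95 <= hubs90
    for node, metrics in prov.items():
        assert metrics  # every selected node has provenance
    marked = netint.mark_selected(ct, 95.0)
    assert set(marked.index[marked["selected"]]) == hubs95


# ------------------------------------------------------- enrichment

def test_hypergeom_full_overlap_combinatorial_value():
    universe = {f"u{i}" for i in range(20)}
    chosen = set(sorted(universe)[:5])
    out = netint.hypergeom_enrich(chosen, {"s": chosen}, universe, min_size=5)
    assert out.loc[0, "p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)


def test_hypergeom_small_sets_excluded_and_zero_overlap():
    universe = {f"u{i}" for i in range(20)}
    query = set(sorted(universe)[:5])
    sets = {
        "tiny": set(sorted(universe)[:4]),
        "disjoint": set(sorted(universe)[10:16]),
    }
    out = netint.hypergeom_enrich(query, sets, universe, min_size=5)
    assert list(out["set_name"]) == ["disjoint"]
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_hypergeom_matches_enumeration_on_small_universes():
    """Upper-tail p equals the exact combinatorial sum for universes <= 15."""
    rng = np.random.default_rng(11)
    for _ in range(60):
        n = int(rng.integers(6, 16))
        universe = [f"u{i}" for i in range(n)]
        k_set = int(rng.integers(1, n + 1))
        k_query = int(rng.integers(1, n + 1))
        geneset = set(rng.choice(universe, k_set, replace=False))
        query = set(rng.choice(universe, k_query, replace=False))
        out = netint.hypergeom_enrich(
            query, {"s": geneset}, set(universe), min_size=0
        )
        obs = len(geneset & query)
        exact = sum(
            comb(k_set, j) * comb(n - k_set, k_query - j) / comb(n, k_query)
            for j in range(obs, min(k_set, k_query) + 1)
        )
        assert out.loc[0, "p"] == pytest.approx(exact, rel=1e-10)


def test_query_outside_universe_rejected():
    with pytest.raises(InvalidArgumentError):
        netint.hypergeom_enrich({"x"}, {}, {"a", "b"})
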