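"""Graph metrics against closed forms and a brute-force shortest-path oracle."""

import itertools

import numpy as np
import pytest

from micnet.graphstats import (
    SignificanceGraph,
    betweenness_centrality,
    degree_centrality,
    global_efficiency,
    graph_summary,
    local_efficiency,
    vertex_metrics_table,
)

from micnet.synthgen import DEFAULT_TONGUE_EDGES as TABLE1_EDGES


# --------------------------------------------------------------------------
# Brute-force oracle: explicit all-pairs shortest-path enumeration.
# --------------------------------------------------------------------------

def _all_shortest_paths(adj: dict[int, set[int]], s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path by breadth-limited DFS enumeration."""
    if s == t:
        return [(s,)]
    best: list[tuple[int, ...]] = []
    frontier = [(s,)]
    while frontier and not best:
        nxt = []
        for path in frontier:
            for nb in adj[path[-1]]:
                if nb in path:
                    continue
                new = path + (nb,)
                if nb == t:
                    best.append(new)
                else:
                    nxt.append(new)
        frontier = nxt
    return best


def brute_betweenness(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    adj = {v: set() for v in range(1, n + 1)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(1, n + 1), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(1, n + 1):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v - 1] += through / len(paths)
    return bc


def brute_distances(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    adj = {v: set() for v in range(1, n + 1)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    dist = np.full((n, n), np.inf)
    for s in range(1, n + 1):
        dist[s - 1, s - 1] = 0
        seen = {s}
        frontier = {s}
        d = 0
        while frontier:
            d += 1
            frontier = {nb for v in frontier for nb in adj[v]} - seen
            for v in frontier:
                dist[s - 1, v - 1] = d
            seen |= frontier
    return dist


def brute_global_efficiency(n: int, edges: set[tuple[int, int]]) -> float:
    dist = brute_distances(n, edges)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean()) if len(inv) else 0.0


def random_graph(n: int, p: float, rng: np.random.Generator) -> SignificanceGraph:
    edges = {
        (i, j)
        for i, j in itertools.combinations(range(1, n + 1), 2)
        if rng.random() < p
    }
    return SignificanceGraph(n_vertices=n, edges=frozenset(edges))


# --------------------------------------------------------------------------


class TestSignificanceGraph:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            SignificanceGraph(n_vertices=5, edges=frozenset({(2, 2)}))

    def test_out_of_range_vertex_rejected(self):
        with pytest.raises(ValueError):
            SignificanceGraph(n_vertices=5, edges=frozenset({(1, 6)}))

    def test_edges_canonicalized_undirected(self):
        g = SignificanceGraph(n_vertices=5, edges=frozenset({(3, 1), (1, 3)}))
        assert g.edges == {(1, 3)}
        assert g.n_edges == 1


class TestDegreeCentrality:
    def test_published_graph_degree_ranking(self, montage):
        # The 19 published tongue-contrast pairs: degree 5 at FC3, C3, Cz;
        # 4 at FCz, C1; 3 at FC2, FC4.
        g = SignificanceGraph(n_vertices=22, edges=frozenset(TABLE1_EDGES))
        assert g.n_edges == 19
        deg = degree_centrality(g)["degree"]
        by_name = {montage.name_of(v + 1): int(deg[v]) for v in range(22)}
        assert by_name["FC3"] == by_name["C3"] == by_name["Cz"] == 5
        assert by_name["FCz"] == by_name["C1"] == 4
        assert by_name["FC2"] == by_name["FC4"] == 3
        ranking = degree_centrality(g)["ranking"]
        assert {name for name, d in ranking if d == 5} == {"FC3", "C3", "Cz"}

    def test_edgeless_graph_all_zero(self):
        g = SignificanceGraph(n_vertices=6)
        deg = degree_centrality(g, include_isolated=True)
        assert np.all(deg["degree"] == 0)
        assert deg["mean"] == 0.0

    def test_complete_graph_uniform_degree(self):
        edges = frozenset(itertools.combinations(range(1, 6), 2))
        g = SignificanceGraph(n_vertices=5, edges=edges)
        assert np.all(degree_centrality(g)["degree"] == 4)

    def test_handshake_sum_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            g = random_graph(8, 0.4, rng)
            assert degree_centrality(g, include_isolated=True)["degree"].sum() == 2 * g.n_edges

    def test_isolated_vertices_excluded_from_summary_by_default(self):
        g = SignificanceGraph(n_vertices=10, edges=frozenset({(1, 2), (2, 3)}))
        summary = degree_centrality(g)
        assert summary["mean"] == pytest.approx((1 + 2 + 1) / 3)


class TestBetweenness:
    def test_complete_graph_zero(self):
        edges = frozenset(itertools.combinations(range(1, 7), 2))
        g = SignificanceGraph(n_vertices=6, edges=edges)
        assert np.all(betweenness_centrality(g)["raw"] == 0)

    def test_star_center_raw_and_normalized(self):
        # Star, 3 leaves: every leaf pair routes through the center ->
        # raw 3, normalized 3 / ((4-1)(4-2)/2) = 1.
        g = SignificanceGraph(n_vertices=4, edges=frozenset({(1, 2), (1, 3), (1, 4)}))
        bc = betweenness_centrality(g)
        assert bc["raw"][0] == pytest.approx(3.0, abs=1e-12)
        assert bc["normalized"][0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(bc["raw"][1:] == 0)

    def test_path_middle_vertex(self):
        g = SignificanceGraph(n_vertices=3, edges=frozenset({(1, 2), (2, 3)}))
        assert betweenness_centrality(g)["raw"][1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            g = random_graph(n, float(rng.uniform(0.15, 0.8)), rng)
            expected = brute_betweenness(n, set(g.edges))
            got = betweenness_centrality(g)["raw"]
            assert np.allclose(got, expected, atol=1e-9)


class TestEfficiency:
    def test_complete_graph_unit_efficiency(self):
        for n in (2, 5, 8):
            edges = frozenset(itertools.combinations(range(1, n + 1), 2))
            g = SignificanceGraph(n_vertices=n, edges=edges)
            assert global_efficiency(g) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_graph_zero_efficiency(self):
        g = SignificanceGraph(n_vertices=6)
        assert global_efficiency(g) == 0.0

    def test_three_path_closed_form(self):
        # P3: distances 1, 1, 2 -> mean(1, 1, 1/2) = 5/6.
        g = SignificanceGraph(n_vertices=3, edges=frozenset({(1, 2), (2, 3)}))
        assert global_efficiency(g) == pytest.approx(5 / 6, abs=1e-12)

    def test_single_vertex_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(SignificanceGraph(n_vertices=1))

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = random_graph(n, float(rng.uniform(0.1, 0.9)), rng)
            assert global_efficiency(g) == pytest.approx(
                brute_global_efficiency(n, set(g.edges)), abs=1e-9
            )

    def test_edge_addition_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = 7
            g = random_graph(n, 0.3, rng)
            missing = [
                e for e in itertools.combinations(range(1, n + 1), 2)
                if e not in g.edges
            ]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            g2 = SignificanceGraph(n_vertices=n, edges=g.edges | {extra})
            assert global_efficiency(g2) >= global_efficiency(g) - 1e-12


class TestLocalEfficiency:
    def test_triangle_unit_everywhere(self):
        g = SignificanceGraph(n_vertices=3,
                              edges=frozenset({(1, 2), (2, 3), (1, 3)}))
        assert np.allclose(local_efficiency(g)["local_efficiency"], 1.0)

    def test_star_center_zero(self):
        g = SignificanceGraph(n_vertices=4, edges=frozenset({(1, 2), (1, 3), (1, 4)}))
        loc = local_efficiency(g)["local_efficiency"]
        assert loc[0] == 0.0  # leaves are mutually unconnected
        assert np.all(loc[1:] == 0.0)  # leaves have a single neighbor

    def test_k4_minus_edge_induced_path(self):
        # K4 without edge (3,4): vertices 1 and 2 see neighbors {the other
        # degree-3 vertex, 3, 4} inducing a path -> E_loc = 5/6.
        edges = frozenset({(1, 2), (1, 3), (1, 4), (2, 3), (2, 4)})
        g = SignificanceGraph(n_vertices=4, edges=edges)
        loc = local_efficiency(g)["local_efficiency"]
        assert loc[0] == pytest.approx(5 / 6, abs=1e-12)
        assert loc[1] == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_induced_subgraph_oracle_on_random_graphs(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = random_graph(n, float(rng.uniform(0.2, 0.8)), rng)
            loc = local_efficiency(g)["local_efficiency"]
            adj = {v: set() for v in range(1, n + 1)}
            for i, j in g.edges:
                adj[i].add(j)
                adj[j].add(i)
            for v in range(1, n + 1):
                nbrs = sorted(adj[v])
                if len(nbrs) < 2:
                    assert loc[v - 1] == 0.0
                    continue
                relabel = {u: k + 1 for k, u in enumerate(nbrs)}
                sub_edges = {
                    (relabel[i], relabel[j])
                    for i, j in g.edges
                    if i in relabel and j in relabel
                }
                assert loc[v - 1] == pytest.approx(
                    brute_global_efficiency(len(nbrs), sub_edges), abs=1e-9
                )


class TestInvariance:
    def test_metrics_invariant_under_vertex_relabeling(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            n = 8
            g = random_graph(n, 0.4, rng)
            perm = rng.permutation(n) + 1
            mapping = {v: int(perm[v - 1]) for v in range(1, n + 1)}
            g2 = SignificanceGraph(
                n_vertices=n,
                edges=frozenset((mapping[i], mapping[j]) for i, j in g.edges),
            )
            at = perm - 1  # metric of original vertex v sits at perm[v-1]-1
            deg1 = degree_centrality(g, include_isolated=True)["degree"]
            deg2 = degree_centrality(g2, include_isolated=True)["degree"]
            assert np.array_equal(deg1, deg2[at])
            bc1 = betweenness_centrality(g)["raw"]
            bc2 = betweenness_centrality(g2)["raw"]
            assert np.allclose(bc1, bc2[at])
            loc1 = local_efficiency(g)["local_efficiency"]
            loc2 = local_efficiency(g2)["local_efficiency"]
            assert np.allclose(loc1, loc2[at])
            assert global_efficiency(g) == pytest.approx(global_efficiency(g2))


class TestExports:
    def test_vertex_metrics_table_layout(self, montage):
        g = SignificanceGraph(n_vertices=22, edges=frozenset(TABLE1_EDGES))
        df = vertex_metrics_table(g, montage)
        assert list(df.columns) == [
            "vertex", "degree", "betweenness_raw", "betweenness_norm",
            "local_efficiency",
        ]
        assert len(df) == 22
        assert df.loc[df.vertex == "C3", "degree"].item() == 5

    def test_graph_summary_fields(self):
        g = SignificanceGraph(n_vertices=22, edges=frozenset(TABLE1_EDGES))
        summary = graph_summary(g)
        assert summary["n_edges"] == 19
        assert 0.0 <= summary["global_efficiency"] <= 1.0
        assert 0.0 <= summary["mean_local_efficiency"] <= 1.0
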