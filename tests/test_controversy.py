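"""Random-walk controversy estimators vs the absorbing-chain oracle, boundary
connectivity, and classic partition quality."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from echograph.controversy import (
    WalkConfig,
    authoritative_nodes,
    average_shortest_path,
    boundary_connectivity,
    boundary_sets,
    drwc,
    estimate_arwc,
    estimate_rwc,
    exact_rwc,
    partition_quality,
)
from echograph.partition import bisection_from_labels
from echograph.synthetic import PolarizationSpec, generate_planted_graph


def split(G, x_nodes):
    return bisection_from_labels(
        G, {v: ("A" if v in set(x_nodes) else "B") for v in G.nodes}
    )


def two_cliques(k, bridged=False):
    G = nx.Graph()
    for base in (0, k):
        for i in range(base, base + k):
            for j in range(i + 1, base + k):
                G.add_edge(i, j, weight=1)
    if bridged:
        G.add_edge(0, k, weight=1)
    return G


def bridged_stars(k):
    G = nx.Graph()
    for i in range(1, k + 1):
        G.add_edge("c1", f"x{i}")
        G.add_edge("c2", f"y{i}")
    G.add_edge("c1", "c2")
    bis = split(G, {"c1", *(f"x{i}" for i in range(1, k + 1))})
    return G, bis


class TestAverageShortestPath:
    def test_path_of_three(self):
        assert average_shortest_path(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_clique(self):
        assert average_shortest_path(nx.complete_graph(5)) == 1

    def test_two_components_uses_larger(self):
        G = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(2))
        assert average_shortest_path(G) == pytest.approx(4 / 3)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            average_shortest_path(nx.empty_graph(3))


class TestAuthoritativeNodes:
    def test_ceil_of_percentile(self):
        G = two_cliques(20)
        G.add_edge(0, 1)  # no-op, keeps degrees equal within cliques
        bis = split(G, range(20))
        auth = authoritative_nodes(G, bis, auth_pct=15)
        # all degrees tie within a side -> the whole side is included
        assert auth["X"] == set(range(20))

    def test_star_center_is_authoritative_and_leaf_ties_included(self):
        G, bis = bridged_stars(6)
        auth = authoritative_nodes(G, bis, auth_pct=15)
        assert "c1" in auth["X"] and "c2" in auth["Y"]
        # cutoff degree is a leaf's degree, so the tie rule pulls in every leaf
        assert auth["X"] == set(bis.X)

    def test_distinct_degrees_select_top_k(self):
        G = nx.Graph()
        for i in range(1, 7):  # x1 has degree 6, x2 degree 5, ...
            for j in range(i):
                G.add_edge(f"x{i}", f"f{i}_{j}")
        G.add_edge("x1", "x2")
        nodes = sorted(G.nodes)
        half = set(nodes[: len(nodes) // 2])
        bis = split(G, half)
        auth = authoritative_nodes(G, bis, auth_pct=20)
        for side in ("X", "Y"):
            members = bis.X if side == "X" else bis.Y
            k = math.ceil(0.2 * len(members))
            assert len(auth[side]) >= k


class TestExactRWC:
    def test_disconnected_sides_give_one(self):
        G = two_cliques(6)
        assert exact_rwc(G, split(G, range(6))) == pytest.approx(1.0)

    def test_exchangeable_sides_give_zero(self):
        C = nx.cycle_graph(4)
        bis = split(C, {0, 1})
        assert exact_rwc(C, bis, auth={"X": {0}, "Y": {2}}) == pytest.approx(0.0)

    def test_two_triangles_bridge_matches_hand_solution(self):
        G = nx.Graph(
            [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"),
             ("d", "f"), ("e", "f")]
        )
        bis = split(G, {"a", "b", "c"})
        # absorption probabilities solved by hand: x_b=4/5, x_c=3/5, x_e=x_f=0
        # -> P_XX = 21/23, P_YY = 28/37, RWC = 21/23 + 28/37 - 1 = 570/851
        value = exact_rwc(G, bis, auth={"X": {"a"}, "Y": {"d"}})
        assert value == pytest.approx(float(Fraction(570, 851)), abs=1e-12)

    def test_end_conditioned_probability_identities(self):
        spec = PolarizationSpec(n_users=12, p_in=0.8, p_out=0.2, seed=5)
        G, labels = generate_planted_graph(spec, min_edge_weight=1)
        bis = bisection_from_labels(
            G, {v: ("A" if labels[v] == 0 else "B") for v in G}
        )
        _, probs = exact_rwc(G, bis, return_probabilities=True)
        assert probs["P_XX"] + probs["P_YX"] == pytest.approx(1.0)
        assert probs["P_YY"] + probs["P_XY"] == pytest.approx(1.0)

    def test_unreachable_start_rejected(self):
        # side Y splits into two components; one cannot reach any absorber
        G = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        G.add_edge("c", "d")
        G.add_edge("f", "g")  # disconnected from everything absorbing
        bis = split(G, {"a", "b", "c"})
        with pytest.raises(ValueError):
            exact_rwc(G, bis, auth={"X": {"a"}, "Y": {"d"}})


class TestEstimators:
    def test_disconnected_sides_estimate_one_exactly(self):
        G = two_cliques(6)
        bis = split(G, range(6))
        cfg = WalkConfig(seed=0, l_rw=20)
        assert estimate_rwc(G, bis, cfg).value == 1.0
        assert estimate_arwc(G, bis, cfg).value == 1.0

    def test_estimator_matches_oracle_under_sampled_starts(self):
        spec = PolarizationSpec(n_users=12, p_in=0.8, p_out=0.15, seed=2)
        G, labels = generate_planted_graph(spec, min_edge_weight=1)
        bis = bisection_from_labels(
            G, {v: ("A" if labels[v] == 0 else "B") for v in G}
        )
        cfg = WalkConfig(seed=4, l_rw=60, walks_per_start=700)
        est = estimate_rwc(G, bis, cfg)
        ex = exact_rwc(
            G, bis,
            start_distribution=(
                est.diagnostics["starts_X"], est.diagnostics["starts_Y"]
            ),
        )
        assert abs(est.value - ex) <= 0.02
        p = est.probabilities
        assert p["P_XX"] + p["P_YX"] == pytest.approx(1.0)
        assert p["P_YY"] + p["P_XY"] == pytest.approx(1.0)

    def test_arwc_below_rwc_when_hubs_are_linked(self):
        G, bis = bridged_stars(8)
        auth = {"X": {"c1"}, "Y": {"c2"}}
        rwc = exact_rwc(G, bis, auth=auth, start_distribution="uniform")
        arwc = exact_rwc(G, bis, auth=auth, start_distribution="authoritative")
        assert arwc < rwc
        # closed forms: ARWC = (k-1)/(k+1) with k leaves
        assert arwc == pytest.approx((8 - 1) / (8 + 1))

    def test_restart_failure_reports_l_rw(self):
        # a 60-cycle with one chorded hub per side: the authoritative nodes
        # cluster around the hubs, so single-step walks from the rest of the
        # cycle cannot absorb
        G = nx.cycle_graph(60)
        for off in (2, 4, 6, 8):
            G.add_edge(0, off)
            G.add_edge(30, 30 + off)
        bis = split(G, range(30))
        cfg = WalkConfig(seed=0, l_rw=1, restart_cap=0, walks_per_start=2)
        with pytest.raises(RuntimeError, match="l_rw"):
            estimate_rwc(G, bis, cfg)


class TestDRWC:
    def test_disconnected_sides_give_one(self):
        G = two_cliques(5)
        assert drwc(G, split(G, range(5)), WalkConfig(seed=1, l_rw=8)).value == 1.0

    def test_complete_bipartite_gives_zero(self):
        G = nx.complete_bipartite_graph(5, 5)
        bis = split(G, range(5))
        assert drwc(G, bis, WalkConfig(seed=1, l_rw=8)).value == 0.0

    def test_bounds_and_step_budget(self):
        spec = PolarizationSpec(n_users=10, p_in=0.9, p_out=0.4, seed=9)
        G, labels = generate_planted_graph(spec, min_edge_weight=1)
        bis = bisection_from_labels(
            G, {v: ("A" if labels[v] == 0 else "B") for v in G}
        )
        cfg = WalkConfig(seed=2, l_rw=11)
        est = drwc(G, bis, cfg)
        assert 0 <= est.value <= 1
        for frac in est.diagnostics["per_node"]:
            n_cc = round((1 - frac) * est.diagnostics["l_rw"])
            assert 0 <= n_cc <= est.diagnostics["l_rw"]


class TestBoundary:
    def test_path_example(self):
        G = nx.path_graph(6)
        bis = split(G, {0, 1, 2})
        sets = boundary_sets(G, bis)
        assert sets.B == {2, 3}
        assert sets.I == {0, 1, 4, 5}
        assert boundary_connectivity(G, bis) == pytest.approx(0.0)

    def test_disconnected_sides_have_empty_boundary(self):
        G = two_cliques(4)
        sets = boundary_sets(G, split(G, range(4)))
        assert sets.B == set()
        with pytest.raises(ValueError, match="undefined"):
            boundary_connectivity(G, split(G, range(4)))

    def test_complete_bipartite_has_empty_boundary(self):
        G = nx.complete_bipartite_graph(3, 3)
        assert boundary_sets(G, split(G, range(3))).B == set()

    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_bridged_stars_closed_form(self, k):
        G, bis = bridged_stars(k)
        assert boundary_connectivity(G, bis) == pytest.approx(k / (k + 1) - 0.5)

    def test_bc_within_range_on_random_partitions(self):
        spec = PolarizationSpec(n_users=15, p_in=0.5, p_out=0.3, seed=3)
        G, _ = generate_planted_graph(spec, min_edge_weight=1)
        nodes = sorted(G.nodes)
        for cut in (len(nodes) // 3, len(nodes) // 2):
            bis = split(G, nodes[:cut])
            try:
                for own in (False, True):
                    assert -0.5 <= boundary_connectivity(G, bis, own_side_only=own) <= 0.5
            except ValueError:
                pass  # empty boundary is a legal outcome here


class TestPartitionQuality:
    def test_no_cross_edges_full_coverage_half_modularity(self):
        G = two_cliques(5)
        q = partition_quality(G, split(G, range(5)))
        assert q["coverage"] == 1.0
        assert q["modularity"] == pytest.approx(0.5)

    def test_clique_bisection_coverage_by_direct_count(self):
        G = nx.complete_graph(6)
        bis = split(G, {0, 1, 2})
        q = partition_quality(G, bis)
        assert q["coverage"] == pytest.approx(6 / 15)  # 2*C(3,2) of 15 edges


class TestMonotonicityOnPlantedGraphs:
    def test_controversy_decreases_with_cross_rate(self):
        grid = [0.05, 0.15, 0.3, 0.5, 0.8]
        mean_rwc = []
        mean_drwc = []
        for p_out in grid:
            r_vals, d_vals = [], []
            for seed in range(20):
                spec = PolarizationSpec(
                    n_users=15, p_in=0.8, p_out=p_out, seed=300 + seed
                )
                G, labels = generate_planted_graph(spec, min_edge_weight=1)
                bis = bisection_from_labels(
                    G, {v: ("A" if labels[v] == 0 else "B") for v in G}
                )
                r_vals.append(exact_rwc(G, bis))
                d_vals.append(
                    drwc(G, bis, WalkConfig(seed=seed, l_rw=10)).value
                )
            mean_rwc.append(np.mean(r_vals))
            mean_drwc.append(np.mean(d_vals))
        slack = 0.03  # Monte-Carlo / planting noise allowance
        assert all(
            b <= a + slack for a, b in zip(mean_rwc, mean_rwc[1:])
        ), mean_rwc
        assert all(
            b <= a + slack for a, b in zip(mean_drwc, mean_drwc[1:])
        ), mean_drwc
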