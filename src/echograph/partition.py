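"""Two-way balanced graph partitioning via multilevel bisection.

The partitioner follows the classic multilevel scheme: (1) coarsen the graph
by repeated heavy-edge matching until at most ``coarsen_to`` vertices remain,
(2) bisect the coarsest graph by greedy region growing (best of several
seeded restarts), and (3) project the partition back level by level,
refining at each level with boundary Fiduccia–Mattheyses (Kernighan–Lin
style) passes under a balance constraint.

Balance: a bisection of n vertices is admissible when
``max(|X|, |Y|) <= max(ceil(n/2), floor(tol * n / 2))``; the ``max`` with
``ceil(n/2)`` keeps the most balanced split admissible for odd n, where a
literal ``tol * n / 2`` bound close to 1 would be unattainable.

A brute-force enumerator over all admissible bisections (|V| <= 14) serves
as the optimality oracle in tests.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = [
    "Bisection",
    "multilevel_bisect",
    "brute_force_min_cut",
    "community_changes",
    "allowed_max_side",
]

Node = Hashable
Adj = dict[Node, dict[Node, float]]


@dataclass(frozen=True)
class Bisection:
    """A two-way node partition with its cut and balance summary."""

    X: frozenset
    Y: frozenset
    cut_weight: float
    imbalance: float

    @property
    def nodes(self) -> frozenset:
        return self.X | self.Y

    def side_of(self, node: Node) -> str:
        if node in self.X:
            return "X"
        if node in self.Y:
            return "Y"
        raise KeyError(node)

    def labels(self) -> dict[Node, str]:
        """Community labels, ``"A"`` for side X and ``"B"`` for side Y."""
        out = {v: "A" for v in self.X}
        out.update({v: "B" for v in self.Y})
        return out


def allowed_max_side(n: int, imbalance_tol: float) -> int:
    """Largest admissible side size for a bisection of ``n`` vertices."""
    return max(math.ceil(n / 2), math.floor(imbalance_tol * n / 2))


def _adjacency(G: nx.Graph, weight: str) -> Adj:
    adj: Adj = {v: {} for v in G.nodes}
    for u, v, data in G.edges(data=True):
        w = float(data.get(weight, 1.0))
        adj[u][v] = w
        adj[v][u] = w
    return adj


def _cut_weight(adj: Adj, in_x: Mapping[Node, bool]) -> float:
    cut = 0.0
    for u, nbrs in adj.items():
        for v, w in nbrs.items():
            if in_x[u] != in_x[v]:
                cut += w
    return cut / 2.0


def _finalize(G: nx.Graph, x_nodes: Iterable[Node], weight: str) -> Bisection:
    X = frozenset(x_nodes)
    Y = frozenset(G.nodes) - X
    # canonical orientation: X holds the smallest vertex identifier
    if Y and (not X or min(map(str, Y)) < min(map(str, X))):
        X, Y = Y, X
    in_x = {v: (v in X) for v in G.nodes}
    cut = _cut_weight(_adjacency(G, weight), in_x)
    n = len(in_x)
    return Bisection(
        X=X, Y=Y, cut_weight=cut, imbalance=2.0 * max(len(X), len(Y)) / n
    )


# ---------------------------------------------------------------------------
# multilevel machinery


def _coarsen(
    adj: Adj, nw: dict[Node, int], rng: random.Random
) -> tuple[Adj, dict[Node, int], dict[Node, tuple[Node, ...]]]:
    """One level of heavy-edge matching; returns coarse graph and mapping."""
    order = sorted(adj)
    rng.shuffle(order)
    matched: dict[Node, Node] = {}
    for u in order:
        if u in matched:
            continue
        best_v, best_w = None, -1.0
        for v, w in adj[u].items():
            if v in matched or v == u:
                continue
            if w > best_w or (w == best_w and str(v) < str(best_v)):
                best_v, best_w = v, w
        if best_v is not None:
            matched[u] = best_v
            matched[best_v] = u

    groups: dict[Node, tuple[Node, ...]] = {}
    owner: dict[Node, Node] = {}
    cid = 0
    for u in sorted(adj):
        if u in owner:
            continue
        members = (u, matched[u]) if u in matched else (u,)
        groups[cid] = members
        for m in members:
            owner[m] = cid
        cid += 1

    cadj: Adj = {c: {} for c in groups}
    cnw = {c: sum(nw[m] for m in members) for c, members in groups.items()}
    for u, nbrs in adj.items():
        cu = owner[u]
        for v, w in nbrs.items():
            cv = owner[v]
            if cu == cv:
                continue
            cadj[cu][cv] = cadj[cu].get(cv, 0.0) + w
    return cadj, cnw, groups


def _weighted_degree(adj: Adj, v: Node) -> float:
    return sum(adj[v].values())


def _grow_bisection(
    adj: Adj,
    nw: dict[Node, int],
    allowed_w: int,
    rng: random.Random,
    n_restarts: int,
) -> dict[Node, bool] | None:
    """Greedy region growing from random seed vertices; best admissible cut."""
    nodes = sorted(adj)
    W = sum(nw.values())
    n_restarts = max(n_restarts, min(len(nodes), 10))
    if len(nodes) <= n_restarts:
        starts = list(nodes)
    else:
        starts = rng.sample(nodes, n_restarts)
    best: tuple[float, float, dict[Node, bool]] | None = None
    for start in starts:
        in_x = {v: False for v in nodes}
        in_x[start] = True
        wx = nw[start]
        conn = {v: adj[start].get(v, 0.0) for v in nodes if v != start}
        cut = _weighted_degree(adj, start)
        state_best: tuple[float, float] | None = None
        state_best_set: dict[Node, bool] | None = None

        def consider() -> None:
            nonlocal state_best, state_best_set
            if max(wx, W - wx) <= allowed_w and 0 < wx < W:
                key = (cut, 2.0 * max(wx, W - wx) / W)
                if state_best is None or key < state_best:
                    state_best = key
                    state_best_set = dict(in_x)

        consider()
        while wx < W / 2:
            cand_v, cand_key = None, None
            for v in nodes:
                if in_x[v] or wx + nw[v] > allowed_w:
                    continue
                key = (-conn.get(v, 0.0), str(v))
                if cand_key is None or key < cand_key:
                    cand_v, cand_key = v, key
            if cand_v is None:
                break
            in_x[cand_v] = True
            wx += nw[cand_v]
            cut += _weighted_degree(adj, cand_v) - 2.0 * conn.pop(cand_v, 0.0)
            for v, w in adj[cand_v].items():
                if not in_x[v]:
                    conn[v] = conn.get(v, 0.0) + w
            consider()
        if state_best is not None:
            key = (state_best[0], state_best[1])
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], state_best_set)  # type: ignore[arg-type]
    if best is None:
        return None
    return best[2]


def _fm_refine(
    adj: Adj,
    nw: dict[Node, int],
    in_x: dict[Node, bool],
    allowed_w: int,
    max_passes: int = 10,
) -> float:
    """Boundary FM/KL refinement; never worsens the cut.  Returns final cut."""
    nodes = sorted(adj)
    W = sum(nw.values())

    def side_weights() -> tuple[int, int]:
        wx = sum(nw[v] for v in nodes if in_x[v])
        return wx, W - wx

    # forced rebalancing if the projected partition violates the constraint
    wx, wy = side_weights()
    gain = {
        v: sum(w for u, w in adj[v].items() if in_x[u] != in_x[v])
        - sum(w for u, w in adj[v].items() if in_x[u] == in_x[v])
        for v in nodes
    }
    while max(wx, wy) > allowed_w:
        from_x = wx > wy
        cand = None
        for v in nodes:
            if in_x[v] != from_x:
                continue
            key = (-gain[v], str(v))
            if cand is None or key < cand[0]:
                cand = (key, v)
        if cand is None:
            break
        v = cand[1]
        _apply_move(adj, in_x, gain, v)
        if from_x:
            wx -= nw[v]
            wy += nw[v]
        else:
            wx += nw[v]
            wy -= nw[v]

    cut = _cut_weight(adj, in_x)
    for _ in range(max_passes):
        start_cut = cut
        start_imb = max(side_weights())
        locked: set[Node] = set()
        trail: list[Node] = []
        cur_cut = cut
        wx, wy = side_weights()
        best_prefix = 0
        best_key = (cut, max(wx, wy))
        for _step in range(len(nodes)):
            cand = None
            for v in nodes:
                if v in locked:
                    continue
                from_x = in_x[v]
                new_wx = wx - nw[v] if from_x else wx + nw[v]
                new_wy = W - new_wx
                if max(new_wx, new_wy) > allowed_w or new_wx <= 0 or new_wy <= 0:
                    continue
                key = (-gain[v], 0 if (from_x == (wx >= wy)) else 1, str(v))
                if cand is None or key < cand[0]:
                    cand = (key, v)
            if cand is None:
                break
            v = cand[1]
            from_x = in_x[v]
            cur_cut -= gain[v]
            _apply_move(adj, in_x, gain, v)
            if from_x:
                wx -= nw[v]
                wy += nw[v]
            else:
                wx += nw[v]
                wy -= nw[v]
            locked.add(v)
            trail.append(v)
            key = (cur_cut, max(wx, wy))
            if key < best_key:
                best_key = key
                best_prefix = len(trail)
        # roll back moves beyond the best prefix
        for v in reversed(trail[best_prefix:]):
            _apply_move(adj, in_x, gain, v)
        cut = best_key[0]
        assert cut <= start_cut + 1e-9, "FM pass must not worsen the cut"
        if not (cut < start_cut - 1e-12 or (cut == start_cut and best_key[1] < start_imb)):
            break
    return cut


def _apply_move(
    adj: Adj, in_x: dict[Node, bool], gain: dict[Node, float], v: Node
) -> None:
    old_side = in_x[v]
    in_x[v] = not old_side
    gain[v] = -gain[v]
    for u, w in adj[v].items():
        if u == v:
            continue
        if in_x[u] == old_side:
            gain[u] += 2.0 * w
        else:
            gain[u] -= 2.0 * w


def _bisect_connected(
    adj: Adj,
    seed: int,
    allowed_nodes: int,
    coarsen_to: int = 50,
    n_restarts: int = 10,
) -> set[Node]:
    """Multilevel bisection of one connected graph; returns the X side."""
    rng = random.Random(seed)
    nw = {v: 1 for v in adj}
    levels: list[tuple[Adj, dict[Node, int], dict[Node, tuple[Node, ...]]]] = []
    cur_adj, cur_nw = adj, nw
    while len(cur_adj) > coarsen_to:
        cadj, cnw, groups = _coarsen(cur_adj, cur_nw, rng)
        if len(cadj) >= len(cur_adj) * 0.95:
            break
        levels.append((cur_adj, cur_nw, groups))
        cur_adj, cur_nw = cadj, cnw

    W = sum(cur_nw.values())
    max_nw = max(cur_nw.values())
    allowed_w = max(allowed_nodes, math.ceil(W / 2) + max_nw - 1)
    in_x = _grow_bisection(cur_adj, cur_nw, allowed_w, rng, n_restarts)
    if in_x is None:
        # fall back: put half the (sorted) vertices on one side
        nodes = sorted(cur_adj)
        half = len(nodes) // 2
        in_x = {v: i < half for i, v in enumerate(nodes)}
    _fm_refine(cur_adj, cur_nw, in_x, allowed_w)

    while levels:
        fine_adj, fine_nw, groups = levels.pop()
        fine_in_x = {}
        for c, members in groups.items():
            for m in members:
                fine_in_x[m] = in_x[c]
        max_nw = max(fine_nw.values())
        allowed_w = max(allowed_nodes, math.ceil(sum(fine_nw.values()) / 2) + max_nw - 1)
        _fm_refine(fine_adj, fine_nw, fine_in_x, allowed_w)
        in_x = fine_in_x
    return {v for v, flag in in_x.items() if flag}


def multilevel_bisect(
    G: nx.Graph,
    imbalance_tol: float = 1.03,
    seed: int = 0,
    weight: str = "weight",
    coarsen_to: int = 50,
    n_restarts: int = 10,
) -> Bisection:
    """Split a conversation graph into two balanced communities.

    Connected graphs go through the full multilevel scheme.  If the graph is
    disconnected and no component exceeds the admissible side size, whole
    components are packed greedily onto the two sides (cut weight 0);
    otherwise the largest component is bisected and the remaining components
    are assigned, largest first, to the smaller side.  Deterministic for a
    fixed seed.
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("bisection needs at least 2 vertices")
    allowed = allowed_max_side(n, imbalance_tol)
    adj = _adjacency(G, weight)

    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), str(min(map(str, c)))))
    if len(comps) == 1:
        x = _bisect_connected(adj, seed, allowed, coarsen_to, n_restarts)
        bis = _finalize(G, x, weight)
    elif len(comps[0]) <= allowed:
        sides: list[set[Node]] = [set(), set()]
        for comp in comps:
            target = 0 if len(sides[0]) <= len(sides[1]) else 1
            sides[target] |= comp
        bis = _finalize(G, sides[0], weight)
    else:
        big = comps[0]
        sub = {v: {u: w for u, w in adj[v].items() if u in big} for v in big}
        x = _bisect_connected(sub, seed, allowed_max_side(len(big), imbalance_tol),
                              coarsen_to, n_restarts)
        side_x, side_y = set(x), set(big) - set(x)
        for comp in comps[1:]:
            if len(side_x) <= len(side_y):
                side_x |= comp
            else:
                side_y |= comp
        bis = _finalize(G, side_x, weight)

    if max(len(bis.X), len(bis.Y)) > allowed:
        raise ValueError(
            "balance tolerance unattainable: sizes "
            f"({len(bis.X)}, {len(bis.Y)}) with allowed max side {allowed}; "
            f"components: {[len(c) for c in comps]}"
        )
    return bis


def brute_force_min_cut(
    G: nx.Graph, imbalance_tol: float = 1.03, weight: str = "weight"
) -> Bisection:
    """Exhaustive minimum balanced cut; test oracle, refuses |V| > 14."""
    nodes = sorted(G.nodes, key=str)
    n = len(nodes)
    if n < 2:
        raise ValueError("bisection needs at least 2 vertices")
    if n > 14:
        raise ValueError("brute-force oracle refuses graphs with more than 14 vertices")
    allowed = allowed_max_side(n, imbalance_tol)
    adj = _adjacency(G, weight)
    anchor, rest = nodes[0], nodes[1:]
    best: tuple[float, float, tuple] | None = None
    for k in range(0, n):
        size_x = k + 1
        if max(size_x, n - size_x) > allowed or n - size_x < 1:
            continue
        for extra in combinations(rest, k):
            X = (anchor,) + extra
            in_x = {v: False for v in nodes}
            for v in X:
                in_x[v] = True
            cut = _cut_weight(adj, in_x)
            imb = 2.0 * max(size_x, n - size_x) / n
            key = (cut, imb, X)
            if best is None or key < best:
                best = key
    assert best is not None
    return _finalize(G, best[2], weight)


def bisection_from_labels(
    G: nx.Graph, labels: Mapping[Node, str], weight: str = "weight"
) -> Bisection:
    """Rebuild a :class:`Bisection` from per-node community labels.

    Any two distinct label values work; the side containing the smallest
    label value becomes X.
    """
    values = sorted(set(labels.values()))
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 community labels, got {values}")
    x_nodes = [v for v in G.nodes if labels[v] == values[0]]
    return _finalize(G, x_nodes, weight)


def community_changes(reference: Bisection, other: Bisection) -> dict[str, int]:
    """Count members whose community differs between two bisections.

    ``fixed_label_count`` keeps the X/Y labels as given; ``best_match_count``
    additionally allows the global label swap, reporting the smaller count.
    """
    if reference.nodes != other.nodes:
        raise ValueError("bisections cover different vertex sets")
    fixed = sum(1 for v in reference.nodes
                if (v in reference.X) != (v in other.X))
    n = len(reference.nodes)
    return {"fixed_label_count": fixed, "best_match_count": min(fixed, n - fixed)}
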