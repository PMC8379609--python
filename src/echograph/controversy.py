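"""Controversy measures over a two-way partition of the conversation graph.

Random Walk Controversy (RWC) runs random walks that are absorbed on first
arrival at an *authoritative* node (top-degree percentile per community) and
reports ``P_XX * P_YY - P_XY * P_YX`` with the end-conditioned probabilities
``P_AB = P[started in A | absorbed in B]``.  ARWC restricts start nodes to
the authoritative sets.  DRWC runs fixed-length walks with no absorption and
counts community-crossing steps.  Boundary Connectivity (BC) scores how much
boundary vertices prefer internal over boundary neighbours.  Modularity and
coverage complete the report.

Walks move to a neighbour with probability proportional to the active edge
weight (``weight_biased=True``, the default) or uniformly.  A walk that is
not absorbed within ``l_rw`` steps (twice the average shortest path by
default) restarts from a freshly drawn start node, up to ``restart_cap``
times.  The exact oracle solves the absorbing-chain linear system with the
same transition rule and no step cap; absorption is evaluated strictly after
the first step, so an authoritative start node is not trivially absorbed at
itself (this keeps the estimator and the oracle on one convention, and keeps
ARWC non-degenerate).
"""

from __future__ import annotations

import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import accumulate
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .partition import Bisection

__all__ = [
    "WalkConfig",
    "ControversyEstimate",
    "BoundarySets",
    "average_shortest_path",
    "authoritative_nodes",
    "estimate_rwc",
    "estimate_arwc",
    "exact_rwc",
    "drwc",
    "boundary_sets",
    "boundary_connectivity",
    "partition_quality",
]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the random-walk controversy estimators.

    ``sample_frac``: fraction of each partition sampled as walk starts
    (default 0.60).  ``auth_pct``: top-degree percentile defining
    authoritative nodes per community (default 15).  ``l_rw``: walk length;
    ``None`` means ``ceil(2 * average shortest path)``.  ``restart_cap``:
    maximum restarts per start before the episode counts as failed.
    """

    sample_frac: float = 0.60
    auth_pct: float = 15.0
    l_rw: int | None = None
    restart_cap: int = 50
    walks_per_start: int = 10
    weight_biased: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sample_frac <= 1:
            raise ValueError("sample_frac must be in (0, 1]")
        if not 0 < self.auth_pct < 100:
            raise ValueError("auth_pct must be in (0, 100)")
        if self.l_rw is not None and self.l_rw < 1:
            raise ValueError("l_rw must be >= 1")


@dataclass
class ControversyEstimate:
    measure: str
    value: float
    std_error: float = float("nan")
    probabilities: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class BoundarySets:
    B_X: set
    B_Y: set
    I_X: set
    I_Y: set
    d_i: dict
    d_b: dict

    @property
    def B(self) -> set:
        return self.B_X | self.B_Y

    @property
    def I(self) -> set:  # noqa: E743 - field name from the measure's definition
        return self.I_X | self.I_Y


def average_shortest_path(G: nx.Graph) -> float:
    """Mean unweighted hop distance over the largest connected component."""
    if G.number_of_nodes() < 2 or G.number_of_edges() == 0:
        raise ValueError("average shortest path requires a graph with edges")
    lcc = max(nx.connected_components(G), key=len)
    return nx.average_shortest_path_length(G.subgraph(lcc))


def _resolve_l_rw(G: nx.Graph, cfg: WalkConfig) -> int:
    if cfg.l_rw is not None:
        return cfg.l_rw
    return math.ceil(2.0 * average_shortest_path(G))


def authoritative_nodes(
    G: nx.Graph, bisection: Bisection, auth_pct: float = 15.0
) -> dict[str, set]:
    """Top-degree nodes per community: the highest ceil(pct% * |side|) degrees,
    with every tie at the cutoff degree included."""
    out = {}
    for name, side in (("X", bisection.X), ("Y", bisection.Y)):
        if not side:
            raise ValueError(f"partition side {name} is empty")
        k = math.ceil(auth_pct / 100.0 * len(side))
        ranked = sorted(side, key=lambda v: (-G.degree(v), str(v)))
        cutoff = G.degree(ranked[k - 1])
        out[name] = {v for v in side if G.degree(v) >= cutoff}
    return out


# ---------------------------------------------------------------------------
# walk machinery


class _WalkTable:
    """Per-node neighbour lists with cumulative weights for O(log d) steps."""

    def __init__(self, G: nx.Graph, weight_biased: bool, weight: str = "weight"):
        self.nbrs: dict = {}
        self.cum: dict = {}
        for v in G.nodes:
            items = sorted(G[v].items(), key=lambda kv: str(kv[0]))
            nbrs = [u for u, _ in items]
            if weight_biased:
                ws = [float(d.get(weight, 1.0)) for _, d in items]
            else:
                ws = [1.0] * len(nbrs)
            self.nbrs[v] = nbrs
            self.cum[v] = list(accumulate(ws))

    def step(self, v, rng: random.Random):
        cum = self.cum[v]
        if not cum:
            return None
        r = rng.random() * cum[-1]
        return self.nbrs[v][bisect_right(cum, r)]


def _sample_starts(
    bisection: Bisection,
    pool_x: Sequence,
    pool_y: Sequence,
    sample_frac: float,
    rng: random.Random,
) -> list[tuple[object, str]]:
    m = math.ceil(sample_frac * min(len(pool_x), len(pool_y)))
    m = max(1, m)
    sx = rng.sample(sorted(pool_x, key=str), min(m, len(pool_x)))
    sy = rng.sample(sorted(pool_y, key=str), min(m, len(pool_y)))
    return [(v, "X") for v in sx] + [(v, "Y") for v in sy]


def _run_absorbing_walks(
    G: nx.Graph,
    bisection: Bisection,
    cfg: WalkConfig,
    measure: str,
    authoritative_only_starts: bool,
) -> ControversyEstimate:
    auth = authoritative_nodes(G, bisection, cfg.auth_pct)
    absorbing_side = {v: "X" for v in auth["X"]}
    absorbing_side.update({v: "Y" for v in auth["Y"]})
    l_rw = _resolve_l_rw(G, cfg)
    rng = random.Random(cfg.seed)
    table = _WalkTable(G, cfg.weight_biased)

    if authoritative_only_starts:
        pool_x, pool_y = sorted(auth["X"], key=str), sorted(auth["Y"], key=str)
    else:
        pool_x, pool_y = sorted(bisection.X, key=str), sorted(bisection.Y, key=str)
    starts = _sample_starts(bisection, pool_x, pool_y, cfg.sample_frac, rng)

    counts = {"XX": 0, "XY": 0, "YX": 0, "YY": 0}
    restarts = 0
    failures = 0
    episodes = 0
    for start, start_side in starts:
        for _ in range(cfg.walks_per_start):
            episodes += 1
            cur, cur_side = start, start_side
            attempts = 0
            absorbed = None
            while absorbed is None:
                v = cur
                for _step in range(l_rw):
                    v = table.step(v, rng)
                    if v is None:  # isolated start; cannot move
                        break
                    if v in absorbing_side:
                        absorbed = absorbing_side[v]
                        break
                if absorbed is not None:
                    break
                attempts += 1
                if attempts > cfg.restart_cap:
                    failures += 1
                    break
                restarts += 1
                # fresh random start: side with probability 0.5, node uniform
                cur_side = "X" if rng.random() < 0.5 else "Y"
                pool = pool_x if cur_side == "X" else pool_y
                cur = pool[rng.randrange(len(pool))]
            if absorbed is not None:
                counts[cur_side + absorbed] += 1

    if episodes and failures / episodes > 0.5:
        raise RuntimeError(
            f"{failures}/{episodes} walks failed to reach an authoritative node "
            f"within {cfg.restart_cap} restarts; increase l_rw (currently {l_rw})"
        )

    end_x = counts["XX"] + counts["YX"]
    end_y = counts["YY"] + counts["XY"]
    if end_x == 0 or end_y == 0:
        raise RuntimeError(
            "no walk was absorbed on one of the sides; cannot condition on the end"
        )
    p_xx = counts["XX"] / end_x
    p_yx = counts["YX"] / end_x
    p_yy = counts["YY"] / end_y
    p_xy = counts["XY"] / end_y
    value = p_xx * p_yy - p_xy * p_yx
    var = p_xx * (1 - p_xx) / end_x + p_yy * (1 - p_yy) / end_y
    return ControversyEstimate(
        measure=measure,
        value=value,
        std_error=math.sqrt(var),
        probabilities={"P_XX": p_xx, "P_XY": p_xy, "P_YX": p_yx, "P_YY": p_yy},
        diagnostics={
            "n_walks": episodes,
            "n_absorbed": end_x + end_y,
            "restarts": restarts,
            "failures": failures,
            "l_rw": l_rw,
            "n_starts": len(starts),
            "starts_X": [v for v, s in starts if s == "X"],
            "starts_Y": [v for v, s in starts if s == "Y"],
            "auth_sizes": {"X": len(auth["X"]), "Y": len(auth["Y"])},
        },
    )


def estimate_rwc(
    G: nx.Graph, bisection: Bisection, cfg: WalkConfig | None = None
) -> ControversyEstimate:
    """Monte-Carlo Random Walk Controversy with restart mechanism."""
    return _run_absorbing_walks(G, bisection, cfg or WalkConfig(), "RWC", False)


def estimate_arwc(
    G: nx.Graph, bisection: Bisection, cfg: WalkConfig | None = None
) -> ControversyEstimate:
    """Authoritative RWC: identical protocol, starts drawn from the
    authoritative sets only."""
    return _run_absorbing_walks(G, bisection, cfg or WalkConfig(), "ARWC", True)


def exact_rwc(
    G: nx.Graph,
    bisection: Bisection,
    auth: Mapping[str, set] | None = None,
    start_distribution: str | tuple[Sequence, Sequence] = "uniform",
    weight_biased: bool = True,
    auth_pct: float = 15.0,
    weight: str = "weight",
    return_probabilities: bool = False,
):
    """Closed-form RWC via the absorbing Markov chain (oracle, |V| <= 2000).

    Authoritative nodes absorb; absorption probabilities for every start are
    obtained from the linear system ``(I - Q) B = R`` of the chain, with the
    estimator's transition rule and no step cap.  ``start_distribution`` is
    ``"uniform"`` (over each side, RWC), ``"authoritative"`` (ARWC), or an
    explicit pair of start-node sequences ``(starts_X, starts_Y)`` — e.g. the
    sampled starts an estimator reports in its diagnostics.
    """
    n = G.number_of_nodes()
    if n > 2000:
        raise ValueError("exact oracle limited to 2000 vertices")
    if auth is None:
        auth = authoritative_nodes(G, bisection, auth_pct)
    nodes = sorted(G.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    absorbing = set(auth["X"]) | set(auth["Y"])

    P = np.zeros((n, n))
    for v in nodes:
        nbrs = list(G[v].items())
        if not nbrs:
            continue
        ws = np.array(
            [float(d.get(weight, 1.0)) if weight_biased else 1.0 for _, d in nbrs]
        )
        ws = ws / ws.sum()
        for (u, _), w in zip(nbrs, ws):
            P[index[v], index[u]] = w

    transient = [v for v in nodes if v not in absorbing]
    t_idx = [index[v] for v in transient]
    a_idx = [index[v] for v in sorted(absorbing, key=str)]
    a_class = np.array(
        [0 if v in auth["X"] else 1 for v in sorted(absorbing, key=str)]
    )
    Q = P[np.ix_(t_idx, t_idx)]
    R = P[np.ix_(t_idx, a_idx)]
    Rc = np.zeros((len(t_idx), 2))
    Rc[:, 0] = R[:, a_class == 0].sum(axis=1)
    Rc[:, 1] = R[:, a_class == 1].sum(axis=1)
    if len(t_idx):
        B = np.linalg.solve(np.eye(len(t_idx)) - Q, Rc)
    else:
        B = np.zeros((0, 2))
    b_of = {v: B[i] for i, v in enumerate(transient)}

    def absorb_from(v) -> np.ndarray:
        """P(absorbed in X / Y) for a walk leaving v (first check after a step)."""
        out = np.zeros(2)
        for u, d in G[v].items():
            w = float(d.get(weight, 1.0)) if weight_biased else 1.0
            if u in absorbing:
                out += w * np.array(
                    [1.0, 0.0] if u in auth["X"] else [0.0, 1.0]
                )
            else:
                out += w * b_of[u]
        total = sum(
            float(d.get(weight, 1.0)) if weight_biased else 1.0
            for _, d in G[v].items()
        )
        if total == 0:
            raise ValueError(f"start {v!r} is isolated; cannot reach any absorbing node")
        out = out / total
        if out.sum() < 1.0 - 1e-9:
            raise ValueError(
                f"start {v!r} cannot reach an authoritative node with probability 1"
            )
        return out

    if isinstance(start_distribution, tuple):
        starts_x, starts_y = list(start_distribution[0]), list(start_distribution[1])
        if not starts_x or not starts_y:
            raise ValueError("explicit start sets must be nonempty on both sides")
    elif start_distribution == "uniform":
        starts_x, starts_y = sorted(bisection.X, key=str), sorted(bisection.Y, key=str)
    elif start_distribution == "authoritative":
        starts_x, starts_y = sorted(auth["X"], key=str), sorted(auth["Y"], key=str)
    else:
        raise ValueError(f"unknown start distribution {start_distribution!r}")

    hx = np.mean([absorb_from(v) for v in starts_x], axis=0)
    hy = np.mean([absorb_from(v) for v in starts_y], axis=0)
    # joint P(start side, absorbed side) with sides drawn 0.5 / 0.5
    joint = 0.5 * np.array([hx, hy])  # rows: start X/Y, cols: absorbed X/Y
    end = joint.sum(axis=0)
    p_xx = joint[0, 0] / end[0]
    p_yx = joint[1, 0] / end[0]
    p_yy = joint[1, 1] / end[1]
    p_xy = joint[0, 1] / end[1]
    value = float(p_xx * p_yy - p_xy * p_yx)
    if return_probabilities:
        return value, {"P_XX": p_xx, "P_XY": p_xy, "P_YX": p_yx, "P_YY": p_yy}
    return value


def drwc(
    G: nx.Graph, bisection: Bisection, cfg: WalkConfig | None = None
) -> ControversyEstimate:
    """Displacement RWC: fixed-length walks, counting community crossings.

    For each sampled node one walk of exactly ``l_rw`` steps runs with no
    absorption; ``n_cc`` counts steps whose endpoint lies in the other
    community than the step's origin.  DRWC is the mean of ``1 - n_cc/l_rw``.
    """
    cfg = cfg or WalkConfig()
    l_rw = _resolve_l_rw(G, cfg)
    if l_rw < 1:
        raise ValueError("l_rw must be >= 1")
    rng = random.Random(cfg.seed)
    table = _WalkTable(G, cfg.weight_biased)
    in_x = {v: (v in bisection.X) for v in G.nodes}
    starts = _sample_starts(
        bisection,
        sorted(bisection.X, key=str),
        sorted(bisection.Y, key=str),
        cfg.sample_frac,
        rng,
    )
    per_node = []
    for v, _side in starts:
        cur = v
        n_cc = 0
        for _ in range(l_rw):
            nxt = table.step(cur, rng)
            if nxt is None:
                break
            if in_x[nxt] != in_x[cur]:
                n_cc += 1
            cur = nxt
        per_node.append(1.0 - n_cc / l_rw)
    value = float(np.mean(per_node))
    se = float(np.std(per_node, ddof=1) / math.sqrt(len(per_node))) if len(per_node) > 1 else float("nan")
    return ControversyEstimate(
        measure="DRWC",
        value=value,
        std_error=se,
        diagnostics={"l_rw": l_rw, "n_sampled": len(per_node), "per_node": per_node},
    )


def boundary_sets(
    G: nx.Graph, bisection: Bisection, own_side_only: bool = False
) -> BoundarySets:
    """Boundary/internal vertex sets of both sides.

    A vertex u in X is *boundary* iff it has at least one neighbour in Y and
    at least one neighbour in X that itself has no neighbour in Y (and
    symmetrically for Y).  ``d_i``/``d_b`` count edges from each boundary
    vertex to the internal and boundary sets; by default those are the unions
    I and B across sides, with ``own_side_only`` restricting them to the
    vertex's own side (the source formulation of the measure).
    """
    X, Y = bisection.X, bisection.Y
    touches_other = {
        v: any((u in Y) if v in X else (u in X) for u in G[v]) for v in G.nodes
    }
    B_X = {
        u
        for u in X
        if touches_other[u]
        and any((w in X) and not touches_other[w] for w in G[u])
    }
    B_Y = {
        u
        for u in Y
        if touches_other[u]
        and any((w in Y) and not touches_other[w] for w in G[u])
    }
    I_X, I_Y = set(X) - B_X, set(Y) - B_Y
    d_i: dict = {}
    d_b: dict = {}
    for u in B_X | B_Y:
        if own_side_only:
            internal = I_X if u in X else I_Y
            boundary = B_X if u in X else B_Y
        else:
            internal = I_X | I_Y
            boundary = B_X | B_Y
        d_i[u] = sum(1 for w in G[u] if w in internal)
        d_b[u] = sum(1 for w in G[u] if w in boundary and w != u)
    return BoundarySets(B_X=B_X, B_Y=B_Y, I_X=I_X, I_Y=I_Y, d_i=d_i, d_b=d_b)


def boundary_connectivity(
    G: nx.Graph, bisection: Bisection, own_side_only: bool = False
) -> float:
    """BC = mean over boundary vertices of d_i/(d_b + d_i) - 0.5, in [-0.5, 0.5]."""
    sets = boundary_sets(G, bisection, own_side_only=own_side_only)
    B = sorted(sets.B, key=str)
    if not B:
        raise ValueError("boundary connectivity undefined: boundary set is empty")
    total = 0.0
    for u in B:
        di, db = sets.d_i[u], sets.d_b[u]
        if di + db == 0:
            continue
        total += di / (db + di) - 0.5
    return total / len(B)


def partition_quality(
    G: nx.Graph, bisection: Bisection, weight: str = "weight"
) -> dict[str, float]:
    """Weighted Newman–Girvan modularity and coverage of the 2-partition."""
    if G.number_of_edges() == 0:
        raise ValueError("partition quality requires at least one edge")
    communities = [set(bisection.X) & set(G.nodes), set(bisection.Y) & set(G.nodes)]
    mod = nx.algorithms.community.modularity(G, communities, weight=weight)
    total = 0.0
    intra = 0.0
    for u, v, data in G.edges(data=True):
        w = float(data.get(weight, 1.0))
        total += w
        if (u in bisection.X) == (v in bisection.X):
            intra += w
    return {"modularity": float(mod), "coverage": intra / total}
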