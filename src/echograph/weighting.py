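"""Semantic edge re-weighting of the conversation graph.

Given per-user sentiment means s(v) on [-alpha, +alpha] and topic sets
T(v) within a global topic set T, the four graph representations carry:

* topology:  w_t        (mention count, unchanged)
* sentiment: w_ss = 1 + ss,  ss = 2*alpha - |s(v_i) - s(v_j)|
* topic:     w_ts = 1 + ts,  ts = |T| - |T(v_i) symdiff T(v_j)|
* hybrid:    w_h  = 1 + ss + ts

A similarity of zero leaves weight 1: the bare topological link.  Semantic
modes only replace weights; the edge set never changes, and the original
w_t is retained as an edge attribute for change analyses.
"""

from __future__ import annotations

from typing import Set

import networkx as nx

from .profiles import UserProfiles

__all__ = [
    "sentiment_similarity",
    "topic_similarity",
    "apply_representation",
    "SCHEMES",
]

SCHEMES = ("topology", "sentiment", "topic", "hybrid")


def sentiment_similarity(s_i: float, s_j: float, alpha: int = 30) -> float:
    """ss(v_i, v_j) = 2*alpha - |s_i - s_j|, in [0, 2*alpha]."""
    if not (-alpha <= s_i <= alpha and -alpha <= s_j <= alpha):
        raise ValueError(
            f"sentiment scores ({s_i}, {s_j}) outside [-{alpha}, +{alpha}]"
        )
    return 2 * alpha - abs(s_i - s_j)


def topic_similarity(T_i: Set[int], T_j: Set[int], T: Set[int]) -> int:
    """ts(v_i, v_j) = |T| - |T_i symdiff T_j|, in [0, |T|].

    Maximal (= |T|) iff the two users discuss exactly the same topics;
    minimal (= 0) iff their topic sets are disjoint and jointly cover T.
    """
    T_i, T_j, T = set(T_i), set(T_j), set(T)
    if not (T_i <= T and T_j <= T):
        raise ValueError("user topic sets must be subsets of the global topic set")
    return len(T) - len(T_i ^ T_j)


def apply_representation(
    graph: nx.Graph,
    profiles: UserProfiles,
    mode: str,
    strict: bool = False,
) -> nx.Graph:
    """Return the conversation graph under one of the four weight schemes.

    The edge set is copied unchanged; only the active ``weight`` attribute is
    replaced (w_ss / w_ts / w_h), and ``ss``/``ts`` are stored per edge for
    inspection.  ``mode="topology"`` returns the input untouched.  With
    ``strict`` a missing profile raises instead of defaulting to neutral.
    """
    if mode not in SCHEMES:
        raise ValueError(f"unknown representation {mode!r}; expected one of {SCHEMES}")
    if mode == "topology":
        return graph

    alpha = profiles.alpha
    T = set(range(1, profiles.n_topics + 1))
    if mode in ("topic", "hybrid") and not T:
        raise ValueError("topic-based weighting requires a fitted topic model")

    G = graph.copy()
    G.graph["scheme"] = mode
    for u, v, data in G.edges(data=True):
        if mode in ("sentiment", "hybrid"):
            ss = sentiment_similarity(
                profiles.s(u, strict=strict), profiles.s(v, strict=strict), alpha
            )
            data["ss"] = ss
        if mode in ("topic", "hybrid"):
            ts = topic_similarity(
                profiles.topics(u, strict=strict),
                profiles.topics(v, strict=strict),
                T,
            )
            data["ts"] = ts
        if mode == "sentiment":
            data["weight"] = 1 + data["ss"]
        elif mode == "topic":
            data["weight"] = 1 + data["ts"]
        else:
            data["weight"] = 1 + data["ss"] + data["ts"]
    return G
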