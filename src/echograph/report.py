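"""Per-community homogeneity summaries: sentiment distributions, verified
account shares, topic prevalence and account-description keywords."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import TweetRecord
from .partition import Bisection
from .profiles import UserProfiles
from .topics import tokenize

__all__ = [
    "CommunitySummary",
    "community_summary",
    "topic_prevalence",
    "profile_keywords",
    "plot_community_summaries",
]


@dataclass
class CommunitySummary:
    """Machine-readable homogeneity summary of one community."""

    label: str
    member_count: int
    bin_edges: list[float]
    probabilities: list[float]
    verified_fraction: float  # percent
    verified_probabilities: list[float] | None = None
    mean_sentiment: float = 0.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "member_count": self.member_count,
            "bin_edges": self.bin_edges,
            "probabilities": self.probabilities,
            "verified_fraction": self.verified_fraction,
            "verified_probabilities": self.verified_probabilities,
            "mean_sentiment": self.mean_sentiment,
        }


def _histogram(values: Sequence[float], edges: np.ndarray) -> list[float]:
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        return [0.0] * len(counts)
    return (counts / total).tolist()


def community_summary(
    bisection: Bisection,
    profiles: UserProfiles,
    bins: Sequence[float] | None = None,
    include_verified_histogram: bool = True,
) -> tuple[CommunitySummary, CommunitySummary]:
    """Sentiment histogram and verified share per community.

    Histograms are normalised to probabilities; the default binning centres
    one bin on each integer of the [-alpha, +alpha] scale.
    """
    alpha = profiles.alpha
    edges = (
        np.asarray(bins, dtype=float)
        if bins is not None
        else np.arange(-alpha - 0.5, alpha + 1.5, 1.0)
    )
    out = []
    for label, side in (("A", bisection.X), ("B", bisection.Y)):
        members = sorted(side, key=str)
        if not members:
            raise ValueError(f"community {label} is empty")
        svals = [profiles.s(u) for u in members]
        verified = [u for u in members if profiles.verified(u)]
        ver_hist = None
        if include_verified_histogram and verified:
            ver_hist = _histogram([profiles.s(u) for u in verified], edges)
        out.append(
            CommunitySummary(
                label=label,
                member_count=len(members),
                bin_edges=edges.tolist(),
                probabilities=_histogram(svals, edges),
                verified_fraction=100.0 * len(verified) / len(members),
                verified_probabilities=ver_hist,
                mean_sentiment=float(np.mean(svals)),
            )
        )
    return out[0], out[1]


def topic_prevalence(
    bisection: Bisection, topic_sets: Mapping[str, set[int]]
) -> pd.DataFrame:
    """Per-community member counts for every topic, plus the share difference.

    A member counts towards topic k when k is in their topic set T(v).
    Shares are within-community fractions; ``share_diff`` is share_A - share_B.
    """
    topics = sorted({k for ts in topic_sets.values() for k in ts})
    n_a, n_b = len(bisection.X), len(bisection.Y)
    rows = []
    for k in topics:
        count_a = sum(1 for u in bisection.X if k in topic_sets.get(u, set()))
        count_b = sum(1 for u in bisection.Y if k in topic_sets.get(u, set()))
        share_a = count_a / n_a if n_a else 0.0
        share_b = count_b / n_b if n_b else 0.0
        rows.append(
            {
                "topic": k,
                "count_A": count_a,
                "count_B": count_b,
                "share_A": share_a,
                "share_B": share_b,
                "share_diff": share_a - share_b,
            }
        )
    return pd.DataFrame(
        rows, columns=["topic", "count_A", "count_B", "share_A", "share_B", "share_diff"]
    )


def profile_keywords(
    bisection: Bisection,
    records: Iterable[TweetRecord],
    top_n: int = 50,
    stem: bool = False,
) -> dict[str, list[tuple[str, int]]]:
    """Ranked keywords from members' account descriptions, per community.

    Each member contributes one description (their first non-empty one);
    tokens are counted with the tweet tokenizer (stemming off by default, so
    the keywords stay readable, as in a wordcloud) and the ``top_n`` most
    frequent are returned with their counts.  Order of members is irrelevant.
    """
    desc: dict[str, str] = {}
    for rec in records:
        if rec.author not in desc and rec.description:
            desc[rec.author] = rec.description
    out: dict[str, list[tuple[str, int]]] = {}
    for label, side in (("A", bisection.X), ("B", bisection.Y)):
        counter: Counter[str] = Counter()
        for user in sorted(side, key=str):
            text = desc.get(user, "")
            if text:
                counter.update(tokenize(text, stem=stem))
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        out[label] = ranked[:top_n]
    return out


def plot_community_summaries(
    summary_a: CommunitySummary,
    summary_b: CommunitySummary,
    path,
    verified_only: bool = False,
) -> None:
    """Optional PNG plot: per-community sentiment distributions side by side
    with the verified-account shares.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.2), gridspec_kw={"width_ratios": [3, 1]}
    )
    for summary, color in ((summary_a, "tab:blue"), (summary_b, "tab:red")):
        probs = (
            summary.verified_probabilities
            if verified_only and summary.verified_probabilities is not None
            else summary.probabilities
        )
        edges = np.asarray(summary.bin_edges)
        centers = (edges[:-1] + edges[1:]) / 2
        ax1.plot(centers, probs, color=color,
                 label=f"Community {summary.label}")
    ax1.set_xlabel("sentiment score")
    ax1.set_ylabel("probability")
    ax1.legend()
    ax2.bar(
        ["A", "B"],
        [summary_a.verified_fraction, summary_b.verified_fraction],
        color=["tab:blue", "tab:red"],
    )
    ax2.set_ylabel("verified accounts (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
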