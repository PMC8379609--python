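"""Per-user semantic profiles shared by the weighting and reporting stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .ingest import TweetRecord
from .sentiment import ScalingConfig, SentimentProfile, build_sentiment_profiles
from .topics import TopicModelResult, assign_user_topics, tokenize

__all__ = ["UserProfiles", "build_profiles"]


@dataclass
class UserProfiles:
    """Sentiment means, topic sets and verified flags keyed by username."""

    alpha: int
    n_topics: int
    sentiment: dict[str, SentimentProfile] = field(default_factory=dict)
    topic_sets: dict[str, set[int]] = field(default_factory=dict)

    def s(self, user: str, strict: bool = False) -> float:
        prof = self.sentiment.get(user)
        if prof is None:
            if strict:
                raise KeyError(f"no sentiment profile for user {user!r}")
            return 0.0
        return prof.s

    def topics(self, user: str, strict: bool = False) -> set[int]:
        ts = self.topic_sets.get(user)
        if ts is None:
            if strict:
                raise KeyError(f"no topic set for user {user!r}")
            return set()
        return ts

    def verified(self, user: str) -> bool:
        prof = self.sentiment.get(user)
        return bool(prof.verified) if prof is not None else False

    def to_frame(self) -> pd.DataFrame:
        """Per-user profile table (user, t, s, topics, verified, defaulted)."""
        rows = []
        for user in sorted(self.sentiment):
            prof = self.sentiment[user]
            rows.append(
                {
                    "user": user,
                    "t": prof.t,
                    "s": prof.s,
                    "topics": ";".join(map(str, sorted(self.topics(user)))),
                    "verified": prof.verified,
                    "defaulted": prof.defaulted,
                }
            )
        return pd.DataFrame(rows)


def build_profiles(
    records: Iterable[TweetRecord],
    users: Iterable[str] | None = None,
    scaling: ScalingConfig | None = None,
    empirical_scaling: bool = False,
    topic_model: TopicModelResult | None = None,
    topic_rule: str = "dominant",
    topic_threshold: float = 0.25,
) -> UserProfiles:
    """Assemble sentiment and (optionally) topic profiles for every user.

    ``users`` should be the conversation-graph vertex set so that
    mentioned-but-silent users receive the neutral defaults (s(v)=0, empty
    topic set, flagged ``defaulted``).  Topic sets are only filled in when a
    fitted ``topic_model`` is supplied.
    """
    records = list(records)
    sent = build_sentiment_profiles(
        records, users=users, cfg=scaling, empirical_scaling=empirical_scaling
    )
    alpha = (scaling or ScalingConfig()).alpha
    topic_sets: dict[str, set[int]] = {}
    n_topics = 0
    if topic_model is not None:
        n_topics = topic_model.selected_k
        docs_by_user: dict[str, list[list[str]]] = {}
        for rec in records:
            docs_by_user.setdefault(rec.author, []).append(tokenize(rec.text))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for user in sent:
                topic_sets[user] = assign_user_topics(
                    topic_model,
                    docs_by_user.get(user, []),
                    rule=topic_rule,
                    threshold=topic_threshold,
                    user=user,
                )
    return UserProfiles(
        alpha=alpha, n_topics=n_topics, sentiment=sent, topic_sets=topic_sets
    )
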