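"""Lexicon-based sentiment scoring and the user sentiment score s(v).

Each tweet receives a *compound* score in [-1, +1] from a rule-based lexicon
scorer (word valences plus booster, negation and all-caps rules, squashed by
x / sqrt(x^2 + 15)).  Compound scores are linearly rescaled onto a discrete
integer interval [-alpha, +alpha] (alpha = 30 by default) and a user's
sentiment s(v) is the arithmetic mean of their scaled tweet scores.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from ._lexicon import BOOSTERS, NEGATIONS, VALENCES
from .ingest import TweetRecord

__all__ = [
    "ScalingConfig",
    "SentimentProfile",
    "LexiconSentimentScorer",
    "compound_score",
    "scale_score",
    "user_sentiment",
    "build_sentiment_profiles",
]

_NORM_CONST = 15.0
_CAPS_BOOST = 0.733
_NEGATION_FACTOR = -0.74
_WORD_RE = re.compile(r"[A-Za-z']+")


@dataclass(frozen=True)
class ScalingConfig:
    """Linear conversion from the compound range onto [-alpha, +alpha].

    ``old_min``/``old_max`` default to the compound score's theoretical range
    [-1, +1]; :meth:`from_scores` instead fits them to an observed score
    distribution (empirical scaling).  ``neutral_band`` is expressed on the
    raw compound scale.
    """

    alpha: int = 30
    old_min: float = -1.0
    old_max: float = 1.0
    neutral_band: tuple[float, float] = (-0.05, 0.05)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be a positive integer")
        if not self.old_max > self.old_min:
            raise ValueError("old_max must exceed old_min")

    @property
    def new_min(self) -> int:
        return -self.alpha

    @property
    def new_max(self) -> int:
        return self.alpha

    @property
    def old_range(self) -> float:
        return self.old_max - self.old_min

    @property
    def new_range(self) -> int:
        return 2 * self.alpha

    @classmethod
    def from_scores(cls, scores: Iterable[float], alpha: int = 30) -> "ScalingConfig":
        scores = list(scores)
        if not scores:
            raise ValueError("cannot fit scaling to an empty score list")
        lo, hi = min(scores), max(scores)
        if hi == lo:  # degenerate distribution: fall back to theoretical range
            lo, hi = -1.0, 1.0
        return cls(alpha=alpha, old_min=lo, old_max=hi)

    def is_neutral(self, compound: float) -> bool:
        lo, hi = self.neutral_band
        return lo <= compound <= hi


class LexiconSentimentScorer:
    """Rule-based compound sentiment scorer for short social-media text.

    Word valences from a bundled lexicon are adjusted by intensity boosters
    ("very good"), dampeners ("slightly bad"), negations within a three-token
    window ("not good") and all-caps emphasis, then summed and normalised to
    [-1, +1].  Deterministic: the same text always maps to the same score.
    """

    def __init__(
        self,
        valences: Mapping[str, float] | None = None,
        boosters: Mapping[str, float] | None = None,
        negations: frozenset[str] | None = None,
    ) -> None:
        self.valences = dict(VALENCES if valences is None else valences)
        self.boosters = dict(BOOSTERS if boosters is None else boosters)
        self.negations = NEGATIONS if negations is None else negations

    def score(self, text: str) -> float:
        tokens = _WORD_RE.findall(text)
        if not tokens:
            return 0.0
        lowered = [t.lower().replace("'", "") for t in tokens]
        mixed_case = not all(t.isupper() for t in tokens if t.isalpha())
        total = 0.0
        for i, tok in enumerate(lowered):
            valence = self.valences.get(tok)
            if valence is None:
                continue
            if mixed_case and tokens[i].isupper() and len(tokens[i]) > 1:
                valence += math.copysign(_CAPS_BOOST, valence)
            # booster / dampener words scale with distance (closest strongest)
            for dist, j in enumerate(range(i - 1, max(i - 4, -1), -1)):
                prev = lowered[j]
                if prev in self.boosters:
                    increment = self.boosters[prev] * (1.0 - 0.05 * dist)
                    valence += math.copysign(1.0, valence) * increment
            if any(lowered[j] in self.negations for j in range(max(i - 3, 0), i)):
                valence *= _NEGATION_FACTOR
            total += valence
        compound = total / math.sqrt(total * total + _NORM_CONST)
        return max(-1.0, min(1.0, compound))

    __call__ = score


_default_scorer: LexiconSentimentScorer | None = None


def default_scorer() -> LexiconSentimentScorer:
    global _default_scorer
    if _default_scorer is None:
        _default_scorer = LexiconSentimentScorer()
    return _default_scorer


def compound_score(
    text: str, scorer: Callable[[str], float] | None = None
) -> float:
    """Score a text with a pluggable compound scorer, validating its range."""
    scorer = scorer or default_scorer()
    value = scorer(text)
    if not -1.0 <= value <= 1.0:
        raise ValueError(
            f"sentiment scorer violated its contract: compound {value} outside [-1, 1]"
        )
    return value


def scale_score(x: float, cfg: ScalingConfig | None = None) -> int:
    """Linearly rescale a compound score onto the integer interval [-alpha, +alpha].

    Rounds half away from zero so the conversion stays odd-symmetric about the
    interval midpoint.
    """
    cfg = cfg or ScalingConfig()
    if not cfg.old_min <= x <= cfg.old_max:
        raise ValueError(
            f"compound score {x} outside scaling interval [{cfg.old_min}, {cfg.old_max}]"
        )
    value = (x - cfg.old_min) * cfg.new_range / cfg.old_range + cfg.new_min
    scaled = math.floor(value + 0.5) if value >= 0 else math.ceil(value - 0.5)
    return int(min(max(scaled, cfg.new_min), cfg.new_max))


def user_sentiment(scaled_scores: Sequence[float]) -> float:
    """Arithmetic mean of a user's scaled tweet scores (not re-rounded)."""
    if len(scaled_scores) == 0:
        raise ValueError("user has no scored tweets; caller must decide a default")
    return sum(scaled_scores) / len(scaled_scores)


@dataclass
class SentimentProfile:
    """Per-user sentiment summary."""

    user: str
    raw_scores: list[float] = field(default_factory=list)
    scaled_scores: list[int] = field(default_factory=list)
    verified: bool = False
    defaulted: bool = False  # True for graph users with no tweets (s(v) := 0)

    @property
    def t(self) -> int:
        return len(self.scaled_scores)

    @property
    def s(self) -> float:
        if self.defaulted or not self.scaled_scores:
            return 0.0
        return user_sentiment(self.scaled_scores)


def build_sentiment_profiles(
    records: Iterable[TweetRecord],
    users: Iterable[str] | None = None,
    scorer: Callable[[str], float] | None = None,
    cfg: ScalingConfig | None = None,
    empirical_scaling: bool = False,
) -> dict[str, SentimentProfile]:
    """Score every tweet and aggregate to per-user profiles.

    ``users`` optionally extends the profile set to graph vertices that never
    authored a tweet; those receive a neutral s(v) = 0 and are flagged
    ``defaulted``.  With ``empirical_scaling`` the conversion interval is fit
    to the observed compound-score distribution instead of [-1, +1].
    """
    records = list(records)
    scorer = scorer or default_scorer()
    raw: dict[str, list[float]] = {}
    verified: dict[str, bool] = {}
    for rec in records:
        raw.setdefault(rec.author, []).append(compound_score(rec.text, scorer))
        verified[rec.author] = verified.get(rec.author, False) or rec.verified

    if cfg is None:
        if empirical_scaling:
            cfg = ScalingConfig.from_scores(
                [x for xs in raw.values() for x in xs]
            )
        else:
            cfg = ScalingConfig()

    profiles: dict[str, SentimentProfile] = {}
    for user, xs in raw.items():
        profiles[user] = SentimentProfile(
            user=user,
            raw_scores=xs,
            scaled_scores=[scale_score(x, cfg) for x in xs],
            verified=verified[user],
        )
    if users is not None:
        for user in users:
            if user not in profiles:
                profiles[user] = SentimentProfile(user=user, defaulted=True)
    return profiles
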