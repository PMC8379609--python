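"""Synthetic polarized tweet corpora and planted-partition mention graphs.

The generator plants two user communities with (i) homophilous mention
topology — per-pair mention counts are Poisson with an intra-community mean
``p_in`` and an inter-community mean ``p_out`` — (ii) community-shifted
sentiment, realised through phrases built from lexicon words whose compound
score is calibrated against the bundled scorer, and (iii) community-specific
topic vocabularies mixed with a shared vocabulary.  Corpus and graph share
one seed stream, so the mention graph built from the corpus reproduces the
planted graph exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .ingest import EmptyGraphError, TweetRecord
from .sentiment import default_scorer

__all__ = [
    "PolarizationSpec",
    "generate_planted_graph",
    "generate_polarized_corpus",
    "write_corpus_jsonl",
]

_TOPIC_VOCAB_A = [
    "vaccine", "research", "hospital", "doctors", "testing", "symptoms",
    "treatment", "science", "epidemiology", "immunity", "clinical", "data",
]
_TOPIC_VOCAB_B = [
    "hoax", "conspiracy", "media", "government", "freedom", "borders",
    "election", "propaganda", "china", "blame", "coverup", "patriots",
]
_SHARED_VOCAB = [
    "virus", "outbreak", "pandemic", "cases", "world", "people", "news",
    "update", "spread", "country",
]
_DESCRIPTION_VOCAB_A = [
    "research", "health", "science", "journalist", "medicine", "public",
    "epidemiology", "professor", "reporter", "data",
]
_DESCRIPTION_VOCAB_B = [
    "patriot", "conservative", "freedom", "god", "maga", "family",
    "christian", "truth", "america", "proud",
]


@dataclass(frozen=True)
class PolarizationSpec:
    """Planted-polarization study conditions.

    ``p_in``/``p_out`` are per-pair Poisson means for mention-event counts;
    with the mention threshold of 3 the defaults give a dense intra-community
    graph with only a handful of surviving cross edges (rate ratio 10), i.e.
    strongly but not perfectly separated communities.  Sentiment
    means sit on the compound scale, one positive and one negative community
    (separation 1.2).  Verified-account shares loosely mirror a
    science-leaning versus politics-leaning community.
    """

    n_users: int = 50  # per community
    tweets_per_user: float = 6.0  # extra (non-mention) tweets, Poisson mean
    p_in: float = 3.0
    p_out: float = 0.3
    mu_a: float = 0.6
    mu_b: float = -0.6
    sigma: float = 0.15
    mixing: float = 0.3  # share of topic words drawn from the shared vocabulary
    topic_vocab_a: tuple[str, ...] = tuple(_TOPIC_VOCAB_A)
    topic_vocab_b: tuple[str, ...] = tuple(_TOPIC_VOCAB_B)
    shared_vocab: tuple[str, ...] = tuple(_SHARED_VOCAB)
    verified_p_a: float = 0.22
    verified_p_b: float = 0.12
    min_edge_weight: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out <= self.p_in:
            raise ValueError("require 0 <= p_out <= p_in")
        if not (-1 <= self.mu_a <= 1 and -1 <= self.mu_b <= 1):
            raise ValueError("sentiment means must lie in [-1, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")

    def users(self) -> tuple[list[str], list[str]]:
        width = max(3, len(str(self.n_users - 1)))
        a = [f"a{i:0{width}d}" for i in range(self.n_users)]
        b = [f"b{i:0{width}d}" for i in range(self.n_users)]
        return a, b


def _pair_counts(spec: PolarizationSpec) -> dict[tuple[str, str], int]:
    """Mention-event counts per unordered user pair (the shared seed stream)."""
    rng = np.random.default_rng(spec.seed)
    users_a, users_b = spec.users()
    everyone = users_a + users_b
    community = {u: 0 for u in users_a}
    community.update({u: 1 for u in users_b})
    counts: dict[tuple[str, str], int] = {}
    for i, u in enumerate(everyone):
        for v in everyone[i + 1 :]:
            lam = spec.p_in if community[u] == community[v] else spec.p_out
            c = int(rng.poisson(lam))
            if c > 0:
                counts[(u, v)] = c
    return counts


def generate_planted_graph(
    spec: PolarizationSpec, min_edge_weight: int | None = None
) -> tuple[nx.Graph, dict[str, int]]:
    """Planted mention graph and ground-truth community labels (0 = A, 1 = B).

    Labels are returned for the vertices surviving the edge threshold (as in
    the ingest stage, isolated users are dropped).
    """
    threshold = spec.min_edge_weight if min_edge_weight is None else min_edge_weight
    counts = _pair_counts(spec)
    G = nx.Graph(scheme="topology")
    for (u, v), c in sorted(counts.items()):
        if c >= threshold:
            G.add_edge(u, v, weight=c, w_t=c)
    if G.number_of_edges() == 0:
        raise EmptyGraphError(
            f"planted graph has no edge at threshold {threshold}; "
            "increase p_in or lower the threshold"
        )
    labels = {v: (0 if v.startswith("a") else 1) for v in G.nodes}
    return G, labels


_PHRASE_WORDS_POS = ["good", "great", "hope", "safe", "love", "recover"]
_PHRASE_WORDS_NEG = ["bad", "fear", "death", "crisis", "terrible", "sick"]

_phrase_bank_cache: dict[int, list[tuple[float, str]]] = {}


def _phrase_bank(scorer: Callable[[str], float]) -> list[tuple[float, str]]:
    """(compound score, phrase) ladder calibrated against the scorer."""
    key = id(scorer)
    cached = _phrase_bank_cache.get(key)
    if cached is not None:
        return cached
    phrases = [""]
    for words in (_PHRASE_WORDS_POS, _PHRASE_WORDS_NEG):
        for w in words:
            for k in (1, 2, 3, 4):
                phrases.append(" ".join([w] * k))
            phrases.append(f"very {w}")
            phrases.append(f"slightly {w}")
        for w1 in words:
            for w2 in words:
                if w1 < w2:
                    phrases.append(f"{w1} {w2}")
    bank = sorted((float(scorer(p)), p) for p in set(phrases))
    _phrase_bank_cache[key] = bank
    return bank


def _nearest_phrase(bank: Sequence[tuple[float, str]], target: float) -> str:
    best = min(bank, key=lambda sp: (abs(sp[0] - target), sp[1]))
    return best[1]


def generate_polarized_corpus(
    spec: PolarizationSpec,
    scorer: Callable[[str], float] | None = None,
) -> list[TweetRecord]:
    """Emit tweet records realizing the planted graph, sentiment and topics.

    Mention tweets implement the pair counts of :func:`generate_planted_graph`
    (directions alternate within a pair); every user additionally posts a
    Poisson number of mention-free tweets.  Texts embed a sentiment phrase
    whose compound score approximates a draw from the author community's
    sentiment distribution, topic words from the community and shared
    vocabularies, and the crawl hashtag ``#coronavirus``.
    """
    scorer = scorer or default_scorer()
    bank = _phrase_bank(scorer)
    counts = _pair_counts(spec)
    # content stream separate from the topology stream (keeps counts aligned)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    users_a, users_b = spec.users()
    is_a = {u: True for u in users_a}
    is_a.update({u: False for u in users_b})

    verified = {
        u: bool(rng.random() < (spec.verified_p_a if is_a[u] else spec.verified_p_b))
        for u in users_a + users_b
    }
    descriptions = {}
    for u in users_a + users_b:
        vocab = _DESCRIPTION_VOCAB_A if is_a[u] else _DESCRIPTION_VOCAB_B
        k = min(3, len(vocab))
        words = rng.choice(vocab, size=k, replace=False)
        descriptions[u] = " ".join(words)

    def body(author: str) -> str:
        mu = spec.mu_a if is_a[author] else spec.mu_b
        target = float(np.clip(rng.normal(mu, spec.sigma), -1.0, 1.0))
        phrase = _nearest_phrase(bank, target)
        own = spec.topic_vocab_a if is_a[author] else spec.topic_vocab_b
        words = []
        for _ in range(4):
            pool = spec.shared_vocab if rng.random() < spec.mixing else own
            words.append(str(pool[rng.integers(len(pool))]))
        parts = [phrase, " ".join(words), "#coronavirus"]
        return " ".join(p for p in parts if p)

    records: list[TweetRecord] = []
    tid = 0

    def emit(author: str, mention: str | None) -> None:
        nonlocal tid
        tid += 1
        text = body(author)
        if mention is not None:
            text = f"@{mention} {text}"
        records.append(
            TweetRecord(
                tweet_id=str(tid),
                author=author,
                text=text,
                lang="en",
                description=descriptions[author],
                verified=verified[author],
            )
        )

    for (u, v), c in sorted(counts.items()):
        for k in range(c):
            src, dst = (u, v) if k % 2 == 0 else (v, u)
            emit(src, dst)
    for u in users_a + users_b:
        for _ in range(int(rng.poisson(spec.tweets_per_user))):
            emit(u, None)
    return records


def write_corpus_jsonl(
    records: Sequence[TweetRecord], path: str | Path, spec: PolarizationSpec | None = None
) -> None:
    """Write records in the JSONL format the ingest stage reads; the spec is
    stored as a ``.spec.json`` sidecar for provenance."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": rec.tweet_id,
                        "author": rec.author,
                        "text": rec.text,
                        "lang": rec.lang,
                        "description": rec.description,
                        "verified": rec.verified,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps(asdict(spec), indent=2, sort_keys=True))
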