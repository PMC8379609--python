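"""Topic modelling: tweet tokenization, vocabulary filtering, LDA over a
range of topic counts and coherence-based model selection, and per-user
topic-set assignment T(v).

The number of topics K is chosen by sweeping K over a candidate range
(default 2..30), fitting one LDA model per K, and keeping the model whose
topics maximise a C_V-style coherence (normalised PMI context vectors
compared by cosine similarity under a one-set segmentation, estimated from a
boolean sliding window over the corpus).  Ties go to the smaller K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from ._lexicon import STOPWORDS
from ._stem import porter_stem

__all__ = [
    "tokenize",
    "build_vocabulary",
    "coherence_cv",
    "fit_topic_models",
    "assign_user_topics",
    "TopicModelResult",
]

import re

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"(?:(?<=^)|(?<=[^A-Za-z0-9_]))@[A-Za-z0-9_]+")
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str, stem: bool = True, remove_stopwords: bool = True) -> list[str]:
    """Tweet-aware tokenizer: lowercase, drop URLs and @mentions, strip the
    ``#`` off hashtags, drop punctuation-only tokens and stop-words, then
    Porter-stem."""
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.lower().replace("#", " ")
    tokens = []
    for tok in _TOKEN_RE.findall(text):
        tok = tok.strip("'")
        if not tok or not any(c.isalpha() for c in tok):
            continue
        if remove_stopwords and tok in STOPWORDS:
            continue
        if stem:
            tok = porter_stem(tok)
        if tok:
            tokens.append(tok)
    return tokens


def build_vocabulary(
    docs: Sequence[Sequence[str]],
    min_df: float = 0.02,
    max_df: float = 0.50,
    keep_n: int = 100_000,
) -> list[str]:
    """Document-frequency filter: drop tokens in fewer than ``min_df`` or more
    than ``max_df`` of the documents (as fractions, exclusive bounds), rank the
    survivors by total frequency and keep the top ``keep_n``."""
    if len(docs) == 0:
        raise ValueError("cannot build a vocabulary from zero documents")
    n_docs = len(docs)
    df: dict[str, int] = {}
    tf: dict[str, int] = {}
    for doc in docs:
        seen = set()
        for tok in doc:
            tf[tok] = tf.get(tok, 0) + 1
            if tok not in seen:
                seen.add(tok)
                df[tok] = df.get(tok, 0) + 1
    kept = [
        tok
        for tok, d in df.items()
        if min_df <= d / n_docs <= max_df
    ]
    if not kept:
        raise ValueError(
            "vocabulary is empty after document-frequency filtering; "
            "relax min_df/max_df"
        )
    kept.sort(key=lambda t: (-tf[t], t))
    return kept[:keep_n]


def _doc_term_matrix(
    docs: Sequence[Sequence[str]], vocab: Sequence[str]
) -> sparse.csr_matrix:
    index = {tok: j for j, tok in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.float64
    )


def _sliding_windows(doc: Sequence[str], size: int) -> Iterable[Sequence[str]]:
    if len(doc) <= size:
        yield doc
    else:
        for i in range(len(doc) - size + 1):
            yield doc[i : i + size]


def coherence_cv(
    topics: Sequence[Sequence[str]],
    docs: Sequence[Sequence[str]],
    window: int = 110,
    eps: float = 1e-12,
) -> float:
    """C_V-style coherence of a set of topics against a reference corpus.

    Word and word-pair probabilities are estimated from a boolean sliding
    window (tweets are usually shorter than the window, so in practice one
    window per tweet); every top word gets a context vector of NPMI values
    against the topic's top words, and topic coherence is the mean cosine
    similarity between each word's vector and the vector sum of the whole
    topic (one-set segmentation).  The model score is the mean over topics.
    """
    words = sorted({w for topic in topics for w in topic})
    idx = {w: i for i, w in enumerate(words)}
    n = len(words)
    occ = np.zeros(n)
    joint = np.zeros((n, n))
    n_windows = 0
    for doc in docs:
        for win in _sliding_windows(doc, window):
            n_windows += 1
            present = sorted({idx[t] for t in win if t in idx})
            for a_i, a in enumerate(present):
                occ[a] += 1
                for b in present[a_i + 1 :]:
                    joint[a, b] += 1
                    joint[b, a] += 1
    if n_windows == 0:
        return 0.0
    p = occ / n_windows
    pj = joint / n_windows

    def npmi(a: int, b: int) -> float:
        if a == b:
            return 1.0
        pab = pj[a, b]
        if pab <= 0 or p[a] <= 0 or p[b] <= 0:
            return 0.0
        val = np.log((pab + eps) / (p[a] * p[b])) / -np.log(pab + eps)
        return float(val)

    scores = []
    for topic in topics:
        ids = [idx[w] for w in topic]
        vecs = np.array([[npmi(a, b) for b in ids] for a in ids])
        total = vecs.sum(axis=0)
        tnorm = np.linalg.norm(total)
        sims = []
        for v in vecs:
            vn = np.linalg.norm(v)
            if vn == 0 or tnorm == 0:
                sims.append(0.0)
            else:
                sims.append(float(v @ total / (vn * tnorm)))
        scores.append(float(np.mean(sims)))
    return float(np.mean(scores))


@dataclass
class TopicModelResult:
    """Outcome of the LDA sweep: the selected model plus per-K diagnostics."""

    selected_k: int
    coherence: dict[int, float]
    vocabulary: list[str]
    topic_keywords: list[list[str]]  # per topic, top words ranked
    model: LatentDirichletAllocation = field(repr=False)

    @property
    def topic_set(self) -> set[int]:
        """Global topic set T = {1..K} (1-based indices)."""
        return set(range(1, self.selected_k + 1))

    def doc_topics(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        """Per-document topic probability rows for tokenized docs."""
        X = _doc_term_matrix(docs, self.vocabulary)
        return self.model.transform(X)

    def keywords_table(self) -> list[tuple[int, int, str]]:
        """(topic id, rank, keyword) rows mirroring a per-topic keyword table."""
        rows = []
        for k, words in enumerate(self.topic_keywords, start=1):
            for rank, w in enumerate(words, start=1):
                rows.append((k, rank, w))
        return rows


def fit_topic_models(
    docs: Sequence[Sequence[str]],
    k_range: Iterable[int] = range(2, 31),
    seed: int = 0,
    vocabulary: Sequence[str] | None = None,
    min_df: float = 0.02,
    max_df: float = 0.50,
    keep_n: int = 100_000,
    top_n: int = 10,
    max_iter: int = 20,
) -> TopicModelResult:
    """Fit one LDA model per candidate K and keep the most coherent one.

    Candidate values of K larger than the number of documents are skipped
    with a warning.  Ties in coherence resolve to the smaller K.  The sweep is
    deterministic for a fixed seed.
    """
    docs = list(docs)
    if not docs:
        raise ValueError("empty corpus")
    if vocabulary is None:
        vocabulary = build_vocabulary(docs, min_df=min_df, max_df=max_df, keep_n=keep_n)
    vocabulary = list(vocabulary)
    X = _doc_term_matrix(docs, vocabulary)

    best: tuple[float, int] | None = None
    coh: dict[int, float] = {}
    fitted: dict[int, tuple[LatentDirichletAllocation, list[list[str]]]] = {}
    for k in k_range:
        if k > len(docs):
            warnings.warn(
                f"skipping K={k}: more topics than documents ({len(docs)})",
                stacklevel=2,
            )
            continue
        lda = LatentDirichletAllocation(
            n_components=k,
            random_state=seed,
            max_iter=max_iter,
            learning_method="batch",
        )
        lda.fit(X)
        topics = [
            [vocabulary[j] for j in np.argsort(-row)[:top_n]]
            for row in lda.components_
        ]
        score = coherence_cv(topics, docs)
        coh[k] = score
        fitted[k] = (lda, topics)
        if best is None or score > best[0] + 1e-12:
            best = (score, k)
    if best is None:
        raise ValueError("no candidate K could be fitted")
    k_sel = best[1]
    model, topics = fitted[k_sel]
    return TopicModelResult(
        selected_k=k_sel,
        coherence=coh,
        vocabulary=vocabulary,
        topic_keywords=topics,
        model=model,
    )


def assign_user_topics(
    result: TopicModelResult,
    user_docs: Sequence[Sequence[str]],
    rule: str = "dominant",
    threshold: float = 0.25,
    user: str = "",
) -> set[int]:
    """Topic set T(v) for one user from their tokenized tweets.

    ``rule="dominant"`` takes, per tweet, the single highest-probability topic;
    ``rule="threshold"`` takes every topic whose per-tweet probability reaches
    ``threshold``.  Either way the per-tweet topics are unioned.  Tweets with
    no in-vocabulary token are not analyzable; a user with none yields the
    empty set with a warning.
    """
    if rule not in ("dominant", "threshold"):
        raise ValueError(f"unknown topic assignment rule {rule!r}")
    vocab = set(result.vocabulary)
    analyzable = [doc for doc in user_docs if any(t in vocab for t in doc)]
    if not analyzable:
        warnings.warn(
            f"user {user or '<unknown>'} has no analyzable tweets; T(v) is empty",
            stacklevel=2,
        )
        return set()
    probs = result.doc_topics(analyzable)
    topics: set[int] = set()
    for row in probs:
        if rule == "dominant":
            topics.add(int(np.argmax(row)) + 1)
        else:
            topics.update(int(j) + 1 for j in np.flatnonzero(row >= threshold))
    return topics
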