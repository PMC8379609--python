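"""Tokenization, vocabulary filtering and coherence-selected LDA."""

import numpy as np
import pytest

from echograph.topics import (
    assign_user_topics,
    build_vocabulary,
    coherence_cv,
    fit_topic_models,
    tokenize,
)

VOCABS = [
    ["apple", "banana", "cherry", "grape", "melon", "peach", "plum", "fig"],
    ["hammer", "wrench", "drill", "saw", "pliers", "chisel", "screw", "nail"],
    ["violin", "cello", "flute", "oboe", "trumpet", "drum", "harp", "piano"],
]


def planted_docs(seed: int, n_per_group: int = 40, words_per_doc: int = 6):
    rng = np.random.default_rng(seed)
    docs = []
    for vocab in VOCABS:
        for _ in range(n_per_group):
            docs.append(list(rng.choice(vocab, size=words_per_doc)))
    return docs


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Wuhan LOCKDOWN! http://x.y", ["wuhan", "lockdown"]),
            ("#masks work @who", ["mask", "work"]),
            ("", []),
            ("?!? ...", []),
            ("the viruses are spreading", ["virus", "spread"]),
            ("check www.example.com soon", ["check", "soon"]),
        ],
    )
    def test_rules(self, text, expected):
        assert tokenize(text) == expected

    def test_stemming_and_stopwords_optional(self):
        assert tokenize("the masks", stem=False, remove_stopwords=False) == [
            "the",
            "masks",
        ]


class TestVocabulary:
    def _docs(self):
        # 100 docs: "rare" in 1, "common" in 60, "mid" in 10, filler unique
        docs = [[f"filler{i}"] for i in range(100)]
        docs[0].append("rare")
        for i in range(60):
            docs[i].append("common")
        for i in range(10):
            docs[i].append("mid")
        return docs

    def test_df_bounds(self):
        vocab = build_vocabulary(self._docs(), min_df=0.02, max_df=0.50)
        assert "rare" not in vocab  # df 1% < 2%
        assert "common" not in vocab  # df 60% > 50%
        assert "mid" in vocab  # df 10%, inside both bounds

    def test_idempotent(self):
        docs = self._docs()
        v1 = build_vocabulary(docs, min_df=0.02, max_df=0.50)
        filtered = [[t for t in d if t in v1] for d in docs]
        v2 = build_vocabulary(filtered, min_df=0.02, max_df=0.50)
        assert v1 == v2

    def test_keep_n_truncates_by_frequency(self):
        docs = [["a", "a", "b"], ["a", "b", "c"], ["b", "c", "a"], ["c", "a", "b"]]
        vocab = build_vocabulary(docs, min_df=0.0, max_df=1.01, keep_n=2)
        assert vocab == ["a", "b"]

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_vocabulary([["x"]], min_df=0.9, max_df=0.95)


class TestTopicModelSelection:
    def test_sweep_records_one_coherence_per_candidate(self):
        docs = planted_docs(0, n_per_group=15)
        res = fit_topic_models(docs, k_range=range(2, 7), seed=0, min_df=0.001)
        assert sorted(res.coherence) == [2, 3, 4, 5, 6]
        assert res.selected_k == max(res.coherence, key=lambda k: (res.coherence[k], -k))

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_vocabularies_recovered(self, seed):
        docs = planted_docs(seed)
        res = fit_topic_models(docs, k_range=range(2, 7), seed=seed, min_df=0.001)
        # each planted vocabulary dominates at least one selected topic's top-10
        for vocab in VOCABS:
            assert any(
                sum(w in vocab for w in topic) >= 5
                for topic in res.topic_keywords
            ), vocab

    def test_seeded_determinism(self):
        docs = planted_docs(3, n_per_group=10)
        a = fit_topic_models(docs, k_range=range(2, 5), seed=9, min_df=0.001)
        b = fit_topic_models(docs, k_range=range(2, 5), seed=9, min_df=0.001)
        assert a.selected_k == b.selected_k
        assert a.topic_keywords == b.topic_keywords
        assert a.coherence == b.coherence

    def test_k_above_document_count_skipped(self):
        docs = planted_docs(1, n_per_group=2)  # 6 documents
        with pytest.warns(UserWarning, match="more topics than documents"):
            res = fit_topic_models(docs, k_range=[2, 50], seed=0, min_df=0.001)
        assert sorted(res.coherence) == [2]

    def test_coherence_prefers_coherent_topics(self):
        docs = planted_docs(2, n_per_group=20)
        rng = np.random.default_rng(0)
        all_words = [w for v in VOCABS for w in v]
        shuffled = [list(rng.choice(all_words, size=8, replace=False)) for _ in range(3)]
        assert coherence_cv(VOCABS, docs) > coherence_cv(shuffled, docs)


@pytest.fixture(scope="module")
def model():
    return fit_topic_models(planted_docs(4), k_range=[3], seed=4, min_df=0.001)


class TestAssignUserTopics:
    def _topic_of(self, model, vocab):
        probs = model.doc_topics([list(vocab)])
        return int(np.argmax(probs[0])) + 1

    def test_dominant_rule_single_and_union(self, model):
        t0 = self._topic_of(model, VOCABS[0])
        t1 = self._topic_of(model, VOCABS[1])
        assert assign_user_topics(model, [list(VOCABS[0])] * 3) == {t0}
        assert assign_user_topics(
            model, [list(VOCABS[0]), list(VOCABS[1])]
        ) == {t0, t1}

    def test_threshold_rule_subsets_global_set(self, model):
        ts = assign_user_topics(
            model, [list(VOCABS[0]), list(VOCABS[2])], rule="threshold", threshold=0.4
        )
        assert ts <= model.topic_set and ts

    def test_no_analyzable_tweets_warns_empty(self, model):
        with pytest.warns(UserWarning, match="no analyzable"):
            assert assign_user_topics(model, [], user="ghost") == set()
        with pytest.warns(UserWarning):
            assert assign_user_topics(model, [["zzz_out_of_vocab"]]) == set()

    def test_unknown_rule_rejected(self, model):
        with pytest.raises(ValueError):
            assign_user_topics(model, [list(VOCABS[0])], rule="mystery")
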