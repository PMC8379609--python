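"""Record reading, mention extraction and mention-graph construction."""

import json

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from echograph.ingest import (
    EmptyGraphError,
    ParseError,
    TweetRecord,
    build_mention_graph,
    export_graph,
    extract_mentions,
    filter_records,
    load_graph,
    read_tweet_records,
)


def _write_jsonl(path, rows):
    path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")


ROWS = [
    {"tweet_id": "1", "author": "Ann", "text": "hello @bob", "lang": "en"},
    {"tweet_id": "2", "author": "bob", "text": "hi @Ann", "lang": "en",
     "verified": True, "description": "desc"},
]


class TestReadRecords:
    def test_jsonl_reads_in_order_with_defaults(self, tmp_path):
        p = tmp_path / "t.jsonl"
        _write_jsonl(p, ROWS)
        recs = read_tweet_records(p)
        assert [r.tweet_id for r in recs] == ["1", "2"]
        assert recs[0].author == "ann"  # case-normalized
        assert recs[0].verified is False and recs[0].description == ""
        assert recs[1].verified is True

    def test_csv_equivalent_to_jsonl(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "tweet_id,author,text,lang,verified,description\n"
            '1,Ann,hello @bob,en,,\n'
            '2,bob,hi @Ann,en,true,desc\n'
        )
        j = tmp_path / "t.jsonl"
        _write_jsonl(j, ROWS)
        assert read_tweet_records(p) == read_tweet_records(j)

    def test_missing_text_names_record(self, tmp_path):
        p = tmp_path / "t.jsonl"
        _write_jsonl(p, [{"tweet_id": "1", "author": "a", "lang": "en"}])
        with pytest.raises(ParseError, match="record 1.*text"):
            read_tweet_records(p)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "t.jsonl"
        _write_jsonl(p, ROWS)
        with pytest.raises(ValueError, match="unknown format"):
            read_tweet_records(p, format="parquet")


class TestFilterRecords:
    def _recs(self):
        return [
            TweetRecord("1", "a", "coronavirus x", "en"),
            TweetRecord("2", "b", "coronavirus y", "es"),
            TweetRecord("3", "c", "the CoronaVirus is here", "en"),
            TweetRecord("4", "d", "unrelated", "en"),
        ]

    def test_lang_and_term(self):
        out = filter_records(self._recs(), lang="en", term="coronavirus")
        assert [r.tweet_id for r in out] == ["1", "3"]  # case-insensitive

    def test_empty_term_keeps_all_lang_matches(self):
        out = filter_records(self._recs(), lang="en", term="")
        assert [r.tweet_id for r in out] == ["1", "3", "4"]


class TestExtractMentions:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("hi @Bob and @alice", ["bob", "alice"]),
            ("write a@b.com", []),
            ("@bob @bob", ["bob", "bob"]),
            ("start@middle @ok", ["ok"]),
            (".@leading punct@no", ["leading"]),
            ("(@paren) ,@comma", ["paren", "comma"]),
            ("@" + "x" * 16, []),  # longer than the platform username limit
            ("", []),
        ],
    )
    def test_boundary_rule(self, text, expected):
        assert extract_mentions(text) == expected


def _mention_records(pairs):
    """One record per (author, mentioned) pair."""
    return [
        TweetRecord(str(i), a, f"@{m} hi", "en") for i, (a, m) in enumerate(pairs)
    ]


class TestBuildMentionGraph:
    def test_threshold_inclusive(self):
        G = build_mention_graph(_mention_records([("a", "b")] * 3), 3)
        assert G["a"]["b"]["weight"] == 3

    def test_below_threshold_dropped(self):
        recs = _mention_records([("a", "b")] * 2 + [("c", "d")] * 3)
        G = build_mention_graph(recs, 3)
        assert not G.has_edge("a", "b") and G.has_edge("c", "d")
        assert "a" not in G and "b" not in G  # isolated vertices dropped

    def test_directions_summed(self):
        recs = _mention_records([("a", "b"), ("a", "b"), ("b", "a")])
        G = build_mention_graph(recs, 3)
        assert G["a"]["b"]["weight"] == 3

    def test_self_mentions_dropped_and_empty_graph_error(self):
        with pytest.raises(EmptyGraphError):
            build_mention_graph(_mention_records([("a", "a")] * 5), 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from("abcde"), st.sampled_from("abcde")
            ),
            min_size=1,
            max_size=40,
        ),
        st.integers(min_value=1, max_value=4),
    )
    def test_simple_undirected_and_monotone(self, pairs, threshold):
        recs = _mention_records(pairs)
        try:
            G = build_mention_graph(recs, threshold)
        except EmptyGraphError:
            G = nx.Graph()
        assert all(u != v for u, v in G.edges)
        total_mentions = sum(a != m for a, m in pairs)
        assert sum(d["weight"] for _, _, d in G.edges(data=True)) <= total_mentions
        try:
            G2 = build_mention_graph(recs, threshold + 1)
        except EmptyGraphError:
            G2 = nx.Graph()
        edges = lambda g: {frozenset(e) for e in g.edges}
        assert edges(G2) <= edges(G)  # raising threshold never adds


def test_graph_round_trip(tmp_path):
    G = build_mention_graph(_mention_records([("a", "b")] * 3 + [("b", "c")] * 4), 3)
    G.graph["scheme"] = "sentiment"
    for fmt in ("graphml", "gexf"):
        path = tmp_path / f"g.{fmt}"
        export_graph(G, path)
        H = load_graph(path)
        assert {frozenset(e) for e in H.edges} == {frozenset(e) for e in G.edges}
        assert H["a"]["b"]["weight"] == 3
    # GraphML carries the graph-level scheme attribute through the round trip
    assert load_graph(tmp_path / "g.graphml").graph["scheme"] == "sentiment"
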