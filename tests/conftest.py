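"""Shared fixtures: tiny hand-built corpora and graphs, plus session-scoped
synthetic data so the slow generators run once."""

from __future__ import annotations

import pytest

from echograph.ingest import TweetRecord
from echograph.synthetic import (
    PolarizationSpec,
    generate_planted_graph,
    generate_polarized_corpus,
)


@pytest.fixture()
def five_user_records() -> list[TweetRecord]:
    """Five users, hand-countable mentions and descriptions."""

    def rec(i, author, text, desc="", verified=False):
        return TweetRecord(
            tweet_id=str(i), author=author, text=text, lang="en",
            description=desc, verified=verified,
        )

    rows = [
        rec(1, "ann", "@bob coronavirus update", "health research lab", True),
        rec(2, "ann", "@bob stay safe coronavirus"),
        rec(3, "ann", "@bob masks work coronavirus"),
        rec(4, "bob", "@ann thanks coronavirus", "freedom patriot"),
        rec(5, "bob", "@cat coronavirus hoax", "freedom patriot"),
        rec(6, "cat", "@bob no it is not coronavirus", "science journalist"),
        rec(7, "cat", "@bob really coronavirus", "science journalist"),
        rec(8, "dan", "@eve coronavirus news", "patriot family", False),
        rec(9, "eve", "@dan @dan more coronavirus news", "research data", True),
        rec(10, "dan", "@eve lockdown coronavirus"),
    ]
    return rows


@pytest.fixture(scope="session")
def planted_default():
    spec = PolarizationSpec(seed=7)
    G, labels = generate_planted_graph(spec)
    return spec, G, labels


@pytest.fixture(scope="session")
def polarized_corpus(planted_default):
    spec, _, _ = planted_default
    return generate_polarized_corpus(spec)
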