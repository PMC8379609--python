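"""Reading tweet-like records and building the mention-based conversation graph.

The conversation graph is an undirected, simple, weighted :class:`networkx.Graph`
over usernames: an edge (u, v) carries ``w_t``, the total number of mentions
between u and v in either direction, and only edges with ``w_t`` at or above a
configurable threshold (default 3) survive.  The active edge attribute is
``weight``; the graph-level attribute ``scheme`` identifies which of the four
weighting schemes (topology / sentiment / topic / hybrid) the weights encode.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "TweetRecord",
    "ParseError",
    "EmptyGraphError",
    "read_tweet_records",
    "filter_records",
    "extract_mentions",
    "build_mention_graph",
    "export_graph",
    "load_graph",
]

REQUIRED_FIELDS = ("tweet_id", "author", "text", "lang")

#: default mapping from logical field names to column/key names in input files
DEFAULT_FIELD_MAP = {
    "tweet_id": "tweet_id",
    "author": "author",
    "text": "text",
    "lang": "lang",
    "description": "description",
    "verified": "verified",
    "created_at": "created_at",
}


class ParseError(ValueError):
    """A record could not be parsed (missing field, bad value)."""


class EmptyGraphError(ValueError):
    """No edge survived the mention-count threshold."""


def normalize_username(name: str) -> str:
    """Lowercase a username and strip one leading ``@``."""
    name = name.strip()
    if name.startswith("@"):
        name = name[1:]
    return name.lower()


@dataclass(frozen=True)
class TweetRecord:
    """One tweet-like post with the metadata the pipeline consumes."""

    tweet_id: str
    author: str
    text: str
    lang: str
    description: str = ""
    verified: bool = False
    created_at: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "author", normalize_username(self.author))
        if not self.author:
            raise ParseError("author is empty after normalization")


def _to_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None:
        return False
    s = str(value).strip().lower()
    return s in {"true", "1", "yes", "t", "y"}


def _record_from_mapping(row: dict, index: int, fmap: dict[str, str]) -> TweetRecord:
    data = {}
    for logical in REQUIRED_FIELDS:
        key = fmap[logical]
        if key not in row or row[key] is None or str(row[key]) == "":
            raise ParseError(f"record {index}: missing required field {logical!r}")
        data[logical] = str(row[key])
    desc = row.get(fmap["description"], "")
    created = row.get(fmap["created_at"])
    return TweetRecord(
        tweet_id=data["tweet_id"],
        author=data["author"],
        text=data["text"],
        lang=data["lang"],
        description="" if desc is None else str(desc),
        verified=_to_bool(row.get(fmap["verified"], False)),
        created_at=None if created in (None, "") else str(created),
    )


def read_tweet_records(
    path: str | Path,
    format: str | None = None,
    field_map: dict[str, str] | None = None,
) -> list[TweetRecord]:
    """Read tweet records from a JSONL or CSV file, in file order.

    ``format`` may be ``"jsonl"`` or ``"csv"``; if omitted it is inferred from
    the file extension.  ``field_map`` remaps logical field names to the names
    actually used in the file.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'csv')")
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)

    records: list[TweetRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"record {i}: invalid JSON ({exc})") from exc
                records.append(_record_from_mapping(row, i, fmap))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh), start=1):
                records.append(_record_from_mapping(row, i, fmap))
    return records


def filter_records(
    records: Iterable[TweetRecord], lang: str = "", term: str = ""
) -> list[TweetRecord]:
    """Keep records matching a language code and containing a crawl term.

    The term match is case-insensitive over the tweet text (hashtags are part
    of the text).  An empty ``lang`` or ``term`` disables that filter.
    """
    lang = lang.lower()
    term = term.lower()
    out = []
    for rec in records:
        if lang and rec.lang.lower() != lang:
            continue
        if term and term not in rec.text.lower():
            continue
        out.append(rec)
    return out


_MENTION_RE = re.compile(r"@([A-Za-z0-9_]+)")


def extract_mentions(text: str) -> list[str]:
    """Return lowercased usernames mentioned as ``@name`` tokens.

    A mention's ``@`` must sit at the start of the string or after a
    non-word character, which excludes e-mail-like ``a@b`` occurrences;
    usernames follow the platform grammar ``[A-Za-z0-9_]{1,15}``.
    Duplicates within one tweet are preserved (each is one mention).
    """
    out = []
    for m in _MENTION_RE.finditer(text):
        start = m.start()
        if start > 0 and re.match(r"[A-Za-z0-9_]", text[start - 1]):
            continue
        name = m.group(1)
        if len(name) > 15:
            continue
        out.append(name.lower())
    return out


def build_mention_graph(
    records: Iterable[TweetRecord], min_edge_weight: int = 3
) -> nx.Graph:
    """Build the topology-based conversation graph from mention counts.

    Mentions in both directions between an unordered user pair are summed into
    one undirected edge weight ``w_t``; self-mentions are dropped, edges with
    ``w_t`` below ``min_edge_weight`` are dropped, and vertices left without
    any surviving edge do not appear.
    """
    if min_edge_weight < 1:
        raise ValueError("min_edge_weight must be >= 1")
    counts: Counter[tuple[str, str]] = Counter()
    for rec in records:
        for target in extract_mentions(rec.text):
            if target == rec.author:
                continue
            counts[tuple(sorted((rec.author, target)))] += 1

    G = nx.Graph(scheme="topology")
    for (u, v), w in sorted(counts.items()):
        if w >= min_edge_weight:
            G.add_edge(u, v, weight=w, w_t=w)
    if G.number_of_edges() == 0:
        raise EmptyGraphError(
            f"no edge reached the mention threshold {min_edge_weight}"
        )
    return G


def export_graph(G: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write a conversation graph as GraphML or GEXF (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "graphml"
    if format == "graphml":
        nx.write_graphml(G, path)
    elif format == "gexf":
        nx.write_gexf(G, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def load_graph(path: str | Path) -> nx.Graph:
    """Read a conversation graph written by :func:`export_graph`.

    GraphML round-trips the graph-level ``scheme`` attribute; GEXF has no
    graph-attribute slot in networkx, so graphs loaded from GEXF fall back to
    the ``topology`` scheme tag.
    """
    path = Path(path)
    if path.suffix.lower() == ".gexf":
        raw = nx.read_gexf(path)
    else:
        raw = nx.read_graphml(path)
    G = nx.Graph(raw)
    G.graph.update(raw.graph)
    G.graph.setdefault("scheme", "topology")
    return G
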