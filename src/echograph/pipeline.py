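"""End-to-end orchestration: ingest -> semantics -> four representations ->
bisection -> controversy -> homogeneity reports, with deterministic artifacts.

All stage outputs are pure functions of (input, config, seed); rerunning
with an identical configuration reproduces the partition CSVs and report
JSONs byte for byte (timings live only in the manifest).  The LDA sweep runs
lazily: representations that do not need topics never trigger it.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import yaml

from . import __version__
from .controversy import (
    WalkConfig,
    boundary_connectivity,
    drwc,
    estimate_arwc,
    estimate_rwc,
    partition_quality,
)
from .ingest import (
    build_mention_graph,
    export_graph,
    filter_records,
    read_tweet_records,
)
from .partition import Bisection, community_changes, multilevel_bisect
from .profiles import build_profiles
from .report import community_summary, profile_keywords, topic_prevalence
from .sentiment import ScalingConfig
from .topics import TopicModelResult, fit_topic_models, tokenize
from .weighting import SCHEMES, apply_representation

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("echograph")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults follow the study conditions
    (mention threshold 3, alpha 30, topic sweep 2..30, 60% walk sampling,
    top-15% authoritativeness, walk length twice the average shortest path)."""

    input_path: str = ""
    input_format: str | None = None
    out_dir: str = "echograph_out"
    lang: str = "en"
    term: str = ""
    min_edge_weight: int = 3
    alpha: int = 30
    empirical_scaling: bool = False
    k_min: int = 2
    k_max: int = 30
    topic_rule: str = "dominant"
    topic_threshold: float = 0.25
    representations: Sequence[str] = ("topology", "sentiment", "topic", "hybrid")
    imbalance_tol: float = 1.03
    seed: int = 0
    sample_frac: float = 0.60
    auth_pct: float = 15.0
    l_rw: int | None = None
    restart_cap: int = 50
    walks_per_start: int = 10
    weight_biased: bool = True

    def __post_init__(self) -> None:
        self.representations = tuple(self.representations)
        if not self.representations:
            raise ValueError("select at least one representation")
        unknown = set(self.representations) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown representations: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
        data.update(overrides)
        return cls(**data)

    def walk_config(self) -> WalkConfig:
        return WalkConfig(
            sample_frac=self.sample_frac,
            auth_pct=self.auth_pct,
            l_rw=self.l_rw,
            restart_cap=self.restart_cap,
            walks_per_start=self.walks_per_start,
            weight_biased=self.weight_biased,
            seed=self.seed,
        )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_partition_csv(path: Path, bisection: Bisection) -> None:
    labels = bisection.labels()
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user", "community"])
        for user in sorted(labels, key=str):
            writer.writerow([user, labels[user]])


def _controversy_report(
    G: nx.Graph, bisection: Bisection, cfg: WalkConfig
) -> dict:
    quality = partition_quality(G, bisection)
    rwc = estimate_rwc(G, bisection, cfg)
    arwc = estimate_arwc(G, bisection, cfg)
    dr = drwc(G, bisection, cfg)
    try:
        bc = boundary_connectivity(G, bisection)
        bc_note = None
    except ValueError as exc:
        bc = None
        bc_note = str(exc)
    return {
        "scheme": G.graph.get("scheme", "topology"),
        "modularity": quality["modularity"],
        "coverage": quality["coverage"],
        "rwc": rwc.value,
        "rwc_std_error": rwc.std_error,
        "rwc_probabilities": rwc.probabilities,
        "arwc": arwc.value,
        "arwc_std_error": arwc.std_error,
        "arwc_probabilities": arwc.probabilities,
        "drwc": dr.value,
        "drwc_std_error": dr.std_error,
        "bc": bc,
        "bc_note": bc_note,
        "sizes": {"A": len(bisection.X), "B": len(bisection.Y)},
        "cut_weight": bisection.cut_weight,
        "imbalance": bisection.imbalance,
        "walk_diagnostics": {
            "rwc": {k: v for k, v in rwc.diagnostics.items()},
            "arwc": {k: v for k, v in arwc.diagnostics.items()},
            "drwc": {
                k: v for k, v in dr.diagnostics.items() if k != "per_node"
            },
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write artifacts under ``out_dir``.

    Returns the manifest (also written to ``manifest.json``).  Raises on the
    first failing stage; artifacts written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "config": {
            **asdict(config),
            "representations": list(config.representations),
        },
        "artifacts": [],
        "stages": {},
    }

    def stage(name: str):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name: str, **info) -> None:
        timings[name] = time.perf_counter() - timings[name]
        manifest["stages"][name] = info
        log.info("stage %s done: %s", name, info)

    stage("ingest")
    records = read_tweet_records(config.input_path, config.input_format)
    filtered = filter_records(records, lang=config.lang, term=config.term)
    done("ingest", records=len(records), after_filter=len(filtered))

    stage("build_graph")
    G_topo = build_mention_graph(filtered, config.min_edge_weight)
    done(
        "build_graph",
        nodes=G_topo.number_of_nodes(),
        edges=G_topo.number_of_edges(),
    )

    need_topics = bool({"topic", "hybrid"} & set(config.representations))
    topic_model: TopicModelResult | None = None
    if need_topics:
        stage("topic_model")
        graph_users = set(G_topo.nodes)
        docs = [
            tokenize(rec.text) for rec in filtered if rec.author in graph_users
        ]
        topic_model = fit_topic_models(
            docs,
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.seed,
        )
        with (out / "keywords.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["topic", "rank", "keyword"])
            writer.writerows(topic_model.keywords_table())
        manifest["artifacts"].append("keywords.csv")
        done(
            "topic_model",
            selected_k=topic_model.selected_k,
            n_docs=len(docs),
            vocabulary=len(topic_model.vocabulary),
        )

    stage("profiles")
    profiles = build_profiles(
        filtered,
        users=G_topo.nodes,
        scaling=ScalingConfig(alpha=config.alpha),
        empirical_scaling=config.empirical_scaling,
        topic_model=topic_model,
        topic_rule=config.topic_rule,
        topic_threshold=config.topic_threshold,
    )
    profiles.to_frame().to_csv(out / "profiles.csv", index=False)
    manifest["artifacts"].append("profiles.csv")
    done("profiles", users=len(profiles.sentiment))

    walk_cfg = config.walk_config()
    bisections: dict[str, Bisection] = {}
    # the topology bisection is the reference for change counts
    reps = list(dict.fromkeys(["topology", *config.representations]))
    for rep in reps:
        stage(f"representation:{rep}")
        G_rep = apply_representation(G_topo, profiles, rep)
        bis = multilevel_bisect(
            G_rep, imbalance_tol=config.imbalance_tol, seed=config.seed
        )
        bisections[rep] = bis

        if rep in config.representations:
            export_graph(G_rep, out / f"graph_{rep}.graphml")
            _write_partition_csv(out / f"partition_{rep}.csv", bis)
            report = _controversy_report(G_rep, bis, walk_cfg)
            _write_json(out / f"controversy_{rep}.json", report)
            changes = community_changes(bisections["topology"], bis)
            _write_json(out / f"changes_{rep}.json", changes)

            summary_a, summary_b = community_summary(bis, profiles)
            summary = {
                "A": summary_a.to_dict(),
                "B": summary_b.to_dict(),
                "keywords": {
                    k: [[w, c] for w, c in v]
                    for k, v in profile_keywords(bis, filtered).items()
                },
            }
            if topic_model is not None:
                summary["topic_prevalence"] = topic_prevalence(
                    bis, profiles.topic_sets
                ).to_dict(orient="records")
            _write_json(out / f"summary_{rep}.json", summary)
            manifest["artifacts"].extend(
                [
                    f"graph_{rep}.graphml",
                    f"partition_{rep}.csv",
                    f"controversy_{rep}.json",
                    f"changes_{rep}.json",
                    f"summary_{rep}.json",
                ]
            )
        done(
            f"representation:{rep}",
            cut_weight=bisections[rep].cut_weight,
            sizes=[len(bisections[rep].X), len(bisections[rep].Y)],
        )

    manifest["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    manifest["artifacts"] = sorted(set(manifest["artifacts"]))
    _write_json(out / "manifest.json", manifest)
    return manifest
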