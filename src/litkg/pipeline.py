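"""End-to-end orchestration of the comparative-analysis stages.

:func:`run_pipeline` runs, from one configuration: graph acquisition
(synthetic generation or TSV loading), per-disease metapath relevance
ranking, normalization, cross-disease composites, Venn overlap
quantification, top-percentile selection, biological-process profiling
(counts, normalized percentages, z-scores, overall shares) and
direct/indirect evidence evaluation, writing every artifact plus a
manifest with a configuration hash.  Reruns with identical inputs are
bit-identical.

:func:`reproduce_printed_tables` is deliberately separate from the
graph pipeline: it recomputes, from a file of published summary counts
and precision/recall pairs alone, every derivable reported number
(Venn shares by inclusion-exclusion, F-measures from P/R) and flags
reported values that disagree with the arithmetic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .evidence import DIRECT, INDIRECT, EvidenceLabel, classify_evidence, evaluate, f_measure, read_labels
from .exceptions import ParseError
from .graph import KnowledgeGraph, load_graph
from .metapaths import DEFAULT_DEPTH, DEFAULT_MAX_LENGTH, aggregate_targets, rank_sources
from .processes import (
    default_taxonomy,
    intersection_profile,
    load_taxonomy,
    map_nodes,
    normalize_profile,
    overall_percentages,
    process_zscores,
)
from .ranking import composite_scores, normalize_scores, top_percent
from .synthetic import DISEASES, GeneratorConfig, GroundTruth, SOURCE_TYPE, generate_graph, load_fixture
from .venn import intersect_sets, round_half_away, venn_percentages, venn_summary_from_counts

logger = logging.getLogger("litkg.pipeline")


@dataclass
class PipelineConfig:
    """Single configuration for the full analysis.

    Exactly one graph source applies: a generator configuration, a
    fixture directory, or explicit node/edge tables.  Defaults mirror
    the study conditions: search depth 2, metapath length 3, top 1% of
    AAPP source nodes.
    """

    generator: GeneratorConfig | None = None
    fixture_dir: str | None = None
    node_table: str | None = None
    edge_table: str | None = None
    targets: Mapping[str, str] = field(
        default_factory=lambda: {d: cui for d, (cui, _) in DISEASES.items()}
    )
    source_type: str = SOURCE_TYPE
    depth: int = DEFAULT_DEPTH
    max_length: int = DEFAULT_MAX_LENGTH
    top_pct: float = 1.0
    taxonomy_path: str | None = None
    label_files: tuple[str, ...] = ()
    out_dir: str = "results/pipeline"
    seed: int | None = None
    #: True: per-disease top slices are taken first and then intersected;
    #: False: each pair's full intersection is ranked by pair composite
    #: and the top slice of that ranking is profiled.
    top_before_intersection: bool = True
    #: Standardize raw counts instead of normalized percentages.
    zscores_on_counts: bool = False

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.top_pct <= 100:
            raise ValueError("top_pct must lie in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "generator" in data and data["generator"] is not None:
            data["generator"] = GeneratorConfig.from_dict(data["generator"])
        if "label_files" in data:
            data["label_files"] = tuple(data["label_files"])
        return cls(**data)

    def canonical(self) -> dict:
        data = {
            "generator": None if self.generator is None else self.generator.to_dict(),
            "fixture_dir": self.fixture_dir,
            "node_table": self.node_table,
            "edge_table": self.edge_table,
            "targets": dict(self.targets),
            "source_type": self.source_type,
            "depth": self.depth,
            "max_length": self.max_length,
            "top_pct": self.top_pct,
            "taxonomy_path": self.taxonomy_path,
            "label_files": list(self.label_files),
            "seed": self.seed,
            "top_before_intersection": self.top_before_intersection,
            "zscores_on_counts": self.zscores_on_counts,
        }
        return data


def _acquire_graph(config: PipelineConfig) -> tuple[KnowledgeGraph, GroundTruth | None]:
    if config.generator is not None:
        generator = config.generator
        if config.seed is not None:
            generator = GeneratorConfig.from_dict({**generator.to_dict(), "seed": config.seed})
        graph, truth = generate_graph(generator)
        return graph, truth
    if config.fixture_dir is not None:
        graph, truth, _ = load_fixture(config.fixture_dir)
        return graph, truth
    if config.node_table and config.edge_table:
        return load_graph(config.node_table, config.edge_table), None
    raise ValueError("config must provide a generator, fixture_dir, or node/edge tables")


def _write_json(path: Path, payload: object) -> None:
    path.write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    graph, truth = _acquire_graph(config)
    logger.info("graph: %d nodes, %d triples", graph.n_nodes, graph.n_triples)

    # Stage: per-disease relevance ranking (one simulation per target).
    per_disease_scores: dict[str, pd.DataFrame] = {}
    normalized: dict[str, pd.DataFrame] = {}
    for disease, target_cui in config.targets.items():
        scores = rank_sources(
            graph, [target_cui], config.source_type, config.depth, config.max_length
        )
        table = scores.rename(columns={"source_cui": "cui", "hetesim": "score"})[
            ["cui", "score"]
        ]
        per_disease_scores[disease] = table
        logger.info("ranked %d %s sources for %s", len(table), config.source_type, disease)
        if table.empty:
            normalized[disease] = pd.DataFrame(columns=["cui", "raw_score", "z", "percentile"])
        else:
            normalized[disease] = normalize_scores(table)
        ranked_path = out / f"ranked_{disease}.csv"
        normalized[disease].to_csv(ranked_path, index=False)
        artifacts.append(ranked_path.name)

    # Stage: cross-disease composite scores on raw HeteSim values.
    composite = composite_scores(per_disease_scores)
    composite_path = out / "composite.csv"
    composite.to_csv(composite_path, index=False)
    artifacts.append(composite_path.name)

    # Stage: Venn overlap of the full per-disease returned sets.
    labels = list(config.targets)
    full_sets = {d: set(per_disease_scores[d]["cui"]) for d in labels}
    summary = intersect_sets(full_sets[labels[0]], full_sets[labels[1]], full_sets[labels[2]], labels)
    venn_payload = summary.to_dict()
    venn_payload["percentages"] = {
        d: venn_percentages(summary, d) for d in labels if summary.totals[d] > 0
    }
    venn_path = out / "venn.json"
    _write_json(venn_path, venn_payload)
    artifacts.append(venn_path.name)

    # Stage: top-percentile selection and process profiling.
    taxonomy = (
        load_taxonomy(config.taxonomy_path) if config.taxonomy_path else default_taxonomy()
    )
    if config.top_before_intersection:
        top_sets = {
            d: top_percent(normalized[d], config.top_pct)
            for d in labels
            if not normalized[d].empty
        }
    else:
        # Alternative convention: rank each pair's full intersection by the
        # pair composite score, then slice.
        top_sets = {}
        for d in labels:
            merged = composite[composite["cui"].isin(full_sets[d])]
            renamed = merged.rename(columns={"composite": "score"})[["cui", "score"]]
            top_sets[d] = top_percent(renamed, config.top_pct) if not renamed.empty else set()
    names = {c: graph.node(c).name for s in top_sets.values() for c in s}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mapping = map_nodes(sorted(names.items()), taxonomy)
        counts = intersection_profile(top_sets, mapping)
        normalized_profile = normalize_profile(counts)
        z_input = counts if config.zscores_on_counts else normalized_profile
        zscores = process_zscores(z_input)
        overall = overall_percentages(counts) if counts.to_numpy().sum() else None
    for name, frame in (
        ("process_counts.csv", counts),
        ("process_normalized.csv", normalized_profile),
        ("process_zscores.csv", zscores),
    ):
        frame.to_csv(out / name, index_label="category")
        artifacts.append(name)
    overall_path = out / "process_overall.json"
    _write_json(
        overall_path,
        {
            "unrounded": None if overall is None else overall.round(10).to_dict(),
            "rounded": None if overall is None else {c: int(round_half_away(v, 0)) for c, v in overall.items()},
        },
    )
    artifacts.append(overall_path.name)

    # Stage: direct/indirect evidence classification and evaluation.
    target_cuis = list(config.targets.values())
    predictions: list[EvidenceLabel] = []
    for disease in labels:
        for cui in sorted(top_sets.get(disease, ())):
            predicted = classify_evidence(graph, cui, [config.targets[disease]])
            truth_label = None
            if truth is not None:
                truth_label = DIRECT if truth.direct_flag.get(cui, {}).get(disease) else INDIRECT
            predictions.append(EvidenceLabel(cui, disease, predicted, "graph", truth_label))
    evidence_payload: dict[str, object] = {"n_predictions": len(predictions)}
    if predictions and all(p.truth is not None for p in predictions):
        evidence_payload["graph"] = evaluate(predictions).to_dict()
    for label_file in config.label_files:
        external = read_labels(label_file)
        evaluator = external[0].evaluator if external else Path(label_file).stem
        evidence_payload[evaluator] = evaluate(external).to_dict()
    evidence_path = out / "evidence_report.json"
    _write_json(evidence_path, evidence_payload)
    artifacts.append(evidence_path.name)

    config_blob = json.dumps(config.canonical(), sort_keys=True, ensure_ascii=False)
    manifest = {
        "package": "litkg",
        "version": __version__,
        "config": config.canonical(),
        "config_sha256": hashlib.sha256(config_blob.encode("utf-8")).hexdigest(),
        "graph": {"n_nodes": graph.n_nodes, "n_triples": graph.n_triples},
        "stage_counts": {
            "sources_per_disease": {d: len(per_disease_scores[d]) for d in labels},
            "top_set_sizes": {d: len(top_sets.get(d, ())) for d in labels},
            "evidence_predictions": len(predictions),
        },
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


# --------------------------------------------------------------------------
# reproduction of reported arithmetic
# --------------------------------------------------------------------------


def default_counts_path() -> Path:
    """Path of the packaged reported-counts file."""
    return Path(str(resources.files("litkg.data").joinpath("reported_counts.yaml")))


def reproduce_printed_tables(counts_file: str | Path | None = None) -> pd.DataFrame:
    """Recompute every derivable reported number from summary counts alone.

    Returns a table with one row per quantity: the recomputed value, the
    reported value, a boolean ``match`` at the reported precision, and a
    note flagging inconsistencies.  Venn shares are derived from the
    totals/pairwise/triple counts by inclusion-exclusion; F-measures are
    derived from each evaluator's precision/recall pair.
    """
    path = Path(counts_file) if counts_file is not None else default_counts_path()
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        totals = {k: int(v) for k, v in data["totals"].items()}
        pairwise = data["pairwise"]
        triple = int(data["triple"])
        reported = data.get("reported_percentages", {})
        evaluators = data.get("evaluators", {})
    except (KeyError, TypeError, AttributeError, ValueError, yaml.YAMLError) as exc:
        raise ParseError(f"malformed counts file {path}: {exc}") from exc

    summary = venn_summary_from_counts(totals, pairwise, triple)
    rows = []
    for disease in summary.labels:
        computed = venn_percentages(summary, disease)
        for share, value in computed.items():
            reported_value = reported.get(disease, {}).get(share)
            match = reported_value is not None and float(reported_value) == value
            rows.append(
                {
                    "quantity": f"{disease} {share} share (%)",
                    "computed": value,
                    "reported": reported_value,
                    "match": match,
                    "note": "" if match else "inconsistent with reported value",
                }
            )
    for evaluator, metrics in evaluators.items():
        f = f_measure(float(metrics["precision"]), float(metrics["recall"]))
        f_rounded = None if f is None else round(f, 2)
        reported_f = metrics.get("f_measure")
        match = reported_f is not None and f_rounded == float(reported_f)
        rows.append(
            {
                "quantity": f"{evaluator} F-measure",
                "computed": f_rounded,
                "reported": reported_f,
                "match": match,
                "note": "" if match else "inconsistent with reported value",
            }
        )
    return pd.DataFrame(rows, columns=["quantity", "computed", "reported", "match", "note"])
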