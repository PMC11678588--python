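"""Synthetic heterogeneous knowledge graph with planted ground truth.

The generator emulates the structure a literature knowledge graph query
returns around three disease targets — Alzheimer's Disease (AD,
C0002395), Amyotrophic Lateral Sclerosis (ALS, C0002736) and
Frontotemporal Dementia (FTD, C0338451) — at a size where every
downstream stage (relevance ranking, overlap quantification, process
mapping, evidence classification) can be tested against known answers:

* each AAPP source node is assigned one of the seven exclusive Venn
  regions of the three diseases (or to none of them) by an i.i.d.
  multinomial draw; the default region probabilities follow the
  region proportions observed in the real three-disease comparison,
  with a small "unrelated" remainder;
* each (node, member-disease) pair receives a relevance tier; a tier
  plants that many *distinct* 2-hop bridge paths (node -> bridge ->
  disease), each through a dedicated fresh intermediate node, so the
  HeteSim meeting distribution grows with path count and tiers are
  recoverable from ranks;
* with probability ``direct_edge_prob`` the pair additionally gets a
  length-1 triple to the disease (the "direct evidence" case); if a
  tier plants zero paths the direct edge is forced so that every
  planted membership is realized within two hops;
* each node carries planted process-category labels; with probability
  ``keyword_rate`` per label a lexicon keyword of that category is
  embedded in the node name, which is what the name-based mapper can
  recover.

A single seeded generator stream is consumed in a fixed, documented
order — region draws, then tier/edge draws, then ambient links, then
label/name draws — so identical configurations produce byte-identical
fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .graph import ConceptNode, KnowledgeGraph, SemanticTriple, load_graph

#: Disease targets: label -> (CUI, display name).
DISEASES: dict[str, tuple[str, str]] = {
    "AD": ("C0002395", "Alzheimer's Disease"),
    "ALS": ("C0002736", "Amyotrophic Lateral Sclerosis"),
    "FTD": ("C0338451", "Frontotemporal Dementia"),
}
DISEASE_ORDER = ("AD", "ALS", "FTD")
DISEASE_TYPE = "dsyn"
SOURCE_TYPE = "aapp"

#: Venn regions in draw order; the eighth state is "none" (unrelated node).
REGIONS: tuple[tuple[str, ...], ...] = (
    ("AD",),
    ("ALS",),
    ("FTD",),
    ("AD", "ALS"),
    ("AD", "FTD"),
    ("ALS", "FTD"),
    ("AD", "ALS", "FTD"),
    (),
)
REGION_LABELS = ("AD", "ALS", "FTD", "AD∩ALS", "AD∩FTD", "ALS∩FTD", "AD∩ALS∩FTD", "none")

TIERS = ("high", "mid", "low")

#: Default region probabilities: the seven exclusive-region proportions of
#: the real three-disease comparison (AD-only 6.8%, ALS-only 1.0%, FTD-only
#: 0.05%, AD∩ALS 28.1%, AD∩FTD 0.36%, ALS∩FTD 0.28%, triple 63.4% of the
#: union), scaled by 0.95, plus a 5% unrelated remainder.
DEFAULT_REGION_PROBS = (0.0647, 0.0091, 0.0005, 0.2673, 0.0034, 0.0027, 0.6023, 0.05)

#: Category weights for planted process labels, patterned on the reported
#: overall shares of the eight processes (the unlisted energetics share
#: closes the total to 100%).
DEFAULT_LABEL_WEIGHTS: dict[str, float] = {
    "inflammation and immune response": 0.19,
    "synapse and neurotransmission": 0.19,
    "cell cycle regulation": 0.15,
    "protein aggregation": 0.12,
    "membrane regulation": 0.11,
    "energy and metabolism": 0.11,
    "stress response regulation": 0.09,
    "gene regulation and expression": 0.04,
}

#: Probability a node carries a second process label.
SECOND_LABEL_PROB = 0.3
#: Probability an ambient intermediate links to each disease.
AMBIENT_LINK_PROB = 0.5

RELATION_BRIDGE_IN = "associated_with"  # aapp -> bridge
RELATION_BRIDGE_OUT = "affects"  # bridge -> disease (also ambient -> disease)
RELATION_DIRECT = "interacts_with"  # aapp -> disease

RELATION_VOCABULARY = (RELATION_BRIDGE_IN, RELATION_BRIDGE_OUT, RELATION_DIRECT)


def _keywords_by_category() -> dict[str, tuple[str, ...]]:
    # Imported lazily to avoid a circular import at module load.
    from .processes import default_taxonomy

    taxonomy = default_taxonomy()
    return {c: taxonomy.lexicon[c] for c in taxonomy.categories}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-graph generator.

    ``region_probs`` lists the seven exclusive Venn-region probabilities
    in :data:`REGION_LABELS` order followed by the "none" probability;
    the eight values must sum to 1.  ``paths_per_strength`` maps each
    relevance tier to the number of distinct 2-hop bridge paths planted
    per disease membership and must be non-increasing from high to low.
    """

    n_aapp: int = 200
    region_probs: tuple[float, ...] = DEFAULT_REGION_PROBS
    n_intermediates: Mapping[str, int] = field(
        default_factory=lambda: {"gngm": 60, "celf": 60, "chem": 60}
    )
    direct_edge_prob: float = 0.3
    paths_per_strength: Mapping[str, int] = field(
        default_factory=lambda: {"high": 4, "mid": 2, "low": 1}
    )
    keyword_rate: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_aapp < 0:
            raise ConfigurationError("n_aapp must be non-negative")
        if len(self.region_probs) != len(REGIONS):
            raise ConfigurationError(
                f"region_probs must have {len(REGIONS)} entries (seven regions plus 'none')"
            )
        if any(p < 0 for p in self.region_probs):
            raise ConfigurationError("region_probs entries must be non-negative")
        if abs(sum(self.region_probs) - 1.0) > 1e-12:
            raise ConfigurationError("region_probs must sum to 1 within 1e-12")
        if not self.n_intermediates:
            raise ConfigurationError("n_intermediates must name at least one type")
        for node_type, count in self.n_intermediates.items():
            if count < 0:
                raise ConfigurationError(f"n_intermediates[{node_type!r}] must be non-negative")
        if not 0.0 <= self.direct_edge_prob <= 1.0:
            raise ConfigurationError("direct_edge_prob must lie in [0, 1]")
        if not 0.0 <= self.keyword_rate <= 1.0:
            raise ConfigurationError("keyword_rate must lie in [0, 1]")
        if set(self.paths_per_strength) != set(TIERS):
            raise ConfigurationError(f"paths_per_strength must map exactly the tiers {TIERS}")
        counts = [self.paths_per_strength[t] for t in TIERS]
        if any(c < 0 for c in counts):
            raise ConfigurationError("paths_per_strength values must be non-negative")
        if not (counts[0] >= counts[1] >= counts[2]):
            raise ConfigurationError(
                "paths_per_strength must be non-increasing from high to low"
            )

    def to_dict(self) -> dict:
        data = asdict(self)
        data["region_probs"] = list(self.region_probs)
        data["n_intermediates"] = dict(self.n_intermediates)
        data["paths_per_strength"] = dict(self.paths_per_strength)
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        if "region_probs" in data:
            data["region_probs"] = tuple(float(p) for p in data["region_probs"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted answers recorded alongside a generated graph."""

    membership: dict[str, tuple[str, ...]]
    relevance_tier: dict[str, dict[str, str]]
    process_labels: dict[str, tuple[str, ...]]
    direct_flag: dict[str, dict[str, bool]]

    def region_sets(self) -> dict[str, set[str]]:
        """Per-disease membership sets, the input overlap analysis recovers."""
        sets: dict[str, set[str]] = {d: set() for d in DISEASE_ORDER}
        for cui, diseases in self.membership.items():
            for disease in diseases:
                sets[disease].add(cui)
        return sets

    def to_dict(self) -> dict:
        return {
            "membership": {c: list(m) for c, m in self.membership.items()},
            "relevance_tier": self.relevance_tier,
            "process_labels": {c: list(p) for c, p in self.process_labels.items()},
            "direct_flag": self.direct_flag,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GroundTruth":
        return cls(
            membership={c: tuple(m) for c, m in data["membership"].items()},
            relevance_tier={c: dict(v) for c, v in data["relevance_tier"].items()},
            process_labels={c: tuple(p) for c, p in data["process_labels"].items()},
            direct_flag={
                c: {d: bool(f) for d, f in v.items()}
                for c, v in data["direct_flag"].items()
            },
        )


def generate_graph(config: GeneratorConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a knowledge graph and its ground truth from ``config``.

    Deterministic: identical config (including seed) yields identical
    output.  Every planted membership is realized by a direct edge
    and/or the planted 2-hop bridge paths.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    keywords = _keywords_by_category()
    categories = tuple(DEFAULT_LABEL_WEIGHTS)
    label_weights = np.array([DEFAULT_LABEL_WEIGHTS[c] for c in categories])
    label_weights = label_weights / label_weights.sum()

    bridge_types = sorted(config.n_intermediates)
    type_weights = np.array(
        [config.n_intermediates[t] for t in bridge_types], dtype=float
    )
    if type_weights.sum() > 0:
        type_weights = type_weights / type_weights.sum()
    else:
        type_weights = np.full(len(bridge_types), 1.0 / len(bridge_types))

    nodes: list[ConceptNode] = []
    triples: list[SemanticTriple] = []
    for label in DISEASE_ORDER:
        cui, name = DISEASES[label]
        nodes.append(ConceptNode(cui, name, DISEASE_TYPE))

    aapp_cuis = [f"CA{i:06d}" for i in range(config.n_aapp)]

    # Stage 1: region draws (one multinomial per AAPP node).
    region_idx = rng.choice(len(REGIONS), size=config.n_aapp, p=config.region_probs)

    membership: dict[str, tuple[str, ...]] = {}
    relevance_tier: dict[str, dict[str, str]] = {}
    direct_flag: dict[str, dict[str, bool]] = {}

    pmid_counter = 30000000

    def next_pmid() -> str:
        nonlocal pmid_counter
        pmid_counter += 1
        return str(pmid_counter)

    # Stage 2: tier, direct-edge and bridge draws, in node then disease order.
    bridge_counter = 0
    for i, cui in enumerate(aapp_cuis):
        diseases = REGIONS[region_idx[i]]
        membership[cui] = diseases
        relevance_tier[cui] = {}
        direct_flag[cui] = {}
        for disease in diseases:
            disease_cui = DISEASES[disease][0]
            tier = TIERS[rng.integers(len(TIERS))]
            relevance_tier[cui][disease] = tier
            n_paths = config.paths_per_strength[tier]
            direct = bool(rng.random() < config.direct_edge_prob)
            if n_paths == 0:
                direct = True  # keep the membership realizable within 2 hops
            direct_flag[cui][disease] = direct
            if direct:
                triples.append(
                    SemanticTriple(cui, RELATION_DIRECT, disease_cui, (next_pmid(),))
                )
            if n_paths > 0:
                bridge_type = bridge_types[int(rng.choice(len(bridge_types), p=type_weights))]
                for _ in range(n_paths):
                    bridge_cui = f"CB{bridge_counter:06d}"
                    bridge_counter += 1
                    nodes.append(
                        ConceptNode(bridge_cui, f"{bridge_type} bridge {bridge_cui[2:]}", bridge_type)
                    )
                    triples.append(
                        SemanticTriple(cui, RELATION_BRIDGE_IN, bridge_cui, (next_pmid(),))
                    )
                    triples.append(
                        SemanticTriple(bridge_cui, RELATION_BRIDGE_OUT, disease_cui, (next_pmid(),))
                    )

    # Stage 3: ambient distractor intermediates, sparsely tied to diseases.
    ambient_counter = 0
    for node_type in bridge_types:
        for _ in range(config.n_intermediates[node_type]):
            cui = f"CN{ambient_counter:06d}"
            ambient_counter += 1
            nodes.append(ConceptNode(cui, f"{node_type} concept {cui[2:]}", node_type))
            for disease in DISEASE_ORDER:
                if rng.random() < AMBIENT_LINK_PROB:
                    triples.append(
                        SemanticTriple(
                            cui, RELATION_BRIDGE_OUT, DISEASES[disease][0], (next_pmid(),)
                        )
                    )

    # Stage 4: process labels and keyword-bearing names.
    process_labels: dict[str, tuple[str, ...]] = {}
    for cui in aapp_cuis:
        n_labels = 1 + int(rng.random() < SECOND_LABEL_PROB)
        chosen = rng.choice(len(categories), size=n_labels, replace=False, p=label_weights)
        labels = tuple(sorted(categories[j] for j in chosen))
        process_labels[cui] = labels
        parts = [f"protein {cui[2:]}"]
        for category in labels:
            if rng.random() < config.keyword_rate:
                words = keywords[category]
                parts.append(words[int(rng.integers(len(words)))])
        name = " ".join(parts)
        nodes.append(ConceptNode(cui, name, SOURCE_TYPE))

    type_vocabulary = {SOURCE_TYPE, DISEASE_TYPE, *bridge_types}
    graph = KnowledgeGraph(nodes, triples, type_vocabulary, RELATION_VOCABULARY)
    truth = GroundTruth(membership, relevance_tier, process_labels, direct_flag)
    return graph, truth


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

NODE_FILE = "nodes.tsv"
EDGE_FILE = "edges.tsv"
TRUTH_FILE = "truth.json"
CONFIG_FILE = "config.yaml"


def write_fixture(
    graph: KnowledgeGraph,
    truth: GroundTruth,
    config: GeneratorConfig,
    directory: str | Path,
) -> dict[str, Path]:
    """Write node/edge tables, the ground truth and the config snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": directory / NODE_FILE,
        "edges": directory / EDGE_FILE,
        "truth": directory / TRUTH_FILE,
        "config": directory / CONFIG_FILE,
    }
    graph.write(paths["nodes"], paths["edges"])
    paths["truth"].write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    paths["config"].write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, allow_unicode=True),
        encoding="utf-8",
    )
    return paths


def load_fixture(directory: str | Path) -> tuple[KnowledgeGraph, GroundTruth, GeneratorConfig]:
    """Reload a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    graph = load_graph(directory / NODE_FILE, directory / EDGE_FILE)
    truth = GroundTruth.from_dict(
        json.loads((directory / TRUTH_FILE).read_text(encoding="utf-8"))
    )
    config = GeneratorConfig.from_dict(
        yaml.safe_load((directory / CONFIG_FILE).read_text(encoding="utf-8"))
    )
    return graph, truth, config


# --------------------------------------------------------------------------
# small random graphs for cross-checking the scoring machinery
# --------------------------------------------------------------------------


def random_typed_graph(
    seed: int,
    n_nodes: int = 10,
    n_types: int = 3,
    n_relations: int = 2,
    edge_prob: float = 0.25,
) -> KnowledgeGraph:
    """A small random typed multigraph used to validate metapath scoring.

    Every ordered node pair independently receives each relation with
    probability ``edge_prob``; node types are assigned cyclically so all
    declared types are populated.
    """
    rng = np.random.default_rng(seed)
    types = [f"t{i}" for i in range(n_types)]
    relations = [f"r{i}" for i in range(n_relations)]
    nodes = [
        ConceptNode(f"N{i:03d}", f"node {i}", types[i % n_types]) for i in range(n_nodes)
    ]
    triples = []
    for a in range(n_nodes):
        for b in range(n_nodes):
            if a == b:
                continue
            for relation in relations:
                if rng.random() < edge_prob:
                    triples.append(
                        SemanticTriple(nodes[a].cui, relation, nodes[b].cui, ())
                    )
    return KnowledgeGraph(nodes, triples, types, relations)
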