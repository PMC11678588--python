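"""Biological-process mapping and intersection profiles.

Top-ranked concept nodes are assigned to one or more of eight broad
biological processes (cell cycle regulation; energy and metabolism;
gene regulation and expression; inflammation and immune response;
membrane regulation; protein aggregation; stress response regulation;
synapse and neurotransmission) by deterministic, auditable keyword
matching: a node receives a category iff any lexicon keyword matches
its lower-cased name on a word boundary.  The default lexicon ships
with the package and is replaceable by any YAML file of the same shape.

Profiles count (node, category) *assignments* — a multi-label node
increments each of its categories — per disease-pair intersection, then
normalize each intersection's column to percentages and standardize
each category across intersections with population-SD z-scores.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

#: The eight process categories, in canonical (alphabetical) order.
CATEGORIES = (
    "cell cycle regulation",
    "energy and metabolism",
    "gene regulation and expression",
    "inflammation and immune response",
    "membrane regulation",
    "protein aggregation",
    "stress response regulation",
    "synapse and neurotransmission",
)


@dataclass(frozen=True)
class ProcessTaxonomy:
    """Eight process categories with their keyword lexicons."""

    lexicon: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if tuple(sorted(self.lexicon)) != CATEGORIES:
            raise ConfigurationError(
                f"taxonomy must define exactly the eight categories {CATEGORIES}"
            )
        for category, keywords in self.lexicon.items():
            if not keywords:
                raise ConfigurationError(f"category {category!r} has an empty lexicon")
            lowered = [k.lower() for k in keywords]
            if lowered != list(keywords):
                raise ConfigurationError(f"category {category!r} has non-lowercase keywords")
            if len(set(keywords)) != len(keywords):
                raise ConfigurationError(f"category {category!r} has duplicate keywords")

    @property
    def categories(self) -> tuple[str, ...]:
        return CATEGORIES

    def patterns(self) -> dict[str, re.Pattern]:
        return {
            category: re.compile(
                r"\b(?:" + "|".join(re.escape(k) for k in keywords) + r")\b"
            )
            for category, keywords in self.lexicon.items()
        }


def load_taxonomy(path: str | Path) -> ProcessTaxonomy:
    """Load a taxonomy from a YAML mapping ``category -> [keywords]``."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ProcessTaxonomy({c: tuple(words) for c, words in data.items()})


def default_taxonomy() -> ProcessTaxonomy:
    """The packaged default keyword lexicon."""
    with resources.files("litkg.data").joinpath("process_lexicon.yaml").open(
        "r", encoding="utf-8"
    ) as handle:
        data = yaml.safe_load(handle)
    return ProcessTaxonomy({c: tuple(words) for c, words in data.items()})


def map_nodes(
    nodes: Iterable[tuple[str, str]],
    taxonomy: ProcessTaxonomy | None = None,
) -> dict[str, set[str]]:
    """Assign process categories to ``(cui, name)`` pairs by keyword match.

    Multi-label assignment is permitted; nodes matching no keyword get
    the empty set (and are reported in a warning, since unmapped nodes
    usually indicate a lexicon gap).
    """
    taxonomy = taxonomy or default_taxonomy()
    patterns = taxonomy.patterns()
    mapping: dict[str, set[str]] = {}
    unmatched = 0
    for cui, name in nodes:
        lowered = name.lower()
        assigned = {c for c, pattern in patterns.items() if pattern.search(lowered)}
        mapping[cui] = assigned
        unmatched += not assigned
    if unmatched:
        warnings.warn(f"{unmatched} node(s) matched no process keyword", stacklevel=2)
    return mapping


def intersection_profile(
    top_sets: Mapping[str, set[str]],
    mapping: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Category x intersection assignment counts over pairwise top-set overlaps.

    For each unordered disease pair (X, Y) the column ``X∩Y`` counts,
    per category, the assignments among nodes in ``top_sets[X] &
    top_sets[Y]``.  Requires at least two diseases; an empty
    intersection yields an all-zero column with a warning.
    """
    if len(top_sets) < 2:
        raise ValueError("at least two disease top sets are required")
    columns = {}
    for x, y in combinations(top_sets, 2):
        shared = top_sets[x] & top_sets[y]
        if not shared:
            warnings.warn(f"empty intersection {x}∩{y}", stacklevel=2)
        counts = dict.fromkeys(CATEGORIES, 0)
        for cui in shared:
            for category in mapping.get(cui, ()):
                counts[category] += 1
        columns[f"{x}∩{y}"] = counts
    return pd.DataFrame(columns, index=list(CATEGORIES)).astype(int)


def normalize_profile(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-intersection percentages: each column rescaled to sum to 100.

    All-zero columns stay zero, with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"all-zero intersection column(s): {zero}", stacklevel=2)
    safe = totals.replace(0, np.nan)
    return (100.0 * counts / safe).fillna(0.0)


def process_zscores(profile: pd.DataFrame) -> pd.DataFrame:
    """Standardize each category across intersections (population SD).

    ``profile`` is normally the normalized percentage matrix (counts may
    be passed instead to standardize raw counts).  A zero-variance
    category gets all-zero z-scores with a warning; a single
    intersection is an error since deviation from the mean is undefined.
    """
    if profile.shape[1] < 2:
        raise ValueError("z-scores require at least two intersections")
    values = profile.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)  # population SD over intersections
    flat = sds.ravel() == 0
    if flat.any():
        names = [c for c, is_flat in zip(profile.index, flat) if is_flat]
        warnings.warn(f"zero-variance category(ies): {names}", stacklevel=2)
    z = np.divide(values - means, sds, out=np.zeros_like(values), where=sds > 0)
    return pd.DataFrame(z, index=profile.index, columns=profile.columns)


def overall_percentages(counts: pd.DataFrame) -> pd.Series:
    """Each category's share of all assignments across intersections (percent).

    Returns the unrounded shares; round to the nearest integer for
    display.  An all-zero matrix is an error.
    """
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("no assignments: overall shares undefined")
    return 100.0 * counts.sum(axis=1) / total
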