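"""Score normalization, top-percentile selection and composite scores.

HeteSim scores are only comparable within one simulation (one target
disease), so each per-disease score table is normalized independently:
z-scores remove the mean and scale to unit *population* variance (the
table is the full population of returned nodes, not a sample), and
percentile ranks use the Hazen definition ``100 * (rank - 0.5) / n``
with average ranks on ties, which makes rankings from different-size
simulations commensurable.

The composite score of a source node is the arithmetic mean of its raw
per-disease HeteSim scores over the diseases where it appears; a node
returned for a single disease keeps that disease's score unchanged.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RANKED_COLUMNS = ["cui", "raw_score", "z", "percentile"]
COMPOSITE_COLUMNS = ["cui", "diseases", "composite"]


def _as_score_frame(scores: pd.DataFrame) -> pd.DataFrame:
    if not {"cui", "score"}.issubset(scores.columns):
        # Accept the long-format ranking output as-is.
        if {"source_cui", "hetesim"}.issubset(scores.columns):
            return scores.rename(columns={"source_cui": "cui", "hetesim": "score"})[
                ["cui", "score"]
            ]
        raise ValueError("score table must have columns ('cui', 'score')")
    return scores[["cui", "score"]]


def normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Normalize one simulation's scores to z-scores and Hazen percentiles.

    Parameters
    ----------
    scores
        Table with columns ``cui`` and ``score`` (the raw HeteSim
        values); the long-format output of the ranking step is also
        accepted.

    Returns
    -------
    Table with columns ``cui, raw_score, z, percentile`` sorted by
    descending raw score (ties by ascending CUI).  A single-row table
    gets ``z = 0`` and percentile 50; a zero-variance table gets all
    ``z = 0`` with a warning.
    """
    frame = _as_score_frame(scores)
    if frame.empty:
        raise ValueError("score table must be non-empty")
    raw = frame["score"].to_numpy(dtype=float)
    n = raw.size
    sd = float(np.std(raw))  # population standard deviation
    if sd == 0.0:
        if n >= 2:
            warnings.warn("zero variance in scores; all z set to 0", stacklevel=2)
        z = np.zeros(n)
    else:
        z = (raw - raw.mean()) / sd
    percentile = 100.0 * (rankdata(raw, method="average") - 0.5) / n
    out = pd.DataFrame(
        {"cui": frame["cui"].to_numpy(), "raw_score": raw, "z": z, "percentile": percentile}
    )
    return out.sort_values(
        by=["raw_score", "cui"], ascending=[False, True]
    ).reset_index(drop=True)


def top_percent(table: pd.DataFrame, pct: float) -> set[str]:
    """The ``ceil(n * pct / 100)`` highest raw-score CUIs of a ranked table.

    Ties at the selection threshold are broken by ascending CUI so the
    result always has exactly the ceiling cardinality.  An empty table
    yields the empty set.
    """
    if not 0 < pct <= 100:
        raise ValueError("pct must lie in (0, 100]")
    if table.empty:
        return set()
    score_col = "raw_score" if "raw_score" in table.columns else "score"
    ordered = table.sort_values(by=[score_col, "cui"], ascending=[False, True])
    k = math.ceil(len(ordered) * pct / 100.0)
    return set(ordered["cui"].head(k))


def composite_scores(per_disease: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-disease composite score table.

    ``per_disease`` maps a disease label to that simulation's score
    table (columns ``cui`` and ``score``, raw HeteSim values).  Each
    source node present in at least one table gets one row with the
    diseases it appears under (semicolon-joined, in the mapping's key
    order) and the arithmetic mean of its per-disease scores.
    """
    if not per_disease:
        raise ValueError("at least one disease table is required")
    per_node: dict[str, dict[str, float]] = {}
    for disease, table in per_disease.items():
        frame = _as_score_frame(table)
        for cui, score in zip(frame["cui"], frame["score"]):
            per_node.setdefault(cui, {})[disease] = float(score)
    rows = [
        (cui, ";".join(scores), float(np.mean(list(scores.values()))))
        for cui, scores in per_node.items()
    ]
    out = pd.DataFrame(rows, columns=COMPOSITE_COLUMNS)
    return out.sort_values(
        by=["composite", "cui"], ascending=[False, True]
    ).reset_index(drop=True)
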