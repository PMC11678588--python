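"""Direct/indirect evidence classification and its evaluation.

A source node's evidence for a target disease is *direct* when a single
semantic triple (in either direction) links it to at least one target,
and *indirect* when it is connected only through intermediates — i.e.
the classification is by the shortest metapath link to the targets.
Predictions are scored against ground-truth labels with the usual
confusion-matrix metrics; ratios with zero denominators are reported as
not-applicable (``None``), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ClassificationError, EvaluationError
from .graph import KnowledgeGraph

DIRECT = "direct"
INDIRECT = "indirect"
CLASSES = (DIRECT, INDIRECT)

LABEL_COLUMNS = ["cui", "disease", "predicted", "evaluator", "truth"]


@dataclass(frozen=True)
class EvidenceLabel:
    """One prediction (and optionally its ground truth) for a (node, disease)."""

    cui: str
    disease: str
    predicted: str
    evaluator: str = "graph"
    truth: str | None = None

    def __post_init__(self) -> None:
        if self.predicted not in CLASSES:
            raise EvaluationError(f"predicted must be one of {CLASSES}")
        if self.truth is not None and self.truth not in CLASSES:
            raise EvaluationError(f"truth must be one of {CLASSES}")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived metrics (None where undefined)."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f_measure: float | None
    accuracy: float | None
    positive_class: str

    def rounded(self, digits: int = 2) -> dict[str, float | None]:
        """Metrics rounded for reporting; full precision is kept on the fields."""
        return {
            name: (None if value is None else round(value, digits))
            for name, value in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f_measure", self.f_measure),
                ("accuracy", self.accuracy),
            )
        }

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "positive_class": self.positive_class,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "accuracy": self.accuracy,
            "rounded": self.rounded(),
        }


def classify_evidence(
    graph: KnowledgeGraph,
    cui: str,
    targets: Sequence[str],
    depth: int | None = None,
) -> str:
    """Classify a node's evidence as direct or indirect w.r.t. the targets.

    ``direct`` iff a length-1 triple (either direction) links the node
    to at least one target.  When ``depth`` is given, a node with no
    target within that many hops raises a
    :class:`~litkg.exceptions.ClassificationError`.
    """
    graph.node(cui)
    for target in targets:
        graph.node(target)
    if any(graph.has_link(cui, target) for target in targets):
        return DIRECT
    if depth is not None:
        reachable = graph.neighborhood(cui, depth)
        if not reachable.intersection(targets):
            raise ClassificationError(
                f"{cui!r} is not connected to any target within {depth} hops"
            )
    return INDIRECT


def f_measure(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall (None when both are zero)."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def evaluate(
    predictions: Iterable[EvidenceLabel] | pd.DataFrame,
    positive_class: str = DIRECT,
) -> EvaluationReport:
    """Score predictions against their ground-truth labels.

    Every prediction must carry a truth label; offending CUIs are listed
    otherwise.  ``positive_class`` defaults to ``direct``.
    """
    if positive_class not in CLASSES:
        raise EvaluationError(f"positive_class must be one of {CLASSES}")
    if isinstance(predictions, pd.DataFrame):
        predictions = [
            EvidenceLabel(
                row.cui,
                row.disease,
                row.predicted,
                getattr(row, "evaluator", "graph"),
                None if pd.isna(row.truth) or row.truth == "" else row.truth,
            )
            for row in predictions.itertuples()
        ]
    labels = list(predictions)
    if not labels:
        raise EvaluationError("no predictions to evaluate")
    missing = [label.cui for label in labels if label.truth is None]
    if missing:
        raise EvaluationError(f"missing truth labels for: {sorted(set(missing))}")

    tp = sum(l.predicted == positive_class and l.truth == positive_class for l in labels)
    fp = sum(l.predicted == positive_class and l.truth != positive_class for l in labels)
    fn = sum(l.predicted != positive_class and l.truth == positive_class for l in labels)
    tn = sum(l.predicted != positive_class and l.truth != positive_class for l in labels)

    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f = f_measure(precision, recall) if precision is not None and recall is not None else None
    accuracy = (tp + tn) / len(labels)
    return EvaluationReport(tp, fp, fn, tn, precision, recall, f, accuracy, positive_class)


def write_labels(labels: Iterable[EvidenceLabel], path: str) -> None:
    """Write labels as the CSV dialect ``cui disease predicted evaluator truth``."""
    frame = pd.DataFrame(
        [(l.cui, l.disease, l.predicted, l.evaluator, l.truth or "") for l in labels],
        columns=LABEL_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_labels(path: str) -> list[EvidenceLabel]:
    """Read a label CSV written by :func:`write_labels` (or an external evaluator)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        EvidenceLabel(
            row.cui,
            row.disease,
            row.predicted,
            row.evaluator or "external",
            row.truth or None,
        )
        for row in frame.itertuples()
    ]
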