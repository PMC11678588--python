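"""Three-set overlap quantification (Venn regions by inclusion-exclusion).

Given per-disease node sets A, B, C (or just their printed summary
counts), the seven exclusive Venn regions follow from
inclusion-exclusion, e.g. ``|A only| = |A| - |A∩B| - |A∩C| + |A∩B∩C|``.
Per-disease shares are expressed on that disease's own total: the share
in the triple intersection, the share held exclusively with each of the
other two diseases, and the exclusive share, each rounded to one
decimal, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import ConsistencyError

DEFAULT_LABELS = ("AD", "ALS", "FTD")


def round_half_away(value: float, digits: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1 at one decimal)."""
    factor = 10.0**digits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class VennSummary:
    """Totals, pairwise/triple intersections and exclusive region counts."""

    labels: tuple[str, str, str]
    totals: Mapping[str, int]
    pairwise: Mapping[tuple[str, str], int]
    triple: int
    regions: Mapping[tuple[str, ...], int]

    def region(self, *labels: str) -> int:
        return self.regions[tuple(sorted(labels))]

    def others(self, label: str) -> tuple[str, str]:
        rest = [x for x in self.labels if x != label]
        if len(rest) != 2:
            raise KeyError(f"unknown disease label {label!r}")
        return rest[0], rest[1]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "totals": dict(self.totals),
            "pairwise": {"∩".join(k): v for k, v in self.pairwise.items()},
            "triple": self.triple,
            "regions": {"∩".join(k) if k else "none": v for k, v in self.regions.items()},
        }


def _build_summary(
    labels: Sequence[str],
    totals: Mapping[str, int],
    pairwise: Mapping[tuple[str, str], int],
    triple: int,
) -> VennSummary:
    a, b, c = labels
    regions: dict[tuple[str, ...], int] = {}
    regions[tuple(sorted((a, b, c)))] = triple
    for x, y in ((a, b), (a, c), (b, c)):
        regions[_pair_key(x, y)] = pairwise[_pair_key(x, y)] - triple
    for x in labels:
        y, z = [w for w in labels if w != x]
        regions[(x,)] = (
            totals[x] - pairwise[_pair_key(x, y)] - pairwise[_pair_key(x, z)] + triple
        )
    for key, count in regions.items():
        if count < 0:
            name = "∩".join(key) + (" only" if len(key) < 3 else "")
            raise ConsistencyError(
                f"inconsistent counts: exclusive region {name!r} would be {count}"
            )
    return VennSummary(
        labels=(a, b, c),
        totals=dict(totals),
        pairwise=dict(pairwise),
        triple=triple,
        regions=regions,
    )


def intersect_sets(
    A: set[str],
    B: set[str],
    C: set[str],
    labels: Sequence[str] = DEFAULT_LABELS,
) -> VennSummary:
    """Exact seven-region summary of three identifier sets."""
    a, b, c = labels
    totals = {a: len(A), b: len(B), c: len(C)}
    pairwise = {
        _pair_key(a, b): len(A & B),
        _pair_key(a, c): len(A & C),
        _pair_key(b, c): len(B & C),
    }
    return _build_summary(labels, totals, pairwise, len(A & B & C))


def venn_summary_from_counts(
    totals: Mapping[str, int],
    pairwise: Mapping[tuple[str, str], int] | Mapping[str, int],
    triple: int,
) -> VennSummary:
    """Summary from printed totals, pairwise intersections and the triple count.

    ``pairwise`` keys may be 2-tuples of labels or strings like
    ``"AD∩FTD"``.  Counts violating the containment ordering (a negative
    exclusive region) raise a :class:`~litkg.exceptions.ConsistencyError`
    naming the region.
    """
    labels = tuple(totals)
    if len(labels) != 3:
        raise ValueError("exactly three disease totals are required")
    normalized: dict[tuple[str, str], int] = {}
    for key, value in pairwise.items():
        if isinstance(key, str):
            parts = tuple(key.replace("&", "∩").split("∩"))
        else:
            parts = tuple(key)
        if len(parts) != 2 or any(p not in labels for p in parts):
            raise ValueError(f"unrecognized pairwise key {key!r}")
        normalized[_pair_key(*parts)] = int(value)
    for x, y in ((labels[0], labels[1]), (labels[0], labels[2]), (labels[1], labels[2])):
        if _pair_key(x, y) not in normalized:
            raise ValueError(f"missing pairwise count for {x}∩{y}")
    return _build_summary(labels, {k: int(v) for k, v in totals.items()}, normalized, int(triple))


def venn_percentages(summary: VennSummary, disease: str) -> dict[str, float]:
    """One disease's four region shares, on its own total.

    Returns ``{"triple": ..., "shared_<X>": ..., "shared_<Y>": ...,
    "exclusive": ...}`` where ``shared_<X>`` is the share held
    exclusively with disease X.  Each value is ``100 * region / total``
    rounded to one decimal, half away from zero.
    """
    total = summary.totals[disease]
    if total <= 0:
        raise ZeroDivisionError(f"disease {disease!r} has zero total; shares undefined")
    x, y = summary.others(disease)
    shares = {
        "triple": summary.triple,
        f"shared_{x}": summary.region(disease, x),
        f"shared_{y}": summary.region(disease, y),
        "exclusive": summary.region(disease),
    }
    return {k: round_half_away(100.0 * v / total, 1) for k, v in shares.items()}


def venn_figure(summary: VennSummary, path: str) -> None:
    """Static three-circle Venn figure with region counts (optional export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    a, b, c = summary.labels
    centers = {a: (-0.5, 0.3), b: (0.5, 0.3), c: (0.0, -0.55)}
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, center in centers.items():
        ax.add_patch(Circle(center, 0.85, alpha=0.3, label=label))
        ax.annotate(label, center, xytext=(center[0] * 1.9, center[1] * 1.9), ha="center")
    positions = {
        (a,): (-0.95, 0.55),
        (b,): (0.95, 0.55),
        (c,): (0.0, -1.05),
        _pair_key(a, b): (0.0, 0.6),
        _pair_key(a, c): (-0.6, -0.3),
        _pair_key(b, c): (0.6, -0.3),
        tuple(sorted((a, b, c))): (0.0, 0.0),
    }
    for key, pos in positions.items():
        ax.annotate(str(summary.regions[key]), pos, ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
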