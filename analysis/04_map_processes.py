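"""Profile biological processes across the disease-pair intersections.

Takes each disease's top-ranked slice, maps names to the eight process
categories with the default lexicon, and writes the count,
normalized-percentage and z-score matrices plus overall shares.  At
this desk scale a 1% slice of ~500 ranked sources holds only a handful
of nodes, so the analysis profiles the top 5% to keep each pairwise
intersection populated; the library default remains 1%.
"""

import json
import warnings

import pandas as pd

from common import RESULTS, get_fixture

from litkg.processes import (
    intersection_profile,
    map_nodes,
    normalize_profile,
    overall_percentages,
    process_zscores,
)
from litkg.ranking import top_percent
from litkg.venn import round_half_away


def main() -> None:
    graph, _ = get_fixture()
    pct = 5.0  # desk-scale slice; see module docstring
    top_sets = {}
    for disease in ("AD", "ALS", "FTD"):
        ranked = pd.read_csv(RESULTS / f"ranked_{disease}.csv")
        top_sets[disease] = top_percent(ranked, pct)
        print(f"{disease}: top {pct:g}% -> {len(top_sets[disease])} nodes")
    names = sorted((c, graph.node(c).name) for s in top_sets.values() for c in s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mapping = map_nodes(names)
        counts = intersection_profile(top_sets, mapping)
        normalized = normalize_profile(counts)
        zscores = process_zscores(normalized)
        overall = overall_percentages(counts)
    counts.to_csv(RESULTS / "process_counts.csv", index_label="category")
    normalized.to_csv(RESULTS / "process_normalized.csv", index_label="category")
    zscores.to_csv(RESULTS / "process_zscores.csv", index_label="category")
    (RESULTS / "process_overall.json").write_text(
        json.dumps(
            {c: int(round_half_away(v, 0)) for c, v in overall.items()},
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    print("overall process shares (%):")
    for category, value in overall.sort_values(ascending=False).items():
        print(f"  {category:>34}: {round_half_away(value, 0):.0f}")
    for column in zscores.columns:
        leader = zscores[column].idxmax()
        print(f"most over-represented in {column}: {leader} (z={zscores[column].max():.2f})")


if __name__ == "__main__":
    main()
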