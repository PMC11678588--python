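"""Rank AAPP source nodes against each disease target by HeteSim.

One simulation per disease (depth 2, metapath length 3), normalized
within-simulation to z-scores and percentiles.  Writes
results/ranked_<disease>.csv and results/composite.csv and prints the
top of each ranking.
"""

from common import RESULTS, get_fixture

from litkg.metapaths import rank_sources
from litkg.ranking import composite_scores, normalize_scores
from litkg.synthetic import DISEASES


def main() -> None:
    graph, _ = get_fixture()
    per_disease = {}
    for disease, (cui, _) in DISEASES.items():
        scores = rank_sources(graph, [cui], "aapp")
        table = scores.rename(columns={"source_cui": "cui", "hetesim": "score"})[
            ["cui", "score"]
        ]
        per_disease[disease] = table
        ranked = normalize_scores(table)
        path = RESULTS / f"ranked_{disease}.csv"
        ranked.to_csv(path, index=False)
        print(f"{disease}: {len(ranked)} sources ranked -> {path}")
        print(ranked.head(3).to_string(index=False))
    composite = composite_scores(per_disease)
    composite.to_csv(RESULTS / "composite.csv", index=False)
    print(f"composite scores for {len(composite)} sources -> {RESULTS / 'composite.csv'}")


if __name__ == "__main__":
    main()
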