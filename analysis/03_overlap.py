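"""Quantify the three-way overlap of the per-disease returned node sets.

Builds the seven-region Venn summary of the ranked sets, reports each
disease's shares on its own total, and writes results/venn.json.
"""

import json

import pandas as pd

from common import RESULTS

from litkg.venn import intersect_sets, venn_percentages


def main() -> None:
    sets = {
        d: set(pd.read_csv(RESULTS / f"ranked_{d}.csv")["cui"])
        for d in ("AD", "ALS", "FTD")
    }
    summary = intersect_sets(sets["AD"], sets["ALS"], sets["FTD"])
    payload = summary.to_dict()
    payload["percentages"] = {d: venn_percentages(summary, d) for d in sets}
    (RESULTS / "venn.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False) + "\n"
    )
    print(f"totals: {summary.totals}; triple intersection: {summary.triple}")
    for disease in sets:
        shares = payload["percentages"][disease]
        print(
            f"{disease}: {shares['triple']}% in the triple intersection, "
            f"{shares['exclusive']}% exclusive"
        )
    print(f"wrote {RESULTS / 'venn.json'}")


if __name__ == "__main__":
    main()
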