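"""Recompute the published summary arithmetic from the shipped counts.

Derives every Venn share by inclusion-exclusion from the reported
totals/pairwise/triple counts, and every F-measure from the reported
precision/recall pairs, flagging reported values the arithmetic
contradicts.  Writes results/reported_reproduction.csv.
"""

from common import RESULTS

from litkg.pipeline import reproduce_printed_tables


def main() -> None:
    table = reproduce_printed_tables()
    table.to_csv(RESULTS / "reported_reproduction.csv", index=False)
    print(table.to_string(index=False))
    mismatches = table[~table["match"]]
    print(
        f"\n{len(table) - len(mismatches)}/{len(table)} reported values reproduced; "
        f"{len(mismatches)} inconsistent: {', '.join(mismatches.quantity)}"
    )
    print(f"wrote {RESULTS / 'reported_reproduction.csv'}")


if __name__ == "__main__":
    main()
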