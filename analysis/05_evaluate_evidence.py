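"""Classify direct vs indirect evidence and score against the plant.

Every planted (node, disease) membership is classified from the graph
(direct iff a length-1 triple reaches the disease) and compared with
the ground-truth flags; writes results/evidence_report.json.
"""

import json

from common import RESULTS, get_fixture

from litkg.evidence import DIRECT, INDIRECT, EvidenceLabel, classify_evidence, evaluate
from litkg.synthetic import DISEASES


def main() -> None:
    graph, truth = get_fixture()
    labels = [
        EvidenceLabel(
            cui,
            disease,
            classify_evidence(graph, cui, [DISEASES[disease][0]]),
            truth=DIRECT if flag else INDIRECT,
        )
        for cui, flags in truth.direct_flag.items()
        for disease, flag in flags.items()
    ]
    report = evaluate(labels)
    (RESULTS / "evidence_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    direct_share = sum(l.truth == DIRECT for l in labels) / len(labels)
    print(f"{len(labels)} (node, disease) pairs classified; {direct_share:.1%} direct")
    print(f"metrics vs planted truth: {report.rounded()}")
    print(f"wrote {RESULTS / 'evidence_report.json'}")


if __name__ == "__main__":
    main()
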