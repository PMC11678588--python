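"""Generate the synthetic knowledge graph the analysis runs on.

Emits a 500-source-node heterogeneous graph with three disease targets
(AD, ALS, FTD), planted Venn-region membership, planted 2-hop relevance
tiers, and process-keyword-bearing names, plus the ground-truth record,
under results/fixture/.
"""

from collections import Counter

from common import FIXTURE_DIR, STUDY_CONFIG, get_fixture

from litkg.synthetic import REGION_LABELS, REGIONS


def main() -> None:
    graph, truth = get_fixture()
    print(f"fixture: {FIXTURE_DIR}")
    print(f"graph: {graph.n_nodes} nodes, {graph.n_triples} triples")
    print(f"config: n_aapp={STUDY_CONFIG.n_aapp}, seed={STUDY_CONFIG.seed}")
    regions = Counter(truth.membership.values())
    print("planted region counts:")
    for label, region in zip(REGION_LABELS, REGIONS):
        print(f"  {label:>12}: {regions.get(region, 0)}")


if __name__ == "__main__":
    main()
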