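"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from litkg.synthetic import GeneratorConfig, generate_graph, load_fixture, write_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
FIXTURE_DIR = RESULTS / "fixture"

#: The study-emulating conditions used throughout the analysis.
STUDY_CONFIG = GeneratorConfig(n_aapp=500, seed=17)


def get_fixture():
    """Load the shared synthetic fixture, generating it on first use."""
    if (FIXTURE_DIR / "config.yaml").exists():
        graph, truth, _ = load_fixture(FIXTURE_DIR)
        return graph, truth
    graph, truth = generate_graph(STUDY_CONFIG)
    write_fixture(graph, truth, STUDY_CONFIG, FIXTURE_DIR)
    return graph, truth
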