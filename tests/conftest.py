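import json
from pathlib import Path

import pytest

from grinmap import fixtures, workflow

DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory) -> Path:
    """A synthetic trio workspace shared across the session."""
    directory = tmp_path_factory.mktemp("demo_ws")
    fixtures.write_demo_workspace(directory, seed=DEMO_SEED)
    return directory


@pytest.fixture(scope="session")
def demo_workspace(demo_dir):
    return workflow.Workspace.load(demo_dir)


@pytest.fixture(scope="session")
def demo_map(demo_workspace):
    return workflow.build_equivalence(demo_workspace)


@pytest.fixture(scope="session")
def demo_truth(demo_dir):
    return json.loads((demo_dir / "ground_truth.json").read_text())


@pytest.fixture()
def identity_map():
    """A GluN2A<->GluN2B identity-offset map over 300 positions, built from a
    gapless alignment of identical sequences (positions 1..300 vs 2..301)."""
    import numpy as np

    from grinmap.alignment import AlignedPair, ResidueAlignment, STRUCTURAL
    from grinmap.equivalence import build_map

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    aln = ResidueAlignment(
        ("GluN2A", "GluN2B"),
        [AlignedPair(i + 1, i + 2, seq[i], seq[i], STRUCTURAL) for i in range(300)],
        n_columns=300,
        domain="LBD",
    )
    return build_map([aln])
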