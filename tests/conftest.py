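import numpy as np
import pytest

from lignoamp.primers import load_primer_bundle
from lignoamp.simulate import ReadSimConfig, simulate_community, simulate_family, simulate_reads

PLANTED_SUBFAMILIES = ["MnP", "LiP", "VP", "GP"] * 5


@pytest.fixture(scope="session")
def primer_pairs():
    return load_primer_bundle()


@pytest.fixture(scope="session")
def aa2_family():
    """20 AA2 variants at ~10% divergence with planted subfamily labels."""
    return simulate_family(
        "AA2", 20, 0.10, seed=101, planted_subfamilies=PLANTED_SUBFAMILIES
    )


@pytest.fixture(scope="session")
def gh11_family():
    return simulate_family("GH11", 10, 0.10, seed=202)


@pytest.fixture(scope="session")
def noiseless_gh11_reads(gh11_family):
    community = simulate_community(10, 2, depth=300, shared_fraction=1.0, seed=7)
    cfg = ReadSimConfig(substitution_rate=0.0, n_rate=0.0, chimera_rate=0.0)
    return simulate_reads(gh11_family, community, cfg, seed=7)


def mutate(seq: str, positions, rng=None) -> str:
    """Substitute each listed position with a deterministic different base."""
    rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rotate[out[p]]
    return "".join(out)
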