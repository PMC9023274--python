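import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from cpbind.profiles import ProteinSequence, RnaSequence
from cpbind.scales import STANDARD_AA, AffinityScale, builtin_polar_requirement

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int, name: str = "g") -> RnaSequence:
    return RnaSequence(name, "".join(rng.choice(list(RNA), size=length)))


def random_protein(rng: np.random.Generator, length: int, name: str = "p") -> ProteinSequence:
    return ProteinSequence(name, "".join(rng.choice(list(STANDARD_AA), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def polar() -> AffinityScale:
    return builtin_polar_requirement()


@pytest.fixture
def toy_base_scales() -> dict:
    """Simple distinguishable per-base scales for energy tests."""
    rng = np.random.default_rng(7)
    out = {}
    for i, b in enumerate("AGCU"):
        vals = {aa: float(v) for aa, v in
                zip(STANDARD_AA, rng.normal(0, 1 + i * 0.3, size=20))}
        out[b] = AffinityScale(name=f"toy{b}", values=vals)
    return out
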