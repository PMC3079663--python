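"""Shared fixtures: seeded random sequences and the synthetic study pair."""
from __future__ import annotations

import numpy as np
import pytest

from mitodiff.homology import find_shared_segments, unique_regions
from mitodiff.simulate import simulate_pair

BASES = np.array(list("ACGT"))


def random_dna(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(BASES, size=n))


def random_codons(seed: int, n: int) -> str:
    """n random non-stop codons."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        c = "".join(rng.choice(BASES, size=3))
        if c not in ("TAA", "TAG", "TGA"):
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def study_pair():
    """The reduced-scale study-profile dataset (seed 1)."""
    return simulate_pair(1)


@pytest.fixture(scope="session")
def study_segments(study_pair):
    anc, _, var, _, _, _, _ = study_pair
    return find_shared_segments(var, anc)


@pytest.fixture(scope="session")
def study_regions(study_pair, study_segments):
    _, _, var, _, _, _, _ = study_pair
    return unique_regions(var, study_segments)
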