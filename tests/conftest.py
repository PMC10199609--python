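from __future__ import annotations

import numpy as np
import pytest

from chemtx import GeneUniverse, SignedVector


@pytest.fixture
def universe4() -> GeneUniverse:
    return GeneUniverse(("T1", "T2", "G3", "G4"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230519)


def make_vector(universe: GeneUniverse, values) -> SignedVector:
    return SignedVector(universe, np.asarray(values, dtype=np.int8))


def random_ternary(rng: np.random.Generator, universe: GeneUniverse, p_nonzero=0.4):
    vals = np.zeros(len(universe), dtype=np.int8)
    nz = rng.random(len(universe)) < p_nonzero
    vals[nz] = rng.choice([-1, 1], size=int(nz.sum()))
    return SignedVector(universe, vals)
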