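"""Shared fixtures: small deterministic systems and one mid-size
reference ensemble reused by the slower recovery checks."""

import numpy as np
import pytest

from cgforge.potentials import CKDgParams
from cgforge.sampler import (Frame, PairTables, ThermodynamicState,
                             init_lattice, mc_nvt)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def lj_truth():
    """LJ-like ground-truth interaction (CKD form, smooth well)."""
    return CKDgParams(sigma=1.0, eps=1.0, w_c=0.5, h=0.0, p=1.5, s=0.3)


@pytest.fixture(scope="session")
def lj_system(lj_truth):
    """60-particle LJ-like fluid setup shared by sampler-level tests."""
    N, rho = 60, 0.45
    L = (N / rho) ** (1.0 / 3.0)
    state = ThermodynamicState(T=1.0)
    start = init_lattice(N, L, species=np.array(["A"] * N), seed=1)
    tables = PairTables.single(lj_truth.table(500), "A")
    return {"N": N, "rho": rho, "L": L, "state": state, "start": start,
            "tables": tables}


@pytest.fixture(scope="session")
def lj_reference(lj_system):
    """Well-sampled reference trajectory of the 60-particle fluid.

    Shared (session scope) because the relative-entropy recovery and
    self-consistency checks both consume it and it costs a few seconds.
    """
    return mc_nvt(lj_system["start"], lj_system["tables"],
                  lj_system["state"], n_steps=200_000, max_disp=0.35,
                  seed=11, stride=250)


@pytest.fixture
def random_frame(rng):
    """A random 40-particle single-species frame in a unit-density box."""
    L = 5.0
    pos = rng.uniform(0, L, size=(40, 3))
    return Frame(pos, np.array(["A"] * 40), L)
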