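"""Synthetic reference systems for exercising the coarse-graining loop.

Each fixture plays the role of an all-atom reference ensemble: a toy
system with a *known* ground-truth interaction is sampled with the
built-in Monte-Carlo engine, mapped to CG beads by center of mass, and
analyzed into reference RDFs.  Because the truth is known, optimizer
output can be checked by recovery (does the optimized CG potential
reproduce the reference structure?) rather than against external data.

Kinds
-----
``lj_fluid``
    Point particles with an LJ-like potential (CKD form, smoothly
    truncated well) — single species, identity mapping.
``dimer_fluid``
    Rigid two-site molecules mapped to one COM bead each.
``trimer_fluid``
    Rigid three-site molecules with an unequal mass distribution
    (heavy central site, two light satellites), one COM bead each.
``binary_mixture``
    Two point-particle species with three distinct pair interactions
    (AA, AB, BB), producing three reference RDFs.

Default sizes (N = 60–108 particles, ~10^5 MC moves) keep a full
fixture under ~10 s on one core while leaving per-bin RDF noise well
below the recovery tolerances used in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping_analysis import RDF, compute_rdf, map_com
from .potentials import CKDgParams
from .sampler import (Frame, MoleculeType, PairTables, Site,
                      ThermodynamicState, Topology, Trajectory, init_lattice,
                      mc_nvt)

__all__ = ["ReferenceFixture", "generate_reference_fixture", "mole_fraction"]

FIXTURE_KINDS = ("lj_fluid", "dimer_fluid", "trimer_fluid", "binary_mixture")


@dataclass
class ReferenceFixture:
    """A self-contained reference ensemble with known ground truth."""

    kind: str
    topology: Topology
    state: ThermodynamicState
    L: float
    reference: Trajectory          # site-level ("all-atom") trajectory
    mapped: Trajectory             # COM-mapped CG trajectory
    rdfs: dict                     # pair tuple -> reference RDF
    truth_tables: PairTables       # ground-truth site-site interactions
    truth_params: dict = field(default_factory=dict)
    cg_start: Frame = None         # mapped last frame: CG-run start config
    seed: int = 0

    @property
    def pairs(self):
        return sorted(self.rdfs)


def mole_fraction(counts: dict) -> dict:
    """Mole fractions x_i = N_i / sum N from per-species counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total particle count must be positive")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    return {k: v / total for k, v in counts.items()}


def _lj_like(sigma: float = 1.0, eps: float = 1.0,
             w_c: float = 0.5) -> CKDgParams:
    return CKDgParams(sigma=sigma, eps=eps, w_c=w_c, h=0.0, p=1.5, s=0.3)


def generate_reference_fixture(kind: str, seed: int = 0, *,
                               n: int = 60, rho: float = 0.45,
                               T: float = 1.0, n_steps: int = 150_000,
                               stride: int = 250, max_disp: float = 0.35,
                               equilibration: float = 0.25,
                               r_max: float = None, bin_width: float = 0.1,
                               x: float = 0.5) -> ReferenceFixture:
    """Sample a toy reference system and analyze it into CG targets.

    ``n`` counts molecules, ``rho`` is the molecule number density and
    ``x`` the minority mole fraction of the binary mixture.  Returns
    the raw and COM-mapped trajectories, one reference RDF per CG
    species pair, and the ground-truth interaction tables.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    state = ThermodynamicState(T=T)
    L = (n / rho) ** (1.0 / 3.0)
    truth_params = {}

    if kind == "lj_fluid":
        topo = Topology.point_particles({"A": n})
        p = _lj_like()
        truth_params[("A", "A")] = p
        tables = PairTables({("A", "A"): p.table()})
    elif kind == "binary_mixture":
        n_b = max(1, int(round(x * n)))
        n_a = n - n_b
        topo = Topology.point_particles({"A": n_a, "B": n_b})
        pa = _lj_like(sigma=1.0, eps=1.0)
        pb = _lj_like(sigma=0.85, eps=0.7)
        # cross interaction from geometric/arithmetic combination
        pab = _lj_like(sigma=0.5 * (1.0 + 0.85), eps=np.sqrt(1.0 * 0.7))
        truth_params = {("A", "A"): pa, ("A", "B"): pab, ("B", "B"): pb}
        tables = PairTables({k: v.table() for k, v in truth_params.items()})
    elif kind == "dimer_fluid":
        bond = 0.5
        geom = np.array([[-bond / 2, 0.0, 0.0], [bond / 2, 0.0, 0.0]])
        mt = MoleculeType("D", [Site("d", 1.0), Site("d", 1.0)],
                          geometry=geom)
        topo = Topology([(mt, n)])
        p = _lj_like(sigma=0.8, eps=0.8)
        truth_params[("d", "d")] = p
        tables = PairTables({("d", "d"): p.table()})
    else:  # trimer_fluid — heavy core, two light satellites
        geom = np.array([[0.0, 0.0, 0.0],
                         [0.35, 0.0, 0.0],
                         [-0.11, 0.33, 0.0]])
        mt = MoleculeType("W", [Site("w", 16.0), Site("h", 1.0),
                                Site("h", 1.0)], geometry=geom)
        topo = Topology([(mt, n)])
        pw = _lj_like(sigma=0.9, eps=1.0)
        ph = _lj_like(sigma=0.45, eps=0.2, w_c=0.3)
        pwh = _lj_like(sigma=0.65, eps=np.sqrt(0.2), w_c=0.4)
        truth_params = {("w", "w"): pw, ("h", "h"): ph, ("w", "h"): pwh}
        tables = PairTables({k: v.table() for k, v in truth_params.items()})

    start = init_lattice(0, L, seed=seed, topology=topo)
    reference = mc_nvt(start, tables, state, n_steps=n_steps,
                       max_disp=max_disp, seed=seed + 1, stride=stride,
                       equilibration=equilibration, topology=topo)
    mapped = Trajectory([map_com(f, topo) for f in reference], L)

    if r_max is None:
        # snap to a bin multiple so the RDF edge grid ends exactly at r_max
        r_max = bin_width * int(min(2.4, 0.5 * L) / bin_width)
    bead_species = sorted({b for m, _ in topo.molecules
                           for b in m.bead_species})
    rdfs = {}
    for i, a in enumerate(bead_species):
        for b in bead_species[i:]:
            rdfs[(a, b)] = compute_rdf(mapped, (a, b), r_max, bin_width)
    return ReferenceFixture(kind=kind, topology=topo, state=state, L=L,
                            reference=reference, mapped=mapped, rdfs=rdfs,
                            truth_tables=tables, truth_params=truth_params,
                            cg_start=mapped[-1], seed=seed)
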