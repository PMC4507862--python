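"""NVT Metropolis Monte-Carlo sampling of tabulated pair potentials.

Desk-scale reference and CG ensembles are generated with a Metropolis
chain in a cubic periodic box: single-particle displacements for point
particles, rigid-body translations and rotations for small molecules.
The observables driving coarse-graining (RDFs, pressure, ensemble
averages of potential-parameter derivatives) are configurational, so a
Markov chain over configurations is sufficient — no integrator or
thermostat machinery is needed.  Any externally produced trajectory in
the XYZ dialect below is accepted on equal footing (``read_xyz``).

Interactions are pairwise additive and looked up from
:class:`~cgforge.potentials.PotentialTable` objects (linear
interpolation on the uniform grid); sites belonging to the same
molecule are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .potentials import PotentialTable

__all__ = [
    "Site", "MoleculeType", "Topology", "ThermodynamicState",
    "Frame", "Trajectory", "PairTables",
    "init_lattice", "total_energy", "mc_nvt", "virial_pressure",
    "write_xyz", "read_xyz",
]


@dataclass(frozen=True)
class Site:
    species: str
    mass: float

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("site mass must be positive")


@dataclass
class MoleculeType:
    """Rigid molecule template: sites, internal geometry, bead mapping.

    ``geometry`` holds site offsets from an arbitrary internal origin;
    bonded degrees of freedom are frozen (rigid body).  ``beads`` lists,
    for each CG bead, the local site indices mapped onto it (default:
    all sites collapse onto one bead named after the molecule).
    """

    name: str
    sites: list
    geometry: np.ndarray = None  # type: ignore[assignment]
    beads: list = None           # type: ignore[assignment]
    bead_species: list = None    # type: ignore[assignment]

    def __post_init__(self):
        if self.geometry is None:
            self.geometry = np.zeros((len(self.sites), 3))
        self.geometry = np.asarray(self.geometry, dtype=float)
        if self.geometry.shape != (len(self.sites), 3):
            raise ValueError("geometry shape must be (n_sites, 3)")
        if self.beads is None:
            self.beads = [list(range(len(self.sites)))]
        if self.bead_species is None:
            self.bead_species = [self.name] * len(self.beads)
        assigned = sorted(i for b in self.beads for i in b)
        if assigned != list(range(len(self.sites))):
            raise ValueError("every site must belong to exactly one bead")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class Topology:
    """Molecule types with counts; expands to flat per-site arrays."""

    molecules: list  # list of (MoleculeType, count)

    @classmethod
    def point_particles(cls, species_counts: dict, mass: float = 1.0):
        """Monatomic topology: one single-site molecule type per species."""
        mols = [(MoleculeType(sp, [Site(sp, mass)]), n)
                for sp, n in species_counts.items()]
        return cls(mols)

    def expand(self):
        """Flat arrays: site species, masses, molecule index, site groups."""
        species, masses, mol_of_site, groups = [], [], [], []
        mol = 0
        for mtype, count in self.molecules:
            for _ in range(count):
                start = len(species)
                for s in mtype.sites:
                    species.append(s.species)
                    masses.append(s.mass)
                    mol_of_site.append(mol)
                groups.append((mol, mtype, np.arange(start, len(species))))
                mol += 1
        return (np.array(species), np.array(masses, dtype=float),
                np.array(mol_of_site, dtype=np.intp), groups)

    @property
    def n_molecules(self) -> int:
        return sum(c for _, c in self.molecules)

    @property
    def n_sites(self) -> int:
        return sum(m.n_sites * c for m, c in self.molecules)

    @property
    def species_set(self):
        return sorted({s.species for m, _ in self.molecules for s in m.sites})


@dataclass
class ThermodynamicState:
    """Canonical-ensemble state: temperature and Boltzmann constant."""

    T: float
    k_B: float = 1.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return self.k_B * self.T

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


@dataclass
class Frame:
    """Periodic-box particle configuration with species labels."""

    positions: np.ndarray
    species: np.ndarray
    L: float
    step: int = 0
    index: int = 0

    def __post_init__(self):
        self.positions = np.mod(np.asarray(self.positions, dtype=float),
                                self.L)
        self.species = np.asarray(self.species)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return self.L ** 3

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.species.copy(), self.L,
                     self.step, self.index)


@dataclass
class Trajectory:
    """An ordered list of frames from one box, plus sampling diagnostics."""

    frames: list
    L: float
    acceptance_ratio: float = np.nan
    energies: np.ndarray = field(default_factory=lambda: np.array([]))
    max_bookkeeping_error: float = 0.0

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


class PairTables:
    """Species-pair keyed set of potential tables (unordered keys)."""

    def __init__(self, tables: dict):
        self._tables = {frozenset((a, b)) if a != b else frozenset((a,)): t
                        for (a, b), t in tables.items()}

    @classmethod
    def single(cls, table: PotentialTable, species: str = "A"):
        return cls({(species, species): table})

    def get(self, a: str, b: str) -> PotentialTable:
        key = frozenset((a, b)) if a != b else frozenset((a,))
        try:
            return self._tables[key]
        except KeyError:
            raise KeyError(f"no potential table for species pair "
                           f"({a}, {b})") from None

    def items(self):
        for key, t in self._tables.items():
            pair = tuple(sorted(key))
            yield (pair if len(pair) == 2 else (pair[0], pair[0])), t

    @property
    def max_cutoff(self) -> float:
        return max(t.r_cut for t in self._tables.values())


def minimum_image(delta: np.ndarray, L: float) -> np.ndarray:
    """Displacement vectors mapped to the nearest periodic image."""
    return delta - L * np.round(delta / L)


def init_lattice(N: int, L: float, species=None, seed: int = 0,
                 topology: Topology = None) -> Frame:
    """Deterministic non-overlapping start configuration on a cubic lattice.

    Point particles (or molecule internal origins) are placed on the
    smallest n^3 lattice holding N entries; species (or molecule
    identities) are assigned by a seeded shuffle so mixtures start well
    stirred.  For multi-site molecules the rigid template must fit
    within half a lattice spacing.
    """
    rng = np.random.default_rng(seed)
    if topology is not None:
        _, _, _, groups = topology.expand()
        N = topology.n_molecules
    n = int(np.ceil(N ** (1.0 / 3.0) - 1e-9))
    spacing = L / n
    cells = np.array([(i, j, k) for i in range(n) for j in range(n)
                      for k in range(n)], dtype=float)
    order = rng.permutation(len(cells))[:N]
    centers = (cells[order] + 0.5) * spacing

    if topology is None:
        if species is None:
            species = np.array(["A"] * N)
        species = np.asarray(species)
        perm = rng.permutation(N)
        return Frame(centers, species[perm], L)

    radius = max(np.linalg.norm(m.geometry, axis=1).max()
                 for m, _ in topology.molecules)
    if 2.0 * radius >= spacing:
        raise ValueError(
            f"molecule extent {2 * radius:.3g} exceeds lattice spacing "
            f"{spacing:.3g}: density too high for overlap-free placement")
    site_species, _, _, groups = topology.expand()
    positions = np.empty((topology.n_sites, 3))
    for (mol, mtype, idx), center in zip(groups, centers):
        rot = _random_rotation(rng)
        positions[idx] = center + mtype.geometry @ rot.T
    return Frame(positions, site_species, L)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (axis-angle, axis on the sphere)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    return _axis_angle(axis, angle)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


class _EnergyModel:
    """Pairwise energy/virial bookkeeping for one frame layout."""

    def __init__(self, frame: Frame, tables: PairTables, mol_of_site=None):
        self.L = frame.L
        self.tables = tables
        self.species = frame.species
        uniq = sorted(set(self.species.tolist()))
        self.codes = np.array([uniq.index(s) for s in self.species])
        self.by_species = {u: np.flatnonzero(self.species == u) for u in uniq}
        self.uniq = uniq
        self._table_of = {}
        self._grid_of = {}
        for a in uniq:          # fail fast if a pair table is missing
            for b in uniq:
                t = tables.get(a, b)
                self._table_of[(a, b)] = t
                # augmented lookup grid: linear repulsive continuation at
                # r = 0, exact zero at the cutoff, so one np.interp call
                # covers the whole axis
                inside = t.r < t.r_cut
                rg = np.concatenate([t.r[inside], [t.r_cut]])
                ug = np.concatenate([t.u[inside], [0.0]])
                fg = np.concatenate([t.f[inside], [0.0]])
                if rg[0] > 0.0:
                    rg = np.concatenate([[0.0], rg])
                    ug = np.concatenate([[t.u[0] + t.f[0] * t.r[0]], ug])
                    fg = np.concatenate([[t.f[0]], fg])
                self._grid_of[(a, b)] = (rg, ug, fg)
        if mol_of_site is None:
            mol_of_site = np.arange(len(self.species), dtype=np.intp)
        self.mol_of_site = mol_of_site
        # hot-path cache: for every molecule, the site indices of each
        # species belonging to *other* molecules
        n_mol = int(mol_of_site.max()) + 1 if len(mol_of_site) else 0
        self._others = []
        for mol in range(n_mol):
            outside = mol_of_site != mol
            self._others.append({b: np.flatnonzero(outside
                                                   & (self.species == b))
                                 for b in self.uniq})

    def site_energy(self, positions, sites) -> float:
        """Interaction energy of one molecule's sites with all others."""
        sites = np.atleast_1d(sites)
        others = self._others[self.mol_of_site[sites[0]]]
        L = self.L
        e = 0.0
        for s in sites:
            a = self.species[s]
            ps = positions[s]
            for b, idx in others.items():
                if len(idx) == 0:
                    continue
                d = positions[idx] - ps
                d -= L * np.round(d * (1.0 / L))
                r = np.sqrt(np.einsum("ij,ij->i", d, d))
                rg, ug, _ = self._grid_of[(a, b)]
                e += float(np.interp(r, rg, ug, right=0.0).sum())
        return e

    def total(self, positions) -> float:
        return self.total_and_virial(positions)[0]

    def total_and_virial(self, positions):
        """Sum of pair energies and the virial W = sum f(r)*r, i<j."""
        n = len(positions)
        e = 0.0
        w = 0.0
        ii, jj = np.triu_indices(n, k=1)
        same_mol = self.mol_of_site[ii] == self.mol_of_site[jj]
        ii, jj = ii[~same_mol], jj[~same_mol]
        d = minimum_image(positions[jj] - positions[ii], self.L)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        pa, pb = self.species[ii], self.species[jj]
        for (a, b), _ in self.tables.items():
            sel = ((pa == a) & (pb == b)) | ((pa == b) & (pb == a))
            if sel.any():
                rg, ug, fg = self._grid_of[(a, b)]
                rs = r[sel]
                e += float(np.interp(rs, rg, ug, right=0.0).sum())
                w += float((np.interp(rs, rg, fg, right=0.0) * rs).sum())
        return e, w


def total_energy(frame: Frame, tables: PairTables,
                 topology: Topology = None) -> float:
    """Total pairwise potential energy with minimum-image distances."""
    mol = topology.expand()[2] if topology is not None else None
    return _EnergyModel(frame, tables, mol).total(frame.positions)


def mc_nvt(start: Frame, tables: PairTables, state: ThermodynamicState,
           n_steps: int, max_disp: float, seed: int,
           stride: int = 100, equilibration: float = 0.25,
           topology: Topology = None, max_rot: float = 0.5,
           check_every: int = 1000) -> Trajectory:
    """Metropolis NVT chain; returns recorded frames and diagnostics.

    Moves are single-particle displacements (uniform in a cube of half
    width ``max_disp``); molecules with more than one site get rigid
    translations and rotations (uniform axis, angle ~ U(-max_rot,
    max_rot)) in alternation.  The first ``equilibration`` fraction of
    the chain is discarded, then every ``stride``-th configuration is
    recorded.  Fully reproducible from ``seed``.

    Incremental energy bookkeeping is validated against a full
    recomputation every ``check_every`` accepted moves; the largest
    deviation is reported on the returned trajectory.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    if topology is not None:
        _, _, mol_of_site, groups = topology.expand()
        group_idx = [g[2] for g in groups]
    else:
        mol_of_site = np.arange(start.n, dtype=np.intp)
        group_idx = [np.array([i]) for i in range(start.n)]
    model = _EnergyModel(start, tables, mol_of_site)
    pos = start.positions.copy()
    beta = state.beta
    energy = model.total(pos)

    n_equil = int(equilibration * n_steps)
    frames = []
    energies = []
    accepted = 0
    max_err = 0.0
    n_groups = len(group_idx)

    # one block of random draws per chain keeps the per-move overhead low
    g_draw = rng.integers(n_groups, size=n_steps)
    disp_draw = rng.uniform(-max_disp, max_disp, size=(n_steps, 3))
    acc_draw = rng.random(n_steps)
    rot_draw = rng.random(n_steps)

    for step in range(n_steps):
        idx = group_idx[g_draw[step]]
        old = pos[idx].copy()
        rotate = len(idx) > 1 and rot_draw[step] < 0.5
        if rotate:
            # rotate on unwrapped coordinates: wrapped sites of a
            # boundary-straddling molecule have no meaningful centroid
            old = old[0] + minimum_image(old - old[0], start.L)
            com = old.mean(axis=0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-max_rot, max_rot)
            new = com + (old - com) @ _axis_angle(axis, angle).T
        else:
            new = old + disp_draw[step]
        e_old = model.site_energy(pos, idx)
        pos[idx] = np.mod(new, start.L)
        e_new = model.site_energy(pos, idx)
        dU = e_new - e_old
        if dU <= 0.0 or acc_draw[step] < np.exp(-beta * dU):
            energy += dU
            accepted += 1
            if check_every and accepted % check_every == 0:
                ref = model.total(pos)
                max_err = max(max_err, abs(energy - ref))
                energy = ref
        else:
            pos[idx] = np.mod(old, start.L)
        if step >= n_equil and (step - n_equil) % stride == 0:
            frames.append(Frame(pos.copy(), start.species.copy(), start.L,
                                step=step, index=len(frames)))
            energies.append(energy)

    ratio = accepted / n_steps
    if ratio == 0.0:
        warnings.warn("zero acceptance over the whole run: pathological "
                      "start configuration or max_disp", stacklevel=2)
    return Trajectory(frames, start.L, acceptance_ratio=ratio,
                      energies=np.array(energies),
                      max_bookkeeping_error=max_err)


def virial_pressure(traj: Trajectory, tables: PairTables,
                    state: ThermodynamicState,
                    topology: Topology = None) -> float:
    """Virial pressure P = rho kT + <sum_{i<j} f(r_ij) r_ij> / (3V).

    The density entering the ideal term counts independently moving
    units (molecules when a topology is given, sites otherwise).  No
    tail correction is applied: tabulated potentials vanish at their
    cutoff by construction.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    mol = topology.expand()[2] if topology is not None else None
    model = _EnergyModel(traj[0], tables, mol)
    w_sum = 0.0
    for frame in traj:
        _, w = model.total_and_virial(frame.positions)
        w_sum += w
    V = traj[0].volume
    n_units = (topology.n_molecules if topology is not None else traj[0].n)
    rho = n_units / V
    return rho * state.kT + w_sum / len(traj) / (3.0 * V)


# ---------------------------------------------------------------------------
# XYZ-dialect trajectory I/O

def write_xyz(traj, path) -> None:
    """Write frames in the XYZ dialect (comment line carries box and step)."""
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{frame.n}\n")
            fh.write(f"box={frame.L!r} step={frame.step}\n")
            for sp, (x, y, z) in zip(frame.species, frame.positions):
                fh.write(f"{sp} {x:.17e} {y:.17e} {z:.17e}\n")


def read_xyz(path) -> Trajectory:
    """Read an XYZ-dialect trajectory; tolerates a missing step stamp."""
    frames = []
    L = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        meta = dict(tok.split("=", 1) for tok in lines[i + 1].split()
                    if "=" in tok)
        L = float(meta["box"])
        step = int(meta.get("step", len(frames)))
        species, positions = [], []
        for row in lines[i + 2:i + 2 + n]:
            parts = row.split()
            species.append(parts[0])
            positions.append([float(x) for x in parts[1:4]])
        frames.append(Frame(np.array(positions), np.array(species), L,
                            step=step, index=len(frames)))
        i += 2 + n
    return Trajectory(frames, L)
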