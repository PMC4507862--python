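"""Unit tests for the NVT Monte-Carlo sampler and its observables."""

import numpy as np
import pytest
from scipy import stats

from cgforge.potentials import PotentialTable
from cgforge.sampler import (Frame, MoleculeType, PairTables, Site,
                             ThermodynamicState, Topology, init_lattice,
                             mc_nvt, read_xyz, total_energy, virial_pressure,
                             write_xyz)


def flat_table(u0=0.0, r_cut=1.0, n=50):
    r = np.linspace(0.01, r_cut, n)
    return PotentialTable(r, np.full(n, float(u0)), np.zeros(n), r_cut=r_cut)


def linear_table(r_cut=1.0, slope=-2.0, n=201):
    """u(r) = slope*(r - r_cut): linear ramp hitting zero at the cutoff."""
    r = np.linspace(0.0, r_cut, n)
    return PotentialTable(r, slope * (r - r_cut), np.full(n, slope),
                          r_cut=r_cut)


class TestInitLattice:
    def test_eight_particles_form_cubic_lattice(self):
        frame = init_lattice(8, 4.0, species=np.array(["A"] * 8), seed=0)
        d = frame.positions[None] - frame.positions[:, None]
        d -= 4.0 * np.round(d / 4.0)
        r = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() == pytest.approx(2.0)  # L/2 for a 2x2x2 lattice

    def test_deterministic_from_seed(self):
        a = init_lattice(20, 5.0, species=np.array(["A"] * 20), seed=7)
        b = init_lattice(20, 5.0, species=np.array(["A"] * 20), seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.species, b.species)

    def test_overcrowded_molecules_rejected(self):
        geom = np.array([[-1.5, 0, 0], [1.5, 0, 0]])
        mt = MoleculeType("D", [Site("d", 1.0), Site("d", 1.0)],
                          geometry=geom)
        with pytest.raises(ValueError, match="density"):
            init_lattice(0, 4.0, seed=0, topology=Topology([(mt, 27)]))


class TestTotalEnergy:
    def test_two_particles(self):
        tab = linear_table()
        frame = Frame(np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]),
                      np.array(["A", "A"]), 10.0)
        u = total_energy(frame, PairTables.single(tab, "A"))
        assert u == pytest.approx(-2.0 * (0.5 - 1.0))

    def test_three_collinear_particles(self):
        # spacings r, r, 2r with 2r beyond cutoff -> exactly 2 u(r)
        tab = linear_table(r_cut=1.0)
        r = 0.6
        frame = Frame(np.array([[1.0, 1, 1], [1.0 + r, 1, 1],
                                [1.0 + 2 * r, 1, 1]]),
                      np.array(["A"] * 3), 20.0)
        u = total_energy(frame, PairTables.single(tab, "A"))
        assert u == pytest.approx(2 * (-2.0) * (r - 1.0))

    def test_all_beyond_cutoff(self):
        tab = linear_table(r_cut=1.0)
        frame = Frame(np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0]],
                               dtype=float), np.array(["A"] * 3), 20.0)
        assert total_energy(frame, PairTables.single(tab, "A")) == 0.0

    def test_missing_pair_table_rejected(self):
        frame = Frame(np.array([[0, 0, 0], [1, 0, 0]], dtype=float),
                      np.array(["A", "B"]), 10.0)
        tables = PairTables({("A", "A"): linear_table(),
                             ("B", "B"): linear_table()})
        with pytest.raises(KeyError, match="A.*B|B.*A"):
            total_energy(frame, tables)


class TestMCNVT:
    def test_ideal_gas_accepts_everything(self):
        start = init_lattice(27, 3.0, species=np.array(["A"] * 27), seed=0)
        traj = mc_nvt(start, PairTables.single(flat_table(), "A"),
                      ThermodynamicState(T=1.0), n_steps=3000, max_disp=0.5,
                      seed=1)
        assert traj.acceptance_ratio == 1.0

    def test_ideal_gas_rdf_flat(self):
        from cgforge.mapping_analysis import compute_rdf
        start = init_lattice(64, 4.0, species=np.array(["A"] * 64), seed=0)
        traj = mc_nvt(start, PairTables.single(flat_table(), "A"),
                      ThermodynamicState(T=1.0), n_steps=30_000,
                      max_disp=1.0, seed=2, stride=50)
        g = compute_rdf(traj, ("A", "A"), 2.0, 0.2)
        # Poisson error model per bin: sigma_g = g / sqrt(counts)
        counts = (g.frames * g.g * 64 * 63 / 2 / 4.0 ** 3
                  * 4 * np.pi / 3 * (g.edges[1:] ** 3 - g.edges[:-1] ** 3))
        sigma = 1.0 / np.sqrt(np.maximum(counts, 1.0))
        assert np.all(np.abs(g.g[1:] - 1.0) < 5 * sigma[1:])

    def test_two_particle_distance_distribution(self):
        """Sampled pair distance against the Boltzmann marginal
        p(r) ∝ 4 pi r^2 exp(-beta u(r)) by 1D quadrature (KS check)."""
        L = 3.0
        tab = linear_table(r_cut=1.4, slope=-3.0)
        start = Frame(np.array([[0.1, 0.1, 0.1], [1.0, 0.1, 0.1]]),
                      np.array(["A", "A"]), L)
        state = ThermodynamicState(T=1.0)
        traj = mc_nvt(start, PairTables.single(tab, "A"), state,
                      n_steps=200_000, max_disp=1.2, seed=3, stride=2,
                      equilibration=0.05)
        d = np.array([f.positions[1] - f.positions[0] for f in traj])
        d -= L * np.round(d / L)
        r = np.sqrt((d ** 2).sum(1))
        r = r[r < L / 2]     # compare on the isotropic shell region

        grid = np.linspace(1e-3, L / 2, 2000)
        u = np.interp(grid, tab.r, tab.u, right=0.0)
        w = grid ** 2 * np.exp(-u)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]

        ks = stats.ks_1samp(r, lambda x: np.interp(x, grid, cdf))
        assert ks.statistic < 0.05

    def test_detailed_balance_two_wells(self):
        """Occupation ratio of two flat distance wells matches the
        Boltzmann/entropy ratio from quadrature within 3 sigma."""
        L = 3.0
        r = np.linspace(0.0, 1.4, 400)
        u = np.where(r < 0.7, 0.0, -1.0)     # outer well deeper by 1 kT
        u[r >= 1.39] = 0.0
        tab = PotentialTable(r, u, np.zeros_like(r), r_cut=1.4)
        start = Frame(np.array([[0.1, 0.1, 0.1], [0.5, 0.1, 0.1]]),
                      np.array(["A", "A"]), L)
        traj = mc_nvt(start, PairTables.single(tab, "A"),
                      ThermodynamicState(T=1.0), n_steps=150_000,
                      max_disp=1.0, seed=4, stride=4, equilibration=0.1)
        d = np.array([f.positions[1] - f.positions[0] for f in traj])
        d -= L * np.round(d / L)
        rs = np.sqrt((d ** 2).sum(1))
        lo, hi = 0.65, 1.35
        n1 = int(((rs > 0.1) & (rs < lo)).sum())
        n2 = int(((rs > lo) & (rs < hi)).sum())

        grid = np.linspace(1e-3, L / 2, 4000)
        ug = np.interp(grid, r, u, right=0.0)
        w = grid ** 2 * np.exp(-ug)
        z1 = np.trapezoid(w[(grid > 0.1) & (grid < lo)],
                          grid[(grid > 0.1) & (grid < lo)])
        z2 = np.trapezoid(w[(grid > lo) & (grid < hi)],
                          grid[(grid > lo) & (grid < hi)])
        expected = z2 / z1
        ratio = n2 / max(n1, 1)
        # crude binomial error on the ratio, inflated for correlation
        sigma = ratio * np.sqrt(1 / max(n1, 1) + 1 / max(n2, 1)) * 3
        assert abs(ratio - expected) < 3 * sigma + 0.05 * expected

    def test_energy_bookkeeping(self, lj_system):
        traj = mc_nvt(lj_system["start"], lj_system["tables"],
                      lj_system["state"], n_steps=20_000, max_disp=0.35,
                      seed=5, check_every=1000)
        assert traj.max_bookkeeping_error < 1e-8

    def test_same_seed_bit_identical_trajectory_file(self, tmp_path,
                                                     lj_system):
        paths = []
        for name in ("a.xyz", "b.xyz"):
            traj = mc_nvt(lj_system["start"], lj_system["tables"],
                          lj_system["state"], n_steps=5000, max_disp=0.35,
                          seed=6, stride=100)
            path = tmp_path / name
            write_xyz(traj, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_zero_acceptance_warns(self):
        # an enormous displacement from a deep minimum in a steep well
        r = np.linspace(0.01, 1.0, 100)
        u = 1e6 * (r - 0.5) ** 2 - 1e5
        tab = PotentialTable(r, u, r_cut=1.0)
        start = Frame(np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
                      np.array(["A", "A"]), 40.0)
        with pytest.warns(UserWarning, match="zero acceptance"):
            mc_nvt(start, PairTables.single(tab, "A"),
                   ThermodynamicState(T=1e-6), n_steps=200, max_disp=20.0,
                   seed=7)


class TestRigidMolecules:
    def test_bond_lengths_preserved(self):
        geom = np.array([[-0.25, 0.0, 0.0], [0.25, 0.0, 0.0]])
        mt = MoleculeType("D", [Site("d", 1.0), Site("d", 1.0)],
                          geometry=geom)
        topo = Topology([(mt, 8)])
        start = init_lattice(0, 6.0, seed=1, topology=topo)
        tab = linear_table(r_cut=1.0)
        traj = mc_nvt(start, PairTables.single(tab, "d"),
                      ThermodynamicState(T=1.0), n_steps=5000, max_disp=0.3,
                      seed=8, stride=200, topology=topo)
        for frame in traj:
            for m in range(8):
                d = frame.positions[2 * m + 1] - frame.positions[2 * m]
                d -= 6.0 * np.round(d / 6.0)
                assert np.linalg.norm(d) == pytest.approx(0.5, abs=1e-9)


class TestVirialPressure:
    def test_ideal_gas_exact(self):
        start = init_lattice(27, 3.0, species=np.array(["A"] * 27), seed=0)
        state = ThermodynamicState(T=1.3)
        traj = mc_nvt(start, PairTables.single(flat_table(), "A"), state,
                      n_steps=2000, max_disp=0.5, seed=9, stride=100)
        p = virial_pressure(traj, PairTables.single(flat_table(), "A"),
                            state)
        assert p == pytest.approx(27 / 27.0 * 1.3)

    def test_single_pair_hand_computed(self):
        # linear u => constant force 'slope'; W = f(r) * r
        tab = linear_table(r_cut=1.0, slope=-2.0)
        L = 10.0
        r12 = 0.5
        frame = Frame(np.array([[1, 1, 1], [1 + r12, 1, 1]], dtype=float),
                      np.array(["A", "A"]), L)
        from cgforge.sampler import Trajectory
        traj = Trajectory([frame], L)
        state = ThermodynamicState(T=2.0)
        p = virial_pressure(traj, PairTables.single(tab, "A"), state)
        expected = 2 / L ** 3 * 2.0 + (-2.0 * r12) / (3 * L ** 3)
        assert p == pytest.approx(expected)

    def test_repulsive_fluid_exceeds_ideal(self, lj_system):
        # purely repulsive table: WCA-like branch of the LJ truth
        r = np.linspace(0.01, 1.12, 300)
        u = 4 * ((1 / r) ** 12 - (1 / r) ** 6 + 0.25)
        tab = PotentialTable(r, u, r_cut=1.12)
        tables = PairTables.single(tab, "A")
        state = lj_system["state"]
        traj = mc_nvt(lj_system["start"], tables, state, n_steps=20_000,
                      max_disp=0.35, seed=10, stride=200)
        p = virial_pressure(traj, tables, state)
        assert p > lj_system["rho"] * state.kT

    def test_empty_trajectory_rejected(self):
        from cgforge.sampler import Trajectory
        with pytest.raises(ValueError):
            virial_pressure(Trajectory([], 5.0),
                            PairTables.single(flat_table(), "A"),
                            ThermodynamicState(T=1.0))


class TestXYZ:
    def test_round_trip(self, tmp_path, lj_system):
        traj = mc_nvt(lj_system["start"], lj_system["tables"],
                      lj_system["state"], n_steps=3000, max_disp=0.35,
                      seed=11, stride=150)
        path = tmp_path / "t.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert len(back) == len(traj)
        for a, b in zip(traj, back):
            assert np.array_equal(a.positions, b.positions)
            assert np.array_equal(a.species, b.species)
            assert a.step == b.step

    def test_missing_step_tolerated(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("2\nbox=5.0\nA 1.0 1.0 1.0\nB 2.0 2.0 2.0\n")
        traj = read_xyz(path)
        assert traj[0].n == 2
        assert list(traj[0].species) == ["A", "B"]
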