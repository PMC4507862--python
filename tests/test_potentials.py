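"""Unit tests for the CBSPL and CKDg pair-potential families."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import BSpline

from cgforge.potentials import (CKDgParams, PotentialTable,
                                boltzmann_invert, cbspl_basis_weights,
                                cbspl_evaluate, cbspl_force, cbspl_knot_grid,
                                ckdg_evaluate, ckdg_force, export_table,
                                fit_cbspl, read_table)


def random_pot(seed, r_cut=1.0, dr=0.1):
    rng = np.random.default_rng(seed)
    pot = cbspl_knot_grid(r_cut, dr)
    return pot.with_knots(rng.normal(size=len(pot.knots)))


class TestKnotGrid:
    @pytest.mark.parametrize("r_cut,dr,expected", [
        (0.9, 0.02, 48),      # single-bead water potential layout
        (1.0, 0.01, 103),     # mixture water-water layout
        (1.32, 0.02, 69),     # mixture cross/methanol layout
        (1.0, 0.5, 5),
    ])
    def test_knot_count(self, r_cut, dr, expected):
        pot = cbspl_knot_grid(r_cut, dr)
        assert len(pot.knots) == expected
        # grid extends exactly two intervals beyond the cutoff
        assert pot.positions[-1] == pytest.approx(r_cut + 2 * dr)
        assert np.allclose(np.diff(pot.positions), dr)

    def test_non_integral_ratio_rejected(self):
        with pytest.raises(ValueError, match="0.9.*0.25|0.25.*0.9"):
            cbspl_knot_grid(0.9, 0.25)

    def test_trivial_grid_positions(self):
        pot = cbspl_knot_grid(1.0, 0.5)
        assert np.allclose(pot.positions, [0, 0.5, 1.0, 1.5, 2.0])


class TestEvaluate:
    def test_partition_of_unity_constant_knots(self, rng):
        pot = cbspl_knot_grid(1.0, 0.25)
        pot = pot.with_knots(np.full(len(pot.knots), 3.7))
        r = rng.uniform(0, 1.0, 1000)
        assert np.allclose(cbspl_evaluate(pot, r), 3.7, atol=1e-12)

    def test_segment_start_blend(self):
        # at t=0 the blend is (c_k + 4 c_{k+1} + c_{k+2}) / 6
        pot = cbspl_knot_grid(1.0, 0.5).with_knots([0, 6, 0, 0, 0])
        assert cbspl_evaluate(pot, 0.0) == pytest.approx(4.0)

    def test_segment_end_blend(self):
        pot = cbspl_knot_grid(1.0, 0.5).with_knots([0, 0, 6, 0, 0])
        assert cbspl_evaluate(pot, 0.5 - 1e-12) == pytest.approx(4.0, abs=1e-9)

    def test_zero_beyond_cutoff_and_negative_rejected(self):
        pot = random_pot(0)
        assert cbspl_evaluate(pot, 1.0) == 0.0
        assert cbspl_evaluate(pot, 5.0) == 0.0
        with pytest.raises(ValueError):
            cbspl_evaluate(pot, -0.1)

    def test_linearity_in_knots(self, rng):
        a, b = random_pot(1), random_pot(2)
        mix = a.with_knots(0.3 * a.knots + 1.7 * b.knots)
        r = rng.uniform(0, 1.0, 200)
        assert np.allclose(cbspl_evaluate(mix, r),
                           0.3 * cbspl_evaluate(a, r)
                           + 1.7 * cbspl_evaluate(b, r))

    def test_matches_scipy_bspline(self, rng):
        """Independent oracle: scipy's BSpline with the shifted uniform
        knot vector reproduces the blend-matrix evaluation."""
        pot = random_pot(3)
        t = pot.dr * (np.arange(pot.m + 5) - 3)
        oracle = BSpline(t, pot.knots, 3, extrapolate=False)
        r = rng.uniform(0, 0.999, 500)
        assert np.allclose(cbspl_evaluate(pot, r), oracle(r), atol=1e-12)


class TestBasisWeights:
    def test_segment_start(self):
        pot = cbspl_knot_grid(1.0, 0.5)
        w, k = cbspl_basis_weights(pot, 0.0)
        assert k == 0
        assert np.allclose(w, [1 / 6, 2 / 3, 1 / 6, 0])

    def test_midpoint(self):
        pot = cbspl_knot_grid(1.0, 0.5)
        w, _ = cbspl_basis_weights(pot, 0.25)
        assert np.allclose(6 * w, [0.125, 2.875, 2.875, 0.125])

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity(self, r):
        pot = cbspl_knot_grid(1.0, 0.1)
        w, _ = cbspl_basis_weights(pot, r)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_weights_are_parameter_derivatives(self):
        pot = random_pot(4)
        r = 0.37
        w, k = cbspl_basis_weights(pot, r)
        eps = 1e-7
        for j in range(4):
            bumped = pot.knots.copy()
            bumped[k + j] += eps
            fd = (cbspl_evaluate(pot.with_knots(bumped), r)
                  - cbspl_evaluate(pot, r)) / eps
            assert fd == pytest.approx(w[j], abs=1e-6)


class TestForce:
    def test_constant_knots_zero_force(self, rng):
        pot = cbspl_knot_grid(1.0, 0.2)
        pot = pot.with_knots(np.full(len(pot.knots), 2.0))
        r = rng.uniform(0, 1.0, 100)
        assert np.allclose(cbspl_force(pot, r), 0.0, atol=1e-12)

    def test_matches_finite_difference(self):
        pot = random_pot(5)
        r = np.linspace(0.01, 0.98, 200)
        h = 1e-6
        fd = -(cbspl_evaluate(pot, r + h) - cbspl_evaluate(pot, r - h)) / (2 * h)
        scale = np.maximum(np.abs(fd), 1.0)
        assert np.all(np.abs(cbspl_force(pot, r) - fd) / scale < 1e-6)

    def test_continuity_at_interior_knots(self):
        pot = random_pot(6)
        for rk in pot.positions[1:9]:
            left = cbspl_force(pot, rk - 1e-11)
            right = cbspl_force(pot, rk + 1e-11)
            assert left == pytest.approx(right, rel=1e-7, abs=1e-9)


class TestTailConstraint:
    def test_vanishes_smoothly_at_cutoff(self, rng):
        pot = cbspl_knot_grid(1.0, 0.1)
        knots = rng.normal(size=len(pot.knots))
        knots[pot.frozen] = 0.0     # core has r_min=0 -> only tail frozen
        pot = pot.with_knots(knots)
        assert abs(cbspl_evaluate(pot, 1.0 - 1e-9)) < 1e-10
        assert abs(cbspl_force(pot, 1.0 - 1e-9)) < 1e-10

    def test_frozen_mask_covers_tail_and_core(self):
        pot = cbspl_knot_grid(1.0, 0.1, r_min=0.25)
        frozen_r = pot.positions[pot.frozen]
        assert set(np.round(frozen_r, 10)) == {0.0, 0.1, 0.2, 0.9, 1.0,
                                               1.1, 1.2}


class TestCKDg:
    def test_zero_beyond_well(self):
        p = CKDgParams(sigma=1.0, eps=2.0, w_c=0.4, h=0.0, p=1.2, s=0.2)
        r = p.r_c_lj + p.w_c + 1e-9
        assert ckdg_evaluate(p, r) == pytest.approx(0.0, abs=1e-12)
        assert ckdg_evaluate(p, 10.0) == 0.0

    def test_half_depth_at_well_midpoint(self):
        p = CKDgParams(sigma=1.0, eps=2.0, w_c=0.4, h=0.0, p=1.2, s=0.2)
        r = p.r_c_lj + p.w_c / 2
        assert ckdg_evaluate(p, r) == pytest.approx(-1.0)  # cos^2(pi/4) = 1/2

    def test_continuous_at_lj_cutoff_by_default(self):
        p = CKDgParams(sigma=1.0, eps=1.5, w_c=0.5, h=0.0, p=1.3, s=0.2)
        lo = ckdg_evaluate(p, p.r_c_lj - 1e-9)
        hi = ckdg_evaluate(p, p.r_c_lj + 1e-9)
        assert lo == pytest.approx(-1.5, abs=1e-6)
        assert hi == pytest.approx(-1.5, abs=1e-6)

    def test_as_printed_mode_has_eps_jump(self):
        p = CKDgParams(sigma=1.0, eps=1.5, w_c=0.5, h=0.0, p=1.3, s=0.2,
                       as_printed=True)
        lo = ckdg_evaluate(p, p.r_c_lj - 1e-9)
        hi = ckdg_evaluate(p, p.r_c_lj + 1e-9)
        assert lo - hi == pytest.approx(1.5, abs=1e-6)

    def test_eps_tiny_reduces_to_shifted_gaussian(self):
        g = dict(h=0.8, p=1.1, s=0.25)
        p = CKDgParams(sigma=1.0, eps=1e-14, w_c=0.5, **g, r_c=2.0)
        r = np.linspace(0.9, 1.9, 50)
        expected = (g["h"] * np.exp(-((r - g["p"]) ** 2) / (2 * g["s"] ** 2))
                    - g["h"] * np.exp(-((2.0 - g["p"]) ** 2)
                                      / (2 * g["s"] ** 2)))
        assert np.allclose(ckdg_evaluate(p, r), expected, atol=1e-12)

    def test_gaussian_clamped_beyond_cutoff(self):
        p = CKDgParams(sigma=1.0, eps=1.0, w_c=0.3, h=2.0, p=1.4, s=0.5,
                       r_c=1.5)
        assert ckdg_evaluate(p, 1.6) == 0.0

    def test_force_matches_finite_difference(self):
        p = CKDgParams(sigma=1.0, eps=1.2, w_c=0.5, h=0.4, p=1.3, s=0.2)
        # avoid the (finite-range) kinks at branch boundaries
        r = np.concatenate([np.linspace(0.85, p.r_c_lj - 0.01, 40),
                            np.linspace(p.r_c_lj + 0.01,
                                        p.r_c_lj + p.w_c - 0.01, 40)])
        h = 1e-7
        fd = -(ckdg_evaluate(p, r + h) - ckdg_evaluate(p, r - h)) / (2 * h)
        assert np.allclose(ckdg_force(p, r), fd, rtol=1e-5, atol=1e-5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CKDgParams(sigma=-1.0, eps=1.0, w_c=0.5, h=0.0, p=1.3, s=0.2)
        with pytest.raises(ValueError):
            CKDgParams(sigma=1.0, eps=1.0, w_c=0.5, h=0.0, p=1.3, s=0.2,
                       r_c=1.0)  # r_c < r_c_lj + w_c
        with pytest.raises(ValueError):
            ckdg_evaluate(CKDgParams(1.0, 1.0, 0.5, 0.0, 1.3, 0.2), -1.0)


class TestBoltzmannInversion:
    def test_flat_rdf_gives_zero_potential(self):
        r = np.linspace(0.1, 2.0, 50)
        table = boltzmann_invert(r, np.ones_like(r), kT=1.7)
        assert np.allclose(table.u, 0.0)

    def test_single_bin_value(self):
        table = boltzmann_invert(np.array([1.0]), np.array([np.exp(-1.0)]),
                                 kT=1.0)
        assert table.u[0] == pytest.approx(1.0)

    def test_round_trip(self, rng):
        r = np.linspace(0.5, 2.0, 80)
        g = rng.uniform(0.2, 3.0, size=80)
        table = boltzmann_invert(r, g, kT=0.8)
        assert np.allclose(np.exp(-table.u / 0.8), g, atol=1e-12)

    def test_floor_marks_undefined(self):
        r = np.array([0.1, 0.2, 0.3])
        table = boltzmann_invert(r, np.array([0.0, 1e-12, 1.0]), kT=1.0)
        assert list(table.defined) == [False, False, True]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_invert(np.array([]), np.array([]))


class TestFitCBSPL:
    def test_exact_recovery_of_own_span(self):
        truth = random_pot(7)
        knots = truth.knots.copy()
        knots[truth.frozen] = 0.0
        truth = truth.with_knots(knots)
        r = np.linspace(0.0, 0.999, 400)
        target = PotentialTable(r, cbspl_evaluate(truth, r))
        fitted = fit_cbspl(target, cbspl_knot_grid(1.0, 0.1))
        assert np.allclose(fitted.knots, truth.knots, atol=1e-8)

    def test_constant_target_without_tail_constraint(self):
        r = np.linspace(0.0, 0.999, 200)
        target = PotentialTable(r, np.full_like(r, 2.5))
        fitted = fit_cbspl(target, cbspl_knot_grid(1.0, 0.25), fix_tail=False)
        assert np.allclose(fitted.knots, 2.5, atol=1e-8)

    def test_residual_decreases_with_refinement(self):
        r = np.linspace(0.0, 0.999, 500)
        u = np.cos(3 * r) * np.exp(-r)
        target = PotentialTable(r, u)

        def residual(dr):
            fitted = fit_cbspl(target, cbspl_knot_grid(1.0, dr),
                               fix_tail=False)
            return np.sum((cbspl_evaluate(fitted, r) - u) ** 2)

        assert residual(0.125) <= residual(0.25) + 1e-12

    def test_underdetermined_rejected(self):
        r = np.linspace(0.0, 0.9, 5)
        target = PotentialTable(r, np.zeros(5))
        with pytest.raises(ValueError, match="5"):
            fit_cbspl(target, cbspl_knot_grid(1.0, 0.1))


class TestTableIO:
    def test_round_trip_exact(self, tmp_path, rng):
        r = np.linspace(0.05, 1.5, 100)
        u = rng.normal(size=100)
        f = rng.normal(size=100)
        table = PotentialTable(r, u, f, pair=("A", "B"), r_cut=1.5)
        path = tmp_path / "pot.dat"
        export_table(table, path)
        back = read_table(path)
        assert np.array_equal(back.r, table.r)
        assert np.array_equal(back.u, table.u)
        assert np.array_equal(back.f, table.f)
        assert back.pair == ("A", "B")

    def test_export_is_bit_stable(self, tmp_path):
        p = CKDgParams(sigma=1.0, eps=1.0, w_c=0.5, h=0.2, p=1.3, s=0.2)
        paths = [tmp_path / "a.dat", tmp_path / "b.dat"]
        for path in paths:
            export_table(p.table(200), path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_force_column_consistent_with_energy(self):
        pot = random_pot(8)
        table = pot.table(800)
        du = np.gradient(table.u, table.r)
        interior = slice(5, -5)
        assert np.allclose(table.f[interior], -du[interior], atol=2e-3)

    def test_zero_beyond_cutoff_rows(self, tmp_path):
        pot = random_pot(9)
        r = np.linspace(0.0, pot.r_cut + 2 * pot.dr, 150)
        table = PotentialTable(r, cbspl_evaluate(pot, r),
                               cbspl_force(pot, r), r_cut=pot.r_cut)
        path = tmp_path / "pot.dat"
        export_table(table, path)
        back = read_table(path)
        beyond = back.r >= pot.r_cut
        assert beyond.any()
        assert np.all(back.u[beyond] == 0.0)
        assert np.all(back.f[beyond] == 0.0)
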