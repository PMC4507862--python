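"""Model/Results layer over the two coarse-graining optimizers.

``RelativeEntropyCG`` and ``TargetedCG`` wrap the procedural machinery
in fit-style model objects: a model is constructed from reference data
(a mapped trajectory and/or reference RDFs plus a thermodynamic state),
``fit()`` runs the optimization, and the returned Results object
carries the estimates, uncertainty proxies, diagnostics and a
``summary()`` table.  Everything they do is also reachable through the
underlying modules; this layer is the convenient front door.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import ReferenceFixture
from .mapping_analysis import RDF, compute_rdf
from .potentials import CKDgParams, cbspl_knot_grid
from .relative_entropy import (PotentialSet, REReport, estimate_r_min,
                               initial_guess_from_rdf, re_minimize)
from .sampler import Frame, ThermodynamicState, Trajectory, mc_nvt
from .simplex_opt import (PenaltySpec, SimplexReport, make_ckdg_evaluator,
                          simplex_minimize)

__all__ = ["RelativeEntropyCG", "RelativeEntropyResults",
           "TargetedCG", "TargetedCGResults"]


def _fmt_row(*cols, widths=(22, 14, 14, 14)):
    return "".join(str(c).rjust(w) for c, w in zip(cols, widths))


class RelativeEntropyCG:
    """Relative-entropy CG model: CBSPL pair potentials fitted to a
    mapped reference ensemble by Newton–Raphson S_rel minimization.

    Parameters
    ----------
    reference : Trajectory
        CG-mapped reference configurations (the "all-atom" ensemble
        after mapping).
    state : ThermodynamicState
        Temperature and Boltzmann constant of the reference ensemble.
    r_cut, dr : float
        Spline cutoff and knot spacing shared by all pair potentials.
    rdfs : dict, optional
        Reference RDFs per species pair; computed from the reference
        trajectory when omitted.  They supply the PMF initial guess and
        the default core radius r_min (first nonzero bin).
    """

    def __init__(self, reference: Trajectory, state: ThermodynamicState,
                 r_cut: float, dr: float, rdfs: dict = None,
                 r_min: dict = None, bin_width: float = 0.05,
                 start: Frame = None):
        self.reference = reference
        self.state = state
        self.r_cut = r_cut
        self.dr = dr
        species = sorted(set(reference[0].species.tolist()))
        self.pairs = [(a, b) for i, a in enumerate(species)
                      for b in species[i:]]
        if rdfs is None:
            r_max = min(r_cut + 2 * dr, 0.5 * reference[0].L)
            rdfs = {p: compute_rdf(reference, p, r_max, bin_width)
                    for p in self.pairs}
        self.rdfs = {tuple(sorted(k)): v for k, v in rdfs.items()}
        self.bin_width = bin_width
        self.r_min = r_min or {}
        self.start = start if start is not None else reference[-1]

    @classmethod
    def from_fixture(cls, fixture: ReferenceFixture, r_cut: float,
                     dr: float, **kwargs) -> "RelativeEntropyCG":
        return cls(fixture.mapped, fixture.state, r_cut, dr,
                   rdfs=fixture.rdfs, start=fixture.cg_start, **kwargs)

    def initial_potentials(self) -> PotentialSet:
        # the PMF fit wants finer bins than the comparison RDFs so the
        # least-squares system over the free knots is well determined
        w = self.bin_width
        r_max = w * int(min(self.r_cut + 2 * self.dr,
                            0.5 * self.reference[0].L) / w)
        pots = {}
        for pair in self.pairs:
            key = tuple(sorted(pair))
            fine = compute_rdf(self.reference, key, r_max, w)
            # r_min from the *fine* histogram: a coarse bin would round
            # the onset of sampling upward, anchoring the core
            # extrapolation in the shallow region near the PMF zero
            rmin = self.r_min.get(key, estimate_r_min(fine))
            skel = cbspl_knot_grid(self.r_cut, self.dr, r_min=rmin, pair=key)
            pots[key] = initial_guess_from_rdf(fine, skel, self.state.kT)
        return PotentialSet(pots)

    def fit(self, *, chi: float = 1.0, tol: float = 1e-4,
            max_iter: int = 10, window: int = 5, n_steps: int = 100_000,
            max_disp: float = 0.35, stride: int = 250, seed: int = 0,
            w_lambda: float = 0.0, w_u: float = 1.0,
            callback=None) -> "RelativeEntropyResults":
        pots0 = self.initial_potentials()
        report = re_minimize(self.reference, pots0, self.state, self.start,
                             n_steps=n_steps, max_disp=max_disp,
                             stride=stride, chi=chi, tol=tol,
                             max_iter=max_iter, window=window,
                             w_lambda=w_lambda, w_u=w_u, seed=seed,
                             callback=callback)
        return RelativeEntropyResults(self, report)


class RelativeEntropyResults:
    """Optimized CBSPL potentials plus convergence diagnostics."""

    def __init__(self, model: RelativeEntropyCG, report: REReport):
        self.model = model
        self.report = report
        self.potentials = report.potentials
        self.converged = report.converged
        self.history = report.history

    @property
    def params(self) -> np.ndarray:
        """Free (optimized) knot values across all pair potentials."""
        return self.potentials.vector()[self.potentials.free_indices]

    @property
    def bse(self) -> np.ndarray:
        """Delta-method standard-error proxy for the free knots.

        Propagates the Monte-Carlo standard error of the last gradient
        through the last Hessian, cov ≈ H⁻¹ diag(se²) H⁻¹; a sampling-
        noise scale, not a full posterior.
        """
        H, se = self.report.hessian, self.report.gradient_se
        if H is None:
            return np.full_like(self.params, np.nan)
        Hinv = np.linalg.pinv(H)
        cov = Hinv @ np.diag(se ** 2) @ Hinv
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))

    def sample(self, *, n_steps: int = 100_000, seed: int = 10_000,
               max_disp: float = 0.35, stride: int = 250) -> Trajectory:
        """Sample the CG ensemble of the fitted potentials."""
        return mc_nvt(self.model.start, self.potentials.tables(300),
                      self.model.state, n_steps=n_steps, max_disp=max_disp,
                      seed=seed, stride=stride)

    def rdf(self, pair, traj: Trajectory = None) -> RDF:
        key = tuple(sorted(pair))
        ref = self.model.rdfs[key]
        if traj is None:
            traj = self.sample()
        return compute_rdf(traj, key, float(ref.edges[-1]), ref.bin_width)

    def summary(self) -> str:
        lines = ["Relative-entropy CG fit", "=" * 64]
        lines.append(f"pairs: {', '.join('-'.join(p) for p in self.model.pairs)}")
        lines.append(f"spline: r_cut={self.model.r_cut} dr={self.model.dr} "
                     f"({self.potentials.n_params} knots, "
                     f"{len(self.potentials.free_indices)} free)")
        lines.append(f"iterations: {len(self.history)}   "
                     f"converged: {self.converged}")
        if self.history:
            h = self.history[-1]
            lines.append(f"final eps_tot: {h['eps_tot']:.4g}   "
                         f"|grad|: {h['grad_norm']:.4g}")
        lines.append("-" * 64)
        lines.append(_fmt_row("pair", "r_min", "free knots", "u(min) est"))
        for key in self.potentials.pairs:
            pot = self.potentials.pots[key]
            free_r = pot.positions[~pot.frozen]
            umin = min(pot(r) for r in np.linspace(max(pot.r_min, 1e-3),
                                                   pot.r_cut * 0.999, 200))
            lines.append(_fmt_row("-".join(key), f"{pot.r_min:.3f}",
                                  pot.n_free, f"{umin:.4f}"))
        return "\n".join(lines)


class TargetedCG:
    """Targeted CG model: CKDg parameters fitted to reference structure
    (and optionally pressure) by downhill-simplex penalty minimization.

    Parameters
    ----------
    target_rdf : RDF
        Reference (mapped) radial distribution function.
    state : ThermodynamicState
        Sampling temperature for the CG trial simulations.
    start : Frame
        Shared start configuration for every penalty evaluation.
    r_lo, r_hi : float
        RDF comparison window of the penalty.
    pressure_weight : float
        The switch ``a``; 0 targets structure only.
    target_pressure : float
        Reference pressure entering the penalty when ``a > 0``.
    """

    def __init__(self, target_rdf: RDF, state: ThermodynamicState,
                 start: Frame, *, r_lo: float = 0.0, r_hi: float = None,
                 pressure_weight: float = 0.0, target_pressure: float = 0.0,
                 species: str = None):
        self.penalty_spec = PenaltySpec(target_rdf=target_rdf, r_lo=r_lo,
                                        r_hi=r_hi, a=pressure_weight,
                                        target_pressure=target_pressure)
        self.state = state
        self.start = start
        self.species = species or str(start.species[0])

    @classmethod
    def from_fixture(cls, fixture: ReferenceFixture, pair=None,
                     **kwargs) -> "TargetedCG":
        pair = pair or fixture.pairs[0]
        raw = fixture.mapped[-1]
        sel = raw.species == pair[0]
        start = Frame(raw.positions[sel], raw.species[sel], raw.L)
        return cls(fixture.rdfs[tuple(pair)], fixture.state, start,
                   species=pair[0], **kwargs)

    def initial_vertices(self, center: CKDgParams, spread: float = 0.2,
                         seed: int = 0) -> np.ndarray:
        """n+1 = 7 vertices: the center guess perturbed by ±spread."""
        rng = np.random.default_rng(seed)
        v0 = center.as_vector()
        verts = [v0]
        for _ in range(CKDgParams.N_FREE_PARAMETERS):
            verts.append(v0 * (1.0 + rng.uniform(-spread, spread, len(v0))))
        return np.array(verts)

    def fit(self, initial_vertices, *, max_steps: int = 30, tol: float = 0.0,
            n_steps: int = 40_000, relax_steps: int = 2_000,
            max_disp: float = 0.35, stride: int = 200,
            seed: int = 0) -> "TargetedCGResults":
        evaluator = make_ckdg_evaluator(
            self.penalty_spec, self.state, self.start, species=self.species,
            n_steps=n_steps, relax_steps=relax_steps, max_disp=max_disp,
            stride=stride, seed=seed)
        report = simplex_minimize(np.asarray(initial_vertices), evaluator,
                                  max_steps=max_steps, tol=tol, seed=seed)
        return TargetedCGResults(self, report)


class TargetedCGResults:
    """Best CKDg vertex with the polytope trace."""

    PARAM_NAMES = ("sigma", "eps", "w_c", "h", "p", "s")

    def __init__(self, model: TargetedCG, report: SimplexReport):
        self.model = model
        self.report = report
        self.params = report.best_vertex
        self.best_params = report.best_params
        self.best_penalty = report.best_penalty
        self.trace = report.trace
        self.converged = report.converged

    @property
    def bse(self) -> np.ndarray:
        """Spread of each parameter across the final polytope — the
        optimizer's own resolution scale (not a statistical CI)."""
        return self.report.state.vertices.std(axis=0, ddof=1)

    def summary(self) -> str:
        lines = ["Targeted CG fit (downhill simplex, CKDg form)", "=" * 64]
        lines.append(f"polytope steps: {self.report.state.iteration}   "
                     f"converged: {self.converged}")
        lines.append(f"best penalty: {self.best_penalty:.4f}   "
                     f"(pressure weight a={self.model.penalty_spec.a})")
        lines.append("-" * 64)
        lines.append(_fmt_row("parameter", "estimate", "polytope sd"))
        for name, val, sd in zip(self.PARAM_NAMES, self.params, self.bse):
            lines.append(_fmt_row(name, f"{val:.4f}", f"{sd:.4f}"))
        return "\n".join(lines)
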