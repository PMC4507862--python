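"""Relative-entropy minimization of CBSPL pair potentials.

The relative entropy S_rel between a reference (fine-grained, mapped)
ensemble and a CG model is minimized over the CG parameters λ with a
Newton–Raphson iteration

    λ_{k+1} = λ_k − χ H⁻¹ ∇_λ S_rel ,      χ ∈ (0, 1]

where, in the canonical ensemble,

    ∇_λ S_rel = β ⟨∂U/∂λ⟩_ref − β ⟨∂U/∂λ⟩_CG
    H_ij = β⟨∂²U/∂λi∂λj⟩_ref − β⟨∂²U/∂λi∂λj⟩_CG
           + β²⟨(∂U/∂λi)(∂U/∂λj)⟩_CG − β²⟨∂U/∂λi⟩_CG⟨∂U/∂λj⟩_CG .

For the B-spline form U is linear in the knot values, so the
second-derivative terms vanish and H reduces to β² times the CG-ensemble
covariance of the per-frame derivative sums — symmetric positive
semidefinite, hence a single global minimum.  The reference-ensemble
averages do not depend on λ and are computed once and cached; the
CG-ensemble averages are resampled each iteration with a short
Monte-Carlo run.

Knots in the poorly sampled repulsive core (r ≤ r_min) and in the zero
tail are excluded from the update; core knots are refreshed each
iteration by extrapolating the potential at the first free knot with a
repulsive exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .mapping_analysis import RDF
from .potentials import (KnotPotential, PotentialTable, boltzmann_invert,
                         cbspl_evaluate, fit_cbspl, CBSPL_MATRIX)
from .sampler import (Frame, PairTables, ThermodynamicState,
                      mc_nvt, minimum_image)

__all__ = [
    "PotentialSet", "DerivativeAverages", "NewtonState", "REReport",
    "accumulate_derivatives", "srel_gradient", "srel_hessian",
    "newton_step", "extrapolate_core", "convergence_errors",
    "estimate_r_min", "re_minimize", "gradient_standard_error",
    "initial_guess_from_rdf",
]


class PotentialSet:
    """Ordered set of CBSPL potentials with a concatenated parameter vector.

    The global parameter vector stacks the knot vectors of every
    species-pair potential in sorted pair order; the frozen mask marks
    core and tail knots of each potential.
    """

    def __init__(self, pots: dict):
        norm = {}
        for (a, b), p in pots.items():
            key = tuple(sorted((a, b)))
            norm[key] = p
        self.pairs = sorted(norm)
        self.pots = {k: norm[k] for k in self.pairs}
        sizes = [len(self.pots[k].knots) for k in self.pairs]
        self.offsets = dict(zip(self.pairs, np.concatenate(
            [[0], np.cumsum(sizes)[:-1]]).astype(int)))
        self.n_params = int(sum(sizes))

    @classmethod
    def single(cls, pot: KnotPotential):
        return cls({tuple(pot.pair): pot})

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, pair):
        return self.pots[tuple(sorted(pair))]

    def vector(self) -> np.ndarray:
        return np.concatenate([self.pots[k].knots for k in self.pairs])

    def with_vector(self, v: np.ndarray) -> "PotentialSet":
        out = {}
        for k in self.pairs:
            o = self.offsets[k]
            n = len(self.pots[k].knots)
            out[k] = self.pots[k].with_knots(v[o:o + n])
        return PotentialSet(out)

    @property
    def frozen_mask(self) -> np.ndarray:
        return np.concatenate([self.pots[k].frozen for k in self.pairs])

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.frozen_mask)

    def tables(self, n_points: int = 400) -> PairTables:
        return PairTables({k if len(k) == 2 else (k[0], k[0]):
                           self.pots[k].table(n_points)
                           for k in self.pairs})

    def map(self, fn) -> "PotentialSet":
        return PotentialSet({k: fn(p) for k, p in self.pots.items()})


@dataclass
class DerivativeAverages:
    """Ensemble averages of CG-energy parameter derivatives.

    ``first`` is ⟨∂U/∂λ⟩ over frames; ``second_moment`` is
    ⟨(∂U/∂λi)(∂U/∂λj)⟩; ``second_deriv`` is ⟨∂²U/∂λi∂λj⟩, identically
    zero for parameter-linear forms such as CBSPL.
    """

    first: np.ndarray
    second_moment: np.ndarray
    n_frames: int
    second_deriv: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_frames <= 0:
            raise ValueError("frame count must be positive")
        if self.second_deriv is None:
            self.second_deriv = np.zeros_like(self.second_moment)
        if not np.allclose(self.second_moment, self.second_moment.T):
            raise ValueError("second-moment matrix must be symmetric")

    @property
    def covariance(self) -> np.ndarray:
        return self.second_moment - np.outer(self.first, self.first)

    @property
    def variance(self) -> np.ndarray:
        return np.clip(np.diag(self.covariance), 0.0, None)


def _pair_distances(frame: Frame, a: str, b: str) -> np.ndarray:
    ia = np.flatnonzero(frame.species == a)
    if a == b:
        if len(ia) < 2:
            return np.empty(0)
        ii, jj = np.triu_indices(len(ia), k=1)
        d = minimum_image(frame.positions[ia[jj]] - frame.positions[ia[ii]],
                          frame.L)
    else:
        ib = np.flatnonzero(frame.species == b)
        if len(ia) == 0 or len(ib) == 0:
            return np.empty(0)
        d = minimum_image(frame.positions[ib][None, :, :]
                          - frame.positions[ia][:, None, :],
                          frame.L).reshape(-1, 3)
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def accumulate_derivatives(traj, pots: PotentialSet) -> DerivativeAverages:
    """Per-frame derivative sums Σ_{i<j} ∂u(r_ij)/∂c, averaged over frames.

    For the B-spline form the parameter derivatives are the basis
    weights of each pair separation, scattered onto the four knots of
    its segment.  Pairs inside a potential's frozen core (r ≤ r_min)
    are skipped — those knots are not updated from statistics.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    n = pots.n_params
    s1 = np.zeros(n)
    s2 = np.zeros((n, n))
    for frame in frames:
        d = np.zeros(n)
        for key in pots.pairs:
            pot = pots.pots[key]
            a, b = key if len(key) == 2 else (key[0], key[0])
            r = _pair_distances(frame, a, b)
            r = r[(r < pot.r_cut) & (r > pot.r_min)]
            if len(r) == 0:
                continue
            k = np.floor(r / pot.dr).astype(np.intp)
            k = np.minimum(k, pot.m - 3)
            t = r / pot.dr - k
            tt = np.stack([np.ones_like(t), t, t * t, t ** 3], axis=-1)
            w = tt @ (CBSPL_MATRIX / 6.0)
            np.add.at(d, pots.offsets[key] + k[:, None] + np.arange(4), w)
        s1 += d
        s2 += np.outer(d, d)
    nf = len(frames)
    return DerivativeAverages(s1 / nf, s2 / nf, nf)


def srel_gradient(aa: DerivativeAverages, cg: DerivativeAverages,
                  beta: float, free: np.ndarray = None) -> np.ndarray:
    """∇_λ S_rel = β(⟨∂U/∂λ⟩_ref − ⟨∂U/∂λ⟩_CG), restricted to free knots."""
    if aa.first.shape != cg.first.shape:
        raise ValueError("dimension mismatch between ensembles")
    g = beta * (aa.first - cg.first)
    return g if free is None else g[free]


def srel_hessian(cg: DerivativeAverages, aa: DerivativeAverages,
                 beta: float, free: np.ndarray = None) -> np.ndarray:
    """Hessian of S_rel; for parameter-linear forms β² Cov_CG(∂U/∂λ)."""
    if aa.first.shape != cg.first.shape:
        raise ValueError("dimension mismatch between ensembles")
    H = (beta * aa.second_deriv - beta * cg.second_deriv
         + beta ** 2 * cg.covariance)
    return H if free is None else H[np.ix_(free, free)]


def gradient_standard_error(aa: DerivativeAverages, cg: DerivativeAverages,
                            beta: float, free: np.ndarray = None) -> np.ndarray:
    """Monte-Carlo standard error of each gradient component.

    Treats recorded frames as independent; with correlated chains this
    is a lower bound, so sampling strides should decorrelate frames.
    """
    var = aa.variance / aa.n_frames + cg.variance / cg.n_frames
    se = beta * np.sqrt(var)
    return se if free is None else se[free]


@dataclass
class NewtonState:
    """State of the guarded Newton–Raphson iteration over free knots."""

    lam: np.ndarray
    grad: np.ndarray
    hess: np.ndarray
    chi: float = 1.0
    k: int = 0
    eps_lambda: list = field(default_factory=list)
    eps_u: list = field(default_factory=list)
    eps_tot: list = field(default_factory=list)
    w_lambda: float = 0.0
    w_u: float = 1.0
    tol: float = 1e-6
    max_iter: int = 20
    window: int = 5

    def __post_init__(self):
        n = len(self.lam)
        if self.grad.shape != (n,) or self.hess.shape != (n, n):
            raise ValueError("gradient/Hessian dimensions do not match λ")
        # χ = 0 is the degenerate "no update" case, allowed for testing
        if not (0.0 <= self.chi <= 1.0):
            raise ValueError("relaxation χ must lie in [0, 1]")


def newton_step(state: NewtonState) -> np.ndarray:
    """One relaxed Newton update λ ← λ − χ H⁻¹∇ via Cholesky factorization.

    A numerically singular Hessian gets a ridge τI with
    τ = 1e-8 tr(H)/n before giving up.
    """
    H, g = state.hess, state.grad
    try:
        c = scipy.linalg.cho_factor(H)
        step = scipy.linalg.cho_solve(c, g)
    except scipy.linalg.LinAlgError:
        n = len(g)
        tau = 1e-8 * np.trace(H) / max(n, 1)
        tau = tau if tau > 0 else 1e-12
        warnings.warn(f"singular Hessian: applying ridge tau={tau:.3e}",
                      stacklevel=2)
        try:
            c = scipy.linalg.cho_factor(H + tau * np.eye(n))
            step = scipy.linalg.cho_solve(c, g)
        except scipy.linalg.LinAlgError as exc:
            raise RuntimeError(
                "Hessian singular even after ridge regularization; "
                "check sampling statistics") from exc
    return state.lam - state.chi * step


def extrapolate_core(pot: KnotPotential) -> KnotPotential:
    """Refresh core knots (r ≤ r_min) by repulsive extrapolation.

    The potential's value u0 and slope u0' at the first knot position
    above r_min depend only on free knots; they anchor an exponential
    A·exp(−B·r) (B > 0) continued toward r → 0.  If the anchor is not
    repulsive (u0 ≤ 0 or u0' ≥ 0) a linear continuation is used
    instead.  Core knot values are set from the extrapolant at each
    knot's quasi-interpolation center, which keeps the spline monotone
    on the core (variation diminishing) and leaves it bit-unchanged at
    and above the anchor.
    """
    pos = pot.positions
    core = np.flatnonzero(pos <= pot.r_min + 1e-12)
    if len(core) == 0:
        return pot.with_knots(pot.knots)
    q = core[-1]
    if q + 3 > pot.m:
        raise ValueError("fewer than two free knots above r_min")
    c = pot.knots
    r_a = pos[q + 1]
    u0 = (c[q + 1] + 4.0 * c[q + 2] + c[q + 3]) / 6.0
    du0 = (c[q + 3] - c[q + 1]) / (2.0 * pot.dr)
    # the exponential form is only meaningful anchored inside the
    # repulsive wall; near the potential's zero crossing u0 -> 0 makes
    # B = -u0'/u0 diverge, so such anchors use the linear continuation
    if u0 > 0 and du0 < 0 and -du0 / u0 * pot.dr <= 10.0:
        B = -du0 / u0
        A = u0 * np.exp(B * r_a)
        def f(r):
            return A * np.exp(-B * r)
    else:
        why = ("non-repulsive anchor" if u0 <= 0 or du0 >= 0
               else "anchor too close to the zero crossing")
        warnings.warn(f"{why} at r_min: falling back to linear core "
                      "continuation", stacklevel=2)
        def f(r):
            return u0 + du0 * (r - r_a)
    knots = c.copy()
    # control point c_j dominates the spline near r_{j-1}: u(r_k) blends
    # (c_k + 4 c_{k+1} + c_{k+2})/6, so evaluate the extrapolant one
    # interval to the left of each core knot (r_{-1} = -dr is fine)
    knots[:q + 1] = f(pot.dr * (np.arange(q + 1) - 1))
    return pot.with_knots(knots)


def convergence_errors(lam_k: np.ndarray, lam_km1: np.ndarray,
                       tables_k, tables_km1,
                       w_lambda: float, w_u: float):
    """Convergence errors: plain sums of squares, no square roots.

    ε_λ  = Σ_i (λ_i^k − λ_i^{k−1})²
    ε_u  = Σ_pots Σ_grid (u^k(r_j) − u^{k−1}(r_j))²
    ε_tot = w_λ ε_λ + w_u ε_u
    """
    lam_k = np.asarray(lam_k, float)
    lam_km1 = np.asarray(lam_km1, float)
    if lam_k.shape != lam_km1.shape:
        raise ValueError("parameter vectors differ in length")
    eps_lambda = float(np.sum((lam_k - lam_km1) ** 2))
    eps_u = 0.0
    for tk, tkm in zip(tables_k, tables_km1):
        if tk.r.shape != tkm.r.shape or not np.allclose(tk.r, tkm.r):
            raise ValueError("potential grids do not match between iterates")
        eps_u += float(np.sum((tk.u - tkm.u) ** 2))
    return eps_lambda, eps_u, w_lambda * eps_lambda + w_u * eps_u


def estimate_r_min(rdf: RDF) -> float:
    """Smallest bin center with nonzero reference g(r)."""
    nz = np.flatnonzero(rdf.g > 0)
    if len(nz) == 0:
        raise ValueError("reference RDF is identically zero")
    return float(rdf.r[nz[0]])


@dataclass
class REReport:
    """Outcome of a relative-entropy minimization run."""

    potentials: PotentialSet
    converged: bool
    n_iterations: int
    history: list          # one dict per iteration
    initial: PotentialSet
    gradient: np.ndarray = None          # last free-knot gradient
    gradient_se: np.ndarray = None       # its Monte-Carlo standard error
    hessian: np.ndarray = None           # last free-knot Hessian


def initial_guess_from_rdf(rdf: RDF, skeleton: KnotPotential,
                           kT: float) -> KnotPotential:
    """PMF fit start: Boltzmann-invert the reference RDF, least-squares
    fit the spline over defined bins above r_min, extrapolate the core."""
    pmf = boltzmann_invert(rdf.r, rdf.g, kT=kT, pair=skeleton.pair)
    mask = pmf.defined & (pmf.r > skeleton.r_min)
    target = pmf
    target.u[~mask] = np.nan
    fitted = fit_cbspl(target, skeleton)
    return extrapolate_core(fitted)


def _optimized_range_table(pot: KnotPotential, n_points: int):
    """Tabulate a potential on its optimized range (r_min, r_cut)."""
    r = np.linspace(pot.r_min, pot.r_cut, n_points, endpoint=False)
    return PotentialTable(r, cbspl_evaluate(pot, r), np.zeros(n_points),
                          pair=pot.pair, r_cut=pot.r_cut)


def re_minimize(reference_traj, pots: PotentialSet,
                state: ThermodynamicState, start: Frame, *,
                n_steps: int = 100_000, max_disp: float = 0.2,
                stride: int = 200, equilibration: float = 0.25,
                chi: float = 1.0, tol: float = 1e-6, max_iter: int = 15,
                window: int = 5, w_lambda: float = 0.0, w_u: float = 1.0,
                seed: int = 0, table_points: int = 200,
                callback=None) -> REReport:
    """Full Newton–Raphson relative-entropy loop over CBSPL potentials.

    Per iteration: sample the CG ensemble with the current potentials
    (seed = base seed + iteration, recorded in the report), accumulate
    derivative averages, take a guarded Newton step on the free knots,
    extrapolate the core, and evaluate the convergence errors.
    Reference-ensemble averages are computed once up front.  If ε_tot
    grows three iterations in a row, χ is halved and the step restarted
    from the best iterate; after three halvings the run aborts as
    non-converged.  The returned potentials are the trailing-window
    average of the final iterates (the iteration is stochastic).
    """
    aa = accumulate_derivatives(reference_traj, pots)
    beta = state.beta
    free = pots.free_indices

    lam = pots.vector()
    current = pots.with_vector(lam)
    cg_start = start.copy()
    history = []
    lam_iterates = [lam.copy()]
    grow_streak = 0
    halvings = 0
    converged = False
    grad_free = se_free = hess_free = None
    prev_eps = np.inf
    it = 0

    while it < max_iter:
        run_seed = seed + it
        traj = mc_nvt(cg_start, current.tables(table_points), state,
                      n_steps=n_steps, max_disp=max_disp, seed=run_seed,
                      stride=stride, equilibration=equilibration)
        cg = accumulate_derivatives(traj, current)
        grad_free = srel_gradient(aa, cg, beta, free)
        hess_free = srel_hessian(cg, aa, beta, free)
        se_free = gradient_standard_error(aa, cg, beta, free)

        ns = NewtonState(lam[free], grad_free, hess_free, chi=chi)
        lam_new = lam.copy()
        lam_new[free] = newton_step(ns)
        updated = current.with_vector(lam_new).map(extrapolate_core)
        lam_new = updated.vector()

        # errors over the optimized parameters and the optimized range
        # (the frozen core is extrapolated, not iterated, and would
        # otherwise dominate the sums of squares)
        tabs_new = [_optimized_range_table(updated.pots[k], table_points)
                    for k in updated.pairs]
        tabs_old = [_optimized_range_table(current.pots[k], table_points)
                    for k in current.pairs]
        e_l, e_u, e_tot = convergence_errors(lam_new[free], lam[free],
                                             tabs_new, tabs_old,
                                             w_lambda, w_u)
        record = {"iteration": it, "seed": run_seed, "chi": chi,
                  "eps_lambda": e_l, "eps_u": e_u, "eps_tot": e_tot,
                  "grad_norm": float(np.linalg.norm(grad_free)),
                  "hess_min_eig": float(np.linalg.eigvalsh(hess_free).min()),
                  "acceptance": traj.acceptance_ratio}
        history.append(record)
        if callback is not None:
            callback(it, updated, record)

        if e_tot > prev_eps:
            grow_streak += 1
        else:
            grow_streak = 0
        prev_eps = e_tot

        lam = lam_new
        current = updated
        lam_iterates.append(lam.copy())
        cg_start = traj[-1] if len(traj) else cg_start
        it += 1

        if e_tot < tol:
            converged = True
            break
        if grow_streak >= 3:
            halvings += 1
            if halvings > 3:
                warnings.warn("relative-entropy iteration diverging after "
                              "3 χ halvings: aborting", stacklevel=2)
                break
            chi *= 0.5
            grow_streak = 0
            # restart the step from the best iterate so far
            best = int(np.argmin([h["eps_tot"] for h in history]))
            lam = lam_iterates[best + 1].copy()
            current = pots.with_vector(lam)
            prev_eps = history[best]["eps_tot"]

    w = min(window, len(lam_iterates) - 1)
    lam_avg = np.mean(lam_iterates[-w:], axis=0) if w > 0 else lam
    final = current.with_vector(lam_avg).map(extrapolate_core)
    return REReport(potentials=final, converged=converged, n_iterations=it,
                    history=history, initial=pots, gradient=grad_free,
                    gradient_se=se_free, hessian=hess_free)
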