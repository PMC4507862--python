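"""Downhill-simplex targeted coarse-graining.

A derivative-free polytope optimizer over CG potential parameters
(typically the 6 CKDg parameters).  The current state is n+1 vertices
sorted by penalty; a step reflects the worst vertex through the
centroid of the rest and, depending on the trial penalty, expands,
contracts, or shrinks the whole polytope toward the best vertex:

    reflect   p_r = p̄ + α (p̄ − p_{n+1})        α = 1
    expand    p_e = p̄ + γ (p̄ − p_{n+1})        γ = 2
    contract  p_c = p̄ + ρ (p̄ − p_{n+1})        0 < ρ < 1
    reduce    p_i → σ (p_i + p_1),  i ≠ 1       σ = 0.5

Decision flow (this toolkit triggers contraction on y_r > y_{n+1},
i.e. against the *worst* vertex, where textbook Nelder–Mead uses the
second worst): reflect; if y_r < y_1 try
the expansion and keep the better of p_e / p_r; if y_r > y_{n+1}
contract, and if even the contraction does not beat the worst vertex,
reduce; otherwise accept the reflection.

The penalty for targeted coarse-graining is the absolute RDF deviation
summed over a bin range plus a switchable pressure term,

    y = Σ_{r_i in [r_lo, r_hi]} |g_CG(r_i) − g_ref(r_i)| + a |p_CG − p_ref|.

Penalties come from short CG simulations, so the objective is
stochastic; within one polytope step every candidate is evaluated with
the same sampler seed (common random numbers) to reduce noise-induced
misordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

log = logging.getLogger(__name__)

from .mapping_analysis import RDF, compute_rdf
from .potentials import CKDgParams
from .sampler import (Frame, PairTables, ThermodynamicState, mc_nvt,
                      virial_pressure)

__all__ = [
    "SimplexState", "PenaltySpec", "SimplexReport",
    "sort_vertices", "reflect", "expand", "contract", "reduce_simplex",
    "simplex_step", "penalty_rdf_pressure",
    "write_state_file", "read_state_file", "next_action",
    "make_ckdg_evaluator", "simplex_minimize",
]

PENDING = "pending"
DONE = "done"


@dataclass
class SimplexState:
    """n+1 parameter vertices with penalties and transformation coefficients."""

    vertices: np.ndarray          # (n+1, n)
    penalties: np.ndarray         # (n+1,)
    status: list = None           # type: ignore[assignment]
    alpha: float = 1.0
    gamma: float = 2.0
    rho: float = 0.5
    sigma: float = 0.5
    iteration: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.penalties = np.asarray(self.penalties, dtype=float)
        n1, n = self.vertices.shape
        if n1 != n + 1:
            raise ValueError(f"need n+1 vertices of dimension n, got shape "
                             f"{self.vertices.shape}")
        if self.status is None:
            self.status = [PENDING if np.isnan(p) else DONE
                           for p in self.penalties]
        if self.alpha <= 0:
            raise ValueError("reflection coefficient α must be positive")
        if self.gamma <= 1:
            raise ValueError("expansion coefficient γ must exceed 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("contraction coefficient ρ must lie in (0, 1)")

    @property
    def n(self) -> int:
        return self.vertices.shape[1]

    @property
    def all_evaluated(self) -> bool:
        return all(s == DONE for s in self.status)

    @property
    def spread(self) -> float:
        return float(self.penalties[-1] - self.penalties[0])

    def copy(self) -> "SimplexState":
        return replace(self, vertices=self.vertices.copy(),
                       penalties=self.penalties.copy(),
                       status=list(self.status))


def sort_vertices(state: SimplexState) -> SimplexState:
    """Sort vertices by penalty, ascending; ties keep insertion order."""
    if not state.all_evaluated:
        raise ValueError("cannot sort a state with pending vertices")
    order = np.argsort(state.penalties, kind="stable")
    out = state.copy()
    out.vertices = state.vertices[order]
    out.penalties = state.penalties[order]
    out.status = [state.status[i] for i in order]
    return out


def _centroid(state: SimplexState) -> np.ndarray:
    return state.vertices[:-1].mean(axis=0)


def reflect(state: SimplexState) -> np.ndarray:
    """p_r = p̄ + α(p̄ − p_worst)."""
    c = _centroid(state)
    return c + state.alpha * (c - state.vertices[-1])


def expand(state: SimplexState) -> np.ndarray:
    """p_e = p̄ + γ(p̄ − p_worst)."""
    c = _centroid(state)
    return c + state.gamma * (c - state.vertices[-1])


def contract(state: SimplexState) -> np.ndarray:
    """p_c = p̄ + ρ(p̄ − p_worst)."""
    c = _centroid(state)
    return c + state.rho * (c - state.vertices[-1])


def reduce_simplex(state: SimplexState) -> SimplexState:
    """Shrink toward the best vertex: p_i → σ(p_i + p_1) for i ≠ 1.

    The printed form is used verbatim; with σ = 0.5 it coincides with
    the conventional p_1 + σ(p_i − p_1) midpoint shrink.
    """
    out = state.copy()
    p1 = state.vertices[0]
    out.vertices[1:] = state.sigma * (state.vertices[1:] + p1)
    out.penalties[1:] = np.nan
    for i in range(1, len(out.status)):
        out.status[i] = PENDING
    return out


def _safe_eval(evaluator, point):
    try:
        y = float(evaluator(point))
    except Exception as exc:
        log.warning("vertex evaluation failed (%s: %s): penalty set to "
                    "+inf", type(exc).__name__, exc)
        return math.inf
    return y if not math.isnan(y) else math.inf


def simplex_step(state: SimplexState, evaluator) -> SimplexState:
    """One polytope transformation following the decision flow above."""
    if not state.all_evaluated:
        raise ValueError("evaluate pending vertices before transforming")
    state = sort_vertices(state)
    y = state.penalties
    p_r = reflect(state)
    y_r = _safe_eval(evaluator, p_r)

    if y_r < y[0]:
        p_e = expand(state)
        y_e = _safe_eval(evaluator, p_e)
        new_p, new_y = (p_e, y_e) if y_e < y_r else (p_r, y_r)
    elif y_r > y[-1]:
        p_c = contract(state)
        y_c = _safe_eval(evaluator, p_c)
        if y_c <= y[-1]:
            new_p, new_y = p_c, y_c
        else:
            out = reduce_simplex(state)
            for i in range(1, len(out.status)):
                out.penalties[i] = _safe_eval(evaluator, out.vertices[i])
                out.status[i] = DONE
            out = sort_vertices(out)
            out.iteration = state.iteration + 1
            return out
    else:
        new_p, new_y = p_r, y_r

    out = state.copy()
    out.vertices[-1] = new_p
    out.penalties[-1] = new_y
    out = sort_vertices(out)
    out.iteration = state.iteration + 1
    return out


@dataclass
class PenaltySpec:
    """Objective definition: RDF comparison range, pressure weight, targets."""

    target_rdf: RDF
    r_lo: float = 0.0
    r_hi: float = None  # type: ignore[assignment]
    a: float = 0.0
    target_pressure: float = 0.0

    def __post_init__(self):
        if self.r_hi is None:
            self.r_hi = float(self.target_rdf.edges[-1])
        if not self.r_lo < self.r_hi:
            raise ValueError("need r_lo < r_hi")
        if self.a < 0:
            raise ValueError("pressure weight a must be non-negative")


def penalty_rdf_pressure(g_cg: RDF, spec: PenaltySpec,
                         p_cg: float = 0.0) -> float:
    """y = Σ |g_CG(r_i) − g_ref(r_i)| over the bin range, + a|p_CG − p_ref|.

    With a = 0 the pressure term is switched off entirely.
    """
    ref = spec.target_rdf
    if g_cg.g.shape != ref.g.shape or not np.allclose(g_cg.edges, ref.edges):
        raise ValueError("CG and target RDFs are on different bin grids")
    sel = (ref.r >= spec.r_lo - 1e-12) & (ref.r <= spec.r_hi + 1e-12)
    y = float(np.abs(g_cg.g[sel] - ref.g[sel]).sum())
    if spec.a > 0:
        y += spec.a * abs(p_cg - spec.target_pressure)
    return y


# ---------------------------------------------------------------------------
# state-file workflow (§-style evaluate/communicate cycle)

def write_state_file(state: SimplexState, path) -> None:
    """Line-based text state: header, then 'id status params... penalty'."""
    with open(path, "w") as fh:
        fh.write(f"# simplex state\nn {state.n}\n")
        fh.write(f"alpha {state.alpha!r}\ngamma {state.gamma!r}\n")
        fh.write(f"rho {state.rho!r}\nsigma {state.sigma!r}\n")
        fh.write(f"iteration {state.iteration}\n")
        for i, (v, y, s) in enumerate(zip(state.vertices, state.penalties,
                                          state.status)):
            params = " ".join(repr(float(x)) for x in v)
            pen = "nan" if s == PENDING or np.isnan(y) else repr(float(y))
            fh.write(f"{i} {s} {params} {pen}\n")


def read_state_file(path) -> SimplexState:
    header = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].isdigit():
                try:
                    idx = int(parts[0])
                    status = parts[1]
                    if status not in (PENDING, DONE):
                        raise ValueError(f"unknown status {status!r}")
                    values = [float(x) for x in parts[2:]]
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"{path}: malformed vertex record on line "
                        f"{lineno}: {exc}") from None
                rows.append((idx, status, values))
            else:
                try:
                    header[parts[0]] = parts[1]
                except IndexError:
                    raise ValueError(f"{path}: malformed header on line "
                                     f"{lineno}") from None
    n = int(header["n"])
    vertices = np.empty((len(rows), n))
    penalties = np.empty(len(rows))
    status = [PENDING] * len(rows)
    for idx, st, values in rows:
        if len(values) != n + 1:
            raise ValueError(f"{path}: vertex {idx} has {len(values) - 1} "
                             f"parameters, expected {n}")
        vertices[idx] = values[:n]
        penalties[idx] = values[n]
        status[idx] = st
    return SimplexState(vertices, penalties, status=status,
                        alpha=float(header["alpha"]),
                        gamma=float(header["gamma"]),
                        rho=float(header["rho"]),
                        sigma=float(header["sigma"]),
                        iteration=int(header["iteration"]))


def next_action(state: SimplexState) -> str:
    """Workflow rule: pending vertices must be evaluated before any move."""
    return "evaluate" if not state.all_evaluated else "transform"


# ---------------------------------------------------------------------------
# targeted coarse-graining driver

@dataclass
class SimplexReport:
    """Outcome of a targeted-coarse-graining simplex run."""

    best_vertex: np.ndarray
    best_penalty: float
    best_params: CKDgParams
    state: SimplexState
    trace: list
    converged: bool


def make_ckdg_evaluator(penalty_spec: PenaltySpec,
                        state: ThermodynamicState, start: Frame, *,
                        species: str = "A", n_steps: int = 20_000,
                        max_disp: float = 0.2, stride: int = 100,
                        equilibration: float = 0.25,
                        relax_steps: int = 2_000, seed: int = 0,
                        r_c: float = None):
    """Build a vertex → penalty evaluator for 6-vector CKDg parameters.

    Each evaluation: construct the potential (out-of-bounds vertices get
    +inf), relax the shared start configuration with a greedy
    zero-temperature chain (stands in for an energy minimization — an
    expansion move can produce parameters under which the start
    configuration is highly strained), sample an NVT chain, measure the
    RDF on the target grid (and the virial pressure when the penalty
    weights it), and score.
    """
    ref = penalty_spec.target_rdf
    r_max = float(ref.edges[-1])
    width = ref.bin_width

    def evaluate(vertex, eval_seed=None):
        eval_seed = seed if eval_seed is None else eval_seed
        try:
            params = CKDgParams.from_vector(vertex, r_c=r_c)
        except ValueError:
            return math.inf
        tables = PairTables.single(params.table(), species)
        cold = ThermodynamicState(T=1e-9 * state.T, k_B=state.k_B)
        relaxed = mc_nvt(start, tables, cold, n_steps=relax_steps,
                         max_disp=max_disp, seed=eval_seed, stride=relax_steps,
                         equilibration=0.0, check_every=0)
        begin = relaxed[-1] if len(relaxed) else start
        traj = mc_nvt(begin, tables, state, n_steps=n_steps,
                      max_disp=max_disp, seed=eval_seed + 1, stride=stride,
                      equilibration=equilibration, check_every=0)
        g = compute_rdf(traj, (species, species), r_max, width)
        p = (virial_pressure(traj, tables, state)
             if penalty_spec.a > 0 else 0.0)
        return penalty_rdf_pressure(g, penalty_spec, p)

    return evaluate


def simplex_minimize(initial_vertices, evaluator, *,
                     alpha: float = 1.0, gamma: float = 2.0,
                     rho: float = 0.5, sigma: float = 0.5,
                     max_steps: int = 100, tol: float = 0.0,
                     seed: int = 0, seed_per_step: bool = True,
                     r_c: float = None, on_step=None) -> SimplexReport:
    """Run the polytope loop from n+1 initial vertices to convergence.

    ``evaluator(vertex, eval_seed=...)`` may accept a seed keyword; the
    same seed is used for every evaluation within one polytope step
    (common random numbers).  Stops when the penalty spread across the
    polytope drops below ``tol`` or after ``max_steps`` transformations.
    """
    vertices = np.asarray(initial_vertices, dtype=float)

    def seeded(step):
        if seed_per_step:
            def ev(v):
                try:
                    return evaluator(v, eval_seed=seed + 1000 * step)
                except TypeError:
                    return evaluator(v)
            return ev
        return evaluator

    ev0 = seeded(0)
    penalties = np.array([_safe_eval(ev0, v) for v in vertices])
    state = SimplexState(vertices, penalties, alpha=alpha, gamma=gamma,
                         rho=rho, sigma=sigma)
    state = sort_vertices(state)
    trace = [{"step": 0, "best": float(state.penalties[0]),
              "worst": float(state.penalties[-1])}]
    converged = state.spread < tol
    step = 0
    while not converged and step < max_steps:
        step += 1
        state = simplex_step(state, seeded(step))
        trace.append({"step": step, "best": float(state.penalties[0]),
                      "worst": float(state.penalties[-1])})
        if on_step is not None:
            on_step(step, state)
        converged = state.spread < tol
    best = state.vertices[0]
    params = None
    if state.n == CKDgParams.N_FREE_PARAMETERS:
        try:
            params = CKDgParams.from_vector(best, r_c=r_c)
        except (ValueError, TypeError):
            pass
    return SimplexReport(best_vertex=best.copy(),
                         best_penalty=float(state.penalties[0]),
                         best_params=params, state=state, trace=trace,
                         converged=converged)
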