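"""Coarse-grained pair-potential families: uniform cubic B-splines and CKDg.

Two functional forms are supported for CG pair interactions:

* ``KnotPotential`` — a pair potential represented by knot values on a
  uniform cubic B-spline (CBSPL) grid.  The form is linear in its
  parameters, which makes relative-entropy minimization over it convex,
  and C2-continuous, which keeps forces smooth for sampling.
* ``CKDgParams`` — a 6-parameter analytic form: a WCA-like repulsion,
  a cosine-squared smoothed attractive well of depth ``eps`` and width
  ``w_c``, plus a shifted Gaussian bump (amplitude ``h``, mean ``p``,
  width ``s``).  Used by the derivative-free targeted optimizer.

Both can be tabulated to a ``PotentialTable`` (columns r, u, f) which is
what the Monte-Carlo sampler actually consumes.

All quantities are unit-agnostic; the Boltzmann constant enters only
through ``k_B * T`` factors supplied by callers (default ``k_B = 1``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CBSPL_MATRIX",
    "KnotPotential",
    "CKDgParams",
    "PotentialTable",
    "cbspl_knot_grid",
    "cbspl_evaluate",
    "cbspl_basis_weights",
    "cbspl_force",
    "ckdg_evaluate",
    "ckdg_force",
    "boltzmann_invert",
    "fit_cbspl",
    "export_table",
    "read_table",
]

#: Uniform cubic B-spline blending matrix; u(t) = [1 t t^2 t^3] (1/6) M c.
CBSPL_MATRIX = np.array(
    [
        [1.0, 4.0, 1.0, 0.0],
        [-3.0, 0.0, 3.0, 0.0],
        [3.0, -6.0, 3.0, 0.0],
        [-1.0, 3.0, -3.0, 1.0],
    ]
)


@dataclass
class KnotPotential:
    """CBSPL pair potential: knot values c_0..c_m on a uniform grid.

    The knot grid has spacing ``dr = r_cut / (m - 2)`` so that it extends
    two intervals beyond the cutoff; a separation ``r`` on segment ``k``
    (``r_k <= r < r_{k+1}``) blends knots ``c_k .. c_{k+3}``.

    Attributes
    ----------
    knots : ndarray, shape (m+1,)
        Knot values (energy units).
    dr : float
        Knot spacing (length units).
    r_cut : float
        Interaction cutoff; u(r >= r_cut) = 0.
    r_min : float
        Core radius below which the potential is extrapolated rather than
        optimized (poorly sampled region).
    frozen : ndarray of bool, shape (m+1,)
        Knots excluded from optimization: the repulsive core
        (positions <= r_min) and the zero tail (positions >= r_cut - dr).
    pair : tuple of str
        Species-pair label, e.g. ``("A", "A")``.
    """

    knots: np.ndarray
    dr: float
    r_cut: float
    r_min: float = 0.0
    frozen: np.ndarray = field(default=None)  # type: ignore[assignment]
    pair: tuple = ("A", "A")

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.frozen is None:
            self.frozen = self._default_frozen()
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
        if self.frozen.shape != self.knots.shape:
            raise ValueError("frozen mask and knot vector differ in length")

    def _default_frozen(self) -> np.ndarray:
        pos = self.positions
        return (pos <= self.r_min + 1e-12) | (pos >= self.r_cut - self.dr - 1e-12)

    @property
    def m(self) -> int:
        return len(self.knots) - 1

    @property
    def positions(self) -> np.ndarray:
        """Knot positions r_i = i * dr."""
        return self.dr * np.arange(len(self.knots))

    @property
    def n_free(self) -> int:
        return int((~self.frozen).sum())

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.frozen)

    def with_knots(self, knots: np.ndarray) -> "KnotPotential":
        return replace(self, knots=np.asarray(knots, dtype=float),
                       frozen=self.frozen.copy())

    def __call__(self, r):
        return cbspl_evaluate(self, r)

    def force(self, r):
        return cbspl_force(self, r)

    def table(self, n_points: int = 500) -> "PotentialTable":
        r = np.linspace(0.0, self.r_cut, n_points, endpoint=False) + \
            0.5 * self.r_cut / n_points
        return PotentialTable(r, cbspl_evaluate(self, r), cbspl_force(self, r),
                              pair=self.pair, r_cut=self.r_cut)


def cbspl_knot_grid(r_cut: float, dr: float, r_min: float = 0.0,
                    pair: tuple = ("A", "A"), rtol: float = 1e-9) -> KnotPotential:
    """Build an all-zero CBSPL skeleton for a cutoff and grid spacing.

    The number of intervals inside the cutoff is ``n = r_cut / dr``; the
    grid carries two extra intervals beyond the cutoff, giving ``n + 3``
    knots in total (``m = n + 2``).

    Raises
    ------
    ValueError
        If ``r_cut / dr`` is not an integer within ``rtol``.
    """
    if r_cut <= 0 or dr <= 0:
        raise ValueError(f"r_cut and dr must be positive, got {r_cut}, {dr}")
    ratio = r_cut / dr
    n = round(ratio)
    if abs(ratio - n) > rtol * max(1.0, ratio):
        raise ValueError(
            f"cutoff {r_cut} is not an integral multiple of spacing {dr} "
            f"(r_cut/dr = {ratio})")
    m = n + 2
    knots = np.zeros(m + 1)
    return KnotPotential(knots, dr=float(dr), r_cut=float(dr) * n,
                         r_min=float(r_min), pair=pair)


def _segments(pot: KnotPotential, r: np.ndarray):
    """Segment index k and local coordinate t for separations inside cutoff."""
    k = np.floor(r / pot.dr).astype(np.intp)
    n_seg = pot.m - 2  # segments fully inside the cutoff
    k = np.minimum(k, n_seg - 1)
    t = r / pot.dr - k
    return k, t


def _check_r(pot: KnotPotential, r: np.ndarray):
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")


def cbspl_evaluate(pot: KnotPotential, r) -> np.ndarray:
    """Evaluate the CBSPL potential at separation(s) ``r``.

    Returns 0 for ``r >= r_cut``; rejects negative ``r``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    _check_r(pot, r)
    u = np.zeros_like(r)
    inside = r < pot.r_cut
    if np.any(inside):
        k, t = _segments(pot, r[inside])
        tt = np.stack([np.ones_like(t), t, t * t, t ** 3], axis=-1)
        w = tt @ (CBSPL_MATRIX / 6.0)          # (n, 4) basis weights
        c = pot.knots[k[:, None] + np.arange(4)]
        u[inside] = np.einsum("ij,ij->i", w, c)
    return u[0] if scalar else u


def cbspl_basis_weights(pot: KnotPotential, r: float):
    """Basis weights w_k..w_{k+3} = du/dc_j at separation r, plus segment k.

    The weights sum to 1 (partition of unity); because the form is linear
    in the knots, second parameter derivatives vanish identically.
    """
    r = float(r)
    if r < 0:
        raise ValueError("separation r must be non-negative")
    if r >= pot.r_cut:
        return np.zeros(4), -1
    k, t = _segments(pot, np.array([r]))
    k, t = int(k[0]), float(t[0])
    w = np.array([1.0, t, t * t, t ** 3]) @ (CBSPL_MATRIX / 6.0)
    return w, k


def cbspl_force(pot: KnotPotential, r) -> np.ndarray:
    """Force f(r) = -du/dr of the CBSPL potential (analytic derivative)."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    _check_r(pot, r)
    f = np.zeros_like(r)
    inside = r < pot.r_cut
    if np.any(inside):
        k, t = _segments(pot, r[inside])
        dt = np.stack([np.zeros_like(t), np.ones_like(t), 2 * t, 3 * t * t],
                      axis=-1)
        w = dt @ (CBSPL_MATRIX / 6.0)
        c = pot.knots[k[:, None] + np.arange(4)]
        f[inside] = -np.einsum("ij,ij->i", w, c) / pot.dr
    return f[0] if scalar else f


@dataclass
class CKDgParams:
    """The 6 free parameters of the CKDg analytic pair potential.

    u(r) is a piecewise form: a shifted LJ repulsion for r < r_c_lj, a
    smoothed attraction -eps*cos^2(pi (r - r_c_lj) / (2 w_c)) out to
    r_c_lj + w_c, zero beyond — plus a Gaussian of amplitude ``h``, mean
    ``p`` and width ``s``, shifted so it vanishes at its cutoff ``r_c``.

    ``r_c_lj`` is tied to ``2^(1/6) sigma`` (the LJ minimum) and is not a
    free parameter.  By default the repulsive branch is lowered by ``eps``
    so the potential is continuous with minimum ``-eps`` at ``r_c_lj``;
    ``as_printed=True`` keeps the raw discontinuous branch instead.
    """

    sigma: float
    eps: float
    w_c: float
    h: float
    p: float
    s: float
    r_c: float = None  # type: ignore[assignment]  # Gaussian cutoff
    as_printed: bool = False

    def __post_init__(self):
        for name in ("sigma", "eps", "w_c", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_c is None:
            self.r_c = self.r_c_lj + self.w_c
        if self.r_c_lj + self.w_c > self.r_c + 1e-12:
            raise ValueError("gaussian cutoff r_c must satisfy "
                             "r_c >= r_c_lj + w_c")

    @property
    def r_c_lj(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def r_cut(self) -> float:
        """Overall interaction range."""
        return max(self.r_c_lj + self.w_c, self.r_c)

    def as_vector(self) -> np.ndarray:
        return np.array([self.sigma, self.eps, self.w_c, self.h,
                         self.p, self.s])

    @classmethod
    def from_vector(cls, v, r_c: float = None,
                    as_printed: bool = False) -> "CKDgParams":
        return cls(*map(float, v), r_c=r_c, as_printed=as_printed)

    def __call__(self, r):
        return ckdg_evaluate(self, r)

    def table(self, n_points: int = 600) -> "PotentialTable":
        r_max = self.r_cut
        r = np.linspace(0.0, r_max, n_points, endpoint=False) + \
            0.5 * r_max / n_points
        return PotentialTable(r, ckdg_evaluate(self, r), ckdg_force(self, r),
                              r_cut=r_max)

    N_FREE_PARAMETERS = 6


def _ckdg_gauss(params: CKDgParams, r: np.ndarray) -> np.ndarray:
    g = params.h * np.exp(-((r - params.p) ** 2) / (2.0 * params.s ** 2))
    g -= params.h * np.exp(-((params.r_c - params.p) ** 2)
                           / (2.0 * params.s ** 2))
    # clamp: finite range beyond the Gaussian cutoff (shift makes it C0 there)
    return np.where(r > params.r_c, 0.0, g)


def ckdg_evaluate(params: CKDgParams, r) -> np.ndarray:
    """Evaluate the CKDg potential; rejects r <= 0."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("separation r must be positive")
    s6 = (params.sigma / r) ** 6
    rep = 4.0 * params.eps * (s6 * s6 - s6 + 0.25)
    if not params.as_printed:
        rep = rep - params.eps
    x = np.pi * (r - params.r_c_lj) / (2.0 * params.w_c)
    well = -params.eps * np.cos(x) ** 2
    u = np.where(r < params.r_c_lj, rep,
                 np.where(r < params.r_c_lj + params.w_c, well, 0.0))
    u = u + _ckdg_gauss(params, r)
    return u[0] if scalar else u


def ckdg_force(params: CKDgParams, r) -> np.ndarray:
    """Analytic force f = -du/dr of the CKDg potential."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("separation r must be positive")
    s6 = (params.sigma / r) ** 6
    drep = 4.0 * params.eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    x = np.pi * (r - params.r_c_lj) / (2.0 * params.w_c)
    dwell = params.eps * np.sin(2.0 * x) * np.pi / (2.0 * params.w_c)
    du = np.where(r < params.r_c_lj, drep,
                  np.where(r < params.r_c_lj + params.w_c, dwell, 0.0))
    dg = params.h * np.exp(-((r - params.p) ** 2) / (2.0 * params.s ** 2)) \
        * (-(r - params.p) / params.s ** 2)
    du = du + np.where(r > params.r_c, 0.0, dg)
    return -(du[0] if scalar else du)


@dataclass
class PotentialTable:
    """Tabulated pair potential: separation grid r, energy u, force f.

    The sampler consumes tables (linear interpolation between grid points),
    so any potential family — or a hand-edited file — can drive it.
    Bins where the energy is undefined (e.g. from Boltzmann-inverting a
    zero-count RDF bin) carry NaN and are reported by ``defined``.
    """

    r: np.ndarray
    u: np.ndarray
    f: np.ndarray = None  # type: ignore[assignment]
    pair: tuple = ("A", "A")
    r_cut: float = None  # type: ignore[assignment]

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("separation grid must be strictly increasing")
        if self.f is None:
            self.f = -np.gradient(self.u, self.r)
        else:
            self.f = np.asarray(self.f, dtype=float)
        if self.r_cut is None:
            self.r_cut = float(self.r[-1])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.u)

    def u_at(self, r):
        """Energy-only fast path of :meth:`interpolate`."""
        r = np.asarray(r, dtype=float)
        u = np.interp(r, self.r, self.u, right=0.0)
        below = r < self.r[0]
        if np.any(below):
            u = np.where(below, self.u[0] + self.f[0] * (self.r[0] - r), u)
        return np.where(r >= self.r_cut, 0.0, u)

    def interpolate(self, r):
        """Linearly interpolated (u, f) at separations r.

        Zero beyond ``r_cut``; below the first grid point the energy is
        continued linearly with slope ``-f[0]`` (a repulsive wall when the
        tabulated core force is repulsive).
        """
        r = np.asarray(r, dtype=float)
        u = np.interp(r, self.r, self.u, right=0.0)
        f = np.interp(r, self.r, self.f, right=0.0)
        below = r < self.r[0]
        if np.any(below):
            u = np.where(below, self.u[0] + self.f[0] * (self.r[0] - r), u)
            f = np.where(below, self.f[0], f)
        beyond = r >= self.r_cut
        return np.where(beyond, 0.0, u), np.where(beyond, 0.0, f)


def boltzmann_invert(r, g, kT: float = 1.0, g_floor: float = 1e-10,
                     pair: tuple = ("A", "A")) -> PotentialTable:
    """Potential of mean force u(r) = -kT ln g(r).

    Bins with ``g <= g_floor`` are marked undefined (NaN) rather than
    +inf, so downstream least-squares fits can simply drop them.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if r.size == 0:
        raise ValueError("empty RDF grid")
    if np.any(g < 0):
        raise ValueError("RDF values must be non-negative")
    u = np.full_like(g, np.nan)
    ok = g > g_floor
    u[ok] = -kT * np.log(g[ok])
    if len(r) > 1:
        with np.errstate(invalid="ignore"):
            f = -np.gradient(u, r)
    else:
        f = np.zeros_like(u)
    return PotentialTable(r, u, f, pair=pair)


def fit_cbspl(target: PotentialTable, skeleton: KnotPotential,
              fix_tail: bool = True) -> KnotPotential:
    """Least-squares fit of CBSPL knot values to a tabulated target.

    Only defined target points with ``r < r_cut`` enter the residual.
    Tail knots (and nothing else) are held at zero when ``fix_tail``;
    the system must be overdetermined on the remaining knots.
    """
    mask = target.defined & (target.r < skeleton.r_cut) & (target.r >= 0)
    r_fit = target.r[mask]
    u_fit = target.u[mask]
    n_knots = len(skeleton.knots)
    k, t = _segments(skeleton, r_fit)
    tt = np.stack([np.ones_like(t), t, t * t, t ** 3], axis=-1)
    w = tt @ (CBSPL_MATRIX / 6.0)
    design = np.zeros((len(r_fit), n_knots))
    rows = np.arange(len(r_fit))[:, None]
    design[rows, k[:, None] + np.arange(4)] = w

    pos = skeleton.positions
    tail = pos >= skeleton.r_cut - skeleton.dr - 1e-12
    cols = np.flatnonzero(~tail) if fix_tail else np.arange(n_knots)
    # knots with no support on the defined points (e.g. inside an
    # unsampled core) stay at zero instead of making the fit singular;
    # callers refresh them by extrapolation
    support = np.abs(design).sum(axis=0) > 0
    cols = cols[support[cols]]
    if len(r_fit) < len(cols):
        raise ValueError(
            f"underdetermined CBSPL fit: {len(r_fit)} target points for "
            f"{len(cols)} free knots")
    sol, *_ = np.linalg.lstsq(design[:, cols], u_fit, rcond=None)
    knots = np.zeros(n_knots)
    knots[cols] = sol
    return skeleton.with_knots(knots)


# ---------------------------------------------------------------------------
# table file I/O: '#'-prefixed header, columns "r u f", 17 significant digits

def export_table(table: PotentialTable, path) -> None:
    """Write a 3-column (r, u, f) text table; bit-stable for fixed inputs."""
    buf = io.StringIO()
    buf.write(f"# pair: {table.pair[0]}-{table.pair[1]}\n")
    buf.write(f"# r_cut: {table.r_cut!r}\n")
    buf.write("# r u f\n")
    for r, u, f in zip(table.r, table.u, table.f):
        buf.write(f"{r:.17e} {u:.17e} {f:.17e}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path) -> PotentialTable:
    pair = ("A", "A")
    r_cut = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("pair:"):
                    a, _, b = body[5:].strip().partition("-")
                    pair = (a, b)
                elif body.startswith("r_cut:"):
                    r_cut = float(body[6:])
                continue
            rows.append([float(x) for x in line.split()])
    data = np.array(rows)
    return PotentialTable(data[:, 0], data[:, 1], data[:, 2],
                          pair=pair, r_cut=r_cut)
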