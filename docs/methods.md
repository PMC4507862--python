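# Methods

This note documents the models, algorithms and numerical choices in
`cgforge`, the assumptions behind them, and what the synthetic test
systems do and do not demonstrate.

## Pair-potential representations

### Uniform cubic B-spline (CBSPL)

A CG pair potential is stored as knot values c₀…c_m on a uniform grid
r_i = i·Δr with Δr = r_cut/(m−2); the grid extends two intervals past
the cutoff, so a cutoff of n intervals carries n+3 knots (0.9/0.02 →
48 knots; 1.0/0.01 → 103; 1.32/0.02 → 69). On segment k
(r_k ≤ r < r_{k+1}, t = (r−r_k)/Δr) the energy is

    u(r) = [1 t t² t³] (1/6) M [c_k c_{k+1} c_{k+2} c_{k+3}]ᵀ,
    M = [[1,4,1,0], [-3,0,3,0], [3,-6,3,0], [-1,3,-3,1]].

Properties used throughout: partition of unity (the four basis weights
sum to 1), C² continuity, linearity in the knots (so ∂u/∂c_j is just a
basis weight and ∂²u/∂c_i∂c_j ≡ 0), and locality (a knot influences
four segments). All knots at positions r ≥ r_cut − Δr — four of them,
given the two-interval overhang — are pinned to zero, which makes both
u and f = −u′ reach zero smoothly at the cutoff; this is the precise
form chosen here for the qualitative requirement that "a couple" of
knots around the cutoff vanish. Forces are the analytic derivative of
the cubic, not finite differences.

Note an indexing subtlety of this layout: u(r_j) blends
(c_j + 4c_{j+1} + c_{j+2})/6, so control point c_j has its largest
influence around r_{j−1}, one interval to the *left* of its own grid
position. The core extrapolation below depends on getting this right.

### CKDg analytic form

The targeted optimizer uses a 6-parameter form: a shifted LJ repulsion
for r < r_c,LJ, a smoothed attraction −ε·cos²(π(r−r_c,LJ)/(2w_c)) out
to r_c,LJ + w_c, zero beyond, plus a Gaussian bump
h·exp(−(r−p)²/(2s²)) shifted to vanish at its cutoff r_c and clamped
to zero past it (finite range keeps cell lists valid). The free
parameters are σ, ε, w_c, h, p, s.

As commonly written, the piecewise form is discontinuous at r_c,LJ
(the repulsive branch reaches 0 there while the well branch starts at
−ε) and r_c,LJ is not among the optimized parameters. We therefore fix
r_c,LJ = 2^{1/6}σ (the WCA split point, where the LJ minimum sits) and
lower the repulsive branch by ε, making the potential continuous with
minimum −ε. An `as_printed=True` mode retains the discontinuous
variant for comparison. The cos² argument is read as
π(r−r_c,LJ)/(2w_c), which makes the well close smoothly at
r_c,LJ + w_c.

## Sampling

Observables driving both optimizers — RDFs, the virial pressure,
ensemble averages of ∂U/∂λ — are purely configurational, so the
sampler is a Metropolis NVT Monte-Carlo chain rather than an MD
integrator: single-particle displacements (uniform in a cube of half
width `max_disp`), plus rigid-body translations and rotations (uniform
axis, angle ~ U(−θ_max, θ_max), about the molecule's unwrapped
centroid) for multi-site molecules, in a cubic periodic box with
minimum-image distances. Bonded degrees of freedom are frozen — the
toy references are rigid molecules by construction. Any external XYZ
trajectory can be substituted for the built-in sampler
(`read_xyz`), which is the "bring your own engine" entry point.

Numerics: pair energies are linear interpolations of tabulated (r, u,
f) columns on a grid augmented with an exact zero at the cutoff and a
linear repulsive continuation below the first tabulated point; the
same augmented grid backs the incremental ΔU bookkeeping and the full
O(N²) recomputation, which is cross-checked every 10³ accepted moves
(observed drift ≲ 1e-12, asserted < 1e-8). Chains are fully
reproducible from an integer seed (one PCG64 stream; random draws are
pre-blocked per chain). The first 25% of each chain is discarded as
equilibration by default, mirroring the discard fractions of typical
per-iteration CG runs; recorded frames are then taken at a fixed
stride.

The virial pressure is P = ρ k_B T + ⟨Σ_{i<j} f(r_ij)·r_ij⟩/(3V) with
ρ counting independently moving units (molecules when a topology is
given). No tail correction is applied because every potential vanishes
at its cutoff by construction.

## Mapping and analysis

CG beads sit at the mass-weighted mean of their site group, computed
after unwrapping each molecule around its first site (averaging
wrapped coordinates across a periodic boundary is wrong); a molecule
spanning more than half the box is rejected as ambiguous. RDFs use
half-open bins assigned by floor(r/Δ), reported at bin centers,
normalized per frame by the ideal-gas shell count with pair densities
N(N−1)/2/V (like pairs) and N_A·N_B/V (unlike pairs) — the
cross-species convention is declared, not inherited. r_max beyond L/2
is rejected (image ambiguity).

Neighbor lists come in two exact-equivalent flavors: an O(N²)
minimum-image double loop and an O(N) cell list (cell edge ≥ cutoff,
26 periodic neighbor cells, falling back to the simple search below 3
cells per edge). Equivalence is property-tested on randomized frames;
the expected 2-vs-1 log-log time scaling is verified as a trend on
N = 1000–4000 particles.

Frame-parallel analysis is a contract, not a thread implementation:
any pure per-frame function with an associative merge may be fanned
out over workers; partials are merged in frame order, so integer
histograms are bit-identical for every worker count and float
accumulators agree to rounding. The RDF uses this path for its
histogram counts.

## Relative-entropy minimization

In the canonical ensemble, minimizing the relative entropy between the
mapped reference ensemble and the CG model over parameters λ needs
only the ensemble averages of ∂U_CG/∂λ:

    ∇_λ S_rel = β⟨∂U/∂λ⟩_ref − β⟨∂U/∂λ⟩_CG
    H_ij = β⟨∂²U/∂λ_i∂λ_j⟩_ref − β⟨∂²U/∂λ_i∂λ_j⟩_CG
           + β²⟨(∂U/∂λ_i)(∂U/∂λ_j)⟩_CG − β²⟨∂U/∂λ_i⟩_CG⟨∂U/∂λ_j⟩_CG

with U = Σ_{i<j} u(r_ij). For CBSPL the second-derivative terms vanish
and H = β²·Cov_CG of the per-frame derivative sums: symmetric PSD,
hence a single global minimum. Absolute S_rel values (free-energy and
mapping-entropy constants) are never computed — they are constant in λ
and irrelevant to the optimization.

Per iteration: sample the CG ensemble with the current potentials
(seed = base + iteration index, recorded for exact reruns), accumulate
⟨∂U/∂λ⟩ and second moments, take the relaxed Newton step
λ ← λ − χH⁻¹∇ via Cholesky factorization over the free knots only.
The reference-side averages are independent of λ for the spline form
and are computed once and cached. The reweighting alternative to
per-iteration resampling is deliberately not implemented; fresh
resampling is simpler and unbiased.

Stability measures, in order of importance:

* **Frozen core.** Knots at r ≤ r_min never enter the update (their
  rows of H would be zero — unsampled). r_min defaults to the first
  nonzero bin of a *finely binned* reference RDF; a coarse bin rounds
  the sampling onset upward and anchors the extrapolation in the
  shallow region near the potential's zero crossing, which is exactly
  where the exponential continuation misbehaves (see below). Pairs at
  r ≤ r_min are also skipped during accumulation.
* **Core extrapolation.** After each update the core is refreshed by
  continuing the potential from the first knot position above r_min
  (value u₀ and slope u₀′ there depend only on free knots, avoiding
  circular dependence on stale core values) with A·e^{−Br},
  B = −u₀′/u₀. Core control points are set from the extrapolant at
  each knot's quasi-interpolation center r_{j−1}; since the control
  sequence is then monotone, the variation-diminishing property makes
  the spline monotonically repulsive on the core, and nothing at or
  above the anchor changes. Exact interpolation by back-substitution
  was rejected: the recurrence amplifies boundary mismatch by ≈3.7 per
  knot and oscillates on fine grids. When the anchor is not repulsive
  (u₀ ≤ 0 or u₀′ ≥ 0) or sits so close to the zero crossing that
  B·Δr > 10, the continuation is linear instead (with a warning) —
  an exponential anchored at u₀ → 0⁺ would overflow within a few
  knots.
* **Ridge guard.** If the free-knot Hessian fails Cholesky, a ridge
  τI with τ = 1e-8·tr(H)/n is added once; failure after that aborts
  with a diagnostic rather than stepping into garbage.
* **Divergence guard.** If ε_tot grows three iterations in a row, χ is
  halved and the step restarts from the best iterate so far; after
  three halvings the run aborts as non-converged.

Convergence errors are plain sums of squares (no square roots):
ε_λ = Σ(Δλ)² over the *optimized* parameters, ε_u = ΣΣ(Δu)² over the
optimized range (r_min, r_cut), ε_tot = w_λε_λ + w_uε_u. Restricting
both to the optimized region is a deliberate reading of "parameters to
be optimized": the frozen extrapolated core can reach thousands of kT
and would otherwise drown the signal. Defaults w_λ = 0, w_u = 1 (the
potential error is the quantity of scientific interest); χ defaults
to 1 with the halving guard; the trailing average over the last 5
iterates is returned because the iteration is stochastic and jitters
around the minimum at the sampling-noise level. The initial guess is a
least-squares CBSPL fit to the Boltzmann-inverted reference RDF
(PMF), with undefined bins (g ≤ 10⁻¹⁰) dropped rather than set to +∞,
knots without support on defined points left at zero, and the core
extrapolated.

## Targeted (downhill-simplex) optimization

The polytope of n+1 vertices is transformed by reflection (α = 1),
expansion (γ = 2), contraction and reduction (ρ = σ = 0.5); the
contraction range is 0 < ρ < 1 and the reduction p_i → σ(p_i + p_1) is
applied exactly as stated (identical to the conventional midpoint
shrink at σ = 0.5; for other σ the stated form is used and logged).
The decision flow differs from textbook Nelder–Mead in one documented
respect: contraction triggers on y_r > y_{n+1} — strictly against the
worst vertex, where the textbook rule uses the second worst — so a
constant objective accepts
the reflected point rather than contracting. Expansion acceptance
(left open in the original description) keeps p_e only if y_e < y_r.

The penalty is Σ|g_CG(r_i) − g_ref(r_i)| over a configurable bin range
plus a·|p_CG − p_ref|; a = 0 is structure-only mode. Each evaluation
builds the CKDg table, greedily relaxes the shared start configuration
(a zero-temperature chain standing in for an energy minimization — an
expansion move can produce parameters under which the start
configuration is highly strained), samples, and measures. Two
noise-control choices: common random numbers (one sampler seed per
polytope step, shared by all candidate evaluations in that step) to
reduce misordering, and rejection bounds (σ, ε, w_c, s > 0 enforced by
+∞ penalty, as is any evaluator failure, which is logged). Because
surviving vertices keep their penalties, the best-vertex penalty is
monotonically non-increasing by construction.

The optimizer state round-trips through a line-based text file
(header with n, coefficients, iteration; one `id status params…
penalty` record per vertex, `nan` for pending), which is what lets an
external engine be slotted into the evaluate/communicate cycle via the
`simplex-init` / `simplex-eval` / `simplex-update` commands. A CMA-ES
or other optimizer could be slotted behind the same state-file
contract; only the simplex is implemented.

## Synthetic reference systems

The fixtures emulate the *role* of an all-atom reference (an ensemble
to map and match), not its chemistry: an LJ-like fluid (CKD form,
σ = ε = 1, w_c = 0.5, reduced units), rigid dimers, rigid trimers with
a heavy core and two light satellites (a water-like 16:1:1 mass
split), and a binary mixture with three distinct pair interactions.
Defaults — 60 molecules at number density 0.45, T = 1, 1.5·10⁵ MC
moves, stride 250 — keep a fixture under ~10 s on one core while
holding per-bin RDF noise near 0.01, an order of magnitude below the
0.1 recovery tolerance. Recovery experiments are *self-target* tests:
the ground truth is known, so success is "the optimizer reproduces the
reference structure from its own samples", checked as max per-bin RDF
deviation < 0.1 (relative entropy) or best penalty at the target's
self-noise level (simplex).

What these tests do not show: real molecular references have
intramolecular flexibility, long-range electrostatics, many-body
correlations and much larger system sizes; passing here demonstrates
the correctness of the optimization machinery and its statistical
behavior at desk scale, not the physical quality of CG models for any
real liquid. The spline cutoff must also cover the true interaction
range — with a 1.6 cutoff on a truth of range ≈1.62 the recovery
plateaus at a visible tail error, which is why the recovery studies
use r_cut = 1.8.

## Model layer

`RelativeEntropyCG` / `TargetedCG` wrap these loops statsmodels-style:
model object from reference data, `fit()` returning a Results object
with the estimates, an uncertainty proxy, diagnostics and
`summary()`. The uncertainty proxies are deliberately modest: for the
spline fit, a delta-method propagation of the gradient's Monte-Carlo
standard error through the final Hessian (H⁻¹ diag(se²) H⁻¹); for the
simplex, the parameter spread of the final polytope — the optimizer's
own resolution, not a statistical confidence interval.

## Known limitations

* The MC sampler is serial and O(N) per move; it is sized for ≤ a few
  hundred particles, which is the design point of the whole package.
* Newton iterations do not converge to a sharp tolerance: with
  stochastic gradients, ε_tot plateaus at the sampling-noise level and
  runs typically end at max_iter with the trailing average returned
  (flagged `converged: False`). More frames per iteration, not more
  iterations, is the lever.
* r_min estimation is histogram-based; in pathological cases (a single
  stray close pair) it can be set too low, putting a barely sampled
  knot into the update. The symptom is a near-singular Hessian (the
  ridge warning); the remedy is passing r_min explicitly.
* Cross-species RDF normalization and the parallel merge contract are
  this package's declared conventions; files produced by other tools
  should be checked against them before use as targets.
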