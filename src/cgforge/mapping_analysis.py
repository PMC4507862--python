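"""COM mapping, neighbor search and RDF analysis of trajectories.

* :func:`map_com` maps a fine-grained frame onto CG beads at the
  mass-weighted center of each declared site group, unwrapping each
  molecule around its first site before averaging (a mass-weighted mean
  of wrapped coordinates is wrong across periodic boundaries).
* :func:`neighbor_simple` / :func:`neighbor_grid` build cutoff neighbor
  lists by exhaustive O(N^2) pair testing and by an O(N) cell-list
  decomposition respectively; both return identical pair sets.
* :func:`compute_rdf` accumulates species-pair radial distribution
  functions, serially or frame-parallel through
  :func:`parallel_map_frames`, whose merge contract guarantees the
  parallel result equals the serial fold regardless of worker count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .sampler import Frame, Topology, minimum_image

__all__ = [
    "RDF", "NeighborPairs",
    "map_com", "neighbor_simple", "neighbor_grid",
    "compute_rdf", "parallel_map_frames",
    "write_rdf", "read_rdf",
]

log = logging.getLogger(__name__)


@dataclass
class RDF:
    """Radial distribution function on uniform half-open bins."""

    edges: np.ndarray
    g: np.ndarray
    pair: tuple = ("A", "A")
    frames: int = 0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("RDF bins must be uniform")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def r(self) -> np.ndarray:
        """Bin centers."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class NeighborPairs:
    """Unordered particle index pairs (i < j) within a cutoff."""

    pairs: np.ndarray  # (n, 2) int array, i < j, lexicographically sorted

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        p = np.sort(p, axis=1)
        if len(p):
            p = np.unique(p, axis=0)
        self.pairs = p

    def __len__(self):
        return len(self.pairs)

    def as_set(self):
        return {tuple(row) for row in self.pairs}

    def __eq__(self, other):
        return np.array_equal(self.pairs, other.pairs)


def map_com(frame: Frame, topo: Topology) -> Frame:
    """Map a frame to CG beads at the COM of each declared site group.

    Sites are unwrapped around the molecule's first site before the
    mass-weighted mean is taken, then the bead is rewrapped into the
    box.  A molecule whose unwrapped extent exceeds half the box is
    rejected — its periodic image assignment would be ambiguous.
    """
    site_species, masses, _, groups = topo.expand()
    if len(site_species) != frame.n:
        raise ValueError("frame size does not match topology site count")
    if not np.array_equal(site_species, frame.species):
        raise ValueError("frame species do not match topology layout")
    bead_pos, bead_species = [], []
    half = 0.5 * frame.L
    for _, mtype, idx in groups:
        anchor = frame.positions[idx[0]]
        delta = minimum_image(frame.positions[idx] - anchor, frame.L)
        if np.any(np.abs(delta) > half):
            raise ValueError("molecule spans more than half the box; "
                             "image assignment is ambiguous")
        unwrapped = anchor + delta
        for bead, bsp in zip(mtype.beads, mtype.bead_species):
            m = masses[idx[bead]]
            bead_pos.append((m[:, None] * unwrapped[bead]).sum(axis=0)
                            / m.sum())
            bead_species.append(bsp)
    return Frame(np.array(bead_pos), np.array(bead_species), frame.L,
                 step=frame.step, index=frame.index)


def neighbor_simple(frame: Frame, cutoff: float,
                    chunk: int = 1000) -> NeighborPairs:
    """Exhaustive O(N^2) neighbor search with minimum-image distances."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = frame.positions
    n = len(pos)
    found = []
    c2 = cutoff * cutoff
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = pos[start:stop]
        d = minimum_image(pos[None, :, :] - block[:, None, :], frame.L)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        ii, jj = np.nonzero(r2 <= c2)
        ii = ii + start
        keep = ii < jj
        found.append(np.column_stack([ii[keep], jj[keep]]))
    if not found:
        return NeighborPairs(np.empty((0, 2), dtype=np.intp))
    return NeighborPairs(np.concatenate(found))


def neighbor_grid(frame: Frame, cutoff: float) -> NeighborPairs:
    """Cell-list O(N) neighbor search, identical in result to the simple
    search.

    The box is decomposed into cells of edge >= cutoff and pairs are
    collected from each cell and its 26 periodic neighbors.  Boxes
    thinner than 3 cells per edge fall back to the simple search.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_cells = int(frame.L / cutoff)
    if n_cells < 3:
        log.info("box of %d cells per edge (<3): falling back to simple "
                 "neighbor search", n_cells)
        return neighbor_simple(frame, cutoff)
    pos = frame.positions
    n = len(pos)
    if n == 0:
        return NeighborPairs(np.empty((0, 2), dtype=np.intp))
    cell_of = np.floor(pos / frame.L * n_cells).astype(np.intp)
    cell_of = np.minimum(cell_of, n_cells - 1)
    flat = (cell_of[:, 0] * n_cells + cell_of[:, 1]) * n_cells + cell_of[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(n_cells ** 3))
    ends = np.searchsorted(sorted_flat, np.arange(n_cells ** 3), side="right")

    offsets = np.array([(dx, dy, dz)
                        for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                        for dz in (-1, 0, 1)])
    c2 = cutoff * cutoff
    found = []
    for cell in range(n_cells ** 3):
        members = order[starts[cell]:ends[cell]]
        if len(members) == 0:
            continue
        cx, cy, cz = (cell // (n_cells * n_cells),
                      (cell // n_cells) % n_cells, cell % n_cells)
        neigh_cells = ((np.array([cx, cy, cz]) + offsets) % n_cells)
        neigh_flat = np.unique(
            (neigh_cells[:, 0] * n_cells + neigh_cells[:, 1]) * n_cells
            + neigh_cells[:, 2])
        cand = np.concatenate([order[starts[c]:ends[c]]
                               for c in neigh_flat])
        d = minimum_image(pos[cand][None, :, :] - pos[members][:, None, :],
                          frame.L)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        ii, jj = np.nonzero(r2 <= c2)
        a, b = members[ii], cand[jj]
        keep = a < b
        if keep.any():
            found.append(np.column_stack([a[keep], b[keep]]))
    if not found:
        return NeighborPairs(np.empty((0, 2), dtype=np.intp))
    return NeighborPairs(np.concatenate(found))


# ---------------------------------------------------------------------------
# RDF

@dataclass(frozen=True)
class _PairDistanceHistogram:
    """Per-frame pair-distance histogram: a pure, picklable frame analysis.

    Bins are half-open [r_i, r_{i+1}) assigned by floor(r / width);
    distances at or beyond r_max are excluded.
    """

    species_a: str
    species_b: str
    r_max: float
    width: float

    @property
    def n_bins(self) -> int:
        return int(round(self.r_max / self.width))

    def __call__(self, frame: Frame) -> np.ndarray:
        ia = np.flatnonzero(frame.species == self.species_a)
        if self.species_a == self.species_b:
            if len(ia) < 2:
                return np.zeros(self.n_bins, dtype=np.int64)
            ii, jj = np.triu_indices(len(ia), k=1)
            d = minimum_image(frame.positions[ia[jj]]
                              - frame.positions[ia[ii]], frame.L)
        else:
            ib = np.flatnonzero(frame.species == self.species_b)
            if len(ia) == 0 or len(ib) == 0:
                return np.zeros(self.n_bins, dtype=np.int64)
            d = minimum_image(frame.positions[ib][None, :, :]
                              - frame.positions[ia][:, None, :], frame.L)
            d = d.reshape(-1, 3)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        idx = np.floor(r / self.width).astype(np.intp)
        idx = idx[(idx >= 0) & (idx < self.n_bins)]
        return np.bincount(idx, minlength=self.n_bins).astype(np.int64)


def _add(a, b):
    return a + b


def compute_rdf(traj, pair, r_max: float, bin_width: float,
                mode: str = "serial", n_workers: int = 1) -> RDF:
    """Species-pair RDF averaged over the frames of a trajectory.

    The histogram of minimum-image pair distances is normalized per
    frame by the ideal-gas shell count
    ``n_id = rho_pair * (4 pi / 3) ((r + w)^3 - r^3)`` with the pair
    density ``N (N - 1) / 2 / V`` for like pairs and ``N_A N_B / V``
    for unlike pairs.  ``r_max`` may not exceed half the box (image
    ambiguity).
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    L = frames[0].L
    if r_max > 0.5 * L + 1e-12:
        raise ValueError(f"r_max = {r_max} exceeds half the box L/2 = "
                         f"{L / 2}")
    a, b = pair
    hist = _PairDistanceHistogram(a, b, float(r_max), float(bin_width))
    if mode == "parallel" and n_workers > 1:
        counts = parallel_map_frames(frames, hist, _add, n_workers)
    else:
        counts = reduce(_add, (hist(f) for f in frames))

    V = L ** 3
    na = int((frames[0].species == a).sum())
    if a == b:
        pair_density = na * (na - 1) / 2.0 / V
    else:
        nb = int((frames[0].species == b).sum())
        pair_density = na * nb / V
    edges = bin_width * np.arange(hist.n_bins + 1)
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_id = pair_density * shell
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(n_id > 0, counts / len(frames) / n_id, 0.0)
    return RDF(edges, g, pair=(a, b), frames=len(frames))


def parallel_map_frames(traj, frame_fn, merge, n_workers: int = 1):
    """Apply a pure per-frame analysis and merge partial results.

    ``merge`` must be associative; partials are merged in frame order,
    so the result equals the serial fold exactly (bit-identical for
    integer accumulators) for every worker count.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("no frames to analyze")
    if n_workers <= 1:
        partials = [frame_fn(f) for f in frames]
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            chunk = max(1, len(frames) // (4 * n_workers))
            partials = list(pool.map(frame_fn, frames, chunksize=chunk))
    try:
        return reduce(merge, partials)
    except TypeError as exc:
        raise ValueError(f"non-mergeable partial results: {exc}") from exc


# ---------------------------------------------------------------------------
# RDF file I/O: 2-column "r g" text with '#' header

def write_rdf(rdf: RDF, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pair: {rdf.pair[0]}-{rdf.pair[1]}\n")
        fh.write(f"# frames: {rdf.frames}\n")
        fh.write(f"# bin_width: {rdf.bin_width!r}\n")
        fh.write("# r g\n")
        for r, g in zip(rdf.r, rdf.g):
            fh.write(f"{r:.17e} {g:.17e}\n")


def read_rdf(path) -> RDF:
    pair = ("A", "A")
    frames = 0
    width = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("pair:"):
                    x, _, y = body[5:].strip().partition("-")
                    pair = (x, y)
                elif body.startswith("frames:"):
                    frames = int(body[7:])
                elif body.startswith("bin_width:"):
                    width = float(body[10:])
                continue
            rows.append([float(x) for x in line.split()])
    data = np.array(rows)
    r, g = data[:, 0], data[:, 1]
    if width is None:
        width = float(r[1] - r[0])
    # rebuild the uniform edge grid exactly as width * integer index so
    # that write -> read round trips are bit-identical (bin centers are
    # recomputed from these edges with the same arithmetic)
    i0 = int(round(r[0] / width - 0.5))
    edges = width * np.arange(i0, i0 + len(r) + 1)
    return RDF(edges, g, pair=pair, frames=frames)
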