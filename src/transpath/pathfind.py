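"""Two-round transition-pathway search on a 2D free-energy surface.

Round one relaxes randomly initialized elastic bands (7 beads, endpoints
fixed at the two basins) under the perpendicular component of the landscape
gradient plus elastic forces, repeated 100 times for each of four spring
constants (0.3, 0.6, 0.9, 1.2).  Round two runs 50 Metropolis-style grid
walks accepting moves with probability min(1, exp(-dG / kBT)).  Of the 450
candidate paths the one with the lowest free-energy barrier is the
transition pathway and its peak is the transition state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import KB
from .cgsim.metad import FreeEnergySurface
from .structio import pairwise_ca_distances

__all__ = [
    "CandidatePath",
    "PathSearchResult",
    "PathSearchConfig",
    "neb_search",
    "stochastic_walk",
    "two_round_search",
    "extract_ts_ensemble",
    "locate_basins",
    "WalkFailed",
]

DEFAULT_SPRINGS = (0.3, 0.6, 0.9, 1.2)


class WalkFailed(RuntimeError):
    """A stochastic walk did not reach the target basin; reseed and retry."""


@dataclass(frozen=True)
class CandidatePath:
    """One candidate pathway as a polyline in CV space."""

    nodes: np.ndarray          # (k, 2) CV points
    f_values: np.ndarray       # (k,) interpolated free energy
    barrier: float             # max F on path minus F at start
    method: str                # "NEB" or "walk"
    params: dict = field(default_factory=dict)

    @property
    def ts_index(self) -> int:
        return int(np.argmax(self.f_values))

    @property
    def ts_location(self) -> tuple:
        return tuple(self.nodes[self.ts_index])

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.nodes, axis=0),
                                           axis=1)))


@dataclass(frozen=True)
class PathSearchResult:
    candidates: tuple          # of CandidatePath
    best: CandidatePath
    ts_location: tuple


@dataclass(frozen=True)
class PathSearchConfig:
    """Defaults follow the published two-round protocol (450 candidates)."""

    n_beads: int = 7
    neb_iters: int = 1000
    n_neb_repeats: int = 100
    springs: tuple = DEFAULT_SPRINGS
    n_walks: int = 50
    #: walk temperature in K; None scales it to the landscape relief
    #: (kB T = max F / 4), since the walk is a search heuristic and must
    #: be able to climb the surface it is given
    walk_temperature: float | None = None
    walk_max_steps: int = 400_000
    seed: int = 0


# ---------------------------------------------------------------------------
# interpolation helpers
# ---------------------------------------------------------------------------

def _bilinear(values: np.ndarray, x_edges, y_edges, pts: np.ndarray):
    """Vectorized bilinear interpolation of grid values at (k, 2) points."""
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    fx = np.clip((pts[..., 0] - x_edges[0]) / dx, 0, len(x_edges) - 1.0001)
    fy = np.clip((pts[..., 1] - y_edges[0]) / dy, 0, len(y_edges) - 1.0001)
    i0 = fx.astype(int)
    j0 = fy.astype(int)
    tx = fx - i0
    ty = fy - j0
    v00 = values[i0, j0]
    v10 = values[i0 + 1, j0]
    v01 = values[i0, j0 + 1]
    v11 = values[i0 + 1, j0 + 1]
    return ((1 - tx) * (1 - ty) * v00 + tx * (1 - ty) * v10
            + (1 - tx) * ty * v01 + tx * ty * v11)


def _check_inside(fes: FreeEnergySurface, point, name: str):
    x, y = point
    if not (fes.cv1_edges[0] <= x <= fes.cv1_edges[-1]
            and fes.cv2_edges[0] <= y <= fes.cv2_edges[-1]):
        raise ValueError(f"{name} point {point} lies outside the grid")


def _path_f_values(fes: FreeEnergySurface, nodes: np.ndarray,
                   points_per_cell: float = 4.0):
    """Densify a polyline to sub-cell resolution and interpolate F along it."""
    cell = min(fes.spacing)
    dense = [nodes[0]]
    for p, q in zip(nodes[:-1], nodes[1:]):
        seg = np.linalg.norm(q - p)
        k = max(int(np.ceil(seg / cell * points_per_cell)), 1)
        t = np.linspace(0, 1, k + 1)[1:]
        dense.extend(p + t[:, None] * (q - p))
    dense = np.asarray(dense)
    f = _bilinear(fes.F, fes.cv1_edges, fes.cv2_edges, dense)
    return dense, f


def _make_candidate(fes, nodes, method, params) -> CandidatePath:
    dense, f = _path_f_values(fes, np.asarray(nodes, dtype=float))
    barrier = float(f.max() - f[0])
    return CandidatePath(nodes=dense, f_values=f, barrier=barrier,
                         method=method, params=params)


def cell_f_range(fes: FreeEnergySurface) -> float:
    """Largest free-energy variation across a single grid cell.

    The natural resolution limit for comparing path barriers computed on
    the surface: differences smaller than one cell's F-range are not
    meaningful on the grid.
    """
    F = fes.F
    corners = np.stack([F[:-1, :-1], F[1:, :-1], F[:-1, 1:], F[1:, 1:]])
    return float((corners.max(axis=0) - corners.min(axis=0)).max())


def locate_basins(fes: FreeEnergySurface):
    """Return the CV coordinates of the two lowest separated local minima.

    A local minimum is a grid node not higher than its 4-neighbors; raises
    if fewer than two distinct minima exist (basins not separable).
    """
    F = fes.F
    padded = np.pad(F, 1, constant_values=np.inf)
    core = padded[1:-1, 1:-1]
    is_min = (
        (core <= padded[:-2, 1:-1]) & (core <= padded[2:, 1:-1])
        & (core <= padded[1:-1, :-2]) & (core <= padded[1:-1, 2:])
    )
    ii, jj = np.where(is_min)
    if len(ii) == 0:
        raise ValueError("no local minima on the surface")
    cand = sorted(zip(F[ii, jj], ii, jj))
    mins = []
    min_sep = max(F.shape) // 8
    for f, i, j in cand:
        if all(abs(i - i2) + abs(j - j2) > min_sep for _, i2, j2 in mins):
            mins.append((f, i, j))
        if len(mins) == 2:
            break
    if len(mins) < 2:
        raise ValueError("basins not separable: only one minimum found")
    return tuple(
        (float(fes.cv1_edges[i]), float(fes.cv2_edges[j]))
        for _, i, j in mins
    )


# ---------------------------------------------------------------------------
# round 1: elastic band relaxation
# ---------------------------------------------------------------------------

def _neb_batch(fes: FreeEnergySurface, start, end, k_spring: float,
               n_restarts: int, n_beads: int, iters: int,
               rng: np.random.Generator) -> np.ndarray:
    """Relax ``n_restarts`` randomly initialized bands at once.

    Returns bead polylines of shape (R, n_beads, 2).  Interior beads feel
    the perpendicular component of the landscape gradient plus a full
    elastic force (which straightens kinked initializations on flat
    regions); displacement per iteration is capped at a fraction of a grid
    cell that decays over the schedule.
    """
    if not np.all(np.isfinite(fes.F)):
        raise ValueError("non-finite free energy on the surface")
    gx, gy = np.gradient(fes.F, fes.cv1_edges, fes.cv2_edges)
    lo = np.array([fes.cv1_edges[0], fes.cv2_edges[0]])
    hi = np.array([fes.cv1_edges[-1], fes.cv2_edges[-1]])
    cell = min(fes.spacing)

    beads = rng.uniform(lo, hi, size=(n_restarts, n_beads, 2))
    beads[:, 0] = start
    beads[:, -1] = end

    for it in range(iters):
        g = np.stack([
            _bilinear(gx, fes.cv1_edges, fes.cv2_edges, beads[:, 1:-1]),
            _bilinear(gy, fes.cv1_edges, fes.cv2_edges, beads[:, 1:-1]),
        ], axis=-1)
        tau = beads[:, 2:] - beads[:, :-2]
        tau /= np.linalg.norm(tau, axis=-1, keepdims=True) + 1e-12
        g_par = np.sum(g * tau, axis=-1, keepdims=True) * tau
        f_land = -(g - g_par)
        f_el = k_spring * (beads[:, 2:] - 2 * beads[:, 1:-1] + beads[:, :-2])
        f = f_land + f_el

        fmax = np.max(np.linalg.norm(f, axis=-1), axis=(1,), keepdims=True)
        step = cell * (0.25 - 0.225 * it / iters)
        scale = step / (fmax[..., None] + 1e-12)
        beads[:, 1:-1] = np.clip(beads[:, 1:-1] + scale * f, lo, hi)
    return beads


def neb_search(fes: FreeEnergySurface, start, end, k_spring: float,
               n_beads: int = 7, iters: int = 1000,
               seed: int = 0) -> CandidatePath:
    """Single elastic-band relaxation with randomly placed interior beads."""
    _check_inside(fes, start, "start")
    _check_inside(fes, end, "end")
    rng = np.random.default_rng(seed)
    beads = _neb_batch(fes, np.asarray(start, float), np.asarray(end, float),
                       k_spring, 1, n_beads, iters, rng)[0]
    return _make_candidate(fes, beads, "NEB",
                           {"k_spring": k_spring, "seed": seed})


# ---------------------------------------------------------------------------
# round 2: stochastic grid walk
# ---------------------------------------------------------------------------

@njit(cache=True)
def _walk_kernel(F, si, sj, ei, ej, kt, max_steps, seed):
    np.random.seed(seed)
    n1, n2 = F.shape
    pi = np.empty(max_steps + 1, np.int32)
    pj = np.empty(max_steps + 1, np.int32)
    pi[0], pj[0] = si, sj
    count = 1
    ci, cj = si, sj
    for _ in range(max_steps):
        move = np.random.randint(4)
        ni, nj = ci, cj
        if move == 0:
            ni += 1
        elif move == 1:
            ni -= 1
        elif move == 2:
            nj += 1
        else:
            nj -= 1
        if ni < 0 or ni >= n1 or nj < 0 or nj >= n2:
            continue
        dg = F[ni, nj] - F[ci, cj]
        if dg <= 0.0 or np.random.random() < np.exp(-dg / kt):
            ci, cj = ni, nj
            pi[count], pj[count] = ci, cj
            count += 1
            if ci == ei and cj == ej:
                return pi[:count], pj[:count], True
    return pi[:count], pj[:count], False


def _prune_loops(pi: np.ndarray, pj: np.ndarray):
    """Cut revisits: on returning to a cell, discard the loop in between."""
    seen: dict = {}
    keep_i: list = []
    keep_j: list = []
    for i, j in zip(pi.tolist(), pj.tolist()):
        key = (i, j)
        if key in seen:
            k = seen[key]
            for drop in zip(keep_i[k + 1:], keep_j[k + 1:]):
                seen.pop(drop, None)
            del keep_i[k + 1:]
            del keep_j[k + 1:]
        else:
            seen[key] = len(keep_i)
            keep_i.append(i)
            keep_j.append(j)
    return np.array(keep_i), np.array(keep_j)


def stochastic_walk(fes: FreeEnergySurface, start, end,
                    temperature: float = 110.0, seed: int = 0,
                    max_steps: int = 400_000) -> CandidatePath:
    """Metropolis grid walk from start to end.

    From the current cell a uniformly chosen 4-neighbor is accepted with
    probability min(1, exp(-dG / kBT)); downhill moves are always accepted.
    Self-intersections are pruned from the returned path.  Raises
    :class:`WalkFailed` if the end cell is not reached in ``max_steps``
    proposals (callers reseed and retry).
    """
    _check_inside(fes, start, "start")
    _check_inside(fes, end, "end")
    if KB * temperature <= 0:
        raise ValueError("temperature must be positive")
    si, sj = _nearest_node(fes, start)
    ei, ej = _nearest_node(fes, end)
    pi, pj, ok = _walk_kernel(fes.F, si, sj, ei, ej, KB * temperature,
                              max_steps, seed % (2 ** 31))
    if not ok:
        raise WalkFailed(f"walk (seed {seed}) did not reach the end basin "
                         f"within {max_steps} proposals")
    pi, pj = _prune_loops(pi, pj)
    nodes = np.stack([fes.cv1_edges[pi], fes.cv2_edges[pj]], axis=1)
    f = fes.F[pi, pj]
    return CandidatePath(nodes=nodes, f_values=f,
                         barrier=float(f.max() - f[0]),
                         method="walk", params={"seed": seed,
                                                "temperature": temperature})


def _nearest_node(fes: FreeEnergySurface, point):
    return (int(np.argmin(np.abs(fes.cv1_edges - point[0]))),
            int(np.argmin(np.abs(fes.cv2_edges - point[1]))))


# ---------------------------------------------------------------------------
# the two-round search
# ---------------------------------------------------------------------------

def two_round_search(fes: FreeEnergySurface, start=None, end=None,
                     config: PathSearchConfig | None = None) -> PathSearchResult:
    """Full two-round search: elastic-band restarts plus stochastic walks.

    Under default parameters this produces exactly
    ``100 restarts x 4 spring constants + 50 walks = 450`` candidates.
    The best path has the lowest barrier; ties are broken by shorter arc
    length, then lower mean free energy.  Failed walks are reseeded until
    the requested number of successes.
    """
    if config is None:
        config = PathSearchConfig()
    if start is None or end is None:
        basins = locate_basins(fes)
        start = start if start is not None else basins[0]
        end = end if end is not None else basins[1]
    else:
        locate_basins(fes)  # raises if the surface has a single minimum
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    _check_inside(fes, start, "start")
    _check_inside(fes, end, "end")

    rng = np.random.default_rng(config.seed)
    walk_temperature = config.walk_temperature
    if walk_temperature is None:
        walk_temperature = max(float(fes.F.max()) / (4.0 * KB), 1.0)
    candidates: list[CandidatePath] = []

    for k_spring in config.springs:
        beads = _neb_batch(fes, start, end, k_spring,
                           config.n_neb_repeats, config.n_beads,
                           config.neb_iters, rng)
        for r in range(config.n_neb_repeats):
            candidates.append(
                _make_candidate(fes, beads[r], "NEB",
                                {"k_spring": k_spring, "repeat": r}))

    n_ok = 0
    attempt = 0
    while n_ok < config.n_walks:
        seed = int(rng.integers(2 ** 31))
        attempt += 1
        if attempt > 20 * config.n_walks:
            raise RuntimeError("too many failed walks; raise max_steps or "
                               "the walk temperature")
        try:
            cand = stochastic_walk(fes, start, end,
                                   temperature=walk_temperature,
                                   seed=seed,
                                   max_steps=config.walk_max_steps)
        except WalkFailed:
            continue
        candidates.append(cand)
        n_ok += 1

    best = min(candidates,
               key=lambda c: (c.barrier, c.arc_length,
                              float(np.mean(c.f_values))))
    return PathSearchResult(candidates=tuple(candidates), best=best,
                            ts_location=best.ts_location)


# ---------------------------------------------------------------------------
# transition-state ensemble
# ---------------------------------------------------------------------------

def extract_ts_ensemble(frames: np.ndarray, cv_series: np.ndarray,
                        ts_location, window: float = 0.08):
    """Mean pairwise distance matrix over frames near the transition state.

    Frames whose CVs fall within ``+-window`` (nm) of ``ts_location`` in
    both collective variables are averaged; returns ``(mean_matrix,
    frame_indices)``.  Raises if the window is empty.
    """
    frames = np.asarray(frames)
    cv_series = np.asarray(cv_series)
    if frames.shape[0] != cv_series.shape[0]:
        raise ValueError("frames and cv_series lengths differ")
    ts = np.asarray(ts_location, dtype=float)
    sel = np.all(np.abs(cv_series - ts) <= window, axis=1)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(
            "no frames fall inside the transition-state window; sample "
            "longer or widen the window"
        )
    mean = np.zeros((frames.shape[1], frames.shape[1]))
    for k in idx:
        mean += pairwise_ca_distances(frames[k])
    mean /= idx.size
    return mean, idx
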