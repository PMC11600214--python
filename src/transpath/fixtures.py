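"""Synthetic data generators and brute-force oracles.

Everything the test-suite needs without downloads: ideal-geometry two-state
hinge proteins with known ground truth, analytic 2D landscapes with exact
saddles, smooth random landscapes, an exhaustive minimax-path oracle, and a
rule-based training corpus for the distance-matrix models.

Every fixture ships with its ground truth computed by an independent code
path (plain double loops, closed forms) rather than by the module it is
meant to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structio import CaStructure, StatePair, superpose_rmsd
from .cgsim.metad import FreeEnergySurface
from .constants import AA_ORDER

__all__ = [
    "ToyTwoState",
    "AnalyticLandscape",
    "make_toy_two_state",
    "make_analytic_landscape",
    "make_random_landscape",
    "minimax_path_oracle",
    "make_synthetic_training_corpus",
]

# ideal Calpha helix geometry: ~0.38 nm bonds
_HELIX_RADIUS = 0.23     # nm
_HELIX_RISE = 0.15       # nm per residue
_HELIX_TWIST = np.deg2rad(100.0)


@dataclass(frozen=True)
class ToyTwoState:
    """A two-arm hinge protein with generation-time ground truth."""

    pair: StatePair
    known_rmsd: float
    known_unique_contacts_a: tuple
    known_unique_contacts_b: tuple
    known_common_contacts: tuple
    hinge_residues: tuple


@dataclass(frozen=True)
class AnalyticLandscape:
    """A free-energy surface with closed-form ground truth."""

    fes: FreeEnergySurface
    kind: str
    known_saddle: tuple | None = None     # (cv1, cv2)
    known_barrier: float | None = None    # kJ/mol
    basin_a: tuple | None = None
    basin_b: tuple | None = None


# ---------------------------------------------------------------------------
# toy two-state proteins
# ---------------------------------------------------------------------------

def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n) * _HELIX_TWIST
    return np.stack([
        _HELIX_RADIUS * np.cos(t),
        _HELIX_RADIUS * np.sin(t),
        _HELIX_RISE * np.arange(n),
    ], axis=1)


def _rotation_matrix(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def _packed_candidates(coords_straight: np.ndarray, hinge: int,
                       hinge_angle_deg: float):
    """All clash-free packings of the C-terminal arm against the first.

    The arm (a rigidly moved ideal helix segment, so internal bond lengths
    match the straight chain) is tilted by ``hinge_angle_deg`` from the
    N-terminal arm's axis; azimuth, junction elevation and helix phase are
    enumerated on a deterministic grid.  Each candidate is scored by the
    number of inter-arm residue pairs within contact range, subject to a
    steric floor of 0.45 nm.
    """
    n = coords_straight.shape[0]
    template = _helix_coords(n - hinge)
    bond = np.linalg.norm(coords_straight[hinge] - coords_straight[hinge - 1])
    anchor = coords_straight[hinge - 1]
    tilt = _rotation_matrix((0, 1, 0), np.deg2rad(hinge_angle_deg))
    iu, ju = np.triu_indices(n, k=2)

    out = []
    for az in np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False):
        r_az = _rotation_matrix((0, 0, 1), az)
        for elev in (0.2, 0.5, 0.8):
            u = r_az @ np.array([np.cos(elev), 0.0, np.sin(elev)])
            junction = anchor + bond * u
            for phase in np.linspace(0, 2 * np.pi, 6, endpoint=False):
                rot = r_az @ tilt @ _rotation_matrix((0, 0, 1), phase)
                arm = template @ rot.T
                arm += junction - arm[0]
                cand = coords_straight.copy()
                cand[hinge:] = arm
                d = np.linalg.norm(cand[:, None] - cand[None, :], axis=-1)
                if d[iu, ju].min() < 0.45:
                    continue
                score = int((d[:hinge, hinge:] < 0.8).sum())
                out.append((score, cand))
    if not out:
        raise ValueError(
            f"no clash-free packing found for angle {hinge_angle_deg}"
        )
    return out


def _brute_force_contacts(coords: np.ndarray, cutoff: float = 0.8,
                          min_sep: int = 4) -> set:
    """Independent cutoff scan (plain double loop)."""
    out = set()
    n = coords.shape[0]
    for i in range(n):
        for j in range(i + min_sep, n):
            if np.sqrt(np.sum((coords[i] - coords[j]) ** 2)) < cutoff:
                out.add((i, j))
    return out


def make_toy_two_state(n_residues: int = 40, hinge_angle_deg: float = 90.0,
                       seed: int = 0, contact_cutoff: float = 0.8) -> ToyTwoState:
    """Build an ideal two-arm helical chain with a hinge at the middle.

    Both states are packed two-helix conformations: the C-terminal arm is
    bent by ``hinge_angle_deg`` away from the N-terminal arm's axis and
    packed against it, on opposite sides in the two states.  Each state is
    therefore stabilized by its own arm-arm contact interface, and the
    transition is a rigid-body swing of the arm about the hinge.  Ground
    truth (best-fit RMSD, unique/common contact sets, hinge residues) is
    recorded at generation time via independent brute-force scans; the
    hinge set contains the pivot region plus every residue participating
    in a unique contact.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    if hinge_angle_deg == 0.0:
        import warnings
        warnings.warn("hinge angle 0: the two states are identical")
    rng = np.random.default_rng(seed)
    straight = _helix_coords(n_residues)
    hinge = n_residues // 2
    if hinge_angle_deg == 0.0:
        coords_a = straight
        coords_b = straight.copy()
    else:
        # state A: the best-packed interface at the requested bend angle.
        # state B: the most distant well-packed conformation, searched over
        # other bend angles too so the two states differ as rigid-body arm
        # orientations (not merely by the helix's screw pseudo-symmetry).
        cands = _packed_candidates(straight, hinge, hinge_angle_deg)
        best_score = max(c[0] for c in cands)
        coords_a = next(c for s_, c in cands if s_ == best_score)
        # candidate B interfaces must be comparable in size to A's so the
        # two basins have similar stability (uniform contact strength)
        lo, hi = best_score - 2, best_score + 2
        pool = [c for s_, c in cands if lo <= s_ <= hi]
        for tilt in (60.0, 90.0, 120.0, 150.0, 165.0):
            if abs(tilt - hinge_angle_deg) < 20.0:
                continue
            try:
                other = _packed_candidates(straight, hinge, tilt)
            except ValueError:
                continue
            pool.extend(c for s_, c in other if lo <= s_ <= hi)
        coords_b = max(pool, key=lambda c: superpose_rmsd(coords_a, c))

    sequence = "".join(rng.choice(list(AA_ORDER), size=n_residues))
    ss = ["H"] * n_residues
    for k in (hinge - 1, hinge, hinge + 1):
        ss[k] = "C"
    ss = "".join(ss)

    sa = CaStructure(id=f"toy{n_residues}_A", sequence=sequence,
                     coords=coords_a, ss=ss, source="synthetic hinge")
    sb = CaStructure(id=f"toy{n_residues}_B", sequence=sequence,
                     coords=coords_b, ss=ss, source="synthetic hinge")
    pair = StatePair(
        protein_id=f"toy{n_residues}",
        state_a=sa, state_b=sb,
        residue_map=tuple((i, i) for i in range(n_residues)),
    )

    set_a = _brute_force_contacts(coords_a, contact_cutoff)
    set_b = _brute_force_contacts(coords_b, contact_cutoff)
    unique_a = tuple(sorted(set_a - set_b))
    unique_b = tuple(sorted(set_b - set_a))
    pivot = set(range(max(hinge - 3, 0), min(hinge + 4, n_residues)))
    involved = {r for p in unique_a + unique_b for r in p}
    return ToyTwoState(
        pair=pair,
        known_rmsd=superpose_rmsd(coords_a, coords_b),
        known_unique_contacts_a=unique_a,
        known_unique_contacts_b=unique_b,
        known_common_contacts=tuple(sorted(set_a & set_b)),
        hinge_residues=tuple(sorted(pivot | involved)),
    )


class DoubleWell1D:
    """Single particle in an analytic 1D double well; CV is its x position.

    V(x) = barrier * ((x/a)^2 - 1)^2 with minima at x = +-a and an exact
    barrier of ``barrier`` kJ/mol at x = 0.  Implements the same system
    interface as the coarse-grained simulator, so the Langevin/metadynamics
    driver runs on it unchanged — the analytic barrier is the oracle for
    free-energy recovery.
    """

    n_atoms = 1
    n_cvs = 1
    mass = 1.0

    def __init__(self, barrier: float = 10.0, a: float = 0.5):
        self.barrier = float(barrier)
        self.a = float(a)
        self.minima = (-self.a, self.a)

    def energy_forces(self, coords):
        x = coords[0, 0]
        a2 = self.a ** 2
        u = x * x / a2 - 1.0
        e = self.barrier * u * u
        f = np.zeros_like(coords)
        f[0, 0] = -4.0 * self.barrier * x * u / a2
        # confine y/z so the particle stays 1D-like
        e += 50.0 * (coords[0, 1] ** 2 + coords[0, 2] ** 2)
        f[0, 1] = -100.0 * coords[0, 1]
        f[0, 2] = -100.0 * coords[0, 2]
        return e, f

    def cvs_and_grads(self, coords):
        s = np.array([coords[0, 0]])
        grads = np.zeros((1,) + coords.shape)
        grads[0, 0, 0] = 1.0
        return s, grads

    def start_coords(self, which: int = 0) -> np.ndarray:
        return np.array([[self.minima[which], 0.0, 0.0]])


# ---------------------------------------------------------------------------
# analytic landscapes
# ---------------------------------------------------------------------------

def _grid(shape, extent):
    (lo1, hi1), (lo2, hi2) = extent
    return (np.linspace(lo1, hi1, shape[0]),
            np.linspace(lo2, hi2, shape[1]))


def make_analytic_landscape(kind: str, shape=(61, 61),
                            extent=((0.0, 1.0), (0.0, 1.0)),
                            barrier: float = 10.0,
                            wall: float = 80.0) -> AnalyticLandscape:
    """Closed-form landscapes sampled on a regular grid.

    kinds: ``flat`` (F == 0), ``double_well`` (two minima on the main
    diagonal, saddle exactly ``barrier`` at the midpoint), ``triple_well``
    (three minima along the diagonal), ``channel`` (an S-shaped valley with
    a single saddle of height ``barrier`` at its middle, walls elsewhere).
    """
    cv1, cv2 = _grid(shape, extent)
    X, Y = np.meshgrid(cv1, cv2, indexing="ij")
    (lo1, hi1), (lo2, hi2) = extent
    a = np.array([lo1 + 0.25 * (hi1 - lo1), lo2 + 0.25 * (hi2 - lo2)])
    b = np.array([lo1 + 0.75 * (hi1 - lo1), lo2 + 0.75 * (hi2 - lo2)])

    if kind == "flat":
        F = np.zeros(shape)
        land = AnalyticLandscape(
            fes=FreeEnergySurface(cv1, cv2, F, {"kind": kind}),
            kind=kind, basin_a=tuple(a), basin_b=tuple(b))
        return land

    # coordinates along (u) and across (v) the A->B diagonal
    ab = b - a
    L = np.linalg.norm(ab)
    u = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / L ** 2
    v = (-(X - a[0]) * ab[1] + (Y - a[1]) * ab[0]) / L

    if kind in ("double_well", "triple_well"):
        cycles = 1.0 if kind == "double_well" else 2.0
        uc = np.clip(u, 0.0, 1.0)
        F = barrier * 0.5 * (1.0 - np.cos(2.0 * np.pi * cycles * uc))
        F += wall * v ** 2
        F += wall * (np.maximum(u - 1.0, 0.0) ** 2
                     + np.maximum(-u, 0.0) ** 2) * L ** 2
        F -= F.min()
        saddle = tuple(a + 0.5 / cycles * ab)
        return AnalyticLandscape(
            fes=FreeEnergySurface(cv1, cv2, F, {"kind": kind}),
            kind=kind, known_saddle=saddle, known_barrier=barrier,
            basin_a=tuple(a), basin_b=tuple(b))

    if kind == "channel":
        # S-shaped channel: positions P(t) from A to B with a sine swerve.
        # The corridor floor is flat across its width (so grid walks can
        # thread it); outside the half-width the walls rise quadratically.
        t = np.linspace(0.0, 1.0, 400)
        perp = np.array([-ab[1], ab[0]]) / L
        amp = 0.18 * L
        half_width = 0.06 * L
        px = a[0] + t * ab[0] + amp * np.sin(2 * np.pi * t) * perp[0]
        py = a[1] + t * ab[1] + amp * np.sin(2 * np.pi * t) * perp[1]
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        d2 = ((pts[:, None, 0] - px) ** 2
              + (pts[:, None, 1] - py) ** 2)
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(pts)), nearest])
        t_near = t[nearest]
        # linear wall: even the first off-corridor grid node is costly
        F = (barrier * 0.5 * (1.0 - np.cos(2.0 * np.pi * t_near))
             + wall * np.maximum(dist - half_width, 0.0)).reshape(shape)
        F -= F.min()
        saddle_xy = (a + 0.5 * ab + amp * np.sin(np.pi) * perp)
        return AnalyticLandscape(
            fes=FreeEnergySurface(cv1, cv2, F, {"kind": kind}),
            kind=kind, known_saddle=tuple(saddle_xy), known_barrier=barrier,
            basin_a=tuple(a), basin_b=tuple(b))

    raise ValueError(f"unknown landscape kind {kind!r}")


def make_random_landscape(shape=(40, 40), amplitude: float = 6.0,
                          smooth_sigma: float = 3.0, seed: int = 0,
                          extent=((0.0, 1.0), (0.0, 1.0))) -> AnalyticLandscape:
    """Smooth random landscape with two engineered basins.

    Gaussian-filtered white noise scaled to ``amplitude``; two depressions
    are carved near opposite corners so the start/end basins are the global
    minima.  Used for stress-testing the path search against the exhaustive
    minimax oracle.
    """
    rng = np.random.default_rng(seed)
    cv1, cv2 = _grid(shape, extent)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    noise = (noise - noise.min()) / (noise.max() - noise.min())
    F = amplitude * noise

    X, Y = np.meshgrid(cv1, cv2, indexing="ij")
    (lo1, hi1), (lo2, hi2) = extent
    a = np.array([lo1 + 0.15 * (hi1 - lo1), lo2 + 0.15 * (hi2 - lo2)])
    b = np.array([lo1 + 0.85 * (hi1 - lo1), lo2 + 0.85 * (hi2 - lo2)])
    sig = 0.08 * (hi1 - lo1)
    for c in (a, b):
        F -= (amplitude + 2.0) * np.exp(
            -((X - c[0]) ** 2 + (Y - c[1]) ** 2) / (2 * sig ** 2))
    F -= F.min()
    return AnalyticLandscape(
        fes=FreeEnergySurface(cv1, cv2, F, {"kind": "random", "seed": seed}),
        kind="random", basin_a=tuple(a), basin_b=tuple(b))


# ---------------------------------------------------------------------------
# exhaustive minimax-path oracle
# ---------------------------------------------------------------------------

def minimax_path_oracle(fes: FreeEnergySurface, start, end):
    """Exact widest-path (minimax) barrier between two CV points.

    Binary-searches the smallest threshold theta such that the start and end
    cells are 4-connected within {F <= theta}, then returns

    ``(barrier, path)`` with barrier = theta - F(start) and one realizing
    path (list of (cv1, cv2) grid nodes found by BFS at the threshold).
    Deterministic and exhaustive; serves as the independent oracle for the
    two-round search.
    """
    F = fes.F
    si = _nearest_cell(fes, start)
    ei = _nearest_cell(fes, end)
    levels = np.unique(F)
    lo, hi = 0, len(levels) - 1
    if not _connected(F, levels[hi], si, ei):
        raise ValueError("start and end are not connected on the grid")
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected(F, levels[mid], si, ei):
            hi = mid
        else:
            lo = mid + 1
    theta = levels[lo]
    path_cells = _bfs_path(F, theta, si, ei)
    path = [(fes.cv1_edges[i], fes.cv2_edges[j]) for i, j in path_cells]
    return float(theta - F[si]), path


def _nearest_cell(fes: FreeEnergySurface, point) -> tuple:
    i = int(np.argmin(np.abs(fes.cv1_edges - point[0])))
    j = int(np.argmin(np.abs(fes.cv2_edges - point[1])))
    return i, j


def _connected(F, theta, si, ei) -> bool:
    mask = F <= theta
    if not (mask[si] and mask[ei]):
        return False
    labels, _ = ndimage.label(mask)
    return labels[si] == labels[ei]


def _bfs_path(F, theta, si, ei):
    from collections import deque

    mask = F <= theta
    prev = {si: None}
    q = deque([si])
    while q:
        cur = q.popleft()
        if cur == ei:
            break
        i, j = cur
        for ni, nj in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
            if (0 <= ni < F.shape[0] and 0 <= nj < F.shape[1]
                    and mask[ni, nj] and (ni, nj) not in prev):
                prev[(ni, nj)] = cur
                q.append((ni, nj))
    if ei not in prev:
        raise ValueError("no path at threshold (disconnected domain)")
    path = []
    cur = ei
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path[::-1]


# ---------------------------------------------------------------------------
# rule-based training corpus
# ---------------------------------------------------------------------------

def make_synthetic_training_corpus(n_examples: int, l_range=(32, 32),
                                   rule: str = "elementwise_min",
                                   seed: int = 0):
    """Rule-based corpus of two-state feature pairs with known targets.

    Each example is a toy hinge protein (random length in ``l_range``,
    random hinge angle); the input channels are the sigmoid distance
    features of its two states and the target transition-state matrix is
    ``rule`` applied on unique-contact pairs and the midpoint elsewhere.
    rules: ``elementwise_min``, ``geometric_mean``, ``midpoint``.
    """
    from .featurize import DistanceFeature, contact_masks, feature_from_distances
    from .models import TrainingExample
    from .structio import pairwise_ca_distances

    if rule not in ("elementwise_min", "geometric_mean", "midpoint"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_examples):
        L = int(rng.integers(l_range[0], l_range[1] + 1))
        angle = float(rng.uniform(40.0, 130.0))
        toy = make_toy_two_state(L, hinge_angle_deg=angle,
                                 seed=int(rng.integers(2 ** 31)))
        da = feature_from_distances(
            pairwise_ca_distances(toy.pair.state_a), source="state_a")
        db = feature_from_distances(
            pairwise_ca_distances(toy.pair.state_b), source="state_b")
        masks = contact_masks(da, db)
        mid = 0.5 * (da.D + db.D)
        if rule == "elementwise_min":
            on_unique = np.minimum(da.D, db.D)
        elif rule == "geometric_mean":
            on_unique = np.sqrt(da.D * db.D)
        else:
            on_unique = mid
        target = np.where(masks.unique, on_unique, mid)
        out.append(TrainingExample(
            da=da, db=db,
            target_ts=DistanceFeature(D=target, source="ts_sim"),
            masks=masks,
        ))
    return out
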