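"""Langevin dynamics with optional well-tempered metadynamics biasing.

The integrator is BAOAB splitting (velocity Verlet with an
Ornstein-Uhlenbeck kick between the position half-steps); with zero
friction it reduces to plain velocity Verlet, which is used for the
energy-conservation checks.  The metadynamics bias acts on the system's
collective variables and is mapped onto Cartesian forces by the chain
rule through the analytic CV gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import KB
from . import kernels
from .metad import HillsLog, MetaDParams, bias_force, bias_potential
from .topology import DualBasinModel

__all__ = [
    "SimParams",
    "Trajectory",
    "CgSystem",
    "run_dynamics",
    "run_metadynamics",
    "SimulationBlowUp",
]


class SimulationBlowUp(RuntimeError):
    """Raised when coordinates turn non-finite; carries the failing step."""

    def __init__(self, step: int, last_stable: np.ndarray):
        super().__init__(f"simulation blew up at step {step}")
        self.step = step
        self.last_stable = last_stable


@dataclass(frozen=True)
class SimParams:
    """Langevin integration parameters (nm / kJ/mol / ps / K units)."""

    dt: float = 0.0005            # ps
    temperature: float = 110.0    # K
    friction: float = 0.1         # ps^-1 ("low friction limit")
    n_steps: int = 100_000
    frame_stride: int = 100

    def __post_init__(self):
        if self.dt <= 0 or self.temperature < 0 or self.friction < 0:
            raise ValueError("dt must be positive, temperature and friction "
                             "non-negative")


@dataclass
class Trajectory:
    """Saved frames plus the CV series evaluated at those frames."""

    frames: np.ndarray            # (F, N, 3)
    cvs: np.ndarray               # (F, d)
    frame_steps: np.ndarray       # (F,)
    final_coords: np.ndarray
    final_velocities: np.ndarray
    energies: np.ndarray          # potential energy per frame, kJ/mol
    hills: HillsLog | None = None
    provenance: dict = field(default_factory=dict)


class CgSystem:
    """A coarse-grained model plus CV references and optional restraints.

    ``refs`` is a list of reference coordinate sets; each contributes one
    best-fit-RMSD collective variable.  ``contact_sets`` selects which
    contact lists of the model are active (default: all three).
    """

    def __init__(self, model: DualBasinModel, refs=(),
                 contact_sets=("common", "a", "b"),
                 common_r0: str = "mean",
                 include_repulsion: bool = True,
                 restraint_pairs=None, restraint_r0=None,
                 restraint_strength: float = 2.0,
                 restraint_flat_width: float = 0.05):
        self.model = model
        self.refs = [np.asarray(r, dtype=float) for r in refs]
        p = model.params
        self._contacts, self._r0 = model.all_contacts(contact_sets,
                                                      common_r0=common_r0)
        self._reps = (model.repulsion_pairs(contact_sets) if include_repulsion
                      else np.zeros((0, 2), dtype=np.int64))
        self._p = p
        if restraint_pairs is None:
            restraint_pairs = np.zeros((0, 2), dtype=np.int64)
            restraint_r0 = np.zeros(0)
        self._res_pairs = np.asarray(restraint_pairs, dtype=np.int64)
        self._res_r0 = np.asarray(restraint_r0, dtype=float)
        self.restraint_strength = float(restraint_strength)
        self.restraint_flat_width = float(restraint_flat_width)

    @property
    def n_atoms(self) -> int:
        return self.model.n_atoms

    @property
    def n_cvs(self) -> int:
        return len(self.refs)

    @property
    def mass(self) -> float:
        return self._p.mass

    def energy_forces(self, coords):
        forces = np.zeros_like(coords)
        m = self.model
        p = self._p
        e = kernels.bonded_forces(
            coords, m.bonds, m.bond_r0, p.k_bond,
            m.angles, m.angle_theta0, m.angle_k,
            m.dihedrals, m.dihedral_phi0, m.dihedral_k, forces)
        e += kernels.pair_forces(
            coords, self._contacts, self._r0, p.epsilon,
            self._reps, p.excluded_radius, p.epsilon, forces)
        if len(self._res_pairs):
            e += kernels.restraint_forces(
                coords, self._res_pairs, self._res_r0,
                self.restraint_strength, self.restraint_flat_width, forces)
        return e, forces

    def restraint_violation(self, coords) -> float:
        """Mean squared restraint violation (nm^2) at given coordinates."""
        if not len(self._res_pairs):
            return 0.0
        d = np.linalg.norm(
            coords[self._res_pairs[:, 1]] - coords[self._res_pairs[:, 0]],
            axis=1)
        return float(np.mean((d - self._res_r0) ** 2))

    def cvs_and_grads(self, coords):
        s = np.empty(len(self.refs))
        grads = np.empty((len(self.refs),) + coords.shape)
        for k, ref in enumerate(self.refs):
            s[k], grads[k] = kernels.rmsd_and_grad(coords, ref)
        return s, grads


def run_dynamics(system, start_coords, sim: SimParams, seed: int = 0,
                 metad: MetaDParams | None = None,
                 temperature_schedule=None,
                 max_hills: int = 1_000_000) -> Trajectory:
    """Integrate Langevin dynamics, optionally with well-tempered biasing.

    ``temperature_schedule``, if given, maps a step index to a temperature
    in K (used for simulated annealing); otherwise ``sim.temperature`` is
    used throughout.  Frames (and the CV values at them) are recorded every
    ``sim.frame_stride`` steps.  Raises :class:`SimulationBlowUp` on
    non-finite coordinates.

    Coarse-grained systems run through a compiled chunked integrator; any
    other object implementing ``energy_forces`` / ``cvs_and_grads`` (such
    as the analytic test systems) uses the pure-python loop.  Both are
    deterministic under a fixed seed, but their random streams differ.
    """
    if isinstance(system, CgSystem) and len(system.refs) <= 2:
        return _run_dynamics_fast(system, start_coords, sim, seed, metad,
                                  temperature_schedule)
    coords = np.array(start_coords, dtype=float)
    n = coords.shape[0]
    mass = getattr(system, "mass", 1.0)
    rng = np.random.default_rng(seed)

    temp0 = (temperature_schedule(0) if temperature_schedule
             else sim.temperature)
    vel = rng.normal(0.0, np.sqrt(KB * max(temp0, 1e-12) / mass),
                     size=coords.shape)

    biasing = metad is not None and system.n_cvs > 0
    h_steps, h_centers, h_widths, h_heights = [], [], [], []
    centers = np.zeros((0, max(system.n_cvs, 1)))
    widths = np.zeros((0, max(system.n_cvs, 1)))
    heights = np.zeros(0)

    def total_forces(c):
        e, f = system.energy_forces(c)
        s = None
        if system.n_cvs > 0:
            s, grads = system.cvs_and_grads(c)
            if biasing and len(heights):
                fb = bias_force(centers, widths, heights, s)
                for d in range(system.n_cvs):
                    f += fb[d] * grads[d]
        return e, f, s

    energy, forces, cv_now = total_forces(coords)

    c1_const = np.exp(-sim.friction * sim.dt)
    half_dt = 0.5 * sim.dt

    n_frames = sim.n_steps // sim.frame_stride + 1
    frames = np.empty((n_frames, n, 3))
    cvs = np.empty((n_frames, system.n_cvs))
    frame_steps = np.empty(n_frames, dtype=np.int64)
    energies = np.empty(n_frames)
    fi = 0
    frames[fi] = coords
    cvs[fi] = cv_now if cv_now is not None else ()
    frame_steps[fi] = 0
    energies[fi] = energy
    fi += 1
    last_stable = coords.copy()

    noise_block = 1000
    noise = rng.standard_normal((noise_block, n, 3))

    for step in range(1, sim.n_steps + 1):
        temp = (temperature_schedule(step) if temperature_schedule
                else sim.temperature)
        c2 = np.sqrt((1.0 - c1_const ** 2) * KB * temp / mass)

        vel += half_dt * forces / mass
        coords += half_dt * vel
        if sim.friction > 0:
            xi = noise[(step - 1) % noise_block]
            if step % noise_block == 0:
                noise = rng.standard_normal((noise_block, n, 3))
            vel = c1_const * vel + c2 * xi
        coords += half_dt * vel
        energy, forces, cv_now = total_forces(coords)
        vel += half_dt * forces / mass

        if biasing and step % metad.stride == 0:
            if len(heights) >= max_hills:
                raise RuntimeError("maximum hill count exceeded")
            vb = bias_potential(centers, widths, heights, cv_now)
            h = metad.height0 * np.exp(-vb / (KB * metad.delta_t))
            h_steps.append(step)
            h_centers.append(cv_now.copy())
            h_widths.append(np.full(system.n_cvs, metad.width))
            h_heights.append(h)
            centers = np.asarray(h_centers)
            widths = np.asarray(h_widths)
            heights = np.asarray(h_heights)

        if step % sim.frame_stride == 0:
            if not np.all(np.isfinite(coords)):
                raise SimulationBlowUp(step, last_stable)
            frames[fi] = coords
            cvs[fi] = cv_now if cv_now is not None else ()
            frame_steps[fi] = step
            energies[fi] = energy
            fi += 1
            last_stable = coords.copy()

    hills = None
    if biasing:
        hills = HillsLog(
            steps=np.asarray(h_steps, dtype=np.int64),
            centers=(np.asarray(h_centers) if h_centers
                     else np.zeros((0, system.n_cvs))),
            widths=(np.asarray(h_widths) if h_widths
                    else np.zeros((0, system.n_cvs))),
            heights=np.asarray(h_heights),
            params=metad,
        )
    return Trajectory(
        frames=frames[:fi], cvs=cvs[:fi], frame_steps=frame_steps[:fi],
        final_coords=coords, final_velocities=vel, energies=energies[:fi],
        hills=hills,
        provenance={"seed": seed, "dt_ps": sim.dt,
                    "temperature_K": sim.temperature,
                    "friction_per_ps": sim.friction,
                    "n_steps": sim.n_steps},
    )


def _run_dynamics_fast(system: CgSystem, start_coords, sim: SimParams,
                       seed: int, metad: MetaDParams | None,
                       temperature_schedule) -> Trajectory:
    """Chunked compiled integrator for coarse-grained systems."""
    coords = np.array(start_coords, dtype=float)
    n = coords.shape[0]
    mass = system.mass
    m = system.model
    p = m.params
    rng = np.random.default_rng(seed)
    kernels.seed_rng(int(rng.integers(2 ** 31)))

    temp0 = (temperature_schedule(0) if temperature_schedule
             else sim.temperature)
    vel = rng.normal(0.0, np.sqrt(KB * max(temp0, 1e-12) / mass),
                     size=coords.shape)
    c1 = np.exp(-sim.friction * sim.dt)

    n_refs = len(system.refs)
    refs = np.zeros((2, n, 3))
    for k, r in enumerate(system.refs):
        refs[k] = r

    biasing = metad is not None and n_refs > 0
    n_hill_slots = (sim.n_steps // metad.stride + 1) if biasing else 1
    h_centers = np.zeros((n_hill_slots, 2))
    h_widths = np.ones((n_hill_slots, 2))
    h_heights = np.zeros(n_hill_slots)
    h_steps = np.zeros(n_hill_slots, dtype=np.int64)
    n_hills = 0

    # the running bias lives on a grid (potential + negative gradient per
    # CV); each deposit adds a local Gaussian patch, the integrator reads
    # the grids by bilinear interpolation.  The exact hills are still
    # logged for the free-energy estimator.
    bias_lo, bias_hi, bias_h = 0.0, 4.0, 0.0125
    n_bias = int(round((bias_hi - bias_lo) / bias_h)) + 1
    bias_v = np.zeros((n_bias, n_bias))
    bias_f1 = np.zeros((n_bias, n_bias))
    bias_f2 = np.zeros((n_bias, n_bias))
    bias_axis = bias_lo + np.arange(n_bias) * bias_h

    def _deposit(center1, center2, width, height):
        i0 = max(int((center1 - 5 * width - bias_lo) / bias_h), 0)
        i1 = min(int((center1 + 5 * width - bias_lo) / bias_h) + 2, n_bias)
        if i0 >= i1:
            return
        z1 = (bias_axis[i0:i1] - center1) / width
        if n_refs > 1:
            j0 = max(int((center2 - 5 * width - bias_lo) / bias_h), 0)
            j1 = min(int((center2 + 5 * width - bias_lo) / bias_h) + 2, n_bias)
            if j0 >= j1:
                return
            z2 = (bias_axis[j0:j1] - center2) / width
            g = height * np.exp(-0.5 * (z1[:, None] ** 2 + z2[None, :] ** 2))
            bias_v[i0:i1, j0:j1] += g
            bias_f1[i0:i1, j0:j1] += g * z1[:, None] / width
            bias_f2[i0:i1, j0:j1] += g * z2[None, :] / width
        else:
            g = height * np.exp(-0.5 * z1 ** 2)
            bias_v[i0:i1, :] += g[:, None]
            bias_f1[i0:i1, :] += (g * z1 / width)[:, None]

    n_frames = sim.n_steps // sim.frame_stride + 1
    frames = np.empty((n_frames, n, 3))
    cvs = np.empty((n_frames, n_refs))
    frame_steps = np.empty(n_frames, dtype=np.int64)
    energies = np.empty(n_frames)

    s, _ = (system.cvs_and_grads(coords) if n_refs else (np.zeros(0), None))
    e0, _ = system.energy_forces(coords)
    fi = 0
    frames[fi] = coords
    cvs[fi] = s[:n_refs]
    frame_steps[fi] = 0
    energies[fi] = e0
    fi += 1
    last_stable = coords.copy()

    step = 0
    next_frame = sim.frame_stride
    next_hill = metad.stride if biasing else sim.n_steps + 1
    while step < sim.n_steps:
        n_sub = min(next_frame, next_hill, sim.n_steps) - step
        temp = (temperature_schedule(step) if temperature_schedule
                else sim.temperature)
        s1, s2, energy, vbias = kernels.integrate_chunk(
            coords, vel, n_sub, sim.dt, c1, KB * temp, mass,
            m.bonds, m.bond_r0, p.k_bond,
            m.angles, m.angle_theta0, m.angle_k,
            m.dihedrals, m.dihedral_phi0, m.dihedral_k,
            system._contacts, system._r0, p.epsilon,
            system._reps, p.excluded_radius,
            system._res_pairs, system._res_r0,
            system.restraint_strength, system.restraint_flat_width,
            refs, n_refs,
            biasing, bias_v, bias_f1, bias_f2, bias_lo, 1.0 / bias_h,
        )
        step += n_sub
        if not np.all(np.isfinite(coords)):
            raise SimulationBlowUp(step, last_stable)
        if biasing and step == next_hill:
            h = metad.height0 * np.exp(-vbias / (KB * metad.delta_t))
            h_centers[n_hills, 0] = s1
            h_centers[n_hills, 1] = s2
            h_widths[n_hills, 0] = metad.width
            h_widths[n_hills, 1] = metad.width
            h_heights[n_hills] = h
            h_steps[n_hills] = step
            n_hills += 1
            _deposit(s1, s2, metad.width, h)
            next_hill += metad.stride
        if step == next_frame:
            frames[fi] = coords
            if n_refs >= 1:
                cvs[fi, 0] = s1
            if n_refs >= 2:
                cvs[fi, 1] = s2
            frame_steps[fi] = step
            energies[fi] = energy
            fi += 1
            last_stable = coords.copy()
            next_frame += sim.frame_stride

    hills = None
    if biasing:
        hills = HillsLog(
            steps=h_steps[:n_hills],
            centers=h_centers[:n_hills, :max(n_refs, 1)],
            widths=h_widths[:n_hills, :max(n_refs, 1)],
            heights=h_heights[:n_hills],
            params=metad,
        )
    return Trajectory(
        frames=frames[:fi], cvs=cvs[:fi], frame_steps=frame_steps[:fi],
        final_coords=coords, final_velocities=vel, energies=energies[:fi],
        hills=hills,
        provenance={"seed": seed, "dt_ps": sim.dt,
                    "temperature_K": sim.temperature,
                    "friction_per_ps": sim.friction,
                    "n_steps": sim.n_steps, "integrator": "compiled"},
    )


def run_metadynamics(system, start_coords, sim: SimParams,
                     metad: MetaDParams, seed: int = 0) -> Trajectory:
    """Well-tempered metadynamics run; thin wrapper over run_dynamics."""
    if metad is None:
        raise ValueError("metad parameters required; use run_dynamics for "
                         "unbiased runs")
    return run_dynamics(system, start_coords, sim, seed=seed, metad=metad)
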