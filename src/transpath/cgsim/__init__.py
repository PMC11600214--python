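"""Dual-basin coarse-grained simulator with well-tempered metadynamics.

Public surface: topology construction (:func:`build_dual_basin`,
:func:`build_single_basin`), energies/forces (:func:`potential_energy`),
collective variables (:func:`cv_rmsd`), Langevin/metadynamics drivers
(:func:`run_dynamics`, :func:`run_metadynamics`) and free-energy estimation
(:func:`compute_fes`).
"""

from __future__ import annotations

import numpy as np

from .topology import (
    DualBasinModel,
    ForceFieldParams,
    build_dual_basin,
    build_single_basin,
    contact_map,
)
from .metad import (
    FreeEnergySurface,
    HillsLog,
    MetaDParams,
    bias_force,
    bias_potential,
    compute_fes,
    compute_fes_1d,
)
from .dynamics import (
    CgSystem,
    SimParams,
    SimulationBlowUp,
    Trajectory,
    run_dynamics,
    run_metadynamics,
)
from . import kernels

__all__ = [
    "DualBasinModel", "ForceFieldParams", "build_dual_basin",
    "build_single_basin", "contact_map", "FreeEnergySurface", "HillsLog",
    "MetaDParams", "bias_force", "bias_potential", "compute_fes",
    "compute_fes_1d", "CgSystem", "SimParams", "SimulationBlowUp",
    "Trajectory", "run_dynamics", "run_metadynamics", "potential_energy",
    "cv_rmsd",
]


def potential_energy(model: DualBasinModel, coords: np.ndarray,
                     contact_sets=("common", "a", "b"),
                     common_r0: str = "mean",
                     include_repulsion: bool = True):
    """Potential energy (kJ/mol) and analytic forces for a model.

    ``contact_sets`` selects which contact lists are active, e.g.
    ``("common", "a")`` with ``common_r0="a"`` evaluates only the A-side
    and shared terms at state A's native distances (for which state A is an
    exact stationary point when repulsion is off).  Coincident beads make
    the excluded-volume term overflow and raise.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_atoms, 3):
        raise ValueError("coords shape does not match the model")
    system = CgSystem(model, contact_sets=contact_sets, common_r0=common_r0,
                      include_repulsion=include_repulsion)
    try:
        e, f = system.energy_forces(coords)
    except ZeroDivisionError as err:
        raise FloatingPointError(
            "repulsion overflow: coincident beads"
        ) from err
    if not (np.isfinite(e) and np.all(np.isfinite(f))):
        raise FloatingPointError(
            "non-finite energy/forces (coincident beads?)"
        )
    return e, f


def cv_rmsd(coords: np.ndarray, ref) -> float:
    """Best-fit RMSD collective variable (nm) to a reference structure."""
    from ..structio import CaStructure, superpose_rmsd

    ref_coords = ref.coords if isinstance(ref, CaStructure) else np.asarray(ref)
    return superpose_rmsd(np.asarray(coords, dtype=float), ref_coords)
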