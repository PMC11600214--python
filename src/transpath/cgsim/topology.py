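"""Dual-basin Calpha structure-based (Go-type) topology construction.

The Hamiltonian keeps a protein near its native structure(s) through

* harmonic bonds between consecutive beads,
* harmonic pseudo-angles over bead triplets,
* Go-style pseudo-dihedrals over bead quadruplets,
* 12-10 Lennard-Jones-like wells on native-contact pairs (depth epsilon,
  minimum at the native distance),
* an r^-12 excluded-volume repulsion on all remaining non-local pairs.

For a two-state protein the contact set is partitioned into contacts common
to both states (well minimum at the mean of the two native distances) and
contacts unique to one state, making both endpoint structures energy minima
of a single potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..structio import CaStructure, StatePair, pairwise_ca_distances

__all__ = [
    "ForceFieldParams",
    "DualBasinModel",
    "build_dual_basin",
    "build_single_basin",
    "contact_map",
]

#: default native-contact cutoff (nm) on Calpha distances
DEFAULT_CONTACT_CUTOFF = 0.8
#: minimum sequence separation for contacts
CONTACT_MIN_SEPARATION = 4


@dataclass(frozen=True)
class ForceFieldParams:
    """Strengths of the coarse-grained terms (kJ/mol based units)."""

    k_bond: float = 20000.0        # kJ/mol/nm^2 (V = 0.5 k dx^2)
    k_angle: float = 40.0          # kJ/mol/rad^2
    k_dihedral: float = 1.0        # kJ/mol
    epsilon: float = 1.0           # contact well depth, kJ/mol
    excluded_radius: float = 0.4   # nm
    mass: float = 1.0              # reduced bead mass


@dataclass
class DualBasinModel:
    """Arrays describing a (dual-basin) Calpha structure-based model."""

    n_atoms: int
    bonds: np.ndarray              # (nb, 2) int
    bond_r0: np.ndarray            # (nb,)
    angles: np.ndarray             # (na, 3) int
    angle_theta0: np.ndarray       # (na,)
    angle_k: np.ndarray            # (na,) per-angle strength
    dihedrals: np.ndarray          # (nd, 4) int
    dihedral_phi0: np.ndarray      # (nd,)
    dihedral_k: np.ndarray         # (nd,) per-dihedral strength
    contacts_common: np.ndarray    # (nc, 2) int
    r0_common: np.ndarray          # (nc,) mean of the two native distances
    contacts_unique_a: np.ndarray
    r0_unique_a: np.ndarray
    contacts_unique_b: np.ndarray
    r0_unique_b: np.ndarray
    #: per-state native distances of the common contacts (A, B); the mean
    #: (r0_common) is what dynamics uses
    r0_common_a: np.ndarray = None
    r0_common_b: np.ndarray = None
    params: ForceFieldParams = field(default_factory=ForceFieldParams)

    def __post_init__(self):
        for name in ("contacts_common", "contacts_unique_a",
                     "contacts_unique_b"):
            pairs = getattr(self, name)
            if len(pairs) and np.any(
                np.abs(pairs[:, 0] - pairs[:, 1]) < CONTACT_MIN_SEPARATION
            ):
                raise ValueError(f"{name} holds a pair closer than "
                                 f"|i-j| >= {CONTACT_MIN_SEPARATION}")
        sets = [set(map(tuple, getattr(self, n)))
                for n in ("contacts_common", "contacts_unique_a",
                          "contacts_unique_b")]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("contact lists must be disjoint")
        if self.r0_common_a is None:
            self.r0_common_a = self.r0_common.copy()
        if self.r0_common_b is None:
            self.r0_common_b = self.r0_common.copy()
        for r0 in (self.bond_r0, self.r0_common, self.r0_unique_a,
                   self.r0_unique_b):
            if len(r0) and np.any(r0 <= 0):
                raise ValueError("every reference distance must be positive")

    # ---- derived -----------------------------------------------------
    def all_contacts(self, include=("common", "a", "b"),
                     common_r0: str = "mean"):
        """Stacked contact index / r0 arrays for the force kernel.

        ``common_r0`` selects the reference distance of common contacts:
        "mean" (dynamics default), "a" or "b" (that state's native value).
        """
        parts, r0s = [], []
        if "common" in include:
            parts.append(self.contacts_common)
            r0s.append({"mean": self.r0_common, "a": self.r0_common_a,
                        "b": self.r0_common_b}[common_r0])
        if "a" in include:
            parts.append(self.contacts_unique_a)
            r0s.append(self.r0_unique_a)
        if "b" in include:
            parts.append(self.contacts_unique_b)
            r0s.append(self.r0_unique_b)
        pairs = (np.concatenate(parts) if parts
                 else np.zeros((0, 2), dtype=np.int64))
        r0 = np.concatenate(r0s) if r0s else np.zeros(0)
        return pairs.astype(np.int64), np.asarray(r0, dtype=float)

    def repulsion_pairs(self, include=("common", "a", "b")) -> np.ndarray:
        """All |i-j| >= 3 pairs that are not contacts (excluded volume)."""
        n = self.n_atoms
        iu, ju = np.triu_indices(n, k=3)
        contacts, _ = self.all_contacts(include)
        taken = set(map(tuple, contacts))
        mask = np.array([(i, j) not in taken for i, j in zip(iu, ju)])
        return np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)


def contact_map(coords: np.ndarray,
                cutoff: float = DEFAULT_CONTACT_CUTOFF,
                min_separation: int = CONTACT_MIN_SEPARATION) -> set:
    """Native-contact pairs by Calpha cutoff: d < cutoff, |i-j| >= min_sep."""
    d = pairwise_ca_distances(coords)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=min_separation)
    sel = d[iu, ju] < cutoff
    return set(zip(iu[sel].tolist(), ju[sel].tolist()))


def _bonded_geometry(coords: np.ndarray):
    n = coords.shape[0]
    bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    bond_r0 = np.linalg.norm(coords[1:] - coords[:-1], axis=1)

    angles = np.stack([np.arange(n - 2), np.arange(1, n - 1),
                       np.arange(2, n)], axis=1)
    v1 = coords[angles[:, 0]] - coords[angles[:, 1]]
    v2 = coords[angles[:, 2]] - coords[angles[:, 1]]
    cos = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    theta0 = np.arccos(np.clip(cos, -1.0, 1.0))

    dihedrals = np.stack([np.arange(n - 3), np.arange(1, n - 2),
                          np.arange(2, n - 1), np.arange(3, n)], axis=1)
    phi0 = np.array([_dihedral_angle(coords[q]) for q in dihedrals])
    return (bonds.astype(np.int64), bond_r0, angles.astype(np.int64),
            theta0, dihedrals.astype(np.int64), phi0)


def _dihedral_angle(p: np.ndarray) -> float:
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def build_dual_basin(pair: StatePair,
                     contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     params: ForceFieldParams | None = None,
                     conflict_scale: float = 0.0,
                     angle_conflict_tol: float = 0.3,
                     dihedral_conflict_tol: float = 0.5) -> DualBasinModel:
    """Build a dual-basin model from a two-state pair.

    Bonded terms take their reference geometry from state A.  Contacts
    (Calpha cutoff map, default 0.8 nm, |i-j| >= 4) are partitioned into
    common (minimum at the mean of the two native distances, both per-state
    values recorded) and unique to either state.  Angles and dihedrals whose
    reference value conflicts between the states — geometrically (beyond
    the given tolerances, rad) or because the secondary structure differs —
    have their strength scaled by ``conflict_scale`` (default 0: excluded),
    leaving the contacts to decide between the basins there.

    The model indexes the *mapped* residues of the pair, 0..M-1.
    """
    if params is None:
        params = ForceFieldParams()
    ca, cb = pair.mapped_coords()
    m = ca.shape[0]
    if m < 4:
        raise ValueError("need at least 4 mapped residues")

    bonds, bond_r0, angles, theta0, dihedrals, phi0 = _bonded_geometry(ca)
    _, _, _, theta0_b, _, phi0_b = _bonded_geometry(cb)

    set_a = contact_map(ca, contact_cutoff)
    set_b = contact_map(cb, contact_cutoff)
    common = sorted(set_a & set_b)
    only_a = sorted(set_a - set_b)
    only_b = sorted(set_b - set_a)

    da = pairwise_ca_distances(ca)
    db = pairwise_ca_distances(cb)

    def _pairs_r0(pairs, dist):
        arr = (np.array(pairs, dtype=np.int64) if pairs
               else np.zeros((0, 2), dtype=np.int64))
        r0 = np.array([dist[i, j] for i, j in pairs]) if pairs else np.zeros(0)
        return arr, r0

    c_common, _ = _pairs_r0(common, da)
    r0_common = np.array([(da[i, j] + db[i, j]) / 2 for i, j in common]) \
        if common else np.zeros(0)
    c_a, r0_a = _pairs_r0(only_a, da)
    c_b, r0_b = _pairs_r0(only_b, db)

    angle_k = np.full(len(angles), params.k_angle)
    dihedral_k = np.full(len(dihedrals), params.k_dihedral)

    angle_conflict = np.abs(theta0 - theta0_b) > angle_conflict_tol
    dphi = np.abs(np.mod(phi0 - phi0_b + np.pi, 2 * np.pi) - np.pi)
    dihedral_conflict = dphi > dihedral_conflict_tol

    ssa, ssb = pair.state_a.ss, pair.state_b.ss
    if ssa is not None and ssb is not None:
        ia, ib = pair.mapped_a, pair.mapped_b
        differs = np.array([ssa[a] != ssb[b] for a, b in zip(ia, ib)])
        angle_conflict |= differs[angles].any(axis=1)
        dihedral_conflict |= differs[dihedrals].any(axis=1)

    angle_k[angle_conflict] *= conflict_scale
    dihedral_k[dihedral_conflict] *= conflict_scale

    return DualBasinModel(
        n_atoms=m,
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_theta0=theta0, angle_k=angle_k,
        dihedrals=dihedrals, dihedral_phi0=phi0, dihedral_k=dihedral_k,
        contacts_common=c_common, r0_common=r0_common,
        contacts_unique_a=c_a, r0_unique_a=r0_a,
        contacts_unique_b=c_b, r0_unique_b=r0_b,
        r0_common_a=np.array([da[i, j] for i, j in common]) if common else np.zeros(0),
        r0_common_b=np.array([db[i, j] for i, j in common]) if common else np.zeros(0),
        params=params,
    )


def build_single_basin(ref: CaStructure,
                       contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       params: ForceFieldParams | None = None) -> DualBasinModel:
    """Single-basin model of one reference structure (no unique lists)."""
    if params is None:
        params = ForceFieldParams()
    coords = ref.coords
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 residues")
    bonds, bond_r0, angles, theta0, dihedrals, phi0 = _bonded_geometry(coords)
    contacts = sorted(contact_map(coords, contact_cutoff))
    d = pairwise_ca_distances(coords)
    c = (np.array(contacts, dtype=np.int64) if contacts
         else np.zeros((0, 2), dtype=np.int64))
    r0 = np.array([d[i, j] for i, j in contacts]) if contacts else np.zeros(0)
    empty = np.zeros((0, 2), dtype=np.int64)
    return DualBasinModel(
        n_atoms=coords.shape[0],
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_theta0=theta0,
        angle_k=np.full(len(angles), params.k_angle),
        dihedrals=dihedrals, dihedral_phi0=phi0,
        dihedral_k=np.full(len(dihedrals), params.k_dihedral),
        contacts_common=c, r0_common=r0,
        contacts_unique_a=empty, r0_unique_a=np.zeros(0),
        contacts_unique_b=empty, r0_unique_b=np.zeros(0),
        params=params,
    )
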