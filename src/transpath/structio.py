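"""Structure I/O and core geometry.

Houses the Calpha-level structural types used across the package and the
elementary geometric operations on them: PDB parsing to a one-bead-per-residue
representation, Kabsch superposition RMSD, radius of gyration, an approximate
sphere-sampling solvent-accessible surface area, and pairwise distance
matrices.

Internal units are nm everywhere; PDB files (in A) are converted on read and
write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import pdist, squareform

from .constants import (
    AA1_TO_3,
    AA3_TO_1,
    ANG_TO_NM,
    HYDROPHOBIC_RESIDUES,
    residue_radius,
)

__all__ = [
    "CaStructure",
    "StatePair",
    "SurfaceAreas",
    "Superposition",
    "read_ca_structure",
    "write_ca_pdb",
    "write_ca_table",
    "read_ca_table",
    "superpose",
    "superpose_rmsd",
    "radius_of_gyration",
    "approx_sasa",
    "pairwise_ca_distances",
]

_SS_ALPHABET = frozenset("HEC")


@dataclass(frozen=True)
class CaStructure:
    """One protein chain as sequence plus Calpha coordinates (nm).

    Parameters
    ----------
    id : str
        Identifier of the chain (free-form).
    sequence : str
        One-letter amino-acid sequence; unknown residues are ``X``.
    coords : (N, 3) ndarray
        Calpha positions in nm.
    ss : str or None
        Optional per-residue secondary-structure string over ``{H, E, C}``
        (helix, strand, coil).
    source : str
        Provenance note (file / chain the structure came from).
    """

    id: str
    sequence: str
    coords: np.ndarray
    ss: str | None = None
    source: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if coords.shape[0] != len(self.sequence):
            raise ValueError(
                f"coords rows ({coords.shape[0]}) != sequence length "
                f"({len(self.sequence)})"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        if self.ss is not None:
            if len(self.ss) != len(self.sequence):
                raise ValueError("ss length must equal sequence length")
            if not set(self.ss) <= _SS_ALPHABET:
                raise ValueError("ss may only contain H, E, C")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_coords(self, coords: np.ndarray) -> "CaStructure":
        return replace(self, coords=coords)


@dataclass(frozen=True)
class StatePair:
    """Two aligned conformational states (A, B) of the same protein.

    ``residue_map`` lists 0-based index pairs ``(index_a, index_b)`` of
    structurally equivalent residues, strictly increasing in both structures.
    """

    protein_id: str
    state_a: CaStructure
    state_b: CaStructure
    residue_map: tuple = ()
    #: residue pairs mapped despite differing amino-acid type
    substitutions: tuple = ()

    def __post_init__(self):
        rmap = tuple((int(a), int(b)) for a, b in self.residue_map)
        object.__setattr__(self, "residue_map", rmap)
        if rmap:
            ia = np.array([a for a, _ in rmap])
            ib = np.array([b for _, b in rmap])
            if np.any(np.diff(ia) <= 0) or np.any(np.diff(ib) <= 0):
                raise ValueError("residue_map must be strictly increasing")
            if ia.min() < 0 or ia.max() >= len(self.state_a):
                raise ValueError("residue_map index out of range (state A)")
            if ib.min() < 0 or ib.max() >= len(self.state_b):
                raise ValueError("residue_map index out of range (state B)")
            subs = set(self.substitutions)
            for a, b in rmap:
                if (
                    self.state_a.sequence[a] != self.state_b.sequence[b]
                    and (a, b) not in subs
                ):
                    raise ValueError(
                        f"mapped residues differ at ({a}, {b}) and are not a "
                        "recorded substitution"
                    )

    @property
    def mapped_a(self) -> np.ndarray:
        return np.array([a for a, _ in self.residue_map], dtype=int)

    @property
    def mapped_b(self) -> np.ndarray:
        return np.array([b for _, b in self.residue_map], dtype=int)

    def mapped_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.state_a.coords[self.mapped_a],
            self.state_b.coords[self.mapped_b],
        )


@dataclass(frozen=True)
class SurfaceAreas:
    """Total / polar / hydrophobic solvent-accessible surface areas (nm^2)."""

    total: float
    polar: float
    hydrophobic: float

    def __post_init__(self):
        if self.total < 0 or self.polar < 0 or self.hydrophobic < 0:
            raise ValueError("surface areas must be non-negative")
        if not np.isclose(self.total, self.polar + self.hydrophobic,
                          rtol=1e-9, atol=1e-12):
            raise ValueError("total must equal polar + hydrophobic")


@dataclass(frozen=True)
class Superposition:
    """Result of a least-squares rigid superposition (Kabsch)."""

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

class MissingChainError(ValueError):
    pass


class MissingCaError(ValueError):
    pass


def read_ca_structure(pdb_text: str, chain_id: str,
                      struct_id: str | None = None,
                      ss: str | None = None) -> CaStructure:
    """Parse one chain of a PDB document into a :class:`CaStructure`.

    Only ``ATOM`` records are considered.  Alternate locations are resolved
    by keeping the highest-occupancy copy (ties: first encountered).
    Residues are returned in author order (residue number, insertion code);
    a residue that has non-hydrogen atoms but no CA raises
    :class:`MissingCaError`.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    arr = pdb.get_structure(model=1, altloc="occupancy")
    arr = arr[~arr.hetero]
    chains = set(arr.chain_id)
    if chain_id not in chains:
        raise MissingChainError(
            f"chain {chain_id!r} not found (available: {sorted(chains)})"
        )
    arr = arr[arr.chain_id == chain_id]

    # group atoms by residue, sorted by author residue number + insertion code
    keys = sorted(set(zip(arr.res_id.tolist(), arr.ins_code.tolist())))
    seq = []
    coords = []
    for res_id, icode in keys:
        mask = (arr.res_id == res_id) & (arr.ins_code == icode)
        names = arr.atom_name[mask]
        ca = np.flatnonzero(names == "CA")
        if ca.size == 0:
            resname = arr.res_name[mask][0]
            raise MissingCaError(
                f"residue {resname} {res_id}{icode or ''} of chain "
                f"{chain_id!r} has no CA atom"
            )
        idx = np.flatnonzero(mask)[ca[0]]
        seq.append(AA3_TO_1.get(arr.res_name[idx], "X"))
        coords.append(arr.coord[idx])
    return CaStructure(
        id=struct_id or f"chain_{chain_id}",
        sequence="".join(seq),
        coords=np.asarray(coords) * ANG_TO_NM,
        ss=ss,
        source=f"pdb:{chain_id}",
    )


def write_ca_pdb(structs, path_or_buf) -> None:
    """Write one or more structures as a CA-only (multi-model) PDB file."""
    if isinstance(structs, CaStructure):
        structs = [structs]
    n = len(structs[0])
    arrays = []
    for s in structs:
        if len(s) != n:
            raise ValueError("all models must have equal length")
        arr = struc.AtomArray(n)
        arr.coord = s.coords / ANG_TO_NM
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, n + 1)
        arr.res_name[:] = [AA1_TO_3.get(a, "UNK") for a in s.sequence]
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        arrays.append(arr)
    stack = struc.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb = PDBFile()
    pdb.set_structure(stack)
    if hasattr(path_or_buf, "write"):
        pdb.write(path_or_buf)
    else:
        with open(path_or_buf, "w") as fh:
            pdb.write(fh)


def write_ca_table(struct: CaStructure, path) -> None:
    """Write a structure as a plain tab-separated table."""
    with open(path, "w") as fh:
        fh.write("# res_index\taa\tx_nm\ty_nm\tz_nm\tss\n")
        for i, aa in enumerate(struct.sequence):
            x, y, z = struct.coords[i]
            ss = struct.ss[i] if struct.ss else "."
            fh.write(f"{i}\t{aa}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{ss}\n")


def read_ca_table(path, struct_id: str = "table") -> CaStructure:
    seq, coords, ss = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, aa, x, y, z, s = line.split("\t")
            seq.append(aa)
            coords.append([float(x), float(y), float(z)])
            ss.append(s.strip())
    ss_str = "".join(ss)
    return CaStructure(
        id=struct_id,
        sequence="".join(seq),
        coords=np.array(coords),
        ss=None if "." in ss_str else ss_str,
        source=str(path),
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def superpose(coords_a: np.ndarray, coords_b: np.ndarray,
              subset=None) -> Superposition:
    """Least-squares (Kabsch) superposition of B onto A.

    Returns the optimal RMSD together with the rotation/translation that
    maps ``coords_b`` onto ``coords_a``:  ``a ~ R @ b + t``.  The RMSD is
    evaluated over ``subset`` (all points if None); the fit uses the same
    subset.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        a = a[subset]
        b = b[subset]
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if a.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    # degenerate (collinear) point sets leave the rotation about the axis free
    degenerate = bool(s[1] < 1e-12 * max(s[0], 1e-300))
    fitted = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a0) ** 2, axis=1))))
    trans = ca - rot @ cb
    return Superposition(rmsd=rmsd, rotation=rot, translation=trans,
                         degenerate=degenerate)


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                   subset=None) -> float:
    """Best-fit RMSD (nm) after Kabsch superposition."""
    return superpose(coords_a, coords_b, subset=subset).rmsd


def radius_of_gyration(struct: CaStructure | np.ndarray) -> float:
    """Unweighted radius of gyration (nm) of the Calpha positions."""
    coords = struct.coords if isinstance(struct, CaStructure) else np.asarray(struct)
    if coords.shape[0] < 1:
        raise ValueError("need at least one point")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def approx_sasa(struct: CaStructure, point_number: int = 960,
                probe_radius_nm: float = 0.0) -> SurfaceAreas:
    """Approximate solvent-accessible surface area on Calpha spheres.

    Each residue is a single sphere of a residue-type-dependent effective
    radius (fixed table in :mod:`transpath.constants`); accessibility is
    sampled Shrake-Rupley style with a deterministic Fibonacci point set.
    The polar / hydrophobic split follows the fixed residue partition.
    Returned areas are in nm^2.
    """
    n = len(struct)
    arr = struc.AtomArray(n)
    arr.coord = struct.coords / ANG_TO_NM
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, n + 1)
    arr.res_name[:] = [AA1_TO_3.get(a, "UNK") for a in struct.sequence]
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    radii_ang = np.array(
        [residue_radius(a) / ANG_TO_NM for a in struct.sequence]
    )
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius_nm / ANG_TO_NM,
        point_number=point_number,
        vdw_radii=radii_ang,
    )
    per_atom_nm2 = np.nan_to_num(per_atom) * ANG_TO_NM ** 2
    hydro_mask = np.array(
        [a in HYDROPHOBIC_RESIDUES for a in struct.sequence]
    )
    hydro = float(per_atom_nm2[hydro_mask].sum())
    polar = float(per_atom_nm2[~hydro_mask].sum())
    return SurfaceAreas(total=polar + hydro, polar=polar, hydrophobic=hydro)


def pairwise_ca_distances(struct: CaStructure | np.ndarray) -> np.ndarray:
    """Symmetric N x N matrix of Calpha-Calpha distances (nm)."""
    coords = struct.coords if isinstance(struct, CaStructure) else np.asarray(struct)
    return squareform(pdist(coords))
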