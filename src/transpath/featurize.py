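"""Sigmoid distance features, contact masks, residue importance, max-fold.

The central featurization maps a Calpha distance matrix ``r`` (nm) to

    D(r) = 1 - 1 / (1 + exp(1 - r))

so that D = 0.5 exactly at r = 1 nm (the contact-formation threshold),
D -> 0 for large separations, and D(0) = 1 - 1/(1+e) ~ 0.731.  A residue
pair is "in contact" in a state iff D >= 0.5; pairs in contact in exactly
one of two states are *unique* contacts, pairs in contact in both are
*common*, and everything else (including never-in-contact pairs) is
*non-unique*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceFeature",
    "ContactMasks",
    "sigmoid_distance",
    "inverse_sigmoid_distance",
    "contact_masks",
    "residue_importance",
    "max_fold",
    "CONTACT_THRESHOLD",
    "MIN_SEQ_SEPARATION",
]

#: D value at which a residue pair counts as a contact (r = 1 nm).
CONTACT_THRESHOLD = 0.5

#: |i - j| below which pairs are excluded from contact masks (trivially
#: near along the chain).
MIN_SEQ_SEPARATION = 3


@dataclass(frozen=True)
class DistanceFeature:
    """A symmetric sigmoid-transformed distance matrix in (0, 1-1/(1+e)]."""

    D: np.ndarray
    source: str = "state_a"

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square matrix")
        if not np.allclose(D, D.T, atol=1e-9):
            raise ValueError("D must be symmetric")
        if np.any(D < 0) or np.any(D >= 1):
            raise ValueError("D entries must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class ContactMasks:
    """Boolean pair masks: unique / common contacts and the complement."""

    unique: np.ndarray
    common: np.ndarray
    non_unique: np.ndarray

    def __post_init__(self):
        for name in ("unique", "common", "non_unique"):
            m = np.asarray(getattr(self, name), dtype=bool)
            object.__setattr__(self, name, m)
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} mask must be symmetric")
        if np.any(self.unique & self.common):
            raise ValueError("unique and common masks must be disjoint")
        if not np.array_equal(self.non_unique, ~self.unique):
            raise ValueError("non_unique must be the complement of unique")


def sigmoid_distance(r) -> np.ndarray | float:
    """Sigmoid transform of distances (nm): D = 1 - (1+e^(1-r))^-1.

    Strictly decreasing; D(1 nm) = 0.5 exactly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r < 0):
        raise ValueError("distances must be finite and non-negative")
    d = 1.0 - 1.0 / (1.0 + np.exp(1.0 - r))
    return float(d) if d.ndim == 0 else d


def inverse_sigmoid_distance(d) -> np.ndarray | float:
    """Inverse of :func:`sigmoid_distance`: r = 1 - log(D / (1 - D))."""
    d = np.asarray(d, dtype=float)
    dmax = 1.0 - 1.0 / (1.0 + np.e)
    if np.any(d <= 0) or np.any(d > dmax):
        raise ValueError(f"D must lie in (0, {dmax:.6f}] to invert")
    r = 1.0 - np.log(d / (1.0 - d))
    return float(r) if r.ndim == 0 else r


def feature_from_distances(r: np.ndarray, source: str = "state_a") -> DistanceFeature:
    """Convenience: build a :class:`DistanceFeature` from a distance matrix."""
    return DistanceFeature(D=sigmoid_distance(r), source=source)


def contact_masks(da: DistanceFeature | np.ndarray,
                  db: DistanceFeature | np.ndarray,
                  min_separation: int = MIN_SEQ_SEPARATION) -> ContactMasks:
    """Unique / common / non-unique contact masks for a two-state pair.

    A pair is a contact in a state iff D >= 0.5.  Pairs with
    ``|i - j| < min_separation`` are excluded from both the unique and the
    common mask (they are trivially always near along the chain).
    """
    Da = da.D if isinstance(da, DistanceFeature) else np.asarray(da)
    Db = db.D if isinstance(db, DistanceFeature) else np.asarray(db)
    if Da.shape != Db.shape:
        raise ValueError("feature matrices must have equal shapes")
    n = Da.shape[0]
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) < min_separation
    ca = Da >= CONTACT_THRESHOLD
    cb = Db >= CONTACT_THRESHOLD
    unique = (ca ^ cb) & ~near
    common = (ca & cb) & ~near
    return ContactMasks(unique=unique, common=common, non_unique=~unique)


def residue_importance(d_ts: DistanceFeature | np.ndarray,
                       d_native: DistanceFeature | np.ndarray) -> np.ndarray:
    """Per-residue contact-loss score between a high-energy and native state.

    For each residue i the negative parts of the difference matrix
    ``dD = D_ts - D_native`` are summed over partners j and negated, so a
    larger score means more contact loss at the transition.
    """
    Dts = d_ts.D if isinstance(d_ts, DistanceFeature) else np.asarray(d_ts)
    Dn = d_native.D if isinstance(d_native, DistanceFeature) else np.asarray(d_native)
    if Dts.shape != Dn.shape:
        raise ValueError("feature matrices must have equal shapes")
    delta = Dts - Dn
    return -np.minimum(delta, 0.0).sum(axis=1)


def max_fold(x_path, x_a: float, x_b: float) -> float:
    """Ratio of a property's pathway maximum to its endpoint maximum."""
    x_path = np.asarray(x_path, dtype=float)
    if x_path.size == 0:
        raise ValueError("pathway series is empty")
    denom = max(x_a, x_b)
    if denom <= 0:
        raise ValueError("max(x_a, x_b) must be positive")
    return float(x_path.max() / denom)
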