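"""Well-tempered metadynamics bookkeeping and free-energy estimation.

Gaussians of width ``w`` are deposited along the collective variables every
``stride`` steps; in the well-tempered scheme the deposit height decays with
the bias already present,

    h = h0 * exp(-V_bias(s) / (kB * dT)),   dT = (gamma - 1) T,

and the free energy is recovered from the accumulated bias as

    F(s) = -(gamma / (gamma - 1)) * V_bias(s),

shifted so its minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import KB

__all__ = [
    "MetaDParams",
    "HillsLog",
    "FreeEnergySurface",
    "bias_potential",
    "bias_force",
    "compute_fes",
    "compute_fes_1d",
]


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics parameters."""

    stride: int = 500            # steps between deposits
    height0: float = 1.0         # initial Gaussian height, kJ/mol
    width: float = 0.05          # Gaussian width in CV units (nm)
    bias_factor: float = 50.0    # gamma, dimensionless
    temperature: float = 110.0   # K

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.height0 <= 0 or self.width <= 0:
            raise ValueError("height0 and width must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")

    @property
    def delta_t(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature


@dataclass
class HillsLog:
    """Record of deposited Gaussians: step, center(s), width(s), height."""

    steps: np.ndarray            # (k,) int
    centers: np.ndarray          # (k, d)
    widths: np.ndarray           # (k, d)
    heights: np.ndarray          # (k,) kJ/mol
    params: MetaDParams | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.steps) and np.any(np.diff(self.steps) <= 0):
            raise ValueError("hill steps must be strictly increasing")
        if np.any(self.heights <= 0):
            raise ValueError("hill heights must be positive")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def n_cvs(self) -> int:
        return self.centers.shape[1]

    def write(self, path) -> None:
        p = self.params
        with open(path, "w") as fh:
            fh.write("# hills log: step cv... width... height\n")
            if p is not None:
                fh.write(f"# stride={p.stride} height0={p.height0} "
                         f"width={p.width} bias_factor={p.bias_factor} "
                         f"temperature={p.temperature}\n")
            for s, c, w, h in zip(self.steps, self.centers, self.widths,
                                  self.heights):
                cols = [str(s)] + [f"{x:.8g}" for x in c] \
                    + [f"{x:.8g}" for x in w] + [f"{h:.8g}"]
                fh.write(" ".join(cols) + "\n")

    @classmethod
    def read(cls, path, params: MetaDParams | None = None) -> "HillsLog":
        rows = []
        header = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=")
                            header[k] = float(v)
                    continue
                if line.strip():
                    rows.append([float(x) for x in line.split()])
        arr = np.array(rows)
        d = (arr.shape[1] - 2) // 2
        if params is None and header:
            params = MetaDParams(
                stride=int(header.get("stride", 500)),
                height0=header.get("height0", 1.0),
                width=header.get("width", 0.05),
                bias_factor=header.get("bias_factor", 50.0),
                temperature=header.get("temperature", 110.0),
            )
        return cls(steps=arr[:, 0].astype(np.int64),
                   centers=arr[:, 1:1 + d],
                   widths=arr[:, 1 + d:1 + 2 * d],
                   heights=arr[:, -1], params=params)


def bias_potential(centers, widths, heights, s) -> float:
    """Sum of deposited Gaussians evaluated at CV point(s) ``s``."""
    if len(heights) == 0:
        return 0.0
    s = np.atleast_1d(np.asarray(s, dtype=float))
    z = (s[None, :] - centers) / widths
    return float(np.sum(heights * np.exp(-0.5 * np.sum(z * z, axis=1))))


def bias_force(centers, widths, heights, s) -> np.ndarray:
    """-dV_bias/ds at CV point ``s`` (length-d array)."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if len(heights) == 0:
        return np.zeros_like(s)
    z = (s[None, :] - centers) / widths
    g = heights * np.exp(-0.5 * np.sum(z * z, axis=1))
    return np.sum(g[:, None] * z / widths, axis=0)


@dataclass
class FreeEnergySurface:
    """Free energy (kJ/mol) on a regular 2D grid over (cv1, cv2)."""

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    F: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cv1_edges = np.asarray(self.cv1_edges, dtype=float)
        self.cv2_edges = np.asarray(self.cv2_edges, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (len(self.cv1_edges), len(self.cv2_edges)):
            raise ValueError("F shape must match the grid node counts")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite on the declared domain")
        if abs(self.F.min()) > 1e-9:
            raise ValueError("F must be shifted so min(F) == 0")

    @property
    def shape(self):
        return self.F.shape

    @property
    def spacing(self):
        return (float(self.cv1_edges[1] - self.cv1_edges[0]),
                float(self.cv2_edges[1] - self.cv2_edges[0]))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cv1\tcv2\tF_kJ_mol\n")
            for k, v in self.metadata.items():
                fh.write(f"# {k}={v}\n")
            for i, x in enumerate(self.cv1_edges):
                for j, y in enumerate(self.cv2_edges):
                    fh.write(f"{x:.8g}\t{y:.8g}\t{self.F[i, j]:.8g}\n")

    @classmethod
    def read_tsv(cls, path) -> "FreeEnergySurface":
        xs, ys, fs = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                x, y, f = line.split("\t")
                xs.append(float(x)); ys.append(float(y)); fs.append(float(f))
        cv1 = np.unique(xs)
        cv2 = np.unique(ys)
        F = np.asarray(fs).reshape(len(cv1), len(cv2))
        return cls(cv1_edges=cv1, cv2_edges=cv2, F=F)

    def save_npz(self, path) -> None:
        np.savez(path, cv1_edges=self.cv1_edges, cv2_edges=self.cv2_edges,
                 F=self.F)

    @classmethod
    def load_npz(cls, path) -> "FreeEnergySurface":
        data = np.load(path)
        return cls(cv1_edges=data["cv1_edges"], cv2_edges=data["cv2_edges"],
                   F=data["F"])


def _wt_prefactor(bias_factor: float) -> float:
    return bias_factor / (bias_factor - 1.0)


def compute_fes(hills: HillsLog, cv1_edges, cv2_edges,
                bias_factor: float | None = None) -> FreeEnergySurface:
    """Well-tempered free-energy estimate on a 2D grid from a hills log.

    F = -(gamma/(gamma-1)) * V_bias, shifted so min F = 0.  Emits a warning
    with the clipped fraction if hill centers fall outside the grid.
    """
    if len(hills) == 0:
        raise ValueError("hills log is empty")
    if hills.n_cvs != 2:
        raise ValueError("compute_fes expects 2 collective variables")
    if bias_factor is None:
        bias_factor = hills.params.bias_factor if hills.params else 50.0
    cv1_edges = np.asarray(cv1_edges, dtype=float)
    cv2_edges = np.asarray(cv2_edges, dtype=float)

    outside = (
        (hills.centers[:, 0] < cv1_edges[0])
        | (hills.centers[:, 0] > cv1_edges[-1])
        | (hills.centers[:, 1] < cv2_edges[0])
        | (hills.centers[:, 1] > cv2_edges[-1])
    )
    meta = {}
    if outside.any():
        frac = outside.mean()
        import warnings
        warnings.warn(f"{frac:.1%} of hill centers lie outside the grid")
        meta["clipped_fraction"] = float(frac)

    x = cv1_edges[:, None, None]
    y = cv2_edges[None, :, None]
    zx = (x - hills.centers[:, 0]) / hills.widths[:, 0]
    zy = (y - hills.centers[:, 1]) / hills.widths[:, 1]
    vbias = np.sum(hills.heights * np.exp(-0.5 * (zx ** 2 + zy ** 2)), axis=2)
    F = -_wt_prefactor(bias_factor) * vbias
    F -= F.min()
    meta["bias_factor"] = float(bias_factor)
    return FreeEnergySurface(cv1_edges=cv1_edges, cv2_edges=cv2_edges,
                             F=F, metadata=meta)


def compute_fes_1d(hills: HillsLog, edges,
                   bias_factor: float | None = None):
    """1D analogue of :func:`compute_fes`; returns (grid, F)."""
    if len(hills) == 0:
        raise ValueError("hills log is empty")
    if hills.n_cvs != 1:
        raise ValueError("compute_fes_1d expects 1 collective variable")
    if bias_factor is None:
        bias_factor = hills.params.bias_factor if hills.params else 50.0
    edges = np.asarray(edges, dtype=float)
    z = (edges[:, None] - hills.centers[:, 0]) / hills.widths[:, 0]
    vbias = np.sum(hills.heights * np.exp(-0.5 * z ** 2), axis=1)
    F = -_wt_prefactor(bias_factor) * vbias
    return edges, F - F.min()
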