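"""Acquisition protocol constants and diffusion gradient tables.

The default protocol mirrors a 3 T multi-contrast post mortem brain study:
an inversion-recovery spin-echo (IR-SE) series with six inversion times for
T1 mapping, a 12-echo spin-echo (SE) series for T2, a 12-echo gradient-echo
(GRE) series for T2*, and a single-shell diffusion acquisition at
b = 2000 s/mm^2 with 64 isotropically distributed directions plus three
unweighted volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "default_protocol",
    "isotropic_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

# IR-SE inversion times (ms)
IR_TI_MS = (30.0, 80.0, 200.0, 400.0, 700.0, 1200.0)
IR_TE_MS = 12.0
IR_TR_MS = 7060.0

# Multi-contrast SE echo times (ms).  The third echo follows the 9.8 ms
# arithmetic progression of the series (29.4 ms).
SE_TE_MS = (9.8, 19.6, 29.4, 39.2, 49.0, 58.8, 68.6, 78.4, 88.2, 98.0, 107.8, 117.6)
SE_TR_MS = 5720.0

# Multi-echo GRE echo times (ms)
GRE_TE_MS = (5.79, 10.34, 14.40, 18.46, 22.52, 26.58, 30.64, 34.70, 38.76, 42.82, 46.88, 50.94)
GRE_TR_MS = 68.0

DWI_B_S_MM2 = 2000.0
DWI_N_DIRECTIONS = 64
DWI_N_B0 = 3
DWI_TE_MS = 109.0
DWI_TR_MS = 18700.0


def isotropic_directions(n: int) -> np.ndarray:
    """Return ``n`` approximately uniformly distributed unit vectors.

    Uses the spherical Fibonacci lattice, which gives a deterministic,
    well-spread direction set adequate for tensor estimation (any set with
    >= 6 non-collinear directions determines the tensor).
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    # golden-angle longitude, equal-area latitude
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence timing constants parameterizing simulation and fitting.

    All times in ms, b-value in s/mm^2.  ``gradient_set`` holds one unit
    vector per diffusion-weighted direction.
    """

    ti_list: tuple = IR_TI_MS
    ir_te: float = IR_TE_MS
    ir_tr: float = IR_TR_MS
    se_te_list: tuple = SE_TE_MS
    se_tr: float = SE_TR_MS
    gre_te_list: tuple = GRE_TE_MS
    gre_tr: float = GRE_TR_MS
    b_value: float = DWI_B_S_MM2
    n_directions: int = DWI_N_DIRECTIONS
    n_b0: int = DWI_N_B0
    dwi_te: float = DWI_TE_MS
    dwi_tr: float = DWI_TR_MS
    gradient_set: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.gradient_set is None:
            object.__setattr__(self, "gradient_set", isotropic_directions(self.n_directions))
        else:
            g = np.asarray(self.gradient_set, dtype=float)
            object.__setattr__(self, "gradient_set", g)
        self.validate()

    def validate(self) -> None:
        ti = np.asarray(self.ti_list, dtype=float)
        se = np.asarray(self.se_te_list, dtype=float)
        gre = np.asarray(self.gre_te_list, dtype=float)
        for name, arr in (("ti_list", ti), ("se_te_list", se), ("gre_te_list", gre)):
            if arr.size == 0 or np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(np.diff(ti) <= 0):
            raise ValueError("ti_list must be strictly increasing")
        for te, tr, seq in (
            (self.ir_te, self.ir_tr, "IR-SE"),
            (se.max(), self.se_tr, "SE"),
            (gre.max(), self.gre_tr, "GRE"),
            (self.dwi_te, self.dwi_tr, "DWI"),
        ):
            if tr <= 0 or te >= tr:
                raise ValueError(f"{seq}: need 0 < TE < TR (got TE={te}, TR={tr})")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.n_directions < 6:
            raise ValueError("tensor fitting needs at least 6 directions")
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 volume")
        g = self.gradient_set
        if g.shape != (self.n_directions, 3):
            raise ValueError("gradient_set shape must be (n_directions, 3)")
        if np.any(np.abs(np.linalg.norm(g, axis=1) - 1.0) > 1e-6):
            raise ValueError("gradient vectors must be unit-norm")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["gradient_set"] = np.asarray(self.gradient_set).tolist()
        for k in ("ti_list", "se_te_list", "gre_te_list"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        for k in ("ti_list", "se_te_list", "gre_te_list"):
            if k in d:
                d[k] = tuple(d[k])
        if d.get("gradient_set") is not None:
            d["gradient_set"] = np.asarray(d["gradient_set"], dtype=float)
        return cls(**d)

    @property
    def bvals(self) -> np.ndarray:
        """Per-volume b-values, b=0 volumes first (FSL convention)."""
        return np.concatenate([np.zeros(self.n_b0), np.full(self.n_directions, self.b_value)])

    @property
    def bvecs(self) -> np.ndarray:
        """Per-volume gradient vectors, shape (n_b0 + n_directions, 3)."""
        return np.vstack([np.zeros((self.n_b0, 3)), self.gradient_set])


def default_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient tables (one row of b-values; three rows of
    x/y/z components)."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvecs must have shape (n_volumes, 3)")
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
    rows = [" ".join(f"{v:.8f}" for v in bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple:
    """Read FSL-dialect gradient tables -> (bvals (n,), bvecs (n, 3))."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3 table: FSL writes component-major, so transpose
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvec table does not match bval count")
    return bvals, bvecs
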