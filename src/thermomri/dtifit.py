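"""Diffusion tensor estimation and scalar invariants (MD, FA).

The tensor is estimated per voxel by ordinary least squares on
log-signals against the design matrix of the mono-exponential tensor model
log S = log S0 - b g^T D g (the standard log-linear fit).  b=0 volumes are
averaged before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionTensor",
    "design_matrix",
    "fit_tensor",
    "compute_md",
    "compute_fa",
    "fa_from_eigenvalues",
    "fit_dti_maps",
]

_SIGNAL_FLOOR_FRAC = 1e-6  # clamp for non-positive DW signals, relative to S0


@dataclass
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor (mm^2/s) with sorted eigenvalues."""

    tensor: np.ndarray  # (3, 3)
    s0: float
    eigenvalues: np.ndarray = None  # descending
    eigenvectors: np.ndarray = None  # columns match eigenvalues
    clamped: bool = False  # any non-positive input signal floored
    negative_eigenvalues: bool = False

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(self.tensor, self.tensor.T, atol=1e-10):
            raise ValueError("tensor must be symmetric")
        if self.eigenvalues is None:
            w, v = np.linalg.eigh(self.tensor)
            order = np.argsort(w)[::-1]
            self.eigenvalues = w[order]
            self.eigenvectors = v[:, order]
        self.negative_eigenvalues = bool(np.any(self.eigenvalues < 0))


def design_matrix(b_values, directions) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    if g.shape != (b.size, 3):
        raise ValueError("directions must have shape (n, 3)")
    X = np.empty((b.size, 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def fit_tensor(signals, b_values, directions) -> DiffusionTensor:
    """Log-linear OLS tensor fit.

    ``signals`` are per-volume magnitudes; ``b_values`` per-volume b
    (s/mm^2) with >= 1 zero entry; ``directions`` the per-volume unit
    gradients (rows for b=0 volumes are ignored).  b=0 volumes are averaged
    into a single sample.  Non-positive diffusion-weighted signals are
    clamped to a small floor and flagged.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    if s.shape != (b.size,) or g.shape != (b.size, 3):
        raise ValueError("signals, b_values and directions must be per-volume")
    b0_mask = b == 0
    if not b0_mask.any():
        raise ValueError("need at least one b=0 volume")
    dw_mask = ~b0_mask
    if dw_mask.sum() < 6:
        raise ValueError("need at least 6 diffusion-weighted directions")
    norms = np.linalg.norm(g[dw_mask], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("diffusion-weighted directions must be unit-norm")

    s0_mean = float(np.mean(s[b0_mask]))
    if s0_mean <= 0:
        raise ValueError("mean b=0 signal must be positive")
    sdw = s[dw_mask]
    clamped = bool(np.any(sdw <= 0))
    sdw = np.maximum(sdw, _SIGNAL_FLOOR_FRAC * s0_mean)

    y = np.concatenate([[np.log(s0_mean)], np.log(sdw)])
    bb = np.concatenate([[0.0], b[dw_mask]])
    gg = np.vstack([[0.0, 0.0, 0.0], g[dw_mask]])
    X = design_matrix(bb, gg)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(f"rank-deficient diffusion design (rank {rank} < 7): "
                         "directions are collinear or degenerate")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    return DiffusionTensor(tensor=D, s0=float(np.exp(beta[0])), clamped=clamped)


def compute_md(tensor) -> float:
    """Mean diffusivity: trace(D)/3 = (l1 + l2 + l3)/3, in mm^2/s."""
    if isinstance(tensor, DiffusionTensor):
        return float(np.sum(tensor.eigenvalues) / 3.0)
    return float(np.trace(np.asarray(tensor, dtype=float)) / 3.0)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, negative eigenvalues
    clamped to zero.  Vectorized over leading axes; zero tensors give NaN."""
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - md) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    return np.clip(fa, 0.0, 1.0) if np.ndim(fa) else float(np.clip(fa, 0.0, 1.0))


def compute_fa(tensor) -> float:
    """Fractional anisotropy in [0, 1]; NaN (flagged invalid) for the zero
    tensor.  Negative eigenvalues are clamped to zero first."""
    if isinstance(tensor, DiffusionTensor):
        evals = tensor.eigenvalues
    else:
        evals = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))[::-1]
    return float(fa_from_eigenvalues(evals))


def fit_dti_maps(dwi_4d, b_values, directions, mask, voxel_size=(1.0, 1.0, 1.0)) -> dict:
    """Voxel-wise tensor fit over a mask -> MD / FA / S0 maps and flags.

    Returns dict with 'MD', 'FA', 'S0' (:class:`~thermomri.relaxfit.VoxelMap`),
    'tensor' (…,3,3 array) and 'flags' (clamped / negative-eigenvalue masks).
    """
    from .relaxfit import VoxelMap  # local import avoids a cycle

    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    md = np.full(shape, np.nan)
    fa = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    tensors = np.full(shape + (3, 3), np.nan)
    clamped = np.zeros(shape, dtype=bool)
    neg = np.zeros(shape, dtype=bool)
    if mask.any():
        # vectorized log-linear solve over all masked voxels at once
        b = np.asarray(b_values, dtype=float)
        g = np.asarray(directions, dtype=float)
        b0_mask = b == 0
        if not b0_mask.any():
            raise ValueError("need at least one b=0 volume")
        sig = np.asarray(dwi_4d, dtype=float)[mask]  # (n_vox, n_vol)
        s0_mean = sig[:, b0_mask].mean(axis=1)
        sdw = sig[:, ~b0_mask]
        clamp_vox = (sdw <= 0).any(axis=1) | (s0_mean <= 0)
        s0_mean = np.maximum(s0_mean, np.finfo(float).tiny)
        sdw = np.maximum(sdw, _SIGNAL_FLOOR_FRAC * s0_mean[:, None])
        y = np.concatenate([np.log(s0_mean)[:, None], np.log(sdw)], axis=1)
        bb = np.concatenate([[0.0], b[~b0_mask]])
        gg = np.vstack([[0.0, 0.0, 0.0], g[~b0_mask]])
        X = design_matrix(bb, gg)
        if np.linalg.matrix_rank(X) < 7:
            raise ValueError("rank-deficient diffusion design: directions are "
                             "collinear or degenerate")
        beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (n_vox, 7)
        dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(1, 7))
        D = np.empty((beta.shape[0], 3, 3))
        D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dxx, dyy, dzz
        D[:, 0, 1] = D[:, 1, 0] = dxy
        D[:, 0, 2] = D[:, 2, 0] = dxz
        D[:, 1, 2] = D[:, 2, 1] = dyz
        evals = np.linalg.eigvalsh(D)[:, ::-1]
        md[mask] = evals.mean(axis=1)
        fa[mask] = fa_from_eigenvalues(evals)
        s0[mask] = np.exp(beta[:, 0])
        tensors[mask] = D
        clamped[mask] = clamp_vox
        neg[mask] = (evals < 0).any(axis=1)
    return {
        "MD": VoxelMap(md, "MD", "mm^2/s", voxel_size),
        "FA": VoxelMap(fa, "FA", "dimensionless", voxel_size),
        "S0": VoxelMap(s0, "M0", "a.u.", voxel_size),
        "tensor": tensors,
        "flags": {"clamped": clamped, "negative_eigenvalues": neg},
    }
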