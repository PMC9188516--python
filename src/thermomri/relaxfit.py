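"""Voxel-wise relaxometry: mono-exponential T2/T2* fits and the
three-parameter (M0, p, T1) inversion-recovery fit.

The IR-SE model is S = M0 exp(-TE/T2) (1 - p exp(-TI/T1) + exp(-TR/T1)),
fitted per voxel with the voxel's T2 fixed from the preceding
mono-exponential fit.  Magnitude IR data lose the sign of the recovery
curve; polarity is restored by trying every prefix of inversion times as
negative, fitting each candidate and keeping the lowest-residual solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol

__all__ = [
    "VoxelMap",
    "FitDiagnostics",
    "ScalarFit",
    "fit_monoexp",
    "fit_t1_ir",
    "fit_maps",
]

_XTOL = 1e-10
_MAX_NFEV = 500


@dataclass
class VoxelMap:
    """One quantitative parameter volume.  Invalid voxels are NaN."""

    values: np.ndarray
    parameter_kind: str  # T1 | T2 | T2star | MD | FA | M0 | p
    units: str  # "ms" | "mm^2/s" | "a.u." | "dimensionless"
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.parameter_kind == "FA":
            finite = np.isfinite(self.values)
            if finite.any() and (np.nanmin(self.values[finite]) < -1e-9
                                 or np.nanmax(self.values[finite]) > 1 + 1e-9):
                raise ValueError("FA values must lie in [0, 1]")


@dataclass
class FitDiagnostics:
    """Per-voxel fit quality: residual norm, convergence flag, iterations."""

    residual_norm: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray


@dataclass
class ScalarFit:
    """Result of a single-voxel fit."""

    params: dict
    residual_norm: float
    converged: bool
    n_iter: int = 0


def _invalid(params: dict) -> ScalarFit:
    return ScalarFit({k: np.nan for k in params}, np.nan, False)


def fit_monoexp(signals, te_list) -> ScalarFit:
    """Two-parameter mono-exponential fit S = S0 exp(-TE/T2).

    Nonlinear least squares initialized from the log-linear regression of
    log(signal) on TE.  Returns NaN parameters with ``converged=False`` for
    degenerate voxels (all-zero or non-decaying signal) instead of raising.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(te_list, dtype=float)
    if s.shape != te.shape:
        raise ValueError("signals and te_list must have equal length")
    if te.size < 3:
        raise ValueError("need at least 3 echoes")
    if np.any(s < 0):
        raise ValueError("magnitude signals must be non-negative")
    pos = s > 0
    if pos.sum() < 3:
        return _invalid({"s0": 0, "t2": 0})
    slope, intercept = np.polyfit(te[pos], np.log(s[pos]), 1)
    if slope >= -1e-12:  # non-decaying: no finite positive decay constant
        return _invalid({"s0": 0, "t2": 0})
    t2_init = -1.0 / slope
    s0_init = float(np.exp(intercept))

    def resid(theta):
        return theta[0] * np.exp(-te / theta[1]) - s

    def jac(theta):
        e = np.exp(-te / theta[1])
        return np.column_stack([e, theta[0] * e * te / theta[1] ** 2])

    res = least_squares(resid, x0=[s0_init, t2_init], jac=jac,
                        bounds=([0.0, 1e-3], [np.inf, 1e7]),
                        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL, max_nfev=_MAX_NFEV, method="trf")
    s0, t2 = res.x
    ok = res.success and t2 > 0
    if not ok:
        return _invalid({"s0": 0, "t2": 0})
    return ScalarFit({"s0": float(s0), "t2": float(t2)},
                     float(np.linalg.norm(res.fun)), True, int(res.nfev))


def _fit_ir_signed(signed, ti, te, tr, t2_voxel, x0=None, xtol=_XTOL, max_nfev=_MAX_NFEV):
    """Trust-region LS fit of (m0, p, t1) to signed IR data."""
    s_abs_max = float(np.max(np.abs(signed)))
    if s_abs_max == 0:
        return None
    e_te = np.exp(-te / t2_voxel)
    if x0 is not None:
        m0_init, p_init, t1_init = x0
    else:
        # initialize T1 from the zero-crossing (null point): TI_null ~ T1 ln 2
        sign_change = np.nonzero(np.diff(np.signbit(signed)))[0]
        if sign_change.size:
            ti_null = 0.5 * (ti[sign_change[0]] + ti[sign_change[0] + 1])
            t1_init = max(ti_null / np.log(2.0), 1.0)
        else:
            t1_init = max(float(np.median(ti)), 1.0)
        p_init = 2.0
        m0_init = max(abs(signed[-1]) / max(e_te, 1e-12), 1e-6)

    def resid(theta):
        m0, p, t1 = theta
        return (m0 * e_te * (1.0 - p * np.exp(-ti / t1) + np.exp(-tr / t1)) - signed)

    def jac(theta):
        m0, p, t1 = theta
        e1 = np.exp(-ti / t1)
        e2 = np.exp(-tr / t1)
        return np.column_stack([
            e_te * (1.0 - p * e1 + e2),
            -m0 * e_te * e1,
            m0 * e_te * (-p * e1 * ti + e2 * tr) / t1 ** 2,
        ])

    res = least_squares(resid, x0=[m0_init, p_init, t1_init], jac=jac,
                        bounds=([0.0, 1e-3, 1e-2], [np.inf, 2.0, 1e6]),
                        x_scale=[max(m0_init, 1e-6), 1.0, max(t1_init, 1.0)],
                        xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev, method="trf")
    return res


def fit_t1_ir(signals, ti_list, te, tr, t2_voxel, magnitude: bool = True) -> ScalarFit:
    """Three-parameter (M0, p, T1) inversion-recovery fit.

    ``t2_voxel`` is the voxel's T2 from :func:`fit_monoexp`; the factor
    exp(-TE/T2) is evaluated with it so that M0 is a true equilibrium
    magnetization estimate.  With ``magnitude=True`` (default) the sign of
    early inversion times is restored by exhaustive prefix search: for
    every k, the first k samples are negated, the model is fitted, and the
    lowest-residual candidate wins.  Signed input is fitted directly.
    """
    s = np.asarray(signals, dtype=float)
    ti = np.asarray(ti_list, dtype=float)
    if s.shape != ti.shape:
        raise ValueError("signals and ti_list must have equal length")
    if ti.size < 4:
        raise ValueError("need at least 4 inversion times")
    if not np.isfinite(t2_voxel) or t2_voxel <= 0:
        return _invalid({"m0": 0, "p": 0, "t1": 0})
    if magnitude and np.any(s < 0):
        raise ValueError("magnitude data must be non-negative")

    if magnitude:
        candidates = []
        for k in range(ti.size + 1):
            signed = s.copy()
            signed[:k] *= -1.0
            candidates.append(signed)
    else:
        candidates = [s]

    # screen every polarity candidate cheaply, then refine the winner
    best = None
    best_signed = None
    screen_tol = 1e-6 if len(candidates) > 1 else _XTOL
    for signed in candidates:
        res = _fit_ir_signed(signed, ti, float(te), float(tr), float(t2_voxel),
                             xtol=screen_tol, max_nfev=60)
        if res is None:
            continue
        if best is None or res.cost < best.cost:
            best = res
            best_signed = signed
    if best is not None and len(candidates) > 1:
        best = _fit_ir_signed(best_signed, ti, float(te), float(tr), float(t2_voxel),
                              x0=best.x) or best
    if best is None or not best.success:
        return _invalid({"m0": 0, "p": 0, "t1": 0})
    m0, p, t1 = best.x
    if t1 <= 0 or not 0 < p <= 2.0 + 1e-9:
        return _invalid({"m0": 0, "p": 0, "t1": 0})
    return ScalarFit({"m0": float(m0), "p": float(p), "t1": float(t1)},
                     float(np.linalg.norm(best.fun)), True, int(best.nfev))


def fit_maps(signals: dict, protocol: AcquisitionProtocol, mask: np.ndarray,
             voxel_size=(1.0, 1.0, 1.0), magnitude: bool = True) -> dict:
    """Apply the relaxometry fits voxel-wise within ``mask``.

    ``signals`` holds 4D arrays keyed ``se``, ``gre`` and ``ir`` (any subset;
    T1 requires both ``se`` and ``ir``).  Returns a dict of
    :class:`VoxelMap` ("T2", "T2star", "T1", "M0", "p") plus a
    "diagnostics" entry mapping parameter -> :class:`FitDiagnostics`.
    Voxels outside the mask (and failed voxels) are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    out: dict = {"diagnostics": {}}

    def empty():
        return np.full(shape, np.nan)

    def run(name, arr4d, te_list):
        values = empty()
        rn, conv, nit = empty(), np.zeros(shape, dtype=bool), np.zeros(shape, dtype=int)
        s0map = empty()
        for idx in np.argwhere(mask):
            fit = fit_monoexp(arr4d[tuple(idx)], te_list)
            values[tuple(idx)] = fit.params["t2"]
            s0map[tuple(idx)] = fit.params["s0"]
            rn[tuple(idx)] = fit.residual_norm
            conv[tuple(idx)] = fit.converged
            nit[tuple(idx)] = fit.n_iter
        out[name] = VoxelMap(values, name, "ms", voxel_size)
        out["diagnostics"][name] = FitDiagnostics(rn, conv, nit)
        return values

    t2_values = None
    if "se" in signals:
        if signals["se"].shape[:3] != shape:
            raise ValueError("signal volumes and mask must share geometry")
        t2_values = run("T2", signals["se"], np.asarray(protocol.se_te_list))
    if "gre" in signals:
        if signals["gre"].shape[:3] != shape:
            raise ValueError("signal volumes and mask must share geometry")
        run("T2star", signals["gre"], np.asarray(protocol.gre_te_list))

    if "ir" in signals:
        if t2_values is None:
            raise ValueError("T1 fitting requires the SE series (per-voxel T2)")
        ti = np.asarray(protocol.ti_list)
        t1v, m0v, pv = empty(), empty(), empty()
        rn, conv, nit = empty(), np.zeros(shape, dtype=bool), np.zeros(shape, dtype=int)
        for idx in np.argwhere(mask):
            t2_voxel = t2_values[tuple(idx)]
            if not np.isfinite(t2_voxel):
                continue  # skipped: no valid T2 for this voxel
            fit = fit_t1_ir(signals["ir"][tuple(idx)], ti, protocol.ir_te,
                            protocol.ir_tr, t2_voxel, magnitude=magnitude)
            t1v[tuple(idx)] = fit.params["t1"]
            m0v[tuple(idx)] = fit.params["m0"]
            pv[tuple(idx)] = fit.params["p"]
            rn[tuple(idx)] = fit.residual_norm
            conv[tuple(idx)] = fit.converged
            nit[tuple(idx)] = fit.n_iter
        out["T1"] = VoxelMap(t1v, "T1", "ms", voxel_size)
        out["M0"] = VoxelMap(m0v, "M0", "a.u.", voxel_size)
        out["p"] = VoxelMap(pv, "p", "dimensionless", voxel_size)
        out["diagnostics"]["T1"] = FitDiagnostics(rn, conv, nit)
    return out
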