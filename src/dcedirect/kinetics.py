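"""Tracer-kinetic models and voxelwise fitting.

Two nested compartment models link tissue concentration Ct(t) to the plasma
input function Cp(t):

* Patlak (negligible backflux from the EES):
      Ct(t) = vp Cp(t) + Ktrans \\int_0^t Cp(tau) dtau
* extended Tofts (bidirectional plasma <-> EES exchange):
      Ct(t) = vp Cp(t) + Ktrans \\int_0^t Cp(tau) e^{-kep (t - tau)} dtau

Rates Ktrans and kep are in min^-1; the time axis is converted to minutes at
this boundary. Quadrature is cumulative trapezoid on the native acquisition
grid; the exponential convolution uses the recursion

    I_i = E_i I_{i-1} + (dt_i / 2) (Cp_i + E_i Cp_{i-1}),   E_i = e^{-kep dt_i},

which reduces bit-exactly to the cumulative trapezoid when kep = 0, so the
Patlak model is the exact kep -> 0 limit of extended Tofts here, not merely an
approximation.

Patlak parameters are fitted by ordinary linear least squares (closed form);
extended Tofts by bounded limited-memory BFGS with an analytic gradient,
capped at 30 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    DynamicSeries,
    FitReport,
    InputFunction,
    PkMaps,
)

__all__ = [
    "extract_vif",
    "blood_to_plasma",
    "patlak_forward",
    "etofts_forward",
    "exp_conv",
    "exp_conv_grad_kep",
    "fit_patlak",
    "fit_etofts",
    "fit_volume",
    "PatlakModel",
    "ExtendedToftsModel",
    "PkResults",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]

# box bounds and initial point for the eTofts NLS (brain low-permeability
# regime): Ktrans in [0, 0.1] min^-1, kep in [0, 10] min^-1, vp in [0, 1]
DEFAULT_BOUNDS = ((0.0, 0.1), (0.0, 10.0), (0.0, 1.0))
DEFAULT_INIT = (1e-3, 0.1, 0.02)

# internal NLS parameter scaling: typical brain magnitudes, so the scaled
# coordinates are all O(1) and the quasi-Newton Hessian is well conditioned
_NLS_SCALE = np.array([1e-3, 0.3, 0.01])


def extract_vif(series: DynamicSeries, center_voxel: Sequence[int]) -> InputFunction:
    """Average the time courses of the in-plane 3x3 patch around a voxel.

    The vascular input function is taken from a small venous region (e.g. the
    superior sagittal sinus); averaging 9 voxels reduces the noise standard
    deviation threefold. The returned curve carries the series' quantity
    as-is — signal curves still need conversion to concentration, and
    whole-blood concentration needs :func:`blood_to_plasma`.
    """
    x, y, z = (int(v) for v in center_voxel)
    nx, ny, nz, _ = series.values.shape
    if not (1 <= x <= nx - 2 and 1 <= y <= ny - 2 and 0 <= z <= nz - 1):
        raise ValueError(
            f"3x3 neighborhood of voxel ({x}, {y}, {z}) falls outside the "
            f"volume of shape {(nx, ny, nz)}"
        )
    patch = series.values[x - 1 : x + 2, y - 1 : y + 2, z, :]
    curve = patch.reshape(9, -1).mean(axis=0)
    return InputFunction(times=series.times, values=curve, kind="whole_blood")


def blood_to_plasma(cb: InputFunction, hct: float) -> InputFunction:
    """Convert a whole-blood curve to plasma: Cp(t) = Cb(t) / (1 - Hct)."""
    if cb.kind != "whole_blood":
        raise ValueError("blood_to_plasma expects a whole_blood input function")
    if not 0 <= hct < 1:
        raise ValueError(f"hct must lie in [0, 1), got {hct}")
    return InputFunction(times=cb.times, values=cb.values / (1.0 - hct),
                         kind="plasma")


def _times_minutes(times_s: np.ndarray) -> np.ndarray:
    t = np.asarray(times_s, dtype=float) / 60.0
    # the baseline frame (t <= 0) anchors the quadrature at t = 0 with Cp = 0
    return np.clip(t, 0.0, None)


def cumtrapz_grid(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid along the last axis with a zero anchor.

    Accumulated left-to-right so that the kep = 0 exponential recursion in
    :func:`exp_conv` is bit-identical.
    """
    y = np.asarray(y, dtype=float)
    dt = np.diff(t)
    out = np.zeros_like(y)
    for i in range(1, y.shape[-1]):
        out[..., i] = out[..., i - 1] + 0.5 * dt[i - 1] * (
            y[..., i] + y[..., i - 1]
        )
    return out


def exp_conv(cp: np.ndarray, t: np.ndarray, kep) -> np.ndarray:
    """Causal convolution \\int_0^t Cp(tau) e^{-kep (t-tau)} dtau.

    Trapezoid-weighted exponential recursion on the native grid. ``kep`` may
    be a scalar or an array broadcasting against ``cp``'s leading axes, so a
    whole volume of voxel-specific rates is handled in one call.
    """
    cp = np.asarray(cp, dtype=float)
    kep = np.asarray(kep, dtype=float)
    dt = np.diff(t)
    shape = np.broadcast_shapes(
        kep[..., None].shape if kep.ndim else (1,), cp.shape)
    out = np.zeros(shape)
    acc = np.zeros(shape[:-1])
    for i in range(1, cp.shape[-1]):
        e = np.exp(-kep * dt[i - 1])
        acc = e * acc + 0.5 * dt[i - 1] * (cp[..., i] + e * cp[..., i - 1])
        out[..., i] = acc
    return out


def exp_conv_grad_kep(cp: np.ndarray, t: np.ndarray, kep) -> np.ndarray:
    """d/d(kep) of :func:`exp_conv`, by differentiating the recursion."""
    cp = np.asarray(cp, dtype=float)
    kep = np.asarray(kep, dtype=float)
    dt = np.diff(t)
    shape = np.broadcast_shapes(
        kep[..., None].shape if kep.ndim else (1,), cp.shape)
    acc = np.zeros(shape[:-1])
    dacc = np.zeros(shape[:-1])
    out = np.zeros(shape)
    for i in range(1, cp.shape[-1]):
        h = dt[i - 1]
        e = np.exp(-kep * h)
        new_acc = e * acc + 0.5 * h * (cp[..., i] + e * cp[..., i - 1])
        dacc = e * dacc - h * e * acc - 0.5 * h * h * e * cp[..., i - 1]
        acc = new_acc
        out[..., i] = dacc
    return out


def patlak_forward(theta, cp: InputFunction, times=None) -> np.ndarray:
    """Patlak model curve for one voxel: Ct = vp Cp + Ktrans cumint(Cp).

    ``theta`` is (ktrans, vp) with ktrans in min^-1; ``times`` (seconds)
    defaults to ``cp.times``.
    """
    ktrans, vp = float(theta[0]), float(theta[-1])
    t = _times_minutes(cp.times if times is None else times)
    integral = cumtrapz_grid(cp.values, t)
    return vp * cp.values + ktrans * integral


def etofts_forward(theta, cp: InputFunction, times=None) -> np.ndarray:
    """Extended Tofts curve: Ct = vp Cp + Ktrans conv(Cp, e^{-kep t})."""
    ktrans, kep, vp = (float(v) for v in theta)
    if kep < 0:
        raise ValueError(f"kep must be >= 0, got {kep}")
    t = _times_minutes(cp.times if times is None else times)
    conv = exp_conv(cp.values, t, np.float64(kep))
    return vp * cp.values + ktrans * conv


def fit_patlak(
    ct: np.ndarray,
    cp: InputFunction,
    times=None,
    clip_nonnegative: bool = False,
) -> Tuple[np.ndarray, FitReport]:
    """Closed-form linear least squares fit of the Patlak model.

    Design matrix columns are [Cp(t), cumint Cp(t)] over the post-baseline
    frames; solved by QR-based ``lstsq``. Estimates may be negative unless
    ``clip_nonnegative`` is set. A rank-deficient design (e.g. Cp identically
    zero) flags the voxel invalid (NaN estimates).

    Returns ``theta = (ktrans, vp)`` and a :class:`FitReport`.
    """
    ct = np.asarray(ct, dtype=float)
    t = _times_minutes(cp.times if times is None else times)
    if ct.shape[-1] != len(t):
        raise ValueError("ct and times lengths differ")
    if len(t) < 3:
        raise ValueError("Patlak fit requires at least 3 frames")
    integral = cumtrapz_grid(cp.values, t)
    post = t > 0  # baseline excluded from the residuals
    x = np.column_stack([integral[post], cp.values[post]])
    y = ct[post]
    rank = np.linalg.matrix_rank(x)
    if rank < 2 or not np.all(np.isfinite(y)):
        theta = np.array([np.nan, np.nan])
        return theta, FitReport(sse=np.nan, iterations=0, converged=False)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    if clip_nonnegative:
        beta = np.clip(beta, 0.0, None)
    resid = y - x @ beta
    theta = np.array([beta[0], beta[1]])  # (ktrans, vp)
    return theta, FitReport(sse=float(resid @ resid), iterations=1,
                            converged=True)


def _etofts_sse_and_grad(x_scaled, ct_post, cp_vals, t, post):
    """SSE and gradient in the scaled parameterization (analytic)."""
    theta = x_scaled * _NLS_SCALE
    ktrans, kep, vp = theta
    conv = exp_conv(cp_vals, t, np.float64(kep))
    model = vp * cp_vals + ktrans * conv
    r = model[post] - ct_post
    sse = float(r @ r)
    dconv = exp_conv_grad_kep(cp_vals, t, np.float64(kep))
    g_ktrans = 2.0 * (r @ conv[post])
    g_kep = 2.0 * ktrans * (r @ dconv[post])
    g_vp = 2.0 * (r @ cp_vals[post])
    grad = np.array([g_ktrans, g_kep, g_vp]) * _NLS_SCALE
    return sse, grad


def fit_etofts(
    ct: np.ndarray,
    cp: InputFunction,
    times=None,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    max_iter: int = 30,
) -> Tuple[np.ndarray, FitReport]:
    """Bounded quasi-Newton (L-BFGS-B) fit of the extended Tofts model.

    Minimizes the sum of squared residuals over (Ktrans, kep, vp) with box
    bounds and an analytic gradient, capped at ``max_iter`` iterations
    (default 30). Non-convergence is not an error: the best iterate is
    returned with ``converged=False``. Unidentifiable problems (Cp == 0 or
    non-finite data) flag the voxel invalid.
    """
    ct = np.asarray(ct, dtype=float)
    t = _times_minutes(cp.times if times is None else times)
    if len(t) < 4:
        raise ValueError("extended Tofts fit requires at least 4 frames")
    post = t > 0
    if not np.all(np.isfinite(ct)) or not np.any(cp.values != 0):
        theta = np.full(3, np.nan)
        return theta, FitReport(sse=np.nan, iterations=0, converged=False)
    x0 = np.asarray(init, dtype=float) / _NLS_SCALE
    sbounds = [(lo / s, hi / s) for (lo, hi), s in zip(bounds, _NLS_SCALE)]
    res = optimize.minimize(
        _etofts_sse_and_grad,
        x0,
        args=(ct[post], cp.values, t, post),
        jac=True,
        method="L-BFGS-B",
        bounds=sbounds,
        # the quasi-Newton solver runs to its iteration budget rather than
        # stopping on a loose relative-change test
        options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-14},
    )
    theta = res.x * _NLS_SCALE
    return theta, FitReport(sse=float(res.fun), iterations=int(res.nit),
                            converged=bool(res.success))


def fit_volume(
    conc: DynamicSeries,
    cp: InputFunction,
    model: str = "patlak",
    mask: Optional[np.ndarray] = None,
    **fit_kwargs,
) -> Tuple[PkMaps, FitReport]:
    """Apply the per-voxel fit to every voxel of a masked volume.

    Deterministic given its inputs; the Patlak branch is vectorized (one
    shared closed-form solve for all voxels), the extended Tofts branch loops
    over masked voxels. Per-voxel invalid flags propagate into the maps.
    """
    if conc.quantity != "concentration_mM":
        raise ValueError("fit_volume expects a concentration series")
    vol_shape = conc.values.shape[:-1]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol_shape:
        raise ValueError("mask shape does not match the volume")

    n = 3 if model == "etofts" else 2
    theta_flat = np.full(vol_shape + (n,), np.nan)
    sse = np.full(vol_shape, np.nan)
    iters = np.zeros(vol_shape, dtype=int)
    conv = np.zeros(vol_shape, dtype=bool)

    idx = np.argwhere(mask)
    if model == "patlak":
        clip = bool(fit_kwargs.pop("clip_nonnegative", False))
        if fit_kwargs:
            raise TypeError(f"unknown fit options {sorted(fit_kwargs)}")
        t = _times_minutes(conc.times)
        integral = cumtrapz_grid(cp.values, t)
        post = t > 0
        x = np.column_stack([integral[post], cp.values[post]])
        if np.linalg.matrix_rank(x) == 2 and len(idx):
            y = conc.values[mask][:, post]  # (nvox, nt_post)
            finite = np.all(np.isfinite(y), axis=1)
            beta = np.full((y.shape[0], 2), np.nan)
            if np.any(finite):
                sol, _, _, _ = np.linalg.lstsq(x, y[finite].T, rcond=None)
                beta[finite] = sol.T
            if clip:
                beta = np.clip(beta, 0.0, None)
            resid = np.where(finite[:, None], y - beta @ x.T, np.nan)
            theta_flat[mask] = beta
            sse[mask] = np.einsum("ij,ij->i", np.nan_to_num(resid),
                                  np.nan_to_num(resid))
            sse[mask] = np.where(finite, sse[mask], np.nan)
            iters[mask] = 1
            conv[mask] = finite
    elif model == "etofts":
        for vox in idx:
            vox = tuple(vox)
            theta, rep = fit_etofts(conc.values[vox], cp, conc.times,
                                    **fit_kwargs)
            theta_flat[vox] = theta
            sse[vox] = rep.sse
            iters[vox] = rep.iterations
            conv[vox] = rep.converged
    else:
        raise ValueError(f"unknown model {model!r}")

    valid = mask & np.all(np.isfinite(theta_flat), axis=-1)
    maps = PkMaps.from_stack(theta_flat, model=model, valid=valid)
    return maps, FitReport(sse=sse, iterations=iters, converged=conv)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

@dataclass
class PkResults:
    """Results of a tracer-kinetic volume fit.

    Carries the parameter maps, per-voxel residual SSE and convergence
    diagnostics; ``summary()`` tabulates per-parameter statistics over valid
    voxels and ``predict()`` reconstructs the fitted concentration series.
    """

    maps: PkMaps
    report: FitReport
    cp: InputFunction
    times: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        v = self.maps.valid
        for name in self.maps.param_names:
            vals = getattr(self.maps, name)[v]
            rows.append({
                "param": name,
                "unit": "min^-1" if name in ("ktrans", "kep") else "fraction",
                "n_voxels": int(v.sum()),
                "median": float(np.median(vals)) if vals.size else np.nan,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "std": float(np.std(vals)) if vals.size else np.nan,
            })
        rows.append({
            "param": "sse", "unit": "mM^2",
            "n_voxels": int(v.sum()),
            "median": float(np.nanmedian(self.report.sse[v])) if v.any() else np.nan,
            "mean": float(np.nanmean(self.report.sse[v])) if v.any() else np.nan,
            "std": float(np.nanstd(self.report.sse[v])) if v.any() else np.nan,
        })
        return pd.DataFrame(rows).set_index("param")

    def predict(self) -> DynamicSeries:
        """Fitted concentration series from the estimated maps."""
        t = _times_minutes(self.times)
        stack = self.maps.stack()
        if self.maps.model == "patlak":
            integral = cumtrapz_grid(self.cp.values, t)
            fitted = (stack[..., 1:2] * self.cp.values
                      + stack[..., 0:1] * integral)
        else:
            conv = exp_conv(self.cp.values, t,
                            np.nan_to_num(self.maps.kep))
            fitted = (stack[..., 2:3] * self.cp.values
                      + stack[..., 0:1] * conv)
        fitted = np.where(self.maps.valid[..., None], fitted, np.nan)
        return DynamicSeries(values=fitted, times=np.asarray(self.times),
                             quantity="concentration_mM")


class TracerKineticModel:
    """Base for voxelwise tracer-kinetic fits on a concentration volume."""

    model_kind: str = ""

    def __init__(self, conc: DynamicSeries, cp: InputFunction,
                 mask: Optional[np.ndarray] = None):
        if cp.kind != "plasma":
            raise ValueError("kinetic models require a plasma input function")
        self.conc = conc
        self.cp = cp
        self.mask = mask

    def fit(self, **kwargs) -> PkResults:
        maps, report = fit_volume(self.conc, self.cp, model=self.model_kind,
                                  mask=self.mask, **kwargs)
        return PkResults(maps=maps, report=report, cp=self.cp,
                         times=self.conc.times)


class PatlakModel(TracerKineticModel):
    """Linear two-parameter (Ktrans, vp) model, closed-form OLS fit."""

    model_kind = "patlak"


class ExtendedToftsModel(TracerKineticModel):
    """Three-parameter (Ktrans, kep, vp) model, bounded L-BFGS fit."""

    model_kind = "etofts"
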