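"""Joint parameter + kinetic-model-consistency loss.

For a batch of predicted parameter patches theta~ and targets theta,

    L = || theta - theta~ ||^2  +  lambda || Ct(t) - f_tk(theta~) ||^2,

where f_tk is the Patlak or extended Tofts forward model evaluated voxelwise
through the same trapezoid quadrature as the fitting code, using the training
subject's plasma curve. The default ``reduction="sum"`` and raw parameter
scale reproduce the loss literally; training uses ``reduction="mean"`` (each
term averaged over its own element count) and per-channel standardization of
the parameter term, because Ktrans (~1e-3 min^-1) and vp (~1e-2) live on
different scales.

Both the value and the analytic gradient with respect to theta~ are provided;
the gradient of the exponential-kernel convolution is obtained by
differentiating its recursion, so finite differences match to high accuracy.

Shapes are channels-last: theta (N, H, W, n), concentration (N, H, W, T).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ..containers import InputFunction
from ..kinetics import (
    _times_minutes,
    cumtrapz_grid,
    exp_conv,
    exp_conv_grad_kep,
)

__all__ = ["joint_loss", "joint_loss_and_grad", "TargetScaler"]


class TargetScaler:
    """Per-channel affine standardization of parameter targets."""

    def __init__(self, mean, std):
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("standardization std must be > 0")

    @classmethod
    def fit(cls, theta: np.ndarray) -> "TargetScaler":
        """theta: (N, H, W, n) stack of parameter patches."""
        mean = theta.mean(axis=(0, 1, 2))
        std = theta.std(axis=(0, 1, 2))
        std = np.where(std > 0, std, 1.0)
        return cls(mean, std)

    @classmethod
    def identity(cls, n: int) -> "TargetScaler":
        return cls(np.zeros(n), np.ones(n))

    def transform(self, theta):
        return (theta - self.mean) / self.std

    def inverse(self, z):
        return z * self.std + self.mean


def _model_forward(theta, cp_vals, t_min, model_kind):
    """Voxelwise kinetic forward for a batch. theta: (N, H, W, n),
    cp_vals: (N, T). Returns (f, extras for the gradient)."""
    cp_b = cp_vals[:, None, None, :]              # broadcast over voxels
    if model_kind == "patlak":
        integral = cumtrapz_grid(cp_vals, t_min)  # (N, T)
        kt = theta[..., 0:1]
        vp = theta[..., 1:2]
        f = vp * cp_b + kt * integral[:, None, None, :]
        return f, {"integral": integral}
    if model_kind == "etofts":
        kt = theta[..., 0:1]
        kep = np.clip(theta[..., 1], 0.0, None)   # (N, H, W)
        vp = theta[..., 2:3]
        conv = exp_conv(cp_b, t_min, kep)         # (N, H, W, T)
        f = vp * cp_b + kt * conv
        return f, {"conv": conv, "kep_raw": theta[..., 1]}
    raise ValueError(f"unknown model kind {model_kind!r}")


def joint_loss_and_grad(
    theta_true: np.ndarray,
    theta_pred: np.ndarray,
    ct_obs: np.ndarray,
    cp,
    times=None,
    model_kind: str = "patlak",
    lam: float = 1.0,
    scaler: Optional[TargetScaler] = None,
    reduction: str = "sum",
    cp_values: Optional[np.ndarray] = None,
):
    """Loss value and gradient with respect to ``theta_pred``.

    Shapes: ``theta_*`` (N, H, W, n); ``ct_obs`` (N, H, W, T). ``cp`` is an
    :class:`InputFunction` shared by the batch, or ``cp_values`` gives one
    (T,) curve per sample as an (N, T) array with ``times`` in seconds.
    """
    theta_true = np.asarray(theta_true, dtype=float)
    theta_pred = np.asarray(theta_pred, dtype=float)
    ct_obs = np.asarray(ct_obs, dtype=float)
    n_batch, n_par = theta_pred.shape[0], theta_pred.shape[-1]
    n_expected = 2 if model_kind == "patlak" else 3
    if n_par != n_expected:
        raise ValueError(
            f"{model_kind} expects {n_expected} parameter channels, got "
            f"{n_par}"
        )
    if theta_true.shape != theta_pred.shape:
        raise ValueError("theta shapes differ")

    if cp_values is not None:
        cp_vals = np.asarray(cp_values, dtype=float)
        if times is None:
            raise ValueError("times required with cp_values")
        t_sec = np.asarray(times, dtype=float)
    elif isinstance(cp, InputFunction):
        cp_vals = np.broadcast_to(cp.values, (n_batch, len(cp.values)))
        t_sec = cp.times if times is None else np.asarray(times, dtype=float)
    else:
        raise TypeError("cp must be an InputFunction or use cp_values")
    t_min = _times_minutes(t_sec)
    if ct_obs.shape[-1] != len(t_min):
        raise ValueError("ct_obs frame count does not match times")

    if scaler is None:
        scaler = TargetScaler.identity(n_par)
    zt = scaler.transform(theta_true)
    zp = scaler.transform(theta_pred)

    w_par = 1.0 / zt.size if reduction == "mean" else 1.0
    w_con = 1.0 / ct_obs.size if reduction == "mean" else 1.0

    diff = zp - zt
    loss_par = w_par * float(np.sum(diff * diff))
    grad = 2.0 * w_par * diff / scaler.std

    f, extras = _model_forward(theta_pred, cp_vals, t_min, model_kind)
    r = f - ct_obs
    loss_con = w_con * float(np.sum(r * r))

    if model_kind == "patlak":
        integral = extras["integral"]
        grad[..., 0] += 2.0 * lam * w_con * np.einsum(
            "nhwt,nt->nhw", r, integral, optimize=True)
        grad[..., 1] += 2.0 * lam * w_con * np.einsum(
            "nhwt,nt->nhw", r, cp_vals, optimize=True)
    else:
        conv = extras["conv"]
        kt = theta_pred[..., 0]
        kep = np.clip(theta_pred[..., 1], 0.0, None)
        dconv = exp_conv_grad_kep(cp_vals[:, None, None, :], t_min, kep)
        grad[..., 0] += 2.0 * lam * w_con * np.sum(r * conv, axis=-1)
        g_kep = 2.0 * lam * w_con * kt * np.sum(r * dconv, axis=-1)
        # kep is clipped at zero inside the forward; zero gradient below
        grad[..., 1] += np.where(extras["kep_raw"] >= 0, g_kep, 0.0)
        grad[..., 2] += 2.0 * lam * w_con * np.einsum(
            "nhwt,nt->nhw", r, cp_vals, optimize=True)

    return loss_par + lam * loss_con, grad


def joint_loss(theta_true, theta_pred, ct_obs, cp, times=None,
               model_kind: str = "patlak", lam: float = 1.0,
               scaler: Optional[TargetScaler] = None,
               reduction: str = "sum",
               cp_values: Optional[np.ndarray] = None) -> float:
    """Scalar joint loss (see :func:`joint_loss_and_grad`). Non-negative;
    zero exactly when theta_pred = theta_true and ct_obs = f_tk(theta_pred).
    """
    value, _ = joint_loss_and_grad(
        theta_true, theta_pred, ct_obs, cp, times=times,
        model_kind=model_kind, lam=lam, scaler=scaler, reduction=reduction,
        cp_values=cp_values)
    return value
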