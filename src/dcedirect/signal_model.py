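"""SPGR signal model: VFA T1 mapping and signal <-> concentration conversion.

The steady-state spoiled gradient echo (SPGR) magnitude at flip angle alpha is

    S_ss(T1) = M0 sin(alpha) (1 - E) / (1 - cos(alpha) E),   E = exp(-TR/T1).

Pre-contrast T10 is estimated from two flip angles (the variable flip angle
method): with the signal ratio SR = S_a / S_b,

    1/T10 = (1/TR) ln[ (SR sin(a_b) cos(a_a) - sin(a_a) cos(a_b))
                       / (SR sin(a_b) - sin(a_a)) ].

The dynamic series is modelled in the baseline-offset form

    S(t) = M0 sin(a_b) (1 - e^-(K+L)) / (1 - cos(a_b) e^-(K+L))
           + [ S(0) - M0 sin(a_b) (1 - e^-K) / (1 - cos(a_b) e^-K) ],

with K = TR/T10 and L = r1 Ct(t) TR (TR and T10 in seconds, Ct in mM, r1 in
s^-1 mM^-1 so L is dimensionless). The additive bracket makes S(t) = S(0)
exact at zero concentration regardless of how well (M0, T10) describe the
measured baseline. signal_to_concentration is the exact algebraic inverse.

Units: TR and T10 in seconds throughout; concentrations in mM. Kinetic rates
are converted to min^-1 only at the kinetics boundary.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionParams
from .containers import DynamicSeries, RelaxationMaps

__all__ = [
    "spgr_steady_state",
    "compute_t10",
    "compute_m0",
    "spgr_forward",
    "signal_to_concentration",
]


def spgr_steady_state(m0, t10, alpha_deg: float, tr: float) -> np.ndarray:
    """SPGR steady-state magnitude M0 sin(a)(1-E)/(1-cos(a)E), E = e^(-TR/T1)."""
    m0 = np.asarray(m0, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    a = np.deg2rad(alpha_deg)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e = np.exp(-tr / t10)
        return m0 * np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e)


def compute_t10(sa, sb, params: AcquisitionParams) -> RelaxationMaps:
    """Estimate the pre-contrast T1 map from a dual flip angle pair.

    Parameters
    ----------
    sa, sb : ndarray
        Pre-contrast images at ``params.alpha_a`` and ``params.alpha_b``
        (same shape).
    params : AcquisitionParams

    Returns
    -------
    RelaxationMaps
        ``t10`` in seconds; voxels where the estimate is undefined (zero or
        negative log argument, non-positive T10, division by zero) are NaN
        and flagged invalid. No exception is raised for degenerate voxels.
    """
    sa = np.asarray(sa, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError(f"shape mismatch: sa {sa.shape} vs sb {sb.shape}")
    if params.alpha_a == params.alpha_b:
        raise ValueError("degenerate VFA pair: alpha_a == alpha_b")

    aa = np.deg2rad(params.alpha_a)
    ab = np.deg2rad(params.alpha_b)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sr = sa / sb
        num = sr * np.sin(ab) * np.cos(aa) - np.sin(aa) * np.cos(ab)
        den = sr * np.sin(ab) - np.sin(aa)
        arg = num / den
        log_arg = np.log(arg)
        t10 = params.tr / log_arg

    valid = (
        np.isfinite(arg)
        & (arg > 0)
        & np.isfinite(t10)
        & (t10 > 0)
    )
    t10 = np.where(valid, t10, np.nan)
    return RelaxationMaps(t10=t10, valid=valid)


def compute_m0(sb, maps: RelaxationMaps, params: AcquisitionParams) -> RelaxationMaps:
    """Recover equilibrium magnetization M0 from the alpha_b image and T10.

    Algebraic inverse of the SPGR steady state:
    M0 = S_b (1 - cos(a_b) e^-K) / (sin(a_b) (1 - e^-K)), K = TR/T10.
    Voxels with invalid T10 or non-positive S_b propagate invalid.
    """
    sb = np.asarray(sb, dtype=float)
    if sb.shape != maps.t10.shape:
        raise ValueError("sb and t10 shapes differ")
    ab = np.deg2rad(params.alpha_b)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e = np.exp(-params.tr / maps.t10)
        m0 = sb * (1.0 - np.cos(ab) * e) / (np.sin(ab) * (1.0 - e))
    valid = maps.valid & np.isfinite(m0) & (m0 > 0)
    m0 = np.where(valid, m0, np.where(sb == 0, 0.0, np.nan))
    return maps.with_m0(m0=m0, valid=valid)


def _baseline_offset(s0, maps: RelaxationMaps, params: AcquisitionParams):
    """The additive bracket S(0) - S_ss(T10) of the dynamic signal model."""
    s_ss = spgr_steady_state(maps.m0, maps.t10, params.alpha_b, params.tr)
    return np.asarray(s0, dtype=float) - s_ss


def spgr_forward(
    ct: DynamicSeries,
    s0,
    maps: RelaxationMaps,
    params: AcquisitionParams,
    neg_tol: float = 1e-9,
) -> DynamicSeries:
    """Map a concentration series to an SPGR signal series.

    Parameters
    ----------
    ct : DynamicSeries
        Concentration in mM, quantity ``"concentration_mM"``.
    s0 : ndarray
        Measured baseline (pre-contrast) signal, one value per voxel.
    maps : RelaxationMaps
        Valid ``t10`` and ``m0``.
    params : AcquisitionParams
    neg_tol : float
        Concentrations below ``-neg_tol`` raise; tiny negative values from
        round-off are clipped to zero.
    """
    if ct.quantity != "concentration_mM":
        raise ValueError("spgr_forward expects a concentration series")
    c = ct.values
    if np.any(c < -neg_tol):
        raise ValueError("negative concentrations beyond tolerance")
    c = np.clip(c, 0.0, None)

    ab = np.deg2rad(params.alpha_b)
    k = (params.tr / maps.t10)[..., None]
    m0 = maps.m0[..., None]
    ell = params.r1 * c * params.tr
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e = np.exp(-(k + ell))
        enhancing = m0 * np.sin(ab) * (1.0 - e) / (1.0 - np.cos(ab) * e)
    offset = _baseline_offset(s0, maps, params)[..., None]
    sig = enhancing + offset
    valid = np.broadcast_to(maps.valid[..., None], sig.shape)
    sig = np.where(valid, sig, np.nan)
    return DynamicSeries(values=sig, times=ct.times, quantity="signal",
                         valid=np.array(valid))


def signal_to_concentration(
    s: DynamicSeries,
    s0,
    maps: RelaxationMaps,
    params: AcquisitionParams,
    clip_negative: bool = False,
) -> DynamicSeries:
    """Invert the SPGR signal model to contrast-agent concentration.

    Solves the dynamic signal equation for L = r1 Ct TR in closed form:
    with B = S(t) - [S(0) - S_ss(T10)] and
    E = (M0 sin a - B) / (M0 sin a - B cos a), then Ct = (-ln E - K)/(r1 TR).

    Frames where E falls outside (0, 1] (signal beyond the SPGR saturation
    asymptote, or unphysically low) are NaN and masked invalid in the returned
    series — no exception is raised per voxel.

    Negative concentrations produced by noise are retained by default so that
    downstream fitting sees unbiased noise; set ``clip_negative=True`` to
    clip at zero.
    """
    if s.quantity != "signal":
        raise ValueError("signal_to_concentration expects a signal series")
    ab = np.deg2rad(params.alpha_b)
    offset = _baseline_offset(s0, maps, params)[..., None]
    b = s.values - offset
    m0s = (maps.m0 * np.sin(ab))[..., None]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e = (m0s - b) / (m0s - b * np.cos(ab))
        k = (params.tr / maps.t10)[..., None]
        ct = (-np.log(e) - k) / (params.r1 * params.tr)
    valid = (
        np.isfinite(e)
        & (e > 0)
        & (e <= 1)
        & np.broadcast_to(maps.valid[..., None], b.shape)
        & np.isfinite(ct)
    )
    ct = np.where(valid, ct, np.nan)
    if clip_negative:
        ct = np.where(valid, np.clip(ct, 0.0, None), ct)
    return DynamicSeries(values=ct, times=s.times,
                         quantity="concentration_mM", valid=valid)
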