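"""In-memory containers for dynamic series, relaxation maps, input functions
and pharmacokinetic parameter maps.

Invalid voxels are represented as NaN plus an explicit boolean ``valid`` mask;
downstream operations consume the mask rather than testing for NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DynamicSeries",
    "RelaxationMaps",
    "InputFunction",
    "PkMaps",
    "FitReport",
]


@dataclass
class DynamicSeries:
    """A 4D (x, y, z, t) grid of signal intensity or contrast concentration.

    ``times`` are seconds since injection; the first frame is pre-contrast at
    t <= 0. ``quantity`` is ``"signal"`` or ``"concentration_mM"``.
    """

    values: np.ndarray
    times: np.ndarray
    quantity: str = "signal"
    valid: Optional[np.ndarray] = None  # per voxel-frame, broadcastable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"DynamicSeries expects a 4D (x, y, z, t) array, got "
                f"{self.values.ndim}D"
            )
        if self.times.ndim != 1 or len(self.times) != self.values.shape[-1]:
            raise ValueError(
                "times must be 1D with length equal to the t-extent "
                f"({self.values.shape[-1]}), got shape {self.times.shape}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.quantity not in ("signal", "concentration_mM"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[-1]

    def baseline(self) -> np.ndarray:
        """The pre-contrast (first) frame."""
        return self.values[..., 0]


@dataclass
class RelaxationMaps:
    """Per-voxel pre-contrast T1 (s) and equilibrium magnetization M0 (a.u.)."""

    t10: np.ndarray
    m0: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t10 = np.asarray(self.t10, dtype=float)
        if self.m0 is not None:
            self.m0 = np.asarray(self.m0, dtype=float)
            if self.m0.shape != self.t10.shape:
                raise ValueError("m0 and t10 shapes differ")
        if self.valid is None:
            self.valid = np.isfinite(self.t10) & (self.t10 > 0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.t10.shape:
                raise ValueError("valid and t10 shapes differ")

    def with_m0(self, m0: np.ndarray, valid: np.ndarray) -> "RelaxationMaps":
        return RelaxationMaps(t10=self.t10, m0=m0, valid=valid)


@dataclass
class InputFunction:
    """A 1D concentration-time curve on the acquisition grid.

    ``kind`` distinguishes whole-blood from plasma curves; plasma curves are
    obtained from whole blood via division by (1 - Hct).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "plasma"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1D of equal length")
        if self.kind not in ("whole_blood", "plasma"):
            raise ValueError(f"unknown input-function kind {self.kind!r}")


# integer codes for the PK parameter channels, per model
PATLAK_PARAMS = ("ktrans", "vp")
ETOFTS_PARAMS = ("ktrans", "kep", "vp")


@dataclass
class PkMaps:
    """Per-voxel pharmacokinetic parameter maps.

    ktrans and kep are in min^-1, vp is a dimensionless fraction. ``model`` is
    ``"patlak"`` (ktrans, vp) or ``"etofts"`` (ktrans, kep, vp). ve is a
    derived quantity, ktrans / kep where kep > 0.
    """

    ktrans: np.ndarray
    vp: np.ndarray
    model: str = "patlak"
    kep: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ktrans = np.asarray(self.ktrans, dtype=float)
        self.vp = np.asarray(self.vp, dtype=float)
        if self.model not in ("patlak", "etofts"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "etofts":
            if self.kep is None:
                raise ValueError("etofts maps require kep")
            self.kep = np.asarray(self.kep, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.ktrans) & np.isfinite(self.vp)
            if self.kep is not None:
                self.valid &= np.isfinite(self.kep)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def param_names(self):
        return ETOFTS_PARAMS if self.model == "etofts" else PATLAK_PARAMS

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def ve(self) -> np.ndarray:
        """Derived EES volume fraction ktrans / kep (NaN where kep <= 0)."""
        if self.kep is None:
            raise ValueError("ve is defined only for etofts maps")
        with np.errstate(divide="ignore", invalid="ignore"):
            ve = np.where(self.kep > 0, self.ktrans / self.kep, np.nan)
        return ve

    def stack(self) -> np.ndarray:
        """Channels-last stack in canonical parameter order."""
        chans = [getattr(self, name) for name in self.param_names]
        return np.stack(chans, axis=-1)

    @classmethod
    def from_stack(cls, arr: np.ndarray, model: str,
                   valid: Optional[np.ndarray] = None) -> "PkMaps":
        names = ETOFTS_PARAMS if model == "etofts" else PATLAK_PARAMS
        if arr.shape[-1] != len(names):
            raise ValueError(
                f"expected {len(names)} channels for {model}, got "
                f"{arr.shape[-1]}"
            )
        kw = {name: arr[..., i] for i, name in enumerate(names)}
        return cls(model=model, valid=valid, **kw)


@dataclass
class FitReport:
    """Per-voxel fit diagnostics: residual SSE, iterations, convergence."""

    sse: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        self.sse = np.asarray(self.sse, dtype=float)
        self.iterations = np.asarray(self.iterations, dtype=int)
        self.converged = np.asarray(self.converged, dtype=bool)
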