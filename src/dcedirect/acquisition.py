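"""Acquisition protocol constants shared by every forward and inverse transform.

The defaults reproduce a 1.5 T brain DCE protocol: a 3D spoiled gradient echo
sequence with TR = 8.24 ms read out at a 12 degree flip angle, a 2 degree
companion acquisition for variable-flip-angle T1 mapping, 20 post-injection
frames at 73 s temporal resolution on top of one pre-contrast baseline,
gadolinium relaxivity r1 = 4.2 s^-1 mM^-1 and an assumed hematocrit of 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner/protocol constants.

    Parameters
    ----------
    tr : float
        Repetition time in **seconds** (default 8.24e-3).
    alpha_a, alpha_b : float
        The two pre-contrast flip angles in degrees, ``alpha_a < alpha_b``.
        ``alpha_b`` is also the flip angle of the dynamic series.
    r1 : float
        Longitudinal relaxivity of the contrast agent, s^-1 mM^-1.
    frame_interval : float
        Dynamic frame spacing in seconds.
    n_frames : int
        Total frame count (1 baseline + dynamics).
    hct : float
        Hematocrit fraction in [0, 1), used for whole-blood -> plasma
        conversion of the vascular input function.
    """

    tr: float = 8.24e-3
    alpha_a: float = 2.0
    alpha_b: float = 12.0
    r1: float = 4.2
    frame_interval: float = 73.0
    n_frames: int = 21
    hct: float = 0.45

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not 0 < self.alpha_a < self.alpha_b <= 90:
            raise ValueError(
                "flip angles must satisfy 0 < alpha_a < alpha_b <= 90, got "
                f"alpha_a={self.alpha_a}, alpha_b={self.alpha_b}"
            )
        if not self.r1 > 0:
            raise ValueError(f"r1 must be > 0, got {self.r1}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0 <= self.hct < 1:
            raise ValueError(f"hct must lie in [0, 1), got {self.hct}")
        if not self.frame_interval > 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )

    @property
    def times(self):
        """Frame time stamps in seconds.

        The baseline frame is stamped t = 0 (the quadrature anchor, contrast
        concentration defined to be zero there); post-injection frames follow
        at multiples of ``frame_interval``.
        """
        import numpy as np

        return self.frame_interval * np.arange(self.n_frames, dtype=float)
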