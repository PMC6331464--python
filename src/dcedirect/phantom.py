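"""Seeded digital reference object for brain DCE-MRI.

Generates, per synthetic subject: a tissue label map (normal-appearing white
matter, white-matter hyperintensities, deep gray matter, a recent stroke
lesion, and a small venous vessel for input-function extraction), ground-truth
pharmacokinetic maps drawn from tissue-conditional distributions, a
biexponential population plasma input function with per-subject jitter, the
noiseless concentration and signal series obtained by composing the kinetic
forward model with the SPGR signal equation, and a noisy signal series with
additive zero-mean Gaussian noise scaled to the mean baseline signal.

Everything is a pure function of the spec (including its seed), and every
intermediate is stored so each pipeline stage can be tested against the stage
that generated it.

The generator emulates the statistical structure of a 1.5 T stroke-cohort
acquisition (21 frames at 73 s, low-permeability Ktrans of order 1e-3 min^-1)
on simple geometric tissue regions; it makes no attempt at anatomical realism,
motion, or Rician noise floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .acquisition import AcquisitionParams
from .containers import DynamicSeries, InputFunction, PkMaps, RelaxationMaps
from .kinetics import cumtrapz_grid, exp_conv, _times_minutes
from .signal_model import spgr_forward, spgr_steady_state

__all__ = [
    "TISSUE_LABELS",
    "PhantomSpec",
    "PhantomSubject",
    "PhantomDataset",
    "make_tissue_map",
    "sample_parameters",
    "population_aif",
    "simulate_dataset",
]

# integer label codes
TISSUE_LABELS = {
    "background": 0,
    "nawm": 1,
    "wmh": 2,
    "dgm": 3,
    "rsl": 4,
    "vessel": 5,
}

# tissue-conditional parameter means: Ktrans (min^-1), vp (fraction).
# Subtle blood-brain-barrier-leak regime: lesional tissue leakier than
# normal-appearing white matter, vessel dominated by its plasma volume.
_DEFAULT_KTRANS = {"nawm": 1e-3, "wmh": 2e-3, "dgm": 1.5e-3,
                   "rsl": 5e-3, "vessel": 0.0}
_DEFAULT_VP = {"nawm": 0.01, "wmh": 0.015, "dgm": 0.03,
               "rsl": 0.02, "vessel": 0.6}
# pre-contrast T1 (s) at 1.5 T: white matter ~0.6, gray matter ~1.0, blood ~1.4
_DEFAULT_T10 = {"nawm": 0.6, "wmh": 0.8, "dgm": 1.0, "rsl": 1.0,
                "vessel": 1.4}


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the digital reference object.

    ``ktrans_mean`` / ``vp_mean`` are per-tissue means; ``rel_spread`` is the
    relative (fractional) standard deviation applied to both. ``ve`` sets
    kep = Ktrans / ve for extended Tofts phantoms. ``sigma`` is the signal
    noise standard deviation relative to the mean baseline signal.
    ``aif_jitter`` is the relative per-subject log-normal jitter on the input
    function's peak and tail amplitudes.
    """

    shape: Tuple[int, int, int] = (64, 64, 4)
    n_subjects: int = 6
    model: str = "patlak"
    ktrans_mean: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_KTRANS))
    vp_mean: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_VP))
    t10: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_T10))
    rel_spread: float = 0.10
    ve: float = 0.2
    sigma: float = 0.02
    aif_jitter: float = 0.10
    m0: float = 1000.0
    # biexponential plasma input function D (a1 e^{-m1 t} + a2 e^{-m2 t}),
    # t in minutes: a fast bolus peak (~6 mM on the 73 s grid) decaying to a
    # ~1 mM steady tail over the 24-minute acquisition
    aif_dose: float = 1.0
    aif_a1: float = 33.0   # mM
    aif_m1: float = 2.0    # min^-1
    aif_a2: float = 3.3    # mM
    aif_m2: float = 0.05   # min^-1
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("patlak", "etofts"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.sigma < 0 or self.rel_spread < 0 or self.aif_jitter < 0:
            raise ValueError("spreads and noise levels must be >= 0")
        if set(self.ktrans_mean) != set(self.vp_mean):
            raise ValueError("ktrans_mean and vp_mean tissue sets differ")
        if not self.ktrans_mean:
            raise ValueError("tissue set must be non-empty")


@dataclass
class PhantomSubject:
    """All stored intermediates for one synthetic subject."""

    subject_id: int
    labels: np.ndarray
    truth: PkMaps
    cp: InputFunction
    relaxation: RelaxationMaps
    conc_noiseless: DynamicSeries
    signal_noiseless: DynamicSeries
    signal_noisy: DynamicSeries
    seed: int


@dataclass
class PhantomDataset:
    """A fully seeded multi-subject phantom."""

    spec: PhantomSpec
    subjects: list

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def _ellipse_mask(shape2d, center, radii):
    ny, nx = shape2d
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy - center[0]) / radii[0]) ** 2 + \
           ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def make_tissue_map(shape: Tuple[int, int, int], seed: int) -> np.ndarray:
    """Deterministic tissue label map with contiguous per-class regions.

    An elliptical "brain" filled with NAWM hosts a central DGM ellipse,
    a few WMH blobs, one recent-stroke-lesion blob and a small vessel column
    (>= 3x3 in-plane, so a vascular input function patch fits inside it).
    Blob centers and radii carry seeded jitter. Every class occupies at least
    1% of in-brain voxels by construction (checked, with deterministic
    fallback growth of the rarest classes).
    """
    nx, ny, nz = shape
    if nx < 24 or ny < 24:
        raise ValueError("in-plane extent must be at least 24 voxels")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)

    cy, cx = nx / 2.0, ny / 2.0
    brain = _ellipse_mask((nx, ny), (cy, cx), (0.45 * nx, 0.45 * ny))
    for z in range(nz):
        labels[..., z][brain] = TISSUE_LABELS["nawm"]

    # deep gray matter: central ellipse
    dgm = _ellipse_mask((nx, ny), (cy, cx),
                        (0.16 * nx * rng.uniform(0.9, 1.1),
                         0.16 * ny * rng.uniform(0.9, 1.1)))
    # white-matter hyperintensities: a ring of blobs around the DGM
    wmh = np.zeros((nx, ny), dtype=bool)
    n_wmh = 3
    for i in range(n_wmh):
        ang = 2 * np.pi * (i / n_wmh) + rng.uniform(-0.3, 0.3)
        r = 0.30 * min(nx, ny)
        c = (cy + r * np.sin(ang), cx + r * np.cos(ang))
        wmh |= _ellipse_mask((nx, ny), c,
                             (0.07 * nx * rng.uniform(0.8, 1.2),
                              0.07 * ny * rng.uniform(0.8, 1.2)))
    # recent stroke lesion: one off-center blob
    ang = rng.uniform(0, 2 * np.pi)
    r = 0.27 * min(nx, ny)
    rsl = _ellipse_mask((nx, ny),
                        (cy + r * np.sin(ang), cx + r * np.cos(ang)),
                        (0.09 * nx * rng.uniform(0.9, 1.1),
                         0.09 * ny * rng.uniform(0.9, 1.1)))
    rsl &= ~wmh
    wmh &= ~dgm
    rsl &= ~dgm

    # vessel: small square column near the posterior rim (think sagittal
    # sinus), at least 5x5 in-plane so a 3x3 patch sits strictly inside
    vx = int(round(cy + 0.38 * nx))
    vy = int(round(cx))
    vessel = np.zeros((nx, ny), dtype=bool)
    vessel[vx - 2 : vx + 3, vy - 2 : vy + 3] = True

    for z in range(nz):
        sl = labels[..., z]
        sl[brain & dgm] = TISSUE_LABELS["dgm"]
        sl[brain & wmh] = TISSUE_LABELS["wmh"]
        sl[brain & rsl] = TISSUE_LABELS["rsl"]
        sl[brain & vessel] = TISSUE_LABELS["vessel"]

    # guarantee >= 1% in-brain occupancy per class by deterministic growth
    in_brain = int(brain.sum()) * nz
    for name in ("wmh", "dgm", "rsl", "vessel"):
        code = TISSUE_LABELS[name]
        need = int(np.ceil(0.01 * in_brain)) - int((labels == code).sum())
        if need > 0:
            cand = np.argwhere((labels == TISSUE_LABELS["nawm"]))
            take = cand[: need]
            labels[tuple(take.T)] = code
    return labels


def sample_parameters(labels: np.ndarray, spec: PhantomSpec,
                      seed: int) -> PkMaps:
    """Draw per-voxel ground-truth parameters from tissue distributions.

    Gaussian draws (mean, rel_spread * mean) truncated at zero; a zero-spread
    spec yields piecewise-constant maps equal to the tissue means. For
    extended Tofts phantoms kep = Ktrans / ve.
    """
    rng = np.random.default_rng(seed)
    ktrans = np.zeros(labels.shape)
    vp = np.zeros(labels.shape)
    for name, code in TISSUE_LABELS.items():
        if name == "background":
            continue
        m = labels == code
        n = int(m.sum())
        if n == 0:
            continue
        mk = spec.ktrans_mean[name]
        mv = spec.vp_mean[name]
        ktrans[m] = np.clip(rng.normal(mk, spec.rel_spread * mk, n), 0.0, None)
        vp[m] = np.clip(rng.normal(mv, spec.rel_spread * mv, n), 0.0, 1.0)
    valid = labels > 0
    if spec.model == "etofts":
        kep = np.where(valid, ktrans / spec.ve, 0.0)
        return PkMaps(ktrans=ktrans, vp=vp, kep=kep, model="etofts",
                      valid=valid)
    return PkMaps(ktrans=ktrans, vp=vp, model="patlak", valid=valid)


def population_aif(times, spec: PhantomSpec,
                   subject_jitter_seed: Optional[int] = None) -> InputFunction:
    """Biexponential population plasma input function with subject jitter.

    Cp(t) = D (a1 e^{-m1 t} + a2 e^{-m2 t}) for t > 0 (zero at t <= 0), t in
    minutes. With the default parameters the peak lands on the first
    post-injection frame of the 73 s grid (~6 mM) and the tail settles near
    1 mM by the end of the 24-minute acquisition. Per-subject multiplicative
    log-normal jitter acts separately on the peak (a1) and tail (a2) terms;
    a zero-jitter spec gives identical curves for every subject.
    """
    times = np.asarray(times, dtype=float)
    t_min = times / 60.0
    a1, a2 = spec.aif_a1, spec.aif_a2
    if subject_jitter_seed is not None and spec.aif_jitter > 0:
        rng = np.random.default_rng(subject_jitter_seed)
        sig = np.sqrt(np.log1p(spec.aif_jitter ** 2))
        a1 = a1 * rng.lognormal(-0.5 * sig ** 2, sig)
        a2 = a2 * rng.lognormal(-0.5 * sig ** 2, sig)
    vals = spec.aif_dose * (a1 * np.exp(-spec.aif_m1 * t_min)
                            + a2 * np.exp(-spec.aif_m2 * t_min))
    vals = np.where(t_min > 0, vals, 0.0)
    return InputFunction(times=times, values=vals, kind="plasma")


def _kinetic_forward_volume(truth: PkMaps, cp: InputFunction) -> np.ndarray:
    """Vectorized kinetic forward over a whole volume of parameter maps."""
    t = _times_minutes(cp.times)
    if truth.model == "patlak":
        integral = cumtrapz_grid(cp.values, t)
        ct = (truth.vp[..., None] * cp.values
              + truth.ktrans[..., None] * integral)
    else:
        conv = exp_conv(cp.values, t, truth.kep)
        ct = (truth.vp[..., None] * cp.values
              + truth.ktrans[..., None] * conv)
    return np.where(truth.valid[..., None], ct, 0.0)


def simulate_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Compose parameters -> kinetics -> SPGR signal -> additive noise.

    Per subject: sample_parameters feeds the kinetic forward model, the
    resulting concentration series runs through the SPGR forward equation
    with tissue T10s and constant M0, and zero-mean Gaussian noise with
    std = sigma * (mean in-brain baseline signal) is added independently per
    voxel and frame. All intermediates are stored.
    """
    params = spec.acquisition
    times = params.times
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(spec.n_subjects)]

    subjects = []
    for sid, sseed in enumerate(subject_seeds):
        labels = make_tissue_map(spec.shape, seed=sseed)
        truth = sample_parameters(labels, spec, seed=sseed + 1)
        cp = population_aif(times, spec, subject_jitter_seed=sseed + 2)

        t10 = np.full(spec.shape, np.nan)
        for name, code in TISSUE_LABELS.items():
            if name == "background":
                continue
            t10[labels == code] = spec.t10[name]
        valid = labels > 0
        m0 = np.where(valid, spec.m0, np.nan)
        relax = RelaxationMaps(t10=t10, m0=m0, valid=valid)

        ct = _kinetic_forward_volume(truth, cp)
        conc = DynamicSeries(values=ct, times=times,
                             quantity="concentration_mM")
        s0 = spgr_steady_state(m0, t10, params.alpha_b, params.tr)
        s0 = np.where(valid, s0, 0.0)
        clean = spgr_forward(conc, s0, relax, params)
        clean_vals = np.where(valid[..., None], clean.values, 0.0)
        clean = DynamicSeries(values=clean_vals, times=times,
                              quantity="signal")

        rng = np.random.default_rng(sseed + 3)
        baseline_mean = float(clean.values[..., 0][valid].mean())
        noisy_vals = clean.values + rng.normal(
            0.0, spec.sigma * baseline_mean, clean.values.shape)
        noisy = DynamicSeries(values=noisy_vals, times=times,
                              quantity="signal")

        subjects.append(PhantomSubject(
            subject_id=sid, labels=labels, truth=truth, cp=cp,
            relaxation=relax, conc_noiseless=conc, signal_noiseless=clean,
            signal_noisy=noisy, seed=sseed))
    return PhantomDataset(spec=spec, subjects=subjects)
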