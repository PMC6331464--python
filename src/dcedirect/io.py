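"""Shared I/O: NIfTI volumes, input-function text files, YAML run
configuration, and JSON run manifests.

Conventions: voxel indices are 0-based, the time axis is the 4th NIfTI
dimension, affines are preserved verbatim through read -> process -> write
cycles, and no resampling is ever performed. Input functions travel as
2-column delimited text (time_s, conc_mM). Every pipeline stage writes a
manifest recording the config hash, seed, package version and input
checksums, so each artifact is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .acquisition import AcquisitionParams
from .containers import DynamicSeries, InputFunction

__all__ = [
    "read_nifti_4d",
    "read_nifti_3d",
    "save_nifti",
    "read_aif",
    "write_aif",
    "AcquisitionBlock",
    "RunConfig",
    "load_config",
    "write_manifest",
    "file_sha256",
]


def read_nifti_4d(path) -> Tuple[DynamicSeries, np.ndarray]:
    """Load a 4D series; returns (DynamicSeries with placeholder times, affine).

    Frame times are reconstructed from the acquisition config by the caller;
    here they default to the frame index in seconds.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D volume (x, y, z, t), got {data.ndim}D"
        )
    times = np.arange(data.shape[-1], dtype=float)
    return DynamicSeries(values=np.asarray(data, dtype=float), times=times,
                         quantity="signal"), img.affine


def read_nifti_3d(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a 3D map; returns (array, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D"
        )
    return np.asarray(data), img.affine


def save_nifti(path, data: np.ndarray, affine: Optional[np.ndarray] = None
               ) -> None:
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_aif(path, kind: str = "plasma") -> InputFunction:
    """2-column delimited text (time_s, conc_mM) -> InputFunction."""
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (time_s, conc_mM)")
    return InputFunction(times=arr[:, 0], values=arr[:, 1], kind=kind)


def write_aif(path, aif: InputFunction) -> None:
    np.savetxt(str(path), np.column_stack([aif.times, aif.values]),
               header="time_s conc_mM", fmt="%.8g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionBlock(_StrictModel):
    tr: float = 8.24e-3
    alpha_a: float = 2.0
    alpha_b: float = 12.0
    r1: float = 4.2
    frame_interval: float = 73.0
    n_frames: int = 21
    hct: float = 0.45

    def to_params(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class FittingBlock(_StrictModel):
    model: str = "patlak"
    clip_nonnegative: bool = False
    max_iter: int = 30


class NetworkBlock(_StrictModel):
    filters: int = 32
    concat_filters: int = 64
    dense: Tuple[int, int] = (256, 128)
    dilations: Tuple[int, ...] = (2, 4, 8)
    local_depth: int = 3
    kernel: int = 4
    patch: int = 24


class TrainingBlock(_StrictModel):
    learning_rate: float = 1e-3
    decay: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 1000
    val_fraction: float = 0.2
    patience: int = 15
    lam: float = 1.0
    standardize_targets: bool = True
    input_scaling: str = "baseline_mean"


class PhantomBlock(_StrictModel):
    shape: Tuple[int, int, int] = (64, 64, 4)
    n_subjects: int = 6
    model: str = "patlak"
    sigma: float = 0.02
    rel_spread: float = 0.10
    aif_jitter: float = 0.10


class RunConfig(_StrictModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    fitting: FittingBlock = Field(default_factory=FittingBlock)
    network: NetworkBlock = Field(default_factory=NetworkBlock)
    training: TrainingBlock = Field(default_factory=TrainingBlock)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; missing file -> defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, config: RunConfig, inputs=(),
                   outputs=(), extra=None) -> dict:
    """JSON manifest: config hash, seed, version, input checksums."""
    manifest = {
        "stage": stage,
        "package": "dcedirect",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=list))
    return manifest
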