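"""Patch extraction, training protocol, and whole-volume prediction.

Slices are divided into overlapping 24 x 24 patches on a stride-6 lattice
(about 12k patches per full-size subject); training minimizes the joint loss
by mini-batch Adam with a 1/(1 + decay * k) learning-rate schedule, an 80/20
train/validation split, and early stopping with patience 15, restoring the
weights of the best validation epoch. At test time every slice is tiled the
same way and all overlapping predictions of a voxel are averaged — 16 in the
interior, the actual count near borders. Prediction consumes only the trained
weights and the 4D signal series: no input function is needed for a test
subject.

All randomness (split, shuffling, weight initialization) flows from the
single seed in :class:`TrainingConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..containers import DynamicSeries, InputFunction, PkMaps
from .loss import TargetScaler, joint_loss_and_grad
from .network import DirectNet, NetworkSpec, build_network

__all__ = [
    "PatchSet",
    "TrainingConfig",
    "TrainedModel",
    "extract_patches",
    "tile_origins",
    "overlap_counts",
    "train",
    "predict_volume",
    "loso_folds",
    "baseline_scale",
    "DirectInferenceModel",
    "save_trained_model",
    "load_trained_model",
]


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Aligned signal / target / concentration patches, channels-last.

    ``inputs`` (N, p, p, T), ``targets`` (N, p, p, n), ``conc`` (N, p, p, T);
    ``subject_ids`` (N,) and ``origins`` (N, 3) as (x0, y0, z) record
    provenance. n = 2 for Patlak targets, 3 for extended Tofts.
    """

    inputs: np.ndarray
    targets: np.ndarray
    conc: np.ndarray
    subject_ids: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.inputs)
        for arr in (self.targets, self.conc, self.subject_ids, self.origins):
            if len(arr) != n:
                raise ValueError("patch tensors are not aligned by index")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def n_params(self) -> int:
        return self.targets.shape[-1]

    @staticmethod
    def concatenate(sets: Sequence["PatchSet"]) -> "PatchSet":
        return PatchSet(
            inputs=np.concatenate([s.inputs for s in sets]),
            targets=np.concatenate([s.targets for s in sets]),
            conc=np.concatenate([s.conc for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            origins=np.concatenate([s.origins for s in sets]),
        )

    def subset(self, idx) -> "PatchSet":
        return PatchSet(self.inputs[idx], self.targets[idx], self.conc[idx],
                        self.subject_ids[idx], self.origins[idx])


def _lattice(size: int, patch: int, step: int) -> np.ndarray:
    """Stride-``step`` origins with the patch fully inside [0, size)."""
    if size < patch:
        raise ValueError(f"extent {size} smaller than patch {patch}")
    return np.arange(0, size - patch + 1, step)


def tile_origins(size: int, patch: int, step: int) -> np.ndarray:
    """Lattice origins plus a final origin snapped to ``size - patch`` so the
    tiling covers the full extent (used at prediction time)."""
    lat = _lattice(size, patch, step)
    last = size - patch
    if lat[-1] != last:
        lat = np.append(lat, last)
    return lat


def overlap_counts(shape2d: Tuple[int, int], patch: int = 24,
                   step: int = 6, snap_edges: bool = False) -> np.ndarray:
    """Per-voxel count of covering patches, by direct enumeration."""
    h, w = shape2d
    xs = tile_origins(h, patch, step) if snap_edges else _lattice(h, patch, step)
    ys = tile_origins(w, patch, step) if snap_edges else _lattice(w, patch, step)
    counts = np.zeros(shape2d, dtype=int)
    for x0 in xs:
        for y0 in ys:
            counts[x0 : x0 + patch, y0 : y0 + patch] += 1
    return counts


def extract_patches(
    signal: np.ndarray,
    targets: np.ndarray,
    conc: np.ndarray,
    patch: int = 24,
    step: int = 6,
    subject_id: int = 0,
    dtype=np.float32,
) -> PatchSet:
    """Cut aligned stride-``step`` patches from one subject's aligned stacks.

    ``signal`` and ``conc`` are (x, y, z, T); ``targets`` is (x, y, z, n).
    Patch count per slice is (floor((W-p)/s)+1) * (floor((H-p)/s)+1).
    """
    signal = np.asarray(signal)
    targets = np.asarray(targets)
    conc = np.asarray(conc)
    if signal.shape[:3] != targets.shape[:3] or signal.shape != conc.shape:
        raise ValueError("signal/targets/conc stacks are not aligned")
    nx, ny, nz, _ = signal.shape
    xs = _lattice(nx, patch, step)
    ys = _lattice(ny, patch, step)

    ins, tgt, cc, origins = [], [], [], []
    for z in range(nz):
        for x0 in xs:
            for y0 in ys:
                sl = np.s_[x0 : x0 + patch, y0 : y0 + patch, z]
                ins.append(signal[sl])
                tgt.append(targets[sl])
                cc.append(conc[sl])
                origins.append((x0, y0, z))
    n = len(ins)
    return PatchSet(
        inputs=np.asarray(ins, dtype=dtype),
        targets=np.asarray(tgt, dtype=dtype),
        conc=np.asarray(cc, dtype=dtype),
        subject_ids=np.full(n, subject_id, dtype=int),
        origins=np.asarray(origins, dtype=int),
    )


def baseline_scale(signal_values: np.ndarray) -> float:
    """Per-subject input normalization: mean positive baseline signal."""
    base = signal_values[..., 0]
    pos = base[base > 0]
    return float(pos.mean()) if pos.size else 1.0


def loso_folds(subject_ids: Sequence) -> List[Tuple[list, object]]:
    """Leave-one-subject-out folds: one (train_ids, test_id) per subject."""
    uniq = list(dict.fromkeys(subject_ids))
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in uniq if s != test], test) for test in uniq]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol constants (defaults: the full-size protocol)."""

    learning_rate: float = 1e-3
    decay: float = 1e-4          # per-update: lr_k = lr0 / (1 + decay * k)
    max_epochs: int = 200
    batch_size: int = 1000
    val_fraction: float = 0.2
    patience: int = 15
    seed: int = 0
    lam: float = 1.0             # weight of the consistency term
    standardize_targets: bool = True
    input_scaling: str = "baseline_mean"   # or "none"
    loss_reduction: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.input_scaling not in ("none", "baseline_mean"):
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")


@dataclass
class TrainedModel:
    """A trained direct-inference model plus its training record.

    ``history`` holds per-epoch train/validation losses; the stored weights
    correspond to the best validation epoch. ``predict`` consumes only a 4D
    signal series — no input function.
    """

    network: DirectNet
    spec: NetworkSpec
    model_kind: str
    config: TrainingConfig
    scaler: TargetScaler
    history: pd.DataFrame
    best_epoch: int

    def predict(self, signal: DynamicSeries) -> PkMaps:
        return predict_volume(self, signal)

    def summary(self) -> pd.DataFrame:
        h = self.history
        return pd.DataFrame({
            "value": {
                "model": self.model_kind,
                "epochs_run": len(h),
                "best_epoch": self.best_epoch,
                "best_val_loss": float(h["val_loss"].iloc[self.best_epoch]),
                "final_train_loss": float(h["train_loss"].iloc[-1]),
                "n_weights": int(sum(a.size for a in
                                     self.network.get_weights())),
            }
        })


class _Adam:
    """Adam with the 1/(1 + decay * k) learning-rate schedule."""

    def __init__(self, arrays, lr0, decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr0, self.decay = lr0, decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.k = 0  # update counter

    def step(self, grads):
        lr = self.lr0 / (1.0 + self.decay * self.k)
        self.k += 1
        t = self.k
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            g = g.astype(a.dtype, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** t)
            vhat = v / (1 - self.b2 ** t)
            a -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_loss_grad(net_out, targets, conc, cp_rows, times, model_kind,
                     lam, scaler, reduction):
    """Loss and gradient w.r.t. the network output.

    The network predicts parameters on the standardized scale; the loss is
    evaluated on physical parameters, so the gradient is chained through the
    scaler's inverse transform.
    """
    theta_pred = scaler.inverse(net_out.astype(float))
    val, g_phys = joint_loss_and_grad(
        targets, theta_pred, conc, None, times=times, model_kind=model_kind,
        lam=lam, scaler=scaler, reduction=reduction, cp_values=cp_rows)
    return val, g_phys * scaler.std


def _epoch_loss(net, patches, idx, cp_arr, times, model_kind, lam, scaler,
                reduction, batch):
    """Average loss over ``idx`` without updating weights."""
    total, n = 0.0, 0
    for i in range(0, len(idx), batch):
        sel = idx[i : i + batch]
        out = net.forward(patches.inputs[sel], train=False)
        val, _ = _batch_loss_grad(
            out, patches.targets[sel], patches.conc[sel], cp_arr[sel],
            times, model_kind, lam, scaler, reduction)
        total += val * len(sel)
        n += len(sel)
    return total / max(n, 1)


def train(
    network: DirectNet,
    patches: PatchSet,
    config: TrainingConfig,
    cp_by_subject: Dict[int, InputFunction],
    model_kind: str = "patlak",
) -> TrainedModel:
    """Minimize the joint loss by mini-batch Adam with early stopping.

    The consistency term of every patch uses its own training subject's
    plasma curve. Raises on a divergent (non-finite) loss. Fully reproducible
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(patches)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    times = next(iter(cp_by_subject.values())).times
    # per-patch plasma curves, gathered once
    sid_list = sorted(cp_by_subject)
    cp_table = np.stack([cp_by_subject[s].values for s in sid_list])
    row = {s: i for i, s in enumerate(sid_list)}
    cp_arr = cp_table[[row[s] for s in patches.subject_ids]]

    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("empty training split")

    scaler = (TargetScaler.fit(patches.targets[train_idx])
              if config.standardize_targets
              else TargetScaler.identity(patches.n_params))

    arrays = [arr for _, _, arr in network.parameters()]
    opt = _Adam(arrays, config.learning_rate, config.decay)

    history = {"train_loss": [], "val_loss": []}
    best_val, best_epoch, best_weights = np.inf, -1, network.get_weights()
    since_best = 0
    batch = config.batch_size

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        tot, cnt = 0.0, 0
        for i in range(0, len(order), batch):
            sel = order[i : i + batch]
            out = network.forward(patches.inputs[sel], train=True)
            val, dpred = _batch_loss_grad(
                out, patches.targets[sel], patches.conc[sel], cp_arr[sel],
                times, model_kind, config.lam, scaler,
                config.loss_reduction)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {val}")
            network.backward(dpred)
            opt.step([g for _, _, g in network.gradients()])
            tot += val * len(sel)
            cnt += len(sel)
        history["train_loss"].append(tot / cnt)
        # validation is forward-only; larger batches are cheaper
        vloss = _epoch_loss(network, patches, val_idx, cp_arr, times,
                            model_kind, config.lam, scaler,
                            config.loss_reduction, max(batch, 256))
        history["val_loss"].append(vloss)

        if vloss < best_val:
            best_val, best_epoch = vloss, epoch
            best_weights = network.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    network.set_weights(best_weights)
    return TrainedModel(
        network=network,
        spec=network.spec,
        model_kind=model_kind,
        config=config,
        scaler=scaler,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_volume(model: TrainedModel, signal: DynamicSeries,
                   batch: int = 256) -> PkMaps:
    """Overlap-averaged whole-volume inference.

    Tiles every slice with stride-6 patches (edge-snapped so all voxels are
    covered), averages each voxel over the patches containing it — exactly 16
    in the interior — and returns the parameter maps. Requires only the
    weights and the 4D signal; no input function is consumed.
    """
    spec = model.spec
    if signal.n_frames != spec.n_frames:
        raise ValueError(
            f"model expects {spec.n_frames} frames, series has "
            f"{signal.n_frames}"
        )
    vals = signal.values
    if model.config.input_scaling == "baseline_mean":
        vals = vals / baseline_scale(vals)
    nx, ny, nz, _ = vals.shape
    p, s = spec.patch, 6
    xs, ys = tile_origins(nx, p, s), tile_origins(ny, p, s)
    n_par = model.network.n_params

    acc = np.zeros((nx, ny, nz, n_par))
    cnt = np.zeros((nx, ny, nz, 1))
    for z in range(nz):
        patches, slots = [], []
        for x0 in xs:
            for y0 in ys:
                patches.append(vals[x0 : x0 + p, y0 : y0 + p, z])
                slots.append((x0, y0))
        pred = model.network.predict_patches(
            np.asarray(patches, dtype=model.network.dtype), batch=batch)
        pred = model.scaler.inverse(pred.astype(float))
        for (x0, y0), pr in zip(slots, pred):
            acc[x0 : x0 + p, y0 : y0 + p, z] += pr
            cnt[x0 : x0 + p, y0 : y0 + p, z] += 1
    out = acc / cnt
    model_kind = model.model_kind
    return PkMaps.from_stack(out, model=model_kind,
                             valid=np.ones((nx, ny, nz), dtype=bool))


# ---------------------------------------------------------------------------
# model object and serialization
# ---------------------------------------------------------------------------

class DirectInferenceModel:
    """Direct CNN inference of PK maps, statsmodels-style.

    Construct from a :class:`PatchSet` plus the per-subject plasma curves,
    then ``fit(config)`` trains the network and returns a
    :class:`TrainedModel` results object.
    """

    def __init__(self, patches: PatchSet,
                 cp_by_subject: Dict[int, InputFunction],
                 model_kind: str = "patlak",
                 spec: Optional[NetworkSpec] = None):
        n_expected = 2 if model_kind == "patlak" else 3
        if patches.n_params != n_expected:
            raise ValueError(
                f"{model_kind} targets need {n_expected} channels, got "
                f"{patches.n_params}"
            )
        self.patches = patches
        self.cp_by_subject = cp_by_subject
        self.model_kind = model_kind
        self.spec = spec or NetworkSpec(n_frames=patches.inputs.shape[-1],
                                        patch=patches.inputs.shape[1])

    def fit(self, config: Optional[TrainingConfig] = None) -> TrainedModel:
        config = config or TrainingConfig()
        net = build_network(self.spec, n_params=self.patches.n_params,
                            seed=config.seed, dtype=np.float32)
        return train(net, self.patches, config, self.cp_by_subject,
                     model_kind=self.model_kind)


def save_trained_model(model: TrainedModel, path) -> None:
    """Serialize weights + architecture + scaler + history to one HDF5 file."""
    import h5py
    import json

    with h5py.File(path, "w") as f:
        f.attrs["model_kind"] = model.model_kind
        f.attrs["best_epoch"] = model.best_epoch
        f.attrs["spec"] = json.dumps(asdict(model.spec))
        f.attrs["config"] = json.dumps(asdict(model.config))
        f.attrs["n_params"] = model.network.n_params
        g = f.create_group("weights")
        for i, w in enumerate(model.network.get_weights()):
            g.create_dataset(f"{i:03d}", data=w)
        f.create_dataset("scaler/mean", data=model.scaler.mean)
        f.create_dataset("scaler/std", data=model.scaler.std)
        f.create_dataset("history/train_loss",
                         data=model.history["train_loss"].to_numpy())
        f.create_dataset("history/val_loss",
                         data=model.history["val_loss"].to_numpy())


def load_trained_model(path) -> TrainedModel:
    import h5py
    import json

    with h5py.File(path, "r") as f:
        spec_kw = json.loads(f.attrs["spec"])
        spec_kw["dense"] = tuple(spec_kw["dense"])
        spec_kw["dilations"] = tuple(spec_kw["dilations"])
        spec = NetworkSpec(**spec_kw)
        config = TrainingConfig(**json.loads(f.attrs["config"]))
        net = build_network(spec, n_params=int(f.attrs["n_params"]),
                            seed=config.seed, dtype=np.float32)
        keys = sorted(f["weights"])
        net.set_weights([f["weights"][k][()] for k in keys])
        scaler = TargetScaler(f["scaler/mean"][()], f["scaler/std"][()])
        history = pd.DataFrame({
            "train_loss": f["history/train_loss"][()],
            "val_loss": f["history/val_loss"][()],
        })
        return TrainedModel(network=net, spec=spec,
                            model_kind=str(f.attrs["model_kind"]),
                            config=config, scaler=scaler, history=history,
                            best_epoch=int(f.attrs["best_epoch"]))
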