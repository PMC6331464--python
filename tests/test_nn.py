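"""Direct-inference network: patches, architecture, loss, training contract."""

import numpy as np
import pandas as pd
import pytest

from dcedirect import InputFunction, DynamicSeries
from dcedirect.nn import (
    DirectInferenceModel,
    NetworkSpec,
    PatchSet,
    TrainingConfig,
    build_network,
    extract_patches,
    joint_loss,
    loso_folds,
    overlap_counts,
    predict_volume,
    save_trained_model,
    load_trained_model,
    train,
)
from dcedirect.nn.loss import TargetScaler, joint_loss_and_grad
from dcedirect.nn.training import TrainedModel, tile_origins

TINY = NetworkSpec(n_frames=4, patch=24, filters=4, concat_filters=8,
                   dense=(8, 6), dilations=(2, 4, 8))


def _patchset(rng, n=8, t=4, n_par=2, patch=24):
    return PatchSet(
        inputs=rng.uniform(0.5, 1.5, (n, patch, patch, t)).astype(np.float32),
        targets=rng.uniform(0, 0.01, (n, patch, patch, n_par)).astype(
            np.float32),
        conc=rng.uniform(0, 0.1, (n, patch, patch, t)).astype(np.float32),
        subject_ids=np.zeros(n, dtype=int),
        origins=np.zeros((n, 3), dtype=int),
    )


def _cp(t=4):
    times = 73.0 * np.arange(t, dtype=float)
    vals = np.where(times > 0, 5.0 * np.exp(-times / 300.0), 0.0)
    return InputFunction(times, vals)


class TestExtractPatches:
    def test_counting_formula_48(self, rng):
        sig = rng.uniform(size=(48, 48, 1, 3))
        tgt = rng.uniform(size=(48, 48, 1, 2))
        ps = extract_patches(sig, tgt, sig)
        assert len(ps) == 25  # (floor((48-24)/6)+1)^2

    def test_single_patch_when_slice_equals_patch(self, rng):
        sig = rng.uniform(size=(24, 24, 2, 3))
        tgt = rng.uniform(size=(24, 24, 2, 2))
        ps = extract_patches(sig, tgt, sig)
        assert len(ps) == 2  # one per slice
        np.testing.assert_allclose(ps.inputs[0], sig[:, :, 0],
                                   rtol=1e-6)

    def test_interior_voxel_covered_by_16_patches(self):
        counts = overlap_counts((96, 96), patch=24, step=6)
        assert counts[40, 50] == 16
        interior = counts[24:-24, 24:-24]
        assert (interior == 16).all()

    def test_corner_voxel_covered_once(self):
        counts = overlap_counts((96, 96), patch=24, step=6)
        assert counts[0, 0] == 1

    def test_slice_smaller_than_patch_rejected(self, rng):
        sig = rng.uniform(size=(20, 24, 1, 3))
        with pytest.raises(ValueError, match="smaller than patch"):
            extract_patches(sig, sig[..., :2], sig)


class TestNetwork:
    def test_output_shapes_patlak_and_etofts(self):
        x = np.random.default_rng(0).normal(size=(2, 24, 24, 21))
        full = NetworkSpec()
        assert build_network(full, 2).forward(x).shape == (2, 24, 24, 2)
        assert build_network(full, 3).forward(x).shape == (2, 24, 24, 3)

    def test_all_layers_preserve_spatial_extent(self):
        """Walk the graph on random weights; every feature map stays 24x24."""
        net = build_network(TINY, 2, seed=1, dtype=np.float64)
        x = np.random.default_rng(1).normal(size=(3, 24, 24, 4))
        h = net.dw.forward(x)
        assert h.shape[1:3] == (24, 24)
        h = net.agg_relu.forward(net.agg.forward(h))
        assert h.shape[1:3] == (24, 24)
        hl, hg = h, h
        for layer in net.local:
            hl = layer.forward(hl)
            assert hl.shape[1:3] == (24, 24)
        for layer in net.globl:
            hg = layer.forward(hg)
            assert hg.shape[1:3] == (24, 24)
        z = net.fuse.forward(np.concatenate([hl, hg], axis=-1))
        assert z.shape[1:3] == (24, 24)

    def test_zero_weights_give_zero_output(self, rng):
        net = build_network(TINY, 2, seed=0)
        for _, _, arr in net.parameters():
            arr[...] = 0
        x = rng.normal(size=(2, 24, 24, 4))
        assert np.abs(net.forward(x)).max() == 0.0

    def test_weight_gradients_match_finite_differences(self, rng):
        """Backprop vs central differences on every parameter array (biases
        nudged off zero so no pre-activation sits on the ReLU kink)."""
        net = build_network(TINY, 2, seed=2, dtype=np.float64)
        for _, name, arr in net.parameters():
            if name == "b":
                arr += rng.normal(0.0, 0.1, arr.shape)
        x = rng.normal(size=(2, 24, 24, 4))
        dy = rng.normal(size=(2, 24, 24, 2))
        net.forward(x, train=True)
        net.backward(dy)
        grads = {(i, n): g.copy() for i, n, g in net.gradients()}

        def loss():
            return float(np.sum(net.forward(x) * dy))

        for (i, name, arr) in net.parameters():
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps = 1e-6
            old = arr[idx]
            arr[idx] = old + eps
            lp = loss()
            arr[idx] = old - eps
            lm = loss()
            arr[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert grads[(i, name)][idx] == pytest.approx(
                fd, rel=1e-5, abs=1e-7), f"layer {i} {name}"


class TestJointLoss:
    def test_zero_at_consistent_truth(self, rng):
        cp = _cp()
        theta = np.zeros((1, 1, 1, 2))
        theta[..., 0], theta[..., 1] = 2e-3, 0.01
        from dcedirect.kinetics import patlak_forward
        ct = patlak_forward((2e-3, 0.01), cp).reshape(1, 1, 1, -1)
        assert joint_loss(theta, theta, ct, cp) == 0.0

    def test_hand_evaluated_one_voxel_case(self, rng):
        """theta = (0,0), pred = (0, 0.1), Patlak:
        loss = 0.1^2 + sum_t (ct - 0.1 Cp)^2."""
        cp = _cp()
        ct = rng.normal(0, 0.02, (1, 1, 1, 4))
        tt = np.zeros((1, 1, 1, 2))
        tp = np.zeros((1, 1, 1, 2))
        tp[..., 1] = 0.1
        expected = 0.01 + float(np.sum((ct[0, 0, 0] - 0.1 * cp.values) ** 2))
        assert joint_loss(tt, tp, ct, cp) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_nonnegative_and_decomposition(self, rng):
        """Equals the parameter term when ct is consistent with the
        prediction, and the consistency term when the parameters agree."""
        cp = _cp()
        from dcedirect.kinetics import patlak_forward
        tt = np.abs(rng.normal(0.005, 0.002, (1, 1, 1, 2)))
        tp = np.abs(rng.normal(0.005, 0.002, (1, 1, 1, 2)))
        f_pred = patlak_forward(tp[0, 0, 0], cp).reshape(1, 1, 1, -1)
        f_true = patlak_forward(tt[0, 0, 0], cp).reshape(1, 1, 1, -1)
        par_term = float(np.sum((tt - tp) ** 2))
        assert joint_loss(tt, tp, f_pred, cp) == pytest.approx(par_term)
        con_term = float(np.sum((f_true - f_pred) ** 2))
        assert joint_loss(tt, tt, f_pred, cp) == pytest.approx(con_term)
        assert joint_loss(tt, tp, f_true, cp) >= 0

    @pytest.mark.parametrize("kind,n", [("patlak", 2), ("etofts", 3)])
    def test_gradient_matches_finite_differences(self, rng, kind, n):
        cp = _cp()
        tt = np.abs(rng.normal(0.01, 0.004, (1, 1, 1, n)))
        tp = np.abs(rng.normal(0.01, 0.004, (1, 1, 1, n)))
        if kind == "etofts":
            tt[..., 1], tp[..., 1] = 0.4, 0.7
        ct = rng.normal(0.05, 0.02, (1, 1, 1, 4))
        _, g = joint_loss_and_grad(tt, tp, ct, cp, model_kind=kind)
        eps = 1e-7
        for c in range(n):
            up, dn = tp.copy(), tp.copy()
            up[..., c] += eps
            dn[..., c] -= eps
            fd = (joint_loss(tt, up, ct, cp, model_kind=kind)
                  - joint_loss(tt, dn, ct, cp, model_kind=kind)) / (2 * eps)
            assert g[0, 0, 0, c] == pytest.approx(fd, rel=1e-5)

    def test_channel_count_mismatch_rejected(self, rng):
        cp = _cp()
        tt = np.zeros((1, 1, 1, 3))
        ct = np.zeros((1, 1, 1, 4))
        with pytest.raises(ValueError, match="parameter channels"):
            joint_loss(tt, tt, ct, cp, model_kind="patlak")


class TestTraining:
    def _train(self, rng, seed=0, max_epochs=3, patience=2):
        ps = _patchset(rng, n=10)
        cfg = TrainingConfig(max_epochs=max_epochs, patience=patience,
                             batch_size=4, seed=seed)
        net = build_network(TINY, 2, seed=seed)
        return train(net, ps, cfg, {0: _cp()}, model_kind="patlak")

    def test_identical_seeds_identical_weights(self, rng):
        a = self._train(np.random.default_rng(1), seed=7)
        b = self._train(np.random.default_rng(1), seed=7)
        for wa, wb in zip(a.network.get_weights(), b.network.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_different_seeds_differ(self, rng):
        a = self._train(np.random.default_rng(1), seed=7)
        b = self._train(np.random.default_rng(1), seed=8)
        assert any(
            not np.array_equal(wa, wb)
            for wa, wb in zip(a.network.get_weights(),
                              b.network.get_weights()))

    def test_early_stop_restores_best_epoch(self, rng):
        """History ends `patience` epochs after the best validation epoch and
        the restored weights reproduce that epoch's validation loss."""
        ps = _patchset(np.random.default_rng(3), n=12)
        cfg = TrainingConfig(max_epochs=60, patience=3, batch_size=4, seed=1)
        net = build_network(TINY, 2, seed=1)
        tm = train(net, ps, cfg, {0: _cp()}, model_kind="patlak")
        e = len(tm.history)
        if e < 60:  # patience exhausted
            assert tm.best_epoch == e - 1 - cfg.patience
        assert tm.history["val_loss"].iloc[tm.best_epoch] == \
            tm.history["val_loss"].min()

    def test_history_lengths_bounded(self, rng):
        tm = self._train(rng)
        assert len(tm.history) <= 3
        assert {"train_loss", "val_loss"} <= set(tm.history.columns)

    def test_save_load_round_trip(self, rng, tmp_path):
        tm = self._train(rng)
        path = tmp_path / "model.h5"
        save_trained_model(tm, path)
        back = load_trained_model(path)
        for wa, wb in zip(tm.network.get_weights(),
                          back.network.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        assert back.model_kind == tm.model_kind
        assert back.best_epoch == tm.best_epoch
        x = rng.uniform(0.5, 1.5, (2, 24, 24, 4)).astype(np.float32)
        np.testing.assert_array_equal(tm.network.forward(x),
                                      back.network.forward(x))


class _OracleNet:
    """Stands in for a trained network: returns each patch's first-frame
    values as both parameter channels (translation equivariant)."""

    def __init__(self, n_params=2, n_frames=4):
        self.n_params = n_params
        self.dtype = np.float32

    def predict_patches(self, x, batch=256):
        return np.repeat(x[..., :1], self.n_params, axis=-1)


def _oracle_model(n_frames=4):
    spec = NetworkSpec(n_frames=n_frames, patch=24, filters=4,
                       concat_filters=8, dense=(8, 6))
    return TrainedModel(
        network=_OracleNet(2, n_frames), spec=spec, model_kind="patlak",
        config=TrainingConfig(seed=0, input_scaling="none"),
        scaler=TargetScaler.identity(2),
        history=pd.DataFrame({"train_loss": [1.0], "val_loss": [1.0]}),
        best_epoch=0)


class TestPredictVolume:
    def test_oracle_predictions_reassemble_exactly(self, rng):
        """Averaging identical per-patch oracle outputs reproduces the map."""
        vol = rng.uniform(1, 2, (48, 48, 2, 4))
        series = DynamicSeries(vol, 73.0 * np.arange(4), "signal")
        maps = _oracle_model().predict(series)
        np.testing.assert_allclose(maps.ktrans, vol[..., 0], rtol=1e-6)
        np.testing.assert_allclose(maps.vp, vol[..., 0], rtol=1e-6)

    def test_translation_consistency(self, rng):
        """A 6-voxel in-plane shift translates interior predictions."""
        vol = rng.uniform(1, 2, (60, 60, 1, 4))
        shifted = np.roll(vol, 6, axis=0)
        series = DynamicSeries(vol, 73.0 * np.arange(4), "signal")
        sser = DynamicSeries(shifted, 73.0 * np.arange(4), "signal")
        m1 = _oracle_model().predict(series)
        m2 = _oracle_model().predict(sser)
        np.testing.assert_allclose(m2.ktrans[24:-24, 24:-24],
                                   m1.ktrans[18:-30, 24:-24], rtol=1e-6)

    def test_frame_count_mismatch_rejected(self, rng):
        vol = rng.uniform(1, 2, (24, 24, 1, 5))
        series = DynamicSeries(vol, 73.0 * np.arange(5), "signal")
        with pytest.raises(ValueError, match="frames"):
            _oracle_model(n_frames=4).predict(series)

    def test_edge_snapped_tiling_covers_everything(self):
        assert tile_origins(64, 24, 6).max() == 40
        counts = overlap_counts((64, 64), snap_edges=True)
        assert (counts > 0).all()
        assert counts[30, 30] == 16


class TestLosoFolds:
    def test_fifteen_subjects_two_model_kinds_make_thirty_jobs(self):
        folds = loso_folds(list(range(15)))
        assert len(folds) * 2 == 30

    def test_two_subjects(self):
        folds = loso_folds(["a", "b"])
        assert folds == [(["b"], "a"), (["a"], "b")]

    def test_folds_partition_subjects(self):
        ids = list("abcdef")
        folds = loso_folds(ids)
        tests = [t for _, t in folds]
        assert sorted(tests) == sorted(ids)
        for train_ids, test_id in folds:
            assert test_id not in train_ids
            assert sorted(train_ids + [test_id]) == sorted(ids)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(["only"])
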