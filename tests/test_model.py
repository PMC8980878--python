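"""Network correctness (gradients), fold partitioning, training behaviour
and the frozen-encoder transfer contract."""

import numpy as np
import pytest

import murineseg as ms
from murineseg.errors import ArchitectureError
from murineseg.model import TrainConfig, UNetConfig, train_fold, transfer_retrain
from murineseg.nn import UNet, functional as F, is_encoder_param


class TestGradients:
    """Analytic backprop versus central finite differences on a tiny net."""

    def test_every_parameter_grad_matches_numeric(self):
        net = UNet(depth=2, base_filters=2, dtype=np.float64)
        params = net.init_params(seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)

        logits, cache = net.forward(params, x)
        _, dz = F.bce_loss_and_grad(logits, y)
        grads = net.backward(params, cache, dz)

        def loss_at(p):
            lg, _ = net.forward(p, x, want_cache=False)
            return F.bce_loss_and_grad(lg, y)[0]

        eps = 1e-6
        mid = loss_at(params)
        checked = 0
        for name in params:
            idx = tuple(rng.integers(s) for s in params[name].shape)
            q = {k: v.copy() for k, v in params.items()}
            q[name][idx] += eps
            up = loss_at(q)
            q[name][idx] -= 2 * eps
            dn = loss_at(q)
            # ReLU kinks / max-pool argmax switches inside the +/- eps window
            # make the central difference meaningless there; the loss is
            # otherwise smooth, so a large second difference flags a kink
            if abs(up + dn - 2 * mid) > 50 * eps**2:
                continue
            numeric = (up - dn) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-9, rel=1e-6), name
            checked += 1
        assert checked >= 0.7 * len(params)

    def test_output_shape_matches_input(self):
        net = UNet(depth=3, base_filters=4)
        p = net.init_params(0)
        out = net.predict_proba(p, np.random.default_rng(0).random((3, 1, 16, 24)).astype(np.float32))
        assert out.shape == (3, 1, 16, 24)
        assert out.min() >= 0 and out.max() <= 1

    def test_indivisible_shape_rejected(self):
        net = UNet(depth=3, base_filters=4)
        with pytest.raises(ArchitectureError):
            net.forward(net.init_params(0), np.zeros((1, 1, 20, 20), dtype=np.float32))


class TestMakeFolds:
    def test_ten_subjects_five_folds(self):
        folds = ms.make_folds(list(range(10)), 5, seed=0)
        val_union = []
        for train, val in folds:
            assert len(val) == 2
            assert len(train) == 8
            assert not set(train) & set(val)
            val_union += val
        assert sorted(val_union) == list(range(10))

    def test_training_cohort_fold_sizes(self):
        # 291 scans into 5 folds: validation sizes must be 58 or 59
        folds = ms.make_folds([f"scan{i}" for i in range(291)], 5, seed=1)
        sizes = sorted(len(val) for _, val in folds)
        assert sizes == [58, 58, 58, 58, 59]

    def test_deterministic_given_seed(self):
        a = ms.make_folds(list(range(17)), 5, seed=9)
        b = ms.make_folds(list(range(17)), 5, seed=9)
        assert a == b
        assert a != ms.make_folds(list(range(17)), 5, seed=10)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            ms.make_folds([1, 2, 3], 5, seed=0)


def _tiny_slices(rng, n=4, size=16, empty=False):
    x = rng.random((n, size, size)).astype(np.float32) * 0.2
    y = np.zeros((n, size, size), dtype=np.float32)
    if not empty:
        x[:, 4:12, 4:12] += 0.6
        y[:, 4:12, 4:12] = 1.0
    return np.clip(x, 0, 1), y


class TestTraining:
    def test_overfit_all_zero_mask(self):
        rng = np.random.default_rng(0)
        x, _ = _tiny_slices(rng, n=1)
        y = np.zeros_like(x)
        uc = UNetConfig(depth=2, base_filters=8)
        # 30 epochs on one slice is only 30 optimizer steps: use a rate that
        # can actually overfit within that budget
        tc = TrainConfig(learning_rate=3e-2, batch_size=1, epochs=30, n_folds=2, seed=0, keep="last")
        w, hist = train_fold(x, y, x, y, uc, tc)
        prob = uc.build().predict_proba(w, x[:, None])
        assert prob.mean() < 0.1

    def test_single_batch_loss_drops_tenfold(self):
        rng = np.random.default_rng(1)
        x, y = _tiny_slices(rng, n=2)
        uc = UNetConfig(depth=2, base_filters=8)
        tc = TrainConfig(learning_rate=2e-2, batch_size=2, epochs=30, n_folds=2, seed=1, keep="last")
        _, hist = train_fold(x, y, x, y, uc, tc)
        assert hist[-1]["loss"] <= hist[0]["loss"] / 10

    def test_validation_dsc_improves_and_history_complete(self):
        rng = np.random.default_rng(2)
        x, y = _tiny_slices(rng, n=8)
        uc = UNetConfig(depth=2, base_filters=4)
        tc = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=8, n_folds=2, seed=2)
        _, hist = train_fold(x[:6], y[:6], x[6:], y[6:], uc, tc)
        assert len(hist) == 8
        assert max(h["val_dsc"] for h in hist) > hist[0]["val_dsc"]

    def test_kfold_returns_one_weight_set_per_fold(self):
        rng = np.random.default_rng(3)
        data = {}
        for i in range(4):
            x, y = _tiny_slices(rng, n=2)
            data[f"s{i}"] = (x, y)
        uc = UNetConfig(depth=2, base_filters=2)
        tc = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=2, n_folds=2, seed=0)
        ens = ms.train_kfold(data, uc, tc)
        assert len(ens) == 2
        assert all(len(h) == 2 for h in ens.histories)

    def test_ensemble_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        data = {f"s{i}": _tiny_slices(rng, n=1) for i in range(2)}
        uc = UNetConfig(depth=1, base_filters=2)
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, epochs=1, n_folds=2, seed=0)
        ens = ms.train_kfold(data, uc, tc)
        ens.save(tmp_path / "run")
        back = ms.FoldEnsemble.load(tmp_path / "run")
        assert len(back) == len(ens)
        for a, b in zip(ens.weights, back.weights):
            for k in a:
                np.testing.assert_array_equal(a[k], b[k])
        assert back.unet_config == ens.unet_config


class TestTransfer:
    def _base(self):
        uc = UNetConfig(depth=2, base_filters=4)
        return uc, uc.build().init_params(seed=7)

    def test_frozen_encoder_bitwise_invariant_one_step(self):
        uc, base = self._base()
        rng = np.random.default_rng(5)
        data = {"a": _tiny_slices(rng, n=2), "b": _tiny_slices(rng, n=2)}
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, epochs=1, n_folds=2, seed=0)
        new, _ = transfer_retrain(base, data, uc, tc, freeze_encoder=True)
        enc = [k for k in base if is_encoder_param(k)]
        dec = [k for k in base if not is_encoder_param(k)]
        assert enc and dec
        for k in enc:
            assert np.array_equal(base[k], new[k]), k
        assert any(not np.array_equal(base[k], new[k]) for k in dec)

    def test_unfrozen_encoder_moves(self):
        uc, base = self._base()
        rng = np.random.default_rng(6)
        data = {"a": _tiny_slices(rng, n=2), "b": _tiny_slices(rng, n=2)}
        tc = TrainConfig(learning_rate=1e-3, batch_size=2, epochs=1, n_folds=2, seed=0)
        new, _ = transfer_retrain(base, data, uc, tc, freeze_encoder=False)
        assert any(
            not np.array_equal(base[k], new[k]) for k in base if is_encoder_param(k)
        )

    def test_architecture_mismatch_rejected(self):
        uc, base = self._base()
        other = UNetConfig(depth=3, base_filters=4)
        rng = np.random.default_rng(7)
        data = {"a": _tiny_slices(rng, n=1)}
        tc = TrainConfig(learning_rate=1e-3, batch_size=1, epochs=1, n_folds=2, seed=0)
        with pytest.raises(ArchitectureError):
            transfer_retrain(base, data, other, tc)
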