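"""Model families: task weights, weighted loss, PLS grid search, nets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from leafspec import models
from leafspec.containers import PIGMENTS, ParameterError
from leafspec.models import (
    MULTI,
    SINGLE,
    TaskWeightVector,
    build_cnn,
    compute_task_weights,
    count_conv_layers,
    fit_bpnn,
    fit_pls,
    train_cnn,
    weighted_mt_loss,
)


class TestTaskWeights:
    def test_unit_fixed_point(self):
        Y = np.random.default_rng(0).normal(0, 1, (200, 4))
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1) * 0.5  # variance 0.25 per task
        w = compute_task_weights(Y)
        assert np.allclose(w.w, 1.0, atol=1e-12)

    def test_stated_arithmetic(self):
        w = TaskWeightVector(w=0.25 / np.array([0.5, 0.25, 1.0, 0.0625]),
                             var=np.array([0.5, 0.25, 1.0, 0.0625]))
        assert np.allclose(w.w, [0.5, 1.0, 0.25, 4.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.01, 2.0), min_size=4, max_size=4))
    def test_weight_variance_product_identity(self, variances):
        """Defining identity: w_i · var_i = 0.25 for every task."""
        var = np.asarray(variances)
        rng = np.random.default_rng(0)
        # build targets with exactly these sample variances
        base = rng.normal(0, 1, (50, 4))
        base = (base - base.mean(0)) / base.std(0, ddof=1)
        Y = base * np.sqrt(var)
        w = compute_task_weights(Y)
        assert np.abs(w.w * w.var - 0.25).max() <= 1e-9

    def test_zero_variance_rejected(self):
        Y = np.ones((10, 4))
        Y[:, :3] += np.random.default_rng(0).normal(0, 1, (10, 3))
        with pytest.raises(ParameterError):
            compute_task_weights(Y)


class TestWeightedLoss:
    def _w(self, values):
        values = np.asarray(values, float)
        return TaskWeightVector(w=values, var=0.25 / values)

    def test_zero_iff_exact(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(0, 1, (8, 4))
        w = self._w([1, 2, 3, 4])
        assert weighted_mt_loss(pred, pred, w) == 0.0
        assert weighted_mt_loss(pred, pred + 0.1, w) > 0

    def test_unweighted_reduction(self):
        rng = np.random.default_rng(2)
        pred, true = rng.normal(0, 1, (2, 10, 4))
        plain = ((pred - true) ** 2).mean(axis=0).mean()
        assert weighted_mt_loss(pred, true, self._w([1, 1, 1, 1])) == pytest.approx(plain)

    def test_hand_computed_single_sample(self):
        # per-task squared errors (1, 4, 0, 0), w = (1, 0.5, 1, 1) → 0.75
        pred = np.array([[1.0, 2.0, 0.0, 0.0]])
        true = np.zeros((1, 4))
        assert weighted_mt_loss(pred, true, self._w([1, 0.5, 1, 1])) == pytest.approx(0.75)

    def test_linear_in_each_weight(self):
        rng = np.random.default_rng(3)
        pred, true = rng.normal(0, 1, (2, 6, 4))
        base = np.array([1.0, 1.0, 1.0, 1.0])
        l0 = weighted_mt_loss(pred, true, self._w(base))
        bumped = base.copy()
        bumped[2] *= 3
        l1 = weighted_mt_loss(pred, true, self._w(bumped))
        mse2 = ((pred - true) ** 2).mean(axis=0)[2]
        assert l1 - l0 == pytest.approx(2 * mse2 / 4)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            weighted_mt_loss(np.zeros((3, 4)), np.zeros((4, 4)), self._w([1, 1, 1, 1]))


def _rank1_fixture(n=60, b=20, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.normal(0, 1, n)
    X = np.outer(t, rng.uniform(0.5, 1.5, b))
    y = (2.0 * t + 1.0).reshape(-1, 1)
    return X[:40], y[:40], X[40:50], y[40:50], X[50:], y[50:]


class TestPLS:
    def test_rank1_recovery_with_one_component(self):
        X_tr, y_tr, X_va, y_va, X_te, y_te = _rank1_fixture()
        m = fit_pls(X_tr, y_tr, X_va, y_va, task_mode=SINGLE, component_grid=range(1, 6))
        assert m.extras["n_components"] == 1
        pred = m.predict(X_te)
        r = np.corrcoef(y_te.ravel(), pred.ravel())[0, 1]
        assert r >= 0.999

    def test_singleton_grid_forced(self):
        X_tr, y_tr, X_va, y_va, *_ = _rank1_fixture()
        m = fit_pls(X_tr, y_tr, X_va, y_va, task_mode=SINGLE, component_grid=[3])
        assert m.extras["n_components"] == 3

    def test_grid_search_equals_bruteforce_oracle(self, linear_fixture):
        """The selected component count must match an exhaustive re-fit."""
        sp = linear_fixture["splits"]
        X_tr, Y_tr = sp["train"]
        X_va, Y_va = sp["val"]
        grid = range(1, 9)
        m = fit_pls(X_tr, Y_tr, X_va, Y_va, task_mode=MULTI, component_grid=grid)
        # independent oracle: refit each grid value directly with sklearn
        scores = []
        for k in grid:
            oracle = PLSRegression(n_components=k, scale=False).fit(X_tr, Y_tr)
            rmse = np.sqrt(((oracle.predict(X_va) - Y_va) ** 2).mean(axis=0)).mean()
            scores.append(rmse)
        tied = [k for k, s in zip(grid, scores) if s <= min(scores) + 1e-15]
        assert m.extras["n_components"] == min(tied)

    def test_nuisance_band_robustness(self):
        X_tr, y_tr, X_va, y_va, X_te, y_te = _rank1_fixture()
        rng = np.random.default_rng(9)
        noise = [rng.normal(0, 1, (len(a), 10)) for a in (X_tr, X_va, X_te)]
        m_clean = fit_pls(X_tr, y_tr, X_va, y_va, SINGLE, range(1, 6))
        m_noisy = fit_pls(np.hstack([X_tr, noise[0]]), y_tr,
                          np.hstack([X_va, noise[1]]), y_va, SINGLE, range(1, 6))
        rmse_clean = min(m_clean.training_log["val_rmse"])
        rmse_noisy = min(m_noisy.training_log["val_rmse"])
        assert rmse_noisy <= max(1.1 * rmse_clean, rmse_clean + 0.02)

    def test_empty_and_overlarge_grids_rejected(self):
        X_tr, y_tr, X_va, y_va, *_ = _rank1_fixture()
        with pytest.raises(ParameterError):
            fit_pls(X_tr, y_tr, X_va, y_va, SINGLE, [])
        with pytest.raises(ParameterError):
            fit_pls(X_tr, y_tr, X_va, y_va, SINGLE, [100])


class TestBPNN:
    def test_constant_targets_learned(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (40, 10))
        y = np.full((40, 1), 1.7)
        cfg = models.NetConfig(epochs=1500, patience=1500, hidden=8, lr=5e-3)
        m = fit_bpnn(X[:30], y[:30], X[30:], y[30:], SINGLE, cfg, seed=0)
        assert np.abs(m.predict(X) - 1.7).max() <= 0.01

    def test_training_trace_deterministic(self):
        X_tr, y_tr, X_va, y_va, *_ = _rank1_fixture()
        cfg = models.NetConfig(epochs=30, patience=30, hidden=8)
        a = fit_bpnn(X_tr, y_tr, X_va, y_va, SINGLE, cfg, seed=3)
        b = fit_bpnn(X_tr, y_tr, X_va, y_va, SINGLE, cfg, seed=3)
        assert a.training_log["train_loss"] == b.training_log["train_loss"]
        assert a.training_log["val_loss"] == b.training_log["val_loss"]

    def test_capacity_on_linear_fixture(self):
        X_tr, y_tr, X_va, y_va, X_te, y_te = _rank1_fixture()
        cfg = models.NetConfig(epochs=400, patience=100, hidden=32)
        m = fit_bpnn(X_tr, y_tr, X_va, y_va, SINGLE, cfg, seed=0)
        r = np.corrcoef(y_te.ravel(), m.predict(X_te).ravel())[0, 1]
        assert r >= 0.95


class TestCNNArchitecture:
    @pytest.mark.parametrize("variant,n_conv", [("vnir", 3), ("nir", 2), ("nir_small", 1)])
    def test_conv_layer_counts(self, variant, n_conv):
        net = build_cnn(variant, 64, 4)
        assert count_conv_layers(net) == n_conv

    @pytest.mark.parametrize("variant", ["vnir", "nir", "nir_small"])
    @pytest.mark.parametrize("out_width", [1, 4])
    def test_output_shape_contract(self, variant, out_width):
        net = build_cnn(variant, 48, out_width)
        out = net.forward(np.zeros((3, 1, 48)), train=True)
        assert out.shape == (3, out_width)

    def test_head_is_two_dense_layers(self):
        from leafspec import nnet

        for variant in ("vnir", "nir", "nir_small"):
            net = build_cnn(variant, 64, 4)
            assert sum(isinstance(l, nnet.Dense) for l in net.layers) == 2

    def test_zero_input_finite_output(self):
        net = build_cnn("vnir", 32, 4)
        out = net.forward(np.zeros((2, 1, 32)), train=True)
        assert np.all(np.isfinite(out))

    def test_too_few_bands_rejected(self):
        with pytest.raises(ParameterError, match="at least"):
            build_cnn("vnir", 3, 1)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            build_cnn("thermal", 64, 1)


class TestTrainCNN:
    def test_deterministic_loss_trace(self):
        X_tr, y_tr, X_va, y_va, *_ = _rank1_fixture()
        cfg = models.NetConfig(epochs=10, patience=10)
        a = train_cnn(X_tr, y_tr, X_va, y_va, "nir_small", SINGLE, cfg, seed=5)
        b = train_cnn(X_tr, y_tr, X_va, y_va, "nir_small", SINGLE, cfg, seed=5)
        assert a.training_log["train_loss"] == b.training_log["train_loss"]

    def test_zero_epoch_budget_returns_initialization(self):
        X_tr, y_tr, X_va, y_va, X_te, y_te = _rank1_fixture()
        cfg = models.NetConfig(epochs=0, patience=1)
        m = train_cnn(X_tr, y_tr, X_va, y_va, "nir_small", SINGLE, cfg, seed=0)
        assert m.training_log["train_loss"] == []
        assert np.all(np.isfinite(m.predict(X_te)))


class TestPredictContract:
    def test_band_count_mismatch_names_expected(self, trained_suite):
        model = trained_suite["MTPLSR"]
        with pytest.raises(ParameterError, match=str(model.n_bands)):
            model.predict(np.zeros((3, model.n_bands + 5)))

    def test_permutation_equivariance(self, trained_suite, linear_fixture):
        X_te = linear_fixture["splits"]["test"][0]
        perm = np.random.default_rng(0).permutation(len(X_te))
        for name in ("MTPLSR", "MTBPNN", "MTCNN"):
            model = trained_suite[name]
            assert np.allclose(model.predict(X_te)[perm], model.predict(X_te[perm]))

    def test_single_vs_multi_output_widths(self, trained_suite, linear_fixture):
        X_te = linear_fixture["splits"]["test"][0]
        assert trained_suite["STCNN_chla"].predict(X_te).shape == (len(X_te), 1)
        assert trained_suite["MTCNN"].predict(X_te).shape == (len(X_te), 4)

    def test_multi_task_weights_attached(self, trained_suite):
        for name in ("MTBPNN", "MTCNN"):
            w = trained_suite[name].weights
            assert w is not None
            assert np.abs(w.w * w.var - 0.25).max() <= 1e-9


class TestFamilyRecovery:
    def test_every_family_recovers_linear_fixture(self, trained_suite, linear_fixture):
        """On the noise-free fixture every family reaches test r ≥ 0.95."""
        X_te, Y_te = linear_fixture["splits"]["test"]
        for name, model in trained_suite.items():
            pred = model.predict(X_te)
            for j, task in enumerate(model.tasks):
                col = PIGMENTS.index(task) if len(model.tasks) == 1 else j
                r = np.corrcoef(Y_te[:, col], pred[:, j])[0, 1]
                assert r >= 0.95, f"{name}/{task}: r={r:.3f}"
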