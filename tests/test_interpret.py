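"""Metrics, linear fits, Grad-CAM++ maps and peak/valley extraction."""

import numpy as np
import pytest

from leafspec import nnet
from leafspec.containers import ParameterError, WavelengthGrid
from leafspec.interpret import (
    ImportanceMap,
    build_metrics_table,
    evaluate_model,
    gradcam_pp_1d,
    linear_fit,
    peaks_valleys,
    regression_metrics,
)
from leafspec.models import FittedModel


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.2, 1.1, 2.4, 0.9])
        r, rmse = regression_metrics(y, y)
        assert r == pytest.approx(1.0)
        assert rmse == 0.0

    def test_anticorrelation(self):
        y = np.array([-1.0, 0.0, 1.0])
        r, _ = regression_metrics(y, -y)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # y=(0,1,2), yhat=(0,1,4): RMSE = sqrt(4/3); r = 12/sqrt(156)
        r, rmse = regression_metrics([0, 1, 2], [0, 1, 4])
        assert rmse == pytest.approx(np.sqrt(4 / 3), rel=1e-12)
        assert r == pytest.approx(12 / np.sqrt(156), rel=1e-12)

    def test_closed_form_oracle_on_random_vectors(self):
        """r and RMSE agree with direct recomputation to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(0, 2, 30)
            yhat = y + rng.normal(0, 0.5, 30)
            r, rmse = regression_metrics(y, yhat)
            dy, dyh = y - y.mean(), yhat - yhat.mean()
            r_direct = (dy @ dyh) / np.sqrt((dy @ dy) * (dyh @ dyh))
            rmse_direct = np.sqrt(((y - yhat) ** 2).sum() / y.size)
            assert abs(r - r_direct) <= 1e-12
            assert abs(rmse - rmse_direct) <= 1e-12

    def test_scale_covariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(1, 0.5, 40)
        yhat = y + rng.normal(0, 0.1, 40)
        r1, rmse1 = regression_metrics(y, yhat)
        r2, rmse2 = regression_metrics(3.5 * y, 3.5 * yhat)
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert rmse2 == pytest.approx(3.5 * rmse1, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            regression_metrics([1.0], [1.0])
        with pytest.raises(ParameterError):
            regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_identity_line(self):
        y = np.array([0.1, 0.5, 1.2, 2.0])
        slope, intercept = linear_fit(y, y)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_case(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept = linear_fit(y, 2 * y + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0, 3, 200)
        yhat = 0.9 * y + 0.2 + rng.normal(0, 0.05, 200)
        slope, _ = linear_fit(y, yhat)
        assert abs(slope - 0.9) <= 0.05


class TestMetricsTable:
    def test_row_counting_contract(self, trained_suite, linear_fixture):
        sp = linear_fixture["splits"]
        single = {k: v for k, v in trained_suite.items() if k.startswith("ST")}
        table = build_metrics_table(single, sp, camera="vnir", condition="packaged")
        assert len(table) == 12  # 3 single-task families × 4 attributes
        mt = build_metrics_table({"MTCNN": trained_suite["MTCNN"]}, sp, "vnir", "packaged")
        assert len(mt) == 4  # one fit → four rows
        assert set(mt["attribute"]) == {"chla", "chlb", "chlt", "car"}

    def test_r_and_rmse_ranges(self, trained_suite, linear_fixture):
        table = build_metrics_table(trained_suite, linear_fixture["splits"], "vnir", "p")
        for col in ("r_c", "r_v", "r_p"):
            assert table[col].between(-1, 1).all()
        for col in ("RMSEC", "RMSEV", "RMSEP"):
            assert (table[col] >= 0).all()

    def test_csv_round_trip(self, trained_suite, linear_fixture, tmp_path):
        import pandas as pd

        table = build_metrics_table(
            {"MTPLSR": trained_suite["MTPLSR"]}, linear_fixture["splits"], "vnir", "p")
        path = tmp_path / "metrics.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back.shape == table.shape
        assert np.allclose(back["RMSEP"], table["RMSEP"])

    def test_missing_split_rejected(self, trained_suite, linear_fixture):
        sp = dict(linear_fixture["splits"])
        sp.pop("val")
        with pytest.raises(ParameterError, match="val"):
            evaluate_model(trained_suite["MTPLSR"], sp)


def _toy_linear_cnn(kernel, head_weights, n_bands):
    """1-filter conv + linear head, no nonlinearity in the head path."""
    rng = np.random.default_rng(0)
    conv = nnet.Conv1d(1, 1, len(kernel), rng)
    conv.W[...] = np.asarray(kernel).reshape(1, 1, -1)
    conv.b[...] = 0.0
    dense = nnet.Dense(n_bands, 1, rng)
    dense.W[...] = np.asarray(head_weights).reshape(-1, 1)
    dense.b[...] = 0.0
    net = nnet.Sequential([conv, nnet.Flatten(), dense])
    net.last_conv_index = 0
    return FittedModel(
        family="cnn", task_mode="single", tasks=("chla",), n_bands=n_bands,
        predictor=net, x_mean=np.zeros(n_bands), x_std=np.ones(n_bands),
        y_offset=np.zeros(1), y_scale=np.ones(1), extras={"last_conv": 0},
    )


class TestGradCAM:
    def test_map_length_matches_band_count(self, trained_suite, linear_fixture):
        X_te = linear_fixture["splits"]["test"][0]
        grid = linear_fixture["grid"]
        for name in ("MTCNN", "STCNN_chla"):
            imap = gradcam_pp_1d(trained_suite[name], X_te, 0, grid=grid)
            assert imap.weights.shape == (len(grid),)
            assert imap.weights.min() >= 0
            assert imap.weights.max() == pytest.approx(1.0)

    def test_analytic_toy_network(self):
        """Uniform positive head: the map is the rectified activation profile.

        With constant d(score)/dA = c > 0, the Grad-CAM++ channel weight is
        a positive scalar, so the map reduces to relu(A) up to scale.
        """
        n_bands = 12
        model = _toy_linear_cnn([1.0, 2.0, 1.0], np.full(n_bands, 0.5), n_bands)
        X = np.abs(np.random.default_rng(1).normal(0.5, 0.2, (1, n_bands)))
        imap = gradcam_pp_1d(model, X, 0)
        activation = model.predictor.forward(X[:, None, :], train=False)  # run forward
        A = model.predictor.activation(0)[0, 0]
        expected = np.maximum(A, 0.0)
        expected = expected / expected.max()
        assert np.allclose(imap.weights, expected, atol=1e-10)

    def test_zero_head_gives_all_zero_map_with_warning(self):
        n_bands = 12
        model = _toy_linear_cnn([1.0, 2.0, 1.0], np.zeros(n_bands), n_bands)
        X = np.random.default_rng(2).normal(0.5, 0.2, (3, n_bands))
        with pytest.warns(UserWarning, match="all-zero"):
            imap = gradcam_pp_1d(model, X, 0)
        assert imap.all_zero
        assert np.all(imap.weights == 0)

    def test_non_cnn_rejected(self, trained_suite, linear_fixture):
        X_te = linear_fixture["splits"]["test"][0]
        with pytest.raises(ParameterError, match="CNN"):
            gradcam_pp_1d(trained_suite["MTPLSR"], X_te, 0)


class TestPeaksValleys:
    def _map(self, weights, wavelengths=None):
        weights = np.asarray(weights, float)
        wl = wavelengths if wavelengths is not None else np.arange(len(weights), dtype=float)
        return ImportanceMap(weights, np.asarray(wl, float), "chla")

    def test_single_gaussian_peak(self):
        wl = np.linspace(400, 1000, 101)
        weights = np.exp(-((wl - 700) ** 2) / (2 * 30**2))
        report = peaks_valleys(self._map(weights, wl), neighborhood=3)
        assert len(report.peak_wavelengths) == 1
        assert report.peak_wavelengths[0] == pytest.approx(700, abs=6)
        assert report.global_peak == report.peak_wavelengths[0]

    def test_constant_map_has_no_extrema(self):
        report = peaks_valleys(self._map(np.full(50, 0.4)), neighborhood=5)
        assert len(report.peak_wavelengths) == 0
        assert len(report.valley_wavelengths) == 0
        assert report.global_peak is None

    def test_bimodal_map_reports_both_centers(self):
        wl = np.linspace(400, 1000, 201)
        weights = (np.exp(-((wl - 550) ** 2) / (2 * 20**2))
                   + 0.8 * np.exp(-((wl - 800) ** 2) / (2 * 25**2)))
        report = peaks_valleys(self._map(weights, wl), neighborhood=5)
        assert len(report.peak_wavelengths) == 2
        assert report.peak_wavelengths[0] == pytest.approx(550, abs=6)
        assert report.peak_wavelengths[1] == pytest.approx(800, abs=6)
        assert report.global_peak == pytest.approx(550, abs=6)
        # the dip between the modes is a valley
        assert len(report.valley_wavelengths) >= 1

    def test_too_short_map_rejected(self):
        with pytest.raises(ParameterError):
            peaks_valleys(self._map([0.1, 0.2]), neighborhood=1)
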