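"""Model evaluation and wavelength-importance interpretation.

Metrics follow chemometric convention: Pearson correlation r and RMSE
(mg/g) reported separately for the calibration (training), validation and
prediction (testing) sets — r_c/RMSEC, r_v/RMSEV, r_p/RMSEP. Predicted-vs-
actual linear fits visualize the same splits. For the CNN families, a 1-D
adaptation of Grad-CAM++ turns gradients at the last convolutional layer
into a per-wavelength importance map whose peaks and valleys indicate which
spectral regions drive each pigment's prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import pearsonr

from .containers import PIGMENTS, ParameterError, WavelengthGrid
from .models import FittedModel

SPLIT_SUFFIX = {"train": "c", "val": "v", "test": "p"}


def regression_metrics(y, yhat) -> tuple[float, float]:
    """Pearson r and RMSE of predictions against reference values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ParameterError("y and yhat must have equal length")
    if y.size < 2:
        raise ParameterError("need at least 2 samples for r/RMSE")
    if np.ptp(y) == 0:
        raise ParameterError("r is undefined for constant reference values")
    r = float(pearsonr(y, yhat)[0])
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return r, rmse


def linear_fit(y, yhat) -> tuple[float, float]:
    """Ordinary least-squares line of predicted against actual values."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2:
        raise ParameterError("need at least 2 samples for a linear fit")
    if np.ptp(y) == 0:
        raise ParameterError("linear fit is undefined for constant actual values")
    slope, intercept = np.polyfit(y, yhat, 1)
    return float(slope), float(intercept)


def evaluate_model(model: FittedModel, splits: dict) -> pd.DataFrame:
    """One metrics row per task of one fitted model.

    ``splits`` maps 'train'/'val'/'test' to (X, Y) pairs where Y is either
    the full 4-column pigment block (columns ordered chla/chlb/chlt/car) or
    already restricted to the model's tasks.
    """
    for name in SPLIT_SUFFIX:
        if name not in splits:
            raise ParameterError(f"missing split {name!r}")
    rows = {task: {} for task in model.tasks}
    for split_name, suffix in SPLIT_SUFFIX.items():
        X, Y = splits[split_name]
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        pred = model.predict(X)
        for j, task in enumerate(model.tasks):
            if Y.shape[1] == len(model.tasks):
                y_true = Y[:, j]
            elif task in PIGMENTS and Y.shape[1] == len(PIGMENTS):
                y_true = Y[:, PIGMENTS.index(task)]
            else:
                raise ParameterError("target columns do not match the model's tasks")
            r, rmse = regression_metrics(y_true, pred[:, j])
            rows[task][f"r_{suffix}"] = r
            rows[task][f"RMSE{suffix.upper()}"] = rmse
    records = [{"attribute": task, **vals} for task, vals in rows.items()]
    return pd.DataFrame(records)


def build_metrics_table(
    models: dict[str, FittedModel], splits: dict,
    camera: str = "", condition: str = "",
) -> pd.DataFrame:
    """Stack per-model metrics into the standard results-table layout.

    One row per (model, attribute); a multi-task model contributes its four
    rows from a single fit. Rows are keyed by camera, condition, attribute
    and model name.
    """
    frames = []
    for name, model in models.items():
        frame = evaluate_model(model, splits)
        frame.insert(0, "model", name)
        frame.insert(0, "condition", condition)
        frame.insert(0, "camera", camera)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def plot_linear_fits(model: FittedModel, splits: dict, task: str, path) -> None:
    """Predicted-vs-actual scatter with one fitted line per dataset split."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    j = model.tasks.index(task)
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"train": "tab:blue", "val": "tab:orange", "test": "tab:green"}
    for split_name, (X, Y) in splits.items():
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        y = Y[:, PIGMENTS.index(task)] if Y.shape[1] == len(PIGMENTS) else Y[:, j]
        yhat = model.predict(X)[:, j]
        slope, intercept = linear_fit(y, yhat)
        ax.scatter(y, yhat, s=12, alpha=0.6, color=colors.get(split_name))
        xs = np.linspace(y.min(), y.max(), 10)
        ax.plot(xs, slope * xs + intercept, color=colors.get(split_name),
                label=f"{split_name}: y={slope:.2f}x+{intercept:.2f}")
    ax.set_xlabel(f"actual {task} (mg/g)")
    ax.set_ylabel(f"predicted {task} (mg/g)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Grad-CAM++ wavelength importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceMap:
    """Per-wavelength non-negative weights, max-normalized to [0, 1]."""

    weights: np.ndarray
    wavelengths: np.ndarray
    task: str
    model_desc: str = ""
    all_zero: bool = False


def gradcam_pp_1d(
    model: FittedModel, X_batch, task_index: int = 0,
    grid: WavelengthGrid | None = None,
) -> ImportanceMap:
    """1-D Grad-CAM++ importance of each retained wavelength for one task.

    The scalar score is the selected task's regression output. Gradients of
    the score with respect to the last convolutional layer's activations A
    are combined with the second-order weighting

        alpha = g² / (2 g² + Σ_l A·g³),   w_c = Σ_l alpha · relu(g),

    and the map is relu(Σ_c w_c · A_c), averaged over the batch, linearly
    interpolated back to the input band count and max-normalized. A model
    whose selected output is constant yields an all-zero map with a warning.
    """
    if model.family != "cnn":
        raise ParameterError(
            f"Grad-CAM++ supports CNN models only, got family {model.family!r}"
        )
    X = np.asarray(X_batch, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_bands:
        raise ParameterError(f"expected (n, {model.n_bands}) spectra, got {X.shape}")
    if not 0 <= task_index < model.out_width:
        raise ParameterError(f"task_index {task_index} out of range for {model.out_width} outputs")
    net = model.predictor
    conv_idx = model.extras["last_conv"]
    Z = ((X - model.x_mean) / model.x_std)[:, None, :]
    out = net.forward(Z, train=False)
    activations = net.activation(conv_idx)  # (n, C, L)
    one_hot = np.zeros_like(out)
    one_hot[:, task_index] = 1.0
    grads = net.backward(one_hot, stop_at=conv_idx + 1)  # d score / d A

    eps = 1e-12
    g2 = grads**2
    g3 = g2 * grads
    denom = 2.0 * g2 + (activations.sum(axis=2, keepdims=True)) * g3
    alpha = np.where(np.abs(denom) > eps, g2 / np.where(np.abs(denom) > eps, denom, 1.0), 0.0)
    channel_w = (alpha * np.maximum(grads, 0.0)).sum(axis=2)  # (n, C)
    cam = np.maximum((channel_w[:, :, None] * activations).sum(axis=1), 0.0)  # (n, L)
    cam = cam.mean(axis=0)

    # each conv position summarizes `stride` input bands; map to their centers
    stride = max(model.n_bands // cam.size, 1)
    positions = np.arange(cam.size) * stride + (stride - 1) / 2.0
    full = np.interp(np.arange(model.n_bands), positions, cam)
    peak = full.max()
    all_zero = peak <= 0
    if all_zero:
        warnings.warn(
            "Grad-CAM++ produced an all-zero importance map (constant output?)",
            stacklevel=2,
        )
    else:
        full = full / peak
    wavelengths = grid.values if grid is not None else np.arange(model.n_bands, dtype=float)
    if wavelengths.size != model.n_bands:
        raise ParameterError("grid length must equal the model's band count")
    task = model.tasks[task_index]
    return ImportanceMap(full, np.asarray(wavelengths, float), task,
                         model_desc=f"{model.family}/{model.task_mode}", all_zero=all_zero)


@dataclass
class PeakValleyReport:
    """Local extrema of one importance map, in nm."""

    peak_wavelengths: np.ndarray
    peak_weights: np.ndarray
    valley_wavelengths: np.ndarray
    valley_weights: np.ndarray
    global_peak: float | None
    global_valley: float | None

    def as_dict(self) -> dict:
        return {
            "peaks": [
                {"wavelength": float(w), "weight": float(v)}
                for w, v in zip(self.peak_wavelengths, self.peak_weights)
            ],
            "valleys": [
                {"wavelength": float(w), "weight": float(v)}
                for w, v in zip(self.valley_wavelengths, self.valley_weights)
            ],
            "global_peak": self.global_peak,
            "global_valley": self.global_valley,
        }


def peaks_valleys(imap: ImportanceMap, neighborhood: int = 5) -> PeakValleyReport:
    """Local maxima/minima of the map under a band neighborhood.

    A band is a peak (valley) if it strictly exceeds (falls below) every
    band within ``neighborhood`` bands on both sides. A constant map yields
    no extrema. The global extrema among the reported peaks/valleys are
    flagged separately.
    """
    if neighborhood < 1:
        raise ParameterError("neighborhood must be >= 1 band")
    weights = np.asarray(imap.weights, dtype=float)
    if weights.size < 3:
        raise ParameterError("importance map must have at least 3 bands")
    peak_idx = argrelextrema(weights, np.greater, order=neighborhood)[0]
    valley_idx = argrelextrema(weights, np.less, order=neighborhood)[0]
    wl = imap.wavelengths
    global_peak = float(wl[peak_idx[np.argmax(weights[peak_idx])]]) if peak_idx.size else None
    global_valley = float(wl[valley_idx[np.argmin(weights[valley_idx])]]) if valley_idx.size else None
    return PeakValleyReport(
        wl[peak_idx], weights[peak_idx], wl[valley_idx], weights[valley_idx],
        global_peak, global_valley,
    )
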