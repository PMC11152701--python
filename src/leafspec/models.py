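"""Single- and multi-task pigment regressors.

Six families share one ``FittedModel`` contract:

* STPLSR / MTPLSR — PLS1 per pigment vs PLS2 on the 4-column target block,
  latent-variable count chosen by grid search on validation RMSE;
* STBPNN / MTBPNN — one-hidden-layer feed-forward nets trained by
  backpropagation on (weighted) mean squared error;
* STCNN / MTCNN — 1-D convolutional nets (two conv blocks + two dense
  layers; the NIR variant carries one conv layer in its second block, the
  small NIR variant a single block) with hard parameter sharing in the
  multi-task case: one shared trunk, one 4-wide output layer.

Multi-task training uses the variance-balanced loss: each task's MSE is
scaled by w_i = 0.25 / Var(y_i) computed on the training targets, so
high-variance (large-magnitude) pigments do not dominate the shared
gradients, and the loss is the mean of the four weighted task MSEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from . import nnet
from .containers import PIGMENTS, ParameterError

SINGLE = "single"
MULTI = "multi"

CNN_VARIANTS = ("vnir", "nir", "nir_small")


# ---------------------------------------------------------------------------
# Variance-based task weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskWeightVector:
    """Loss weights satisfying w_i × Var(y_i) = 0.25 for every task."""

    w: np.ndarray
    var: np.ndarray
    tasks: tuple = PIGMENTS


def compute_task_weights(Y_train, tasks: tuple = PIGMENTS) -> TaskWeightVector:
    """w_i = 0.25 / Var(y_i) from the training targets (sample variance).

    Larger-variance tasks receive smaller weights so each task contributes
    comparably to the shared loss. Zero-variance columns are rejected.
    """
    Y = np.asarray(Y_train, dtype=float)
    if Y.ndim != 2:
        raise ParameterError("training targets must be a 2-D array")
    var = Y.var(axis=0, ddof=1)
    if np.any(var <= 0):
        bad = int(np.argmin(var))
        raise ParameterError(f"task {bad} has non-positive target variance; cannot weight")
    return TaskWeightVector(w=0.25 / var, var=var, tasks=tuple(tasks))


def weighted_mt_loss(pred, true, weights: TaskWeightVector) -> float:
    """Mean over tasks of w_i × MSE_i. Zero iff pred equals true."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ParameterError(f"prediction shape {pred.shape} != target shape {true.shape}")
    mse = ((pred - true) ** 2).mean(axis=0)
    return float(np.mean(weights.w * mse))


def _loss_and_grad(pred: np.ndarray, true: np.ndarray, weights: TaskWeightVector | None):
    """(weighted) MSE loss and its gradient wrt predictions."""
    diff = pred - true
    n, k = pred.shape
    if weights is None:
        return float((diff**2).mean()), 2.0 * diff / (n * k)
    mse = (diff**2).mean(axis=0)
    loss = float(np.mean(weights.w * mse))
    return loss, (2.0 / (n * k)) * weights.w[None, :] * diff


# ---------------------------------------------------------------------------
# Fitted-model contract
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained predictor with a uniform predict() contract.

    Single-task models predict one column, multi-task models all four
    pigments in one forward pass.
    """

    family: str  # pls | bpnn | cnn
    task_mode: str  # single | multi
    tasks: tuple
    n_bands: int
    predictor: object
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    weights: TaskWeightVector | None = None
    y_offset: np.ndarray | None = None
    y_scale: np.ndarray | None = None
    training_log: dict = field(default_factory=dict)
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def out_width(self) -> int:
        return len(self.tasks)

    def predict(self, X) -> np.ndarray:
        """Predict pigment contents; returns an (n, out_width) array."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_bands:
            raise ParameterError(
                f"expected (n, {self.n_bands}) spectra, got shape {X.shape}"
            )
        if self.family == "pls":
            pred = self.predictor.predict(X)
            return pred.reshape(X.shape[0], self.out_width)
        Z = (X - self.x_mean) / self.x_std
        if self.family == "cnn":
            Z = Z[:, None, :]  # (n, 1, bands)
        pred = self.predictor.forward(Z, train=False).reshape(X.shape[0], self.out_width)
        return pred * self.y_scale + self.y_offset


# ---------------------------------------------------------------------------
# PLS1 / PLS2 with validation grid search
# ---------------------------------------------------------------------------

def fit_pls(
    X_train, Y_train, X_val, Y_val,
    task_mode: str = SINGLE,
    component_grid=range(1, 16),
    tasks: tuple | None = None,
) -> FittedModel:
    """Fit PLS with the latent-variable count chosen on the validation set.

    Single-task (PLS1): Y has one column. Multi-task (PLS2): the 4-column
    target block is fitted jointly and the grid value minimizing the mean
    validation RMSE over tasks wins; ties go to the smaller count. Centering
    only — the spectra are not variance-scaled.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float).T).T
    X_val = np.asarray(X_val, dtype=float)
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float).T).T
    grid = sorted(set(int(k) for k in component_grid))
    if not grid:
        raise ParameterError("component grid is empty")
    max_rank = min(X_train.shape[0] - 1, X_train.shape[1])
    if grid[0] < 1 or grid[-1] > max_rank:
        raise ParameterError(
            f"component grid must lie within [1, {max_rank}] for this training set"
        )
    expected_width = 1 if task_mode == SINGLE else Y_train.shape[1]
    if task_mode == SINGLE and Y_train.shape[1] != 1:
        raise ParameterError("single-task PLS expects a one-column target")

    best = None
    log = {"grid": grid, "val_rmse": []}
    for k in grid:
        model = PLSRegression(n_components=k, scale=False)
        model.fit(X_train, Y_train)
        pred = model.predict(X_val).reshape(Y_val.shape)
        rmse_per_task = np.sqrt(((pred - Y_val) ** 2).mean(axis=0))
        score = float(rmse_per_task.mean())
        log["val_rmse"].append(score)
        if best is None or score < best[0] - 1e-15:
            best = (score, k, model)
    _, chosen, model = best
    log["chosen_components"] = chosen
    if tasks is None:
        tasks = PIGMENTS if expected_width == 4 else ("target",)
    return FittedModel(
        family="pls", task_mode=task_mode, tasks=tuple(tasks),
        n_bands=X_train.shape[1], predictor=model,
        training_log=log, extras={"n_components": chosen},
    )


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters shared by the BPNN and CNN trainers.

    Conventional defaults for ~100-sample 1-D spectra; all overridable.
    """

    lr: float = 1e-3
    epochs: int = 800
    patience: int = 100
    batch_size: int = 16
    hidden: int = 64  # dense head width (CNN) / hidden width (BPNN: 32)
    kernels: tuple = (7, 5)
    channels: tuple = (16, 32)
    pool: int = 2


def _zero_init_head(net: nnet.Sequential) -> nnet.Sequential:
    """Zero the output layer so training starts at the target mean.

    Targets are centered before training, so a zero output head makes the
    initial prediction exactly the training mean; the head then grows only
    the structure the data supports, which also makes the degenerate
    constant-target case exact from step one.
    """
    head = net.layers[-1]
    head.W[...] = 0.0
    head.b[...] = 0.0
    return net


def build_bpnn(n_bands: int, out_width: int, hidden: int, rng) -> nnet.Sequential:
    """Input → one hidden layer (ReLU) → output (zero-initialized)."""
    return _zero_init_head(nnet.Sequential([
        nnet.Dense(n_bands, hidden, rng),
        nnet.ReLU(),
        nnet.Dense(hidden, out_width, rng),
    ]))


def build_cnn(
    variant: str, n_bands: int, out_width: int,
    config: NetConfig | None = None, rng=None,
) -> nnet.Sequential:
    """Assemble one of the three 1-D CNN variants.

    vnir: two conv blocks, the second with two conv layers (3 conv total).
    nir: two conv blocks with one conv layer each (2 conv total).
    nir_small: a single conv block (1 conv), used for the packaged-Car NIR
    task. Every block is conv → batch-norm → ReLU → max-pool; the head is
    two fully connected layers.
    """
    if variant not in CNN_VARIANTS:
        raise ParameterError(f"unknown CNN variant {variant!r}; expected one of {CNN_VARIANTS}")
    config = config or NetConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    k1, k2 = config.kernels
    c1, c2 = config.channels
    n_pools = 1 if variant == "nir_small" else 2
    min_bands = config.pool**n_pools
    if n_bands < min_bands:
        raise ParameterError(
            f"{variant} needs at least {min_bands} bands for its pooling chain, got {n_bands}"
        )
    layers: list[nnet.Layer] = [
        nnet.Conv1d(1, c1, k1, rng),
        nnet.BatchNorm1d(c1),
        nnet.ReLU(),
        nnet.MaxPool1d(config.pool),
    ]
    length = n_bands // config.pool
    out_channels = c1
    if variant in ("vnir", "nir"):
        layers += [nnet.Conv1d(c1, c2, k2, rng), nnet.BatchNorm1d(c2), nnet.ReLU()]
        if variant == "vnir":
            layers += [nnet.Conv1d(c2, c2, k2, rng), nnet.BatchNorm1d(c2), nnet.ReLU()]
        layers.append(nnet.MaxPool1d(config.pool))
        length //= config.pool
        out_channels = c2
    last_conv = max(i for i, l in enumerate(layers) if isinstance(l, nnet.Conv1d))
    layers += [
        nnet.Flatten(),
        nnet.Dense(out_channels * length, config.hidden, rng),
        nnet.ReLU(),
        nnet.Dense(config.hidden, out_width, rng),
    ]
    net = _zero_init_head(nnet.Sequential(layers))
    net.last_conv_index = last_conv  # consumed by the Grad-CAM++ explainer
    return net


def count_conv_layers(net: nnet.Sequential) -> int:
    return sum(isinstance(l, nnet.Conv1d) for l in net.layers)


# ---------------------------------------------------------------------------
# Shared gradient trainer
# ---------------------------------------------------------------------------

def _target_scaling(Y: np.ndarray, task_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-task centering; single-task targets are also scaled to unit SD.

    Multi-task targets keep their raw scale: the variance-balanced loss
    w_i = 0.25/Var(y_i) already equalizes per-task magnitudes (it equals
    0.25 x the MSE of the standardized target), so scaling twice would
    distort the weighting contract.
    """
    offset = Y.mean(axis=0)
    if task_mode == SINGLE:
        scale = Y.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
    else:
        scale = np.ones(Y.shape[1])
    return offset, scale


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each band; scale all bands by one pooled SD.

    A single global scale preserves the relative amplitude of spectral
    features. Per-band autoscaling would blow flat plateau bands (nearly
    pure sensor noise) up to unit variance, which both degrades
    generalization and spreads saliency over uninformative bands.
    """
    mean = X.mean(axis=0)
    scale = max(float(X.std(axis=0).mean()), 1e-8)
    return mean, np.full(X.shape[1], scale)


def _train_network(
    net: nnet.Sequential,
    X_train: np.ndarray, Y_train: np.ndarray,
    X_val: np.ndarray, Y_val: np.ndarray,
    weights: TaskWeightVector | None,
    config: NetConfig,
    seed: int,
    is_cnn: bool,
) -> dict:
    """Adam training with best-validation-epoch snapshotting.

    Returns the training log; the network is left holding the parameters of
    the epoch with the lowest validation loss. Bit-reproducible for a fixed
    seed. Raises on non-finite or exploding loss.
    """
    rng = np.random.default_rng(seed)
    optimizer = nnet.Adam(net.params(), lr=config.lr)
    n = X_train.shape[0]

    def _prep(X):
        return X[:, None, :] if is_cnn else X

    log = {"train_loss": [], "val_loss": []}
    best_state = net.state_dict()
    best_val = np.inf
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = net.forward(_prep(X_train[idx]), train=True)
            loss, grad = _loss_and_grad(pred, Y_train[idx], weights)
            if not np.isfinite(loss) or loss > 1e6:
                raise ParameterError(
                    f"training diverged at epoch {epoch} (loss={loss:.3g}); "
                    "try a smaller learning rate"
                )
            net.backward(grad)
            optimizer.step(net.grads())
            epoch_loss += loss * len(idx)
        log["train_loss"].append(epoch_loss / n)
        val_pred = net.forward(_prep(X_val), train=False)
        val_loss, _ = _loss_and_grad(val_pred, Y_val, weights)
        log["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    net.load_state_dict(best_state)
    log["best_val_loss"] = best_val if np.isfinite(best_val) else None
    return log


def fit_bpnn(
    X_train, Y_train, X_val, Y_val,
    task_mode: str = SINGLE,
    config: NetConfig | None = None,
    seed: int = 0,
    tasks: tuple | None = None,
) -> FittedModel:
    """Train a one-hidden-layer backpropagation network (default width 32).

    Multi-task mode trains the 4-wide output with the variance-balanced
    weighted MSE; single-task uses plain MSE. Spectra are centered per band
    and globally scaled with training-set statistics. The default budget is longer than
    the CNN's because BPNN epochs are cheap and the small net converges
    slowly on low-variance targets.
    """
    config = config or NetConfig(hidden=32, epochs=2000, patience=200)
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float).T).T
    X_val = np.asarray(X_val, dtype=float)
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float).T).T
    weights = compute_task_weights(Y_train) if task_mode == MULTI else None
    mean, std = _standardize_fit(X_train)
    y_off, y_scale = _target_scaling(Y_train, task_mode)
    rng = np.random.default_rng(seed)
    net = build_bpnn(X_train.shape[1], Y_train.shape[1], config.hidden, rng)
    log = _train_network(
        net, (X_train - mean) / std, (Y_train - y_off) / y_scale,
        (X_val - mean) / std, (Y_val - y_off) / y_scale,
        weights, config, seed + 1, is_cnn=False,
    )
    if tasks is None:
        tasks = PIGMENTS if Y_train.shape[1] == 4 else ("target",)
    return FittedModel(
        family="bpnn", task_mode=task_mode, tasks=tuple(tasks),
        n_bands=X_train.shape[1], predictor=net,
        x_mean=mean, x_std=std, weights=weights,
        y_offset=y_off, y_scale=y_scale,
        training_log=log, seed=seed,
    )


def train_cnn(
    X_train, Y_train, X_val, Y_val,
    variant: str = "vnir",
    task_mode: str = SINGLE,
    config: NetConfig | None = None,
    seed: int = 0,
    tasks: tuple | None = None,
) -> FittedModel:
    """Build and train one CNN variant; returns the best-validation model.

    Multi-task mode shares the whole trunk across the four pigments (hard
    parameter sharing) and applies the variance-balanced weighted MSE.
    """
    config = config or NetConfig()
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float).T).T
    X_val = np.asarray(X_val, dtype=float)
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float).T).T
    weights = compute_task_weights(Y_train) if task_mode == MULTI else None
    mean, std = _standardize_fit(X_train)
    y_off, y_scale = _target_scaling(Y_train, task_mode)
    rng = np.random.default_rng(seed)
    net = build_cnn(variant, X_train.shape[1], Y_train.shape[1], config, rng)
    log = _train_network(
        net, (X_train - mean) / std, (Y_train - y_off) / y_scale,
        (X_val - mean) / std, (Y_val - y_off) / y_scale,
        weights, config, seed + 1, is_cnn=True,
    )
    if tasks is None:
        tasks = PIGMENTS if Y_train.shape[1] == 4 else ("target",)
    return FittedModel(
        family="cnn", task_mode=task_mode, tasks=tuple(tasks),
        n_bands=X_train.shape[1], predictor=net,
        x_mean=mean, x_std=std, weights=weights,
        y_offset=y_off, y_scale=y_scale,
        training_log=log, seed=seed,
        extras={"variant": variant, "last_conv": net.last_conv_index},
    )
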