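"""Shared fixtures: synthetic datasets and a trained model suite.

Everything is generated programmatically with fixed seeds; the expensive
model fits are session-scoped so several test modules can share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import leafspec as ls
from leafspec import dataprep, models
from leafspec.containers import PIGMENTS

# sklearn's PLS emits benign deflation warnings on exactly-linear targets
warnings.filterwarnings("ignore", message="y residual is constant")


@pytest.fixture(scope="session")
def linear_fixture():
    """Noise-free VNIR dataset: 150 designed samples, outlier-screened,
    split 3:1:1. Reflectance is exactly linear in the pigment contents, so
    every regressor family should recover the targets."""
    design = ls.packaged_design(seed=7)
    sm, panels = ls.simulate_spectra(design, camera="vnir", noise_sigma=0.0)
    sm = ls.trim_wavelengths(sm)
    X = sm.spectra
    Y = panels[list(PIGMENTS)].to_numpy(float)
    report = dataprep.screen_outliers(X, Y)
    idx = report.retained_indices
    split = dataprep.split_dataset(len(idx), seed=7)
    Xr, Yr = X[idx], Y[idx]
    splits = {
        name: (Xr[getattr(split, name)], Yr[getattr(split, name)])
        for name in ("train", "val", "test")
    }
    return {"grid": sm.grid, "splits": splits, "n_retained": len(idx), "report": report}


@pytest.fixture(scope="session")
def trained_suite(linear_fixture):
    """All six model families fitted once on the linear fixture."""
    sp = linear_fixture["splits"]
    X_train, Y_train = sp["train"]
    X_val, Y_val = sp["val"]
    suite: dict[str, models.FittedModel] = {}
    suite["MTPLSR"] = models.fit_pls(
        X_train, Y_train, X_val, Y_val, task_mode=models.MULTI, component_grid=range(1, 13)
    )
    suite["MTBPNN"] = models.fit_bpnn(
        X_train, Y_train, X_val, Y_val, task_mode=models.MULTI, seed=7
    )
    suite["MTCNN"] = models.train_cnn(
        X_train, Y_train, X_val, Y_val, variant="vnir", task_mode=models.MULTI, seed=7
    )
    for j, pigment in enumerate(PIGMENTS):
        args = (X_train, Y_train[:, [j]], X_val, Y_val[:, [j]])
        suite[f"STPLSR_{pigment}"] = models.fit_pls(
            *args, task_mode=models.SINGLE, component_grid=range(1, 13), tasks=(pigment,)
        )
        suite[f"STBPNN_{pigment}"] = models.fit_bpnn(
            *args, task_mode=models.SINGLE, seed=7, tasks=(pigment,)
        )
        suite[f"STCNN_{pigment}"] = models.train_cnn(
            *args, variant="vnir", task_mode=models.SINGLE, seed=7, tasks=(pigment,)
        )
    return suite


@pytest.fixture()
def ellipse_cube():
    """A 40×40 reflectance cube with a known 500-pixel bright ellipse."""
    from leafspec.containers import ReflectanceCube, WavelengthGrid

    grid = WavelengthGrid(np.linspace(400, 1000, 10), "vnir")
    rows = cols = 40
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = ((rr - 20) / 14.0) ** 2 + ((cc - 20) / 11.45) ** 2 <= 1.0
    reflectance = np.full((rows, cols, 10), 0.05)
    reflectance[mask] = 0.6
    return ReflectanceCube(reflectance, grid), mask
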