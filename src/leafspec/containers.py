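"""Core data containers shared across the pipeline.

The common currency between stages is :class:`SpectraMatrix` — one mean ROI
reflectance spectrum per sample plus storage metadata — together with the
:class:`WavelengthGrid` describing the camera's band centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VNIR = "vnir"
NIR = "nir"

#: Full sensor ranges of the two emulated line-scan cameras (nm).
CAMERA_RANGES: dict[str, tuple[float, float]] = {
    VNIR: (400.0, 1000.0),
    NIR: (900.0, 1700.0),
}

#: Retained wavelength windows after head/tail noise trimming (nm, inclusive).
TRIM_RANGES: dict[str, tuple[float, float]] = {
    VNIR: (475.0, 980.0),
    NIR: (970.0, 1670.0),
}

PIGMENTS = ("chla", "chlb", "chlt", "car")


class LeafspecError(Exception):
    """Base class for package errors."""


class ParameterError(LeafspecError, ValueError):
    """A configuration value violates its contract."""


class SegmentationError(LeafspecError):
    """Leaf/background segmentation produced an empty mask."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-centre wavelengths (nm) of one camera."""

    values: np.ndarray
    camera: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.camera not in CAMERA_RANGES:
            raise ParameterError(f"unknown camera {self.camera!r}; expected one of {sorted(CAMERA_RANGES)}")
        if values.ndim != 1 or values.size < 2:
            raise ParameterError("wavelength grid needs at least 2 bands")
        if not np.all(np.diff(values) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        lo, hi = CAMERA_RANGES[self.camera]
        if values[0] < lo or values[-1] > hi:
            raise ParameterError(
                f"{self.camera} wavelengths must lie within [{lo}, {hi}] nm; got [{values[0]}, {values[-1]}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def nearest_band(self, wavelength: float) -> int:
        """Index of the band whose centre is closest to ``wavelength`` (nm)."""
        return int(np.argmin(np.abs(self.values - wavelength)))


def default_grid(camera: str, n_bands: int = 224) -> WavelengthGrid:
    """Evenly spaced band centres spanning the camera's full sensor range."""
    lo, hi = CAMERA_RANGES[camera]
    return WavelengthGrid(np.linspace(lo, hi, n_bands), camera)


@dataclass
class SpectraMatrix:
    """n samples × b bands reflectance table with per-sample metadata.

    ``meta`` carries at least ``sample_id``, ``condition`` and ``hours``
    columns, one row per spectrum, aligned positionally with ``spectra``.
    """

    spectra: np.ndarray
    grid: WavelengthGrid
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ParameterError("spectra must be a 2-D (samples × bands) array")
        if self.spectra.shape[1] != len(self.grid):
            raise ParameterError(
                f"spectra have {self.spectra.shape[1]} bands but the grid has {len(self.grid)}"
            )
        if self.spectra.shape[0] < 1:
            raise ParameterError("need at least one spectrum")
        if not np.all(np.isfinite(self.spectra)):
            raise ParameterError("spectra contain non-finite values")
        if len(self.meta) != self.spectra.shape[0]:
            raise ParameterError("metadata rows must match spectra rows")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    def select(self, indices) -> "SpectraMatrix":
        idx = np.asarray(indices)
        return SpectraMatrix(self.spectra[idx], self.grid, self.meta.iloc[idx])

    def to_frame(self) -> pd.DataFrame:
        """Flat table: sample_id, condition, hours, then one column per nm."""
        wl_cols = {f"{w:.4f}": self.spectra[:, j] for j, w in enumerate(self.grid.values)}
        return pd.concat([self.meta.reset_index(drop=True), pd.DataFrame(wl_cols)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, camera: str) -> "SpectraMatrix":
        frame = pd.read_csv(path)
        wl_cols = [c for c in frame.columns if _is_number(c)]
        meta_cols = [c for c in frame.columns if c not in wl_cols]
        grid = WavelengthGrid(np.array([float(c) for c in wl_cols]), camera)
        return cls(frame[wl_cols].to_numpy(float), grid, frame[meta_cols])


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


@dataclass
class RawCube:
    """Raw camera counts S: rows × cols × bands, non-negative."""

    counts: np.ndarray
    grid: WavelengthGrid
    sample_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ParameterError("cube counts must be rows × cols × bands")
        if self.counts.shape[2] != len(self.grid):
            raise ParameterError("cube band dimension must match the wavelength grid")
        if np.any(self.counts < 0):
            raise ParameterError("raw counts must be non-negative")


@dataclass
class ReferenceFrames:
    """Dark (B) and white (W) reference frames paired with a raw cube."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ParameterError("dark and white frames must share a shape")
        if not np.all(self.white > self.dark):
            raise ParameterError("white reference must exceed the dark reference everywhere")


@dataclass
class ReflectanceCube:
    """Calibrated reflectance I = (S − B)/(W − B)."""

    reflectance: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 3:
            raise ParameterError("reflectance must be rows × cols × bands")
        if not np.all(np.isfinite(self.reflectance)):
            raise ParameterError("reflectance contains non-finite values")


def save_cube(directory, raw: RawCube, refs: ReferenceFrames) -> Path:
    """Persist one cube as .npy arrays plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / raw.sample_id
    np.save(f"{stem}.counts.npy", raw.counts)
    np.save(f"{stem}.dark.npy", refs.dark)
    np.save(f"{stem}.white.npy", refs.white)
    sidecar = {
        "sample_id": raw.sample_id,
        "camera": raw.grid.camera,
        "wavelengths": raw.grid.values.tolist(),
        "metadata": raw.metadata,
    }
    with open(f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh)
    return Path(f"{stem}.json")


def load_cube(sidecar_path) -> tuple[RawCube, ReferenceFrames]:
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    stem = sidecar_path.with_suffix("")
    grid = WavelengthGrid(np.array(sidecar["wavelengths"]), sidecar["camera"])
    raw = RawCube(
        np.load(f"{stem}.counts.npy"), grid, sidecar["sample_id"], sidecar.get("metadata", {})
    )
    refs = ReferenceFrames(np.load(f"{stem}.dark.npy"), np.load(f"{stem}.white.npy"))
    return raw, refs
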