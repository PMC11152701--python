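"""Synthetic leaf hypercube and pigment-panel generator.

Emulates the storage study this package is designed around: spinach-like
leaves stored unpackaged (0/3/6/9 h) or wrapped in cling film (0/3/6/9/24 h),
imaged by two line-scan cameras (VNIR 400–1000 nm, NIR 900–1700 nm) over a
dark background, with dark/white reference frames for black-white correction.

The forward model is deliberately simple and fully config-pinned:

* pigment contents decline exponentially with storage time, faster for
  unpackaged leaves, with lognormal leaf-to-leaf variation;
* reflectance is a smooth leaf-like baseline minus Gaussian absorption bands
  whose depth is linear in the absorber (Chla ≈ 675 nm, Chlb ≈ 650 nm,
  Car ≈ 490 nm in the VNIR; leaf-water bands ≈ 1200/1450 nm in the NIR,
  scaled by a moisture level that also decays during storage);
* raw counts are dark + (white − dark) × reflectance + additive Gaussian
  sensor noise, leaf pixels forming an ellipse on a darker background.

Inverting the calibration with zero noise recovers the generating spectrum
exactly, which is the oracle every downstream stage is tested against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    NIR,
    PIGMENTS,
    VNIR,
    ParameterError,
    RawCube,
    ReferenceFrames,
    SpectraMatrix,
    WavelengthGrid,
    default_grid,
)

logger = logging.getLogger(__name__)

UNPACKAGED = "unpackaged"
PACKAGED = "packaged"

#: Storage periods (hours) used for each condition in the emulated study.
DEFAULT_PERIODS = {UNPACKAGED: (0, 3, 6, 9), PACKAGED: (0, 3, 6, 9, 24)}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan for one storage condition.

    Unpackaged default: 2 days × 4 periods × 15 leaves = 120 samples per
    camera. Packaged default: 1 day × 5 periods × 30 leaves = 150 samples.
    """

    condition: str = UNPACKAGED
    periods: tuple = DEFAULT_PERIODS[UNPACKAGED]
    leaves_per_period_per_day: int = 15
    days: int = 2
    cameras: tuple = (VNIR, NIR)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in (UNPACKAGED, PACKAGED):
            raise ParameterError(f"condition must be {UNPACKAGED!r} or {PACKAGED!r}")
        periods = tuple(float(p) for p in self.periods)
        if not periods or not np.all(np.diff(periods) > 0):
            raise ParameterError("periods must be non-empty and strictly increasing")
        object.__setattr__(self, "periods", periods)
        if self.leaves_per_period_per_day < 1:
            raise ParameterError("leaves_per_period_per_day must be >= 1")
        if self.days < 1:
            raise ParameterError("days must be >= 1")

    @property
    def n_samples(self) -> int:
        """Total samples per camera."""
        return self.days * len(self.periods) * self.leaves_per_period_per_day


def unpackaged_design(seed: int = 0) -> StudyDesign:
    return StudyDesign(UNPACKAGED, DEFAULT_PERIODS[UNPACKAGED], 15, 2, (VNIR, NIR), seed)


def packaged_design(seed: int = 0) -> StudyDesign:
    return StudyDesign(PACKAGED, DEFAULT_PERIODS[PACKAGED], 30, 1, (VNIR, NIR), seed)


@dataclass(frozen=True)
class DecayConfig:
    """First-order pigment decline during storage.

    Mean content at hour t is ``baseline × exp(−k·t)``; individual leaves
    scatter around the mean with a lognormal factor of log-sigma ``sigma``.
    Packaging slows the decline, so k(unpackaged) ≥ k(packaged) per pigment.
    Baselines are fresh-leaf contents in mg per g fresh weight.
    """

    baselines: dict = field(
        default_factory=lambda: {"chla": 1.82, "chlb": 0.72, "car": 0.38}
    )
    rates: dict = field(
        default_factory=lambda: {
            UNPACKAGED: {"chla": 0.045, "chlb": 0.040, "car": 0.030},
            PACKAGED: {"chla": 0.012, "chlb": 0.010, "car": 0.008},
        }
    )
    sigma: float = 0.12  # lognormal leaf-to-leaf scatter
    moisture_rates: dict = field(
        default_factory=lambda: {UNPACKAGED: 0.030, PACKAGED: 0.005}
    )

    def __post_init__(self) -> None:
        for name, value in self.baselines.items():
            if value <= 0:
                raise ParameterError(f"baseline for {name} must be > 0, got {value}")
        for cond, rates in self.rates.items():
            for name, k in rates.items():
                if k < 0:
                    raise ParameterError(f"decay rate {cond}/{name} must be >= 0, got {k}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")

    def mean_content(self, pigment: str, condition: str, hours: float) -> float:
        return self.baselines[pigment] * np.exp(-self.rates[condition][pigment] * hours)

    def moisture(self, condition: str, hours: float) -> float:
        """Relative leaf water level in (0, 1]; 1 = fresh."""
        return float(np.exp(-self.moisture_rates[condition] * hours))


def generate_pigment_panels(
    design: StudyDesign, decay: DecayConfig | None = None
) -> pd.DataFrame:
    """One pigment panel (chla/chlb/chlt/car, mg/g) per designed sample.

    Returns a DataFrame with metadata columns (sample_id, condition, hours,
    day, moisture) followed by the four pigment columns. Chlt is recomputed
    as chla + chlb. Deterministic for a fixed design seed.
    """
    decay = decay or DecayConfig()
    rng = np.random.default_rng(design.seed)
    rows = []
    counter = 0
    for day in range(1, design.days + 1):
        for hours in design.periods:
            for _ in range(design.leaves_per_period_per_day):
                noise = rng.normal(0.0, 1.0, size=3)
                contents = {}
                for j, pigment in enumerate(("chla", "chlb", "car")):
                    mean = decay.mean_content(pigment, design.condition, hours)
                    contents[pigment] = mean * np.exp(decay.sigma * noise[j])
                counter += 1
                rows.append(
                    {
                        "sample_id": f"{design.condition}_d{day}_h{hours:g}_{counter:04d}",
                        "condition": design.condition,
                        "hours": hours,
                        "day": day,
                        "moisture": decay.moisture(design.condition, hours)
                        * np.exp(decay.sigma * 0.5 * rng.normal()),
                        "chla": contents["chla"],
                        "chlb": contents["chlb"],
                        "chlt": contents["chla"] + contents["chlb"],
                        "car": contents["car"],
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian absorption feature: depth × exp(−(λ−center)²/(2 width²)).

    ``depth`` is the band depth (reflectance units) produced by one
    reference unit (``ref``) of the driving quantity: a pigment content in
    mg/g, or the dimensionless moisture level.
    """

    driver: str  # chla | chlb | car | moisture
    center: float  # nm
    width: float  # nm (Gaussian sigma)
    depth: float  # reflectance deficit at ref level
    ref: float = 1.0


@dataclass(frozen=True)
class OpticsConfig:
    """Baseline reflectance curve plus absorption bands for one camera."""

    camera: str = VNIR
    bands: tuple = ()
    # Logistic red-edge baseline: low in the visible, plateau in the NIR.
    base_low: float = 0.32
    base_high: float = 0.80
    edge_center: float = 715.0  # nm
    edge_width: float = 18.0  # nm
    clip: tuple = (0.01, 0.99)

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-(wl - self.edge_center) / self.edge_width))
        return self.base_low + (self.base_high - self.base_low) * rise


def default_optics(camera: str) -> OpticsConfig:
    if camera == VNIR:
        bands = (
            AbsorptionBand("chla", 675.0, 12.0, 0.20, ref=1.82),
            AbsorptionBand("chla", 430.0, 14.0, 0.12, ref=1.82),
            AbsorptionBand("chlb", 650.0, 10.0, 0.18, ref=0.72),
            AbsorptionBand("car", 490.0, 16.0, 0.20, ref=0.38),
        )
        return OpticsConfig(VNIR, bands)
    if camera == NIR:
        bands = (
            AbsorptionBand("moisture", 1200.0, 35.0, 0.16, ref=1.0),
            AbsorptionBand("moisture", 1450.0, 50.0, 0.40, ref=1.0),
        )
        # NIR plateau: nearly flat, gently declining baseline.
        return OpticsConfig(NIR, bands, base_low=0.78, base_high=0.66,
                            edge_center=1300.0, edge_width=250.0)
    raise ParameterError(f"unknown camera {camera!r}")


def pigment_to_reflectance(
    panel,
    grid: WavelengthGrid,
    optics: OpticsConfig | None = None,
    moisture: float = 1.0,
) -> np.ndarray:
    """Forward model: pigment panel (+ moisture level) → reflectance spectrum.

    ``panel`` is any mapping with chla/chlb/car entries (mg/g). Band depth is
    linear in the driving quantity; the result is clipped to the configured
    reflectance range (default [0.01, 0.99]).
    """
    optics = optics or default_optics(grid.camera)
    wl = grid.values
    spectrum = optics.baseline(wl).copy()
    drivers = {"chla": panel["chla"], "chlb": panel["chlb"], "car": panel["car"],
               "moisture": moisture}
    for band in optics.bands:
        if band.center < wl[0] or band.center > wl[-1]:
            logger.warning(
                "absorption band at %.0f nm lies outside the %s grid span; skipped",
                band.center, grid.camera,
            )
            continue
        level = float(drivers[band.driver])
        depth = band.depth * level / band.ref
        spectrum -= depth * np.exp(-((wl - band.center) ** 2) / (2.0 * band.width**2))
    return np.clip(spectrum, optics.clip[0], optics.clip[1])


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and sensor model for rendering one cube."""

    shape: tuple = (48, 48)  # rows, cols
    ellipse_center: tuple = (24.0, 24.0)  # row, col
    ellipse_axes: tuple = (16.0, 11.0)  # semi-axes in pixels
    background_reflectance: float = 0.008  # below the clipped leaf minimum
    dark_offset: float = 100.0  # counts
    white_level: float = 4000.0  # counts at full reflectance
    noise_sigma: float = 2.0  # additive count noise on the scene
    reference_noise_sigma: float = 0.0  # count noise on the reference frames

    def __post_init__(self) -> None:
        cy, cx = self.ellipse_center
        ay, ax = self.ellipse_axes
        rows, cols = self.shape
        if cy - ay < 0 or cy + ay > rows - 1 or cx - ax < 0 or cx + ax > cols - 1:
            raise ParameterError("leaf ellipse must be contained in the image")
        if self.white_level <= self.dark_offset:
            raise ParameterError("white level must exceed the dark offset")

    def leaf_mask(self) -> np.ndarray:
        rows, cols = self.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        cy, cx = self.ellipse_center
        ay, ax = self.ellipse_axes
        return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def render_cube(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    scene: SceneConfig | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    metadata: dict | None = None,
) -> tuple[RawCube, ReferenceFrames]:
    """Render one leaf spectrum into a raw cube plus reference frames.

    counts = dark + (white − dark) × reflectance + N(0, noise_sigma) with the
    leaf ellipse carrying ``spectrum`` and the background a flat dark
    reflectance. With zero noise, black-white correction inverts this exactly.
    """
    scene = scene or SceneConfig()
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (len(grid),):
        raise ParameterError("spectrum length must equal the grid band count")
    if scene.background_reflectance >= spectrum.min():
        raise ParameterError(
            "background reflectance must stay below the leaf's minimum reflectance"
        )
    rng = np.random.default_rng(seed)
    rows, cols = scene.shape
    bands = len(grid)
    dark = np.full((rows, cols, bands), scene.dark_offset)
    white = np.full((rows, cols, bands), scene.white_level)
    if scene.reference_noise_sigma > 0:
        dark = dark + rng.normal(0.0, scene.reference_noise_sigma, dark.shape)
        white = white + rng.normal(0.0, scene.reference_noise_sigma, white.shape)

    reflectance = np.full((rows, cols, bands), scene.background_reflectance)
    mask = scene.leaf_mask()
    reflectance[mask] = spectrum
    counts = dark + (white - dark) * reflectance
    if scene.noise_sigma > 0:
        counts = counts + rng.normal(0.0, scene.noise_sigma, counts.shape)
    counts = np.clip(counts, 0.0, None)
    raw = RawCube(counts, grid, sample_id, metadata or {})
    return raw, ReferenceFrames(dark, white)


def simulate_spectra(
    design: StudyDesign,
    decay: DecayConfig | None = None,
    optics: OpticsConfig | None = None,
    camera: str = VNIR,
    n_bands: int = 224,
    noise_sigma: float = 0.0,
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Fast path: generate mean ROI spectra directly (no imaging step).

    Returns the spectra matrix and the pigment-panel table. ``noise_sigma``
    adds i.i.d. Gaussian reflectance noise emulating residual sensor and
    illumination variation after ROI averaging.
    """
    decay = decay or DecayConfig()
    grid = default_grid(camera, n_bands)
    optics = optics or default_optics(camera)
    panels = generate_pigment_panels(design, decay)
    rng = np.random.default_rng(design.seed + 1)
    spectra = np.stack(
        [
            pigment_to_reflectance(row, grid, optics, moisture=row["moisture"])
            for _, row in panels.iterrows()
        ]
    )
    if noise_sigma > 0:
        spectra = spectra + rng.normal(0.0, noise_sigma, spectra.shape)
    meta = panels[["sample_id", "condition", "hours", "day"]].copy()
    return SpectraMatrix(spectra, grid, meta), panels


def simulate_cubes(
    design: StudyDesign,
    out_dir,
    decay: DecayConfig | None = None,
    camera: str = VNIR,
    n_bands: int = 224,
    scene: SceneConfig | None = None,
) -> pd.DataFrame:
    """Full path: render one cube + reference pair per designed sample.

    Writes cubes into ``out_dir`` and returns the pigment-panel table.
    """
    from .containers import save_cube

    decay = decay or DecayConfig()
    grid = default_grid(camera, n_bands)
    optics = default_optics(camera)
    scene = scene or SceneConfig()
    panels = generate_pigment_panels(design, decay)
    for i, row in panels.iterrows():
        spectrum = pigment_to_reflectance(row, grid, optics, moisture=row["moisture"])
        raw, refs = render_cube(
            spectrum,
            grid,
            scene,
            seed=design.seed + 1000 + i,
            sample_id=row["sample_id"],
            metadata={"condition": row["condition"], "hours": row["hours"], "day": int(row["day"])},
        )
        save_cube(out_dir, raw, refs)
    return panels
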