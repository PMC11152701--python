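"""Raw cube → trimmed mean ROI spectrum.

Stages: black-white correction I = (S − B)/(W − B); leaf/background
binarization on a single NIR-plateau band (Otsu by default); mean-spectrum
extraction over the leaf mask; head/tail wavelength trimming to 475–980 nm
(VNIR) or 970–1670 nm (NIR). No other spectral preprocessing is applied —
the trimmed mean spectra are modelled as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .containers import (
    NIR,
    TRIM_RANGES,
    VNIR,
    LeafspecError,
    ParameterError,
    RawCube,
    ReferenceFrames,
    ReflectanceCube,
    SegmentationError,
    SpectraMatrix,
)

#: Band used for binarization: leaves are bright on the NIR plateau.
SEGMENTATION_BAND_NM = {VNIR: 800.0, NIR: 1100.0}


def calibrate_cube(raw: RawCube, refs: ReferenceFrames) -> ReflectanceCube:
    """Black-white correction: I = (S − B)/(W − B), elementwise.

    Raises if any reference pixel/band has W ≤ B (degenerate calibration),
    naming the first offending position.
    """
    if refs.dark.shape != raw.counts.shape:
        raise ParameterError(
            f"reference shape {refs.dark.shape} does not match cube shape {raw.counts.shape}"
        )
    span = refs.white - refs.dark
    bad = span <= 0
    if np.any(bad):
        idx = tuple(int(v) for v in np.argwhere(bad)[0])
        raise ParameterError(
            f"white reference does not exceed dark at (row, col, band)={idx}: "
            f"W={refs.white[idx]:.3f} <= B={refs.dark[idx]:.3f}"
        )
    reflectance = (raw.counts - refs.dark) / span
    return ReflectanceCube(reflectance, raw.grid)


@dataclass(frozen=True)
class SegmentationConfig:
    """How to binarize the cube into leaf vs background."""

    band_nm: float | None = None  # default: camera-specific plateau band
    threshold: float | None = None  # fixed threshold; None → Otsu
    min_area: int = 50  # pixels; smaller connected components are dropped


def segment_leaf(cube: ReflectanceCube, config: SegmentationConfig | None = None) -> np.ndarray:
    """Binarize one plateau band into a boolean leaf mask.

    Leaf pixels are the brighter class. Connected components smaller than
    ``min_area`` are removed; an empty result raises SegmentationError.
    """
    config = config or SegmentationConfig()
    band_nm = config.band_nm if config.band_nm is not None else SEGMENTATION_BAND_NM[cube.grid.camera]
    image = cube.reflectance[:, :, cube.grid.nearest_band(band_nm)]
    if config.threshold is not None:
        threshold = config.threshold
    else:
        if np.ptp(image) < 1e-12:
            raise SegmentationError("image has no contrast; cannot binarize")
        threshold = threshold_otsu(image)
        # one intermeans refinement: with very tight clusters the histogram
        # ties can park Otsu's threshold at a cluster edge; recentering to
        # the midpoint of the class means is stable for any contrast
        low, high = image[image <= threshold], image[image > threshold]
        if low.size and high.size:
            threshold = 0.5 * (low.mean() + high.mean())
    mask = image > threshold
    if config.min_area > 1:
        # drop connected components with area < min_area
        mask = remove_small_objects(mask, max_size=config.min_area - 1)
    if not mask.any():
        raise SegmentationError(
            f"segmentation produced an empty mask (band {band_nm:.0f} nm, "
            f"threshold {threshold:.4f}, min_area {config.min_area})"
        )
    return mask


def extract_mean_spectrum(cube: ReflectanceCube, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean reflectance over masked pixels, per band."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.reflectance.shape[:2]:
        raise ParameterError("mask shape must match the cube's spatial shape")
    if not mask.any():
        raise ParameterError("mask is empty; no ROI pixels to average")
    return cube.reflectance[mask].mean(axis=0)


def trim_wavelengths(spectra: SpectraMatrix) -> SpectraMatrix:
    """Cut off noisy head/tail bands, keeping the camera's retained window.

    Retains exactly the bands whose wavelength lies inside the closed
    interval [475, 980] nm (VNIR) or [970, 1670] nm (NIR). Idempotent;
    metadata is untouched; no other preprocessing is applied.
    """
    lo, hi = TRIM_RANGES[spectra.grid.camera]
    keep = (spectra.grid.values >= lo) & (spectra.grid.values <= hi)
    if not keep.any():
        raise LeafspecError(
            f"no bands inside the retained window [{lo}, {hi}] nm for {spectra.grid.camera}"
        )
    grid = type(spectra.grid)(spectra.grid.values[keep], spectra.grid.camera)
    return SpectraMatrix(spectra.spectra[:, keep], grid, spectra.meta)


def extract_dataset(
    cubes_dir,
    config: SegmentationConfig | None = None,
    trim: bool = True,
) -> SpectraMatrix:
    """Run calibrate → segment → extract over every cube in a directory.

    Cubes are located by their JSON sidecars (written by the simulator).
    """
    from .containers import load_cube

    sidecars = sorted(Path(cubes_dir).glob("*.json"))
    if not sidecars:
        raise LeafspecError(f"no cube sidecars found in {cubes_dir}")
    spectra, meta_rows, grid = [], [], None
    for sidecar in sidecars:
        raw, refs = load_cube(sidecar)
        cube = calibrate_cube(raw, refs)
        mask = segment_leaf(cube, config)
        spectra.append(extract_mean_spectrum(cube, mask))
        meta_rows.append(
            {
                "sample_id": raw.sample_id,
                "condition": raw.metadata.get("condition", ""),
                "hours": raw.metadata.get("hours", np.nan),
                "day": raw.metadata.get("day", 0),
            }
        )
        grid = cube.grid
    matrix = SpectraMatrix(np.stack(spectra), grid, pd.DataFrame(meta_rows))
    return trim_wavelengths(matrix) if trim else matrix
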