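"""Reference pigment contents from spectrophotometer absorbances.

Pigments are extracted from ~0.1 g of leaf tissue in 10 mL of 95% ethanol
and read at 665, 649 and 470 nm. Concentrations (µg/mL) follow the standard
95%-ethanol equations

    Ca  = 13.95·A665 − 6.88·A649
    Cb  = 24.96·A649 − 7.32·A665
    Car = (1000·A470 − 2.05·Ca − 114.8·Cb) / 245

and contents in mg per g fresh weight are C × V_mL / (1000 × m_g).
Total chlorophyll is defined as Chla + Chlb. The coefficient set is pinned
in :class:`PigmentCoefficients` so an alternative solvent calibration can be
swapped in without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ParameterError


@dataclass(frozen=True)
class PigmentCoefficients:
    """Linear absorbance→concentration coefficients (95% ethanol)."""

    ca_665: float = 13.95
    ca_649: float = -6.88
    cb_649: float = 24.96
    cb_665: float = -7.32
    car_470: float = 1000.0
    car_ca: float = -2.05
    car_cb: float = -114.8
    car_denom: float = 245.0


@dataclass(frozen=True)
class ExtractionContext:
    """Wet-lab extraction arithmetic: sample mass (g) and solvent volume (mL)."""

    sample_mass: float = 0.1
    extract_volume: float = 10.0

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise ParameterError(f"sample mass must be > 0 g, got {self.sample_mass}")
        if self.extract_volume <= 0:
            raise ParameterError(f"extract volume must be > 0 mL, got {self.extract_volume}")


def pigments_from_absorbance(
    a665,
    a649,
    a470,
    ctx: ExtractionContext | None = None,
    coeffs: PigmentCoefficients | None = None,
) -> pd.DataFrame:
    """Absorbance triples → pigment contents (mg per g fresh weight).

    Accepts scalars or equal-length arrays; returns a DataFrame with
    chla/chlb/chlt/car columns. Computed concentrations that come out
    negative (possible for noisy triples) are floored at zero with a warning.
    """
    ctx = ctx or ExtractionContext()
    coeffs = coeffs or PigmentCoefficients()
    a665 = np.atleast_1d(np.asarray(a665, dtype=float))
    a649 = np.atleast_1d(np.asarray(a649, dtype=float))
    a470 = np.atleast_1d(np.asarray(a470, dtype=float))
    if not (a665.shape == a649.shape == a470.shape):
        raise ParameterError("absorbance arrays must share a shape")
    if np.any(~np.isfinite(a665) | ~np.isfinite(a649) | ~np.isfinite(a470)):
        raise ParameterError("absorbances must be finite")
    if np.any(a665 < 0) or np.any(a649 < 0) or np.any(a470 < 0):
        raise ParameterError("absorbances must be >= 0")

    ca = coeffs.ca_665 * a665 + coeffs.ca_649 * a649
    cb = coeffs.cb_649 * a649 + coeffs.cb_665 * a665
    car = (coeffs.car_470 * a470 + coeffs.car_ca * ca + coeffs.car_cb * cb) / coeffs.car_denom
    concentrations = np.stack([ca, cb, car])  # µg/mL
    if np.any(concentrations < 0):
        warnings.warn(
            "negative computed pigment concentration floored at 0", stacklevel=2
        )
        concentrations = np.clip(concentrations, 0.0, None)
    # µg/mL × mL → µg; /1000 → mg; /g → mg per g fresh weight.
    factor = ctx.extract_volume / (1000.0 * ctx.sample_mass)
    ca_mg, cb_mg, car_mg = concentrations * factor
    return pd.DataFrame(
        {"chla": ca_mg, "chlb": cb_mg, "chlt": ca_mg + cb_mg, "car": car_mg}
    )


def read_absorbance_csv(path) -> pd.DataFrame:
    """Read (sample_id, A665, A649, A470[, mass_g, volume_mL]) rows."""
    frame = pd.read_csv(path)
    required = {"sample_id", "A665", "A649", "A470"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"absorbance table is missing columns: {sorted(missing)}")
    return frame


def pigment_table_from_csv(path, ctx: ExtractionContext | None = None) -> pd.DataFrame:
    """CSV of absorbance triples → CSV-ready pigment content table."""
    frame = read_absorbance_csv(path)
    if {"mass_g", "volume_mL"} <= set(frame.columns):
        panels = []
        for _, row in frame.iterrows():
            panel = pigments_from_absorbance(
                row["A665"], row["A649"], row["A470"],
                ExtractionContext(row["mass_g"], row["volume_mL"]),
            )
            panels.append(panel)
        out = pd.concat(panels, ignore_index=True)
    else:
        out = pigments_from_absorbance(frame["A665"], frame["A649"], frame["A470"], ctx)
    out.insert(0, "sample_id", frame["sample_id"].to_numpy())
    return out
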