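"""Per-cell DNA-content scores.

Two scalar scores summarize the DNA content visible in a preprocessed
sperm-head spectrum:

``I785``
    the apex intensity of the 785 cm^-1 DNA backbone peak, taken as the
    maximum baseline-corrected intensity within +/- 8 cm^-1 of 785 (a
    windowed maximum tolerates small wavenumber miscalibration; the exact
    extraction rule is a package choice).
``area_714_1162``
    the trapezoidal integral of the baseline-corrected intensity over the
    DNA-PO4 skeleton region 714.30-1161.86 cm^-1, with linear
    interpolation to the exact band edges.  Negative post-baseline
    intensities are integrated as-is by default; clipping them at zero
    would bias areas upward.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .spectra_io import FEATURE_COLUMNS, CellRecord, RamanSpectrum

__all__ = [
    "PEAK_CENTER",
    "PEAK_HALF_WIDTH",
    "BAND_LO",
    "BAND_HI",
    "peak_intensity",
    "band_area",
    "extract_features",
]

PEAK_CENTER = 785.0
PEAK_HALF_WIDTH = 8.0
BAND_LO = 714.30
BAND_HI = 1161.86


def peak_intensity(s: RamanSpectrum, center: float = PEAK_CENTER,
                   half_width: float = PEAK_HALF_WIDTH) -> float:
    """Maximum intensity within ``center +/- half_width`` cm^-1."""
    mask = (s.wavenumbers >= center - half_width) & (s.wavenumbers <= center + half_width)
    if not mask.any():
        raise ValueError(
            f"no channel within {half_width} cm^-1 of {center} cm^-1"
        )
    return float(s.intensities[mask].max())


def band_area(s: RamanSpectrum, lo: float = BAND_LO, hi: float = BAND_HI,
              clip_negative: bool = False) -> float:
    """Trapezoidal band integral over [lo, hi] cm^-1.

    The grid must span the band; the integrand is linearly interpolated to
    the exact endpoints so the result does not depend on where grid nodes
    fall relative to the band edges.
    """
    wn, it = s.wavenumbers, s.intensities
    if wn[0] > lo or wn[-1] < hi:
        raise ValueError(
            f"grid [{wn[0]:g}, {wn[-1]:g}] does not cover band [{lo}, {hi}] cm^-1"
        )
    inner = (wn > lo) & (wn < hi)
    x = np.concatenate(([lo], wn[inner], [hi]))
    y = np.concatenate(([np.interp(lo, wn, it)], it[inner], [np.interp(hi, wn, it)]))
    if clip_negative:
        y = np.clip(y, 0.0, None)
    return float(np.trapezoid(y, x))


def extract_features(cells: Sequence[CellRecord], *,
                     peak_center: float = PEAK_CENTER,
                     peak_half_width: float = PEAK_HALF_WIDTH,
                     band_lo: float = BAND_LO, band_hi: float = BAND_HI,
                     clip_negative: bool = False) -> pd.DataFrame:
    """One row of (cell_id, label, I785, area_714_1162) per cell.

    Raises if a cell's grid does not cover the integration band (naming
    the cell) or if a cell_id appears twice.
    """
    seen: set[str] = set()
    rows = []
    for cell in cells:
        if cell.cell_id in seen:
            raise ValueError(f"duplicate cell_id {cell.cell_id!r}")
        seen.add(cell.cell_id)
        try:
            i785 = peak_intensity(cell.spectrum, peak_center, peak_half_width)
            area = band_area(cell.spectrum, band_lo, band_hi, clip_negative)
        except ValueError as exc:
            raise ValueError(f"cell {cell.cell_id!r}: {exc}") from exc
        rows.append((cell.cell_id, cell.label, i785, area))
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    if not np.isfinite(df[["I785", "area_714_1162"]].to_numpy()).all():
        raise ValueError("non-finite feature value")
    return df
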