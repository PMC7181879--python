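"""Elevational-band histograms of total and intact land, and pressure metrics.

The hypsographic backbone of the analysis: clipped elevation values are binned
into 50-m bands, once for all land and once for the subset of cells whose
human-footprint index (HFI) falls below an intactness threshold.  From the two
histograms come the per-band proportion of intact land, the elevation of peak
human pressure, and its position relative to the elevational gradient.

Band convention: bands are half-open intervals ``[lo, lo + width)`` anchored
at ``floor(min_elev / width) * width`` so edges are reproducible across runs;
the top band is closed so that the range maximum falls inside it (a gradient
spanning 1000-4000 m therefore has exactly 60 bands of 50 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError

__all__ = [
    "ElevationBands",
    "PressureProfile",
    "intact_mask",
    "bin_elevations",
    "peak_pressure_elevation",
    "relative_position",
    "pressure_profile",
    "bands_to_frame",
]

DEFAULT_BAND_WIDTH = 50.0
DEFAULT_HFI_THRESHOLD = 4.0
HFI_SCALE = (0.0, 50.0)


@dataclass
class ElevationBands:
    """Per-band total and intact cell counts for one mountain range."""

    band_lo: np.ndarray  # ordered lower edges (m)
    band_width: float
    total_count: np.ndarray
    intact_count: np.ndarray
    base_elev: float  # range minimum elevation (m)
    peak_elev: float  # range maximum elevation (m)

    def __post_init__(self) -> None:
        self.band_lo = np.asarray(self.band_lo, dtype=float)
        self.total_count = np.asarray(self.total_count, dtype=int)
        self.intact_count = np.asarray(self.intact_count, dtype=int)
        if not (
            len(self.band_lo) == len(self.total_count) == len(self.intact_count)
        ):
            raise ValueError("band arrays must have equal length")
        if np.any(self.intact_count > self.total_count):
            raise ValueError("intact_count cannot exceed total_count in any band")
        if np.any(self.intact_count < 0):
            raise ValueError("counts must be nonnegative")
        if self.base_elev > self.peak_elev:
            raise ValueError("base_elev must not exceed peak_elev")

    @property
    def n_bands(self) -> int:
        return len(self.band_lo)

    @property
    def band_hi(self) -> np.ndarray:
        return self.band_lo + self.band_width

    @property
    def band_mid(self) -> np.ndarray:
        return self.band_lo + 0.5 * self.band_width

    @property
    def amplitude(self) -> float:
        """Range amplitude a = maximum minus minimum elevation (m)."""
        return self.peak_elev - self.base_elev


@dataclass
class PressureProfile:
    """Human pressure summarized along the elevational gradient."""

    intact_prop: np.ndarray  # per band, NaN where the band holds no cells
    peak_pressure_elev: float
    relative_position: float
    overall_intact_prop: float


def intact_mask(hfi_values, threshold: float = DEFAULT_HFI_THRESHOLD) -> np.ndarray:
    """Flag cells as intact: HFI strictly below ``threshold``.

    The default threshold of 4 marks land converted to at least pasture as
    under intense pressure; 3 and 7 are the stricter/looser sensitivity
    settings.  Values outside the documented 0-50 HFI scale trigger a warning
    but are still thresholded.
    """
    hfi_values = np.asarray(hfi_values, dtype=float)
    if hfi_values.size and (
        hfi_values.min() < HFI_SCALE[0] or hfi_values.max() > HFI_SCALE[1]
    ):
        warnings.warn(
            "HFI values outside the documented 0-50 scale", stacklevel=2
        )
    return hfi_values < threshold


def bin_elevations(
    elev_values,
    intact_flags,
    band_width: float = DEFAULT_BAND_WIDTH,
) -> ElevationBands:
    """Histogram elevations (total and intact) into anchored bands.

    Bands start at ``floor(min / band_width) * band_width``; the value equal to
    the top edge of the last band is counted in that band (top band closed).
    """
    elev = np.asarray(elev_values, dtype=float)
    flags = np.asarray(intact_flags, dtype=bool)
    if elev.size == 0:
        raise DegenerateSampleError("cannot bin an empty elevation sample")
    if elev.shape != flags.shape:
        raise ValueError("elev_values and intact_flags must have equal length")
    lo = float(elev.min())
    hi = float(elev.max())
    anchor = np.floor(lo / band_width) * band_width
    n_bands = max(1, int(np.ceil((hi - anchor) / band_width)))
    idx = np.floor((elev - anchor) / band_width).astype(int)
    idx = np.minimum(idx, n_bands - 1)  # close the top band
    total = np.bincount(idx, minlength=n_bands)
    intact = np.bincount(idx[flags], minlength=n_bands)
    band_lo = anchor + band_width * np.arange(n_bands)
    return ElevationBands(
        band_lo=band_lo,
        band_width=band_width,
        total_count=total,
        intact_count=intact,
        base_elev=lo,
        peak_elev=hi,
    )


def peak_pressure_elevation(bands: ElevationBands) -> float:
    """Midpoint elevation of the band where the intact proportion is lowest.

    Bands holding no cells (hypsographic gaps) are skipped.  When several
    bands tie at the minimum, the median of the tied bands' midpoints is
    returned (mean of the two central midpoints for an even tie count).
    """
    occupied = bands.total_count > 0
    if not occupied.any():
        raise DegenerateSampleError("all elevational bands are empty")
    prop = bands.intact_count[occupied] / bands.total_count[occupied]
    mids = bands.band_mid[occupied]
    tied = np.isclose(prop, prop.min())
    return float(np.median(mids[tied]))


def relative_position(
    peak_pressure_elev: float, base_elev: float, peak_elev: float
) -> float:
    """Position of peak pressure along the gradient, scaled 0 (base) to 1 (peak)."""
    if not peak_elev > base_elev:
        raise DegenerateSampleError(
            "relative position undefined for zero-amplitude gradient"
        )
    pos = (peak_pressure_elev - base_elev) / (peak_elev - base_elev)
    return float(np.clip(pos, 0.0, 1.0))


def pressure_profile(bands: ElevationBands) -> PressureProfile:
    """Assemble per-band intact proportions and the peak-pressure metrics."""
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(
            bands.total_count > 0,
            bands.intact_count / np.maximum(bands.total_count, 1),
            np.nan,
        )
    peak = peak_pressure_elevation(bands)
    return PressureProfile(
        intact_prop=prop,
        peak_pressure_elev=peak,
        relative_position=relative_position(peak, bands.base_elev, bands.peak_elev),
        overall_intact_prop=float(bands.intact_count.sum() / bands.total_count.sum()),
    )


def bands_to_frame(range_id: str, bands: ElevationBands) -> pd.DataFrame:
    """Tabulate a band histogram for CSV export."""
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(
            bands.total_count > 0,
            bands.intact_count / np.maximum(bands.total_count, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "range_id": range_id,
            "band_lo": bands.band_lo,
            "band_hi": bands.band_hi,
            "total_count": bands.total_count,
            "intact_count": bands.intact_count,
            "intact_prop": prop,
        }
    )
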