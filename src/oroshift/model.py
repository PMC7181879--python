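"""Model/results objects tying the full per-range analysis together.

:class:`MountainRangeModel` is built from co-registered grids (or file paths,
or a synthetic-range config) and a boundary; ``fit()`` runs the whole chain —
clip → band histograms → pressure profile → topography classification (total
and intact) → lapse/warming/shift → species suite → shift simulation — and
returns a :class:`MountainRangeResults` carrying every intermediate product,
with ``summary()`` and ``plot()`` in the spirit of statsmodels results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import climate as _climate
from .classification import ClassificationResult, classify
from .errors import EmptyClipError
from .hypsography import (
    DEFAULT_BAND_WIDTH,
    DEFAULT_HFI_THRESHOLD,
    ElevationBands,
    PressureProfile,
    bands_to_frame,
    bin_elevations,
    intact_mask,
    pressure_profile,
)
from .raster import Grid, RangeBoundary, read_boundary, read_geotiff
from .rangeshift import (
    DEFAULT_MAX_SIZE,
    DEFAULT_SIZE_STEP,
    RangeShiftSummary,
    ShiftOutcome,
    enumerate_species,
    simulate_shifts,
    summarize,
)

__all__ = ["MountainRangeModel", "MountainRangeResults"]


class MountainRangeModel:
    """Per-range analysis model over co-registered DEM/HFI/temperature grids.

    Parameters
    ----------
    dem, hfi, temp_current : Grid
        Co-registered single-band grids (same shape and geometry).
    temp_futures : list of Grid
        One future-temperature layer per climate model.
    boundary : RangeBoundary, optional
        Range outline; cells whose centers fall outside are dropped.  When
        omitted, every unmasked cell participates.
    hfi_threshold : float
        HFI values strictly below this are intact (default 4; 3 and 7 are
        the sensitivity settings).
    scenario : str
        Label recorded with the climate summary (e.g. "RCP8.5").
    """

    def __init__(
        self,
        dem: Grid,
        hfi: Grid,
        temp_current: Grid,
        temp_futures: list[Grid],
        boundary: RangeBoundary | None = None,
        *,
        range_id: str = "range",
        scenario: str = "RCP8.5",
        hfi_threshold: float = DEFAULT_HFI_THRESHOLD,
        band_width: float = DEFAULT_BAND_WIDTH,
        size_step: float = DEFAULT_SIZE_STEP,
        max_size: float = DEFAULT_MAX_SIZE,
    ) -> None:
        grids = {"hfi": hfi, "temp_current": temp_current}
        grids.update({f"temp_future[{i}]": g for i, g in enumerate(temp_futures)})
        for name, g in grids.items():
            if g.shape != dem.shape:
                raise ValueError(
                    f"{name} grid shape {g.shape} does not match DEM {dem.shape}; "
                    "align grids first (see align_bilinear)"
                )
        self.dem = dem
        self.hfi = hfi
        self.temp_current = temp_current
        self.temp_futures = list(temp_futures)
        self.boundary = boundary
        self.range_id = range_id
        self.scenario = scenario
        self.hfi_threshold = float(hfi_threshold)
        self.band_width = float(band_width)
        self.size_step = float(size_step)
        self.max_size = float(max_size)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        dem_path,
        hfi_path,
        temp_current_path,
        temp_future_paths,
        boundary_path=None,
        **kwargs,
    ) -> "MountainRangeModel":
        boundary = read_boundary(boundary_path) if boundary_path else None
        if boundary is not None and "range_id" not in kwargs:
            kwargs["range_id"] = boundary.id
        return cls(
            read_geotiff(dem_path),
            read_geotiff(hfi_path),
            read_geotiff(temp_current_path),
            [read_geotiff(p) for p in temp_future_paths],
            boundary,
            **kwargs,
        )

    @classmethod
    def from_synthetic(cls, config_or_range, **kwargs) -> "MountainRangeModel":
        from .synthetic import SyntheticRange, make_range

        sr = (
            config_or_range
            if isinstance(config_or_range, SyntheticRange)
            else make_range(config_or_range)
        )
        kwargs.setdefault("range_id", sr.config.range_id)
        return cls(
            sr.dem, sr.hfi, sr.temp_current, sr.temp_futures, sr.boundary, **kwargs
        )

    # -- fitting -----------------------------------------------------------

    def _clipped(self) -> dict[str, np.ndarray]:
        """Paired value vectors for all cells inside the boundary and valid
        in every layer."""
        keep = ~self.dem.nodata_mask & ~self.hfi.nodata_mask
        keep &= ~self.temp_current.nodata_mask
        for g in self.temp_futures:
            keep &= ~g.nodata_mask
        if self.boundary is not None:
            cx, cy = self.dem.cell_centers()
            inside = shapely.contains_xy(
                self.boundary.polygon, cx.ravel(), cy.ravel()
            ).reshape(self.dem.shape)
            if not inside.any():
                raise EmptyClipError(
                    f"boundary {self.range_id!r} contains no cell centers (empty clip)"
                )
            keep &= inside
        sel = keep.ravel()
        return {
            "elev": self.dem.values.ravel()[sel],
            "hfi": self.hfi.values.ravel()[sel],
            "temp": self.temp_current.values.ravel()[sel],
            "futures": [g.values.ravel()[sel] for g in self.temp_futures],
        }

    def fit(self, n_boot: int = 999, seed: int = 0) -> "MountainRangeResults":
        vals = self._clipped()
        flags = intact_mask(vals["hfi"], self.hfi_threshold)
        bands = bin_elevations(vals["elev"], flags, self.band_width)
        profile = pressure_profile(bands)
        cls_total = classify(
            vals["elev"], n_boot=n_boot, seed=seed, case="total"
        )
        cls_intact = classify(
            vals["elev"][flags], n_boot=n_boot, seed=seed, case="intact"
        )
        slope, se = _climate.lapse_rate(vals["temp"], vals["elev"])
        warming = _climate.warming_rate(vals["temp"], vals["futures"])
        shift_m = _climate.shift_distance(warming, slope, self.band_width)
        climate = _climate.ClimateSummary(
            lapse_rate=slope,
            lapse_se=se,
            warming=warming,
            shift_m=shift_m,
            scenario=self.scenario,
            n_models=len(vals["futures"]),
        )
        species = enumerate_species(
            amplitude=bands.amplitude,
            base_elev=bands.base_elev,
            band_width=self.band_width,
            size_step=self.size_step,
            max_size=self.max_size,
        )
        outcomes = simulate_shifts(bands, species, shift_m)
        shift_summary = summarize(outcomes)
        return MountainRangeResults(
            model=self,
            bands=bands,
            profile=profile,
            classification={"total": cls_total, "intact": cls_intact},
            climate=climate,
            n_species=len(species),
            outcomes=outcomes,
            shift_summary=shift_summary,
        )


@dataclass
class MountainRangeResults:
    """Fitted per-range results; see the ``*_frame`` methods for CSV tables."""

    model: MountainRangeModel
    bands: ElevationBands
    profile: PressureProfile
    classification: dict[str, ClassificationResult]
    climate: _climate.ClimateSummary
    n_species: int
    outcomes: list[ShiftOutcome]
    shift_summary: RangeShiftSummary
    _: dict = field(default_factory=dict, repr=False)

    @property
    def range_id(self) -> str:
        return self.model.range_id

    # -- tables ------------------------------------------------------------

    def bands_frame(self) -> pd.DataFrame:
        return bands_to_frame(self.range_id, self.bands)

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for case, r in self.classification.items():
            rows.append(
                {
                    "range_id": self.range_id,
                    "case": case,
                    "n": r.n,
                    "dip": r.dip,
                    "dip_p": r.dip_p,
                    "skewness": r.skewness,
                    "mclass": r.mclass.value,
                }
            )
        return pd.DataFrame(rows)

    def pressure_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "range_id": self.range_id,
                    "hfi_threshold": self.model.hfi_threshold,
                    "peak_pressure_elev": self.profile.peak_pressure_elev,
                    "relative_position": self.profile.relative_position,
                    "overall_intact_prop": self.profile.overall_intact_prop,
                }
            ]
        )

    def climate_frame(self) -> pd.DataFrame:
        c = self.climate
        return pd.DataFrame(
            [
                {
                    "range_id": self.range_id,
                    "scenario": c.scenario,
                    "n_models": c.n_models,
                    "warming_C": c.warming,
                    "lapse_C_per_m": c.lapse_rate,
                    "lapse_se": c.lapse_se,
                    "shift_m": c.shift_m,
                }
            ]
        )

    def outcomes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "range_id": self.range_id,
                    "case": o.case,
                    "lower": o.species.lower,
                    "size": o.species.size,
                    "area_baseline": o.area_baseline,
                    "area_projected": o.area_projected,
                    "pct_change": np.nan if o.pct_change is None else o.pct_change,
                }
                for o in self.outcomes
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "range_id": self.range_id,
                    "class_total": self.classification["total"].mclass.value,
                    "class_intact": self.classification["intact"].mclass.value,
                    "peak_pressure_elev": self.profile.peak_pressure_elev,
                    "relative_position": self.profile.relative_position,
                    "overall_intact_prop": self.profile.overall_intact_prop,
                    "warming_C": self.climate.warming,
                    "lapse_C_per_m": self.climate.lapse_rate,
                    "shift_m": self.climate.shift_m,
                    "n_species": self.n_species,
                    "prop_intact_ge_total": self.shift_summary.prop_intact_ge_total,
                }
            ]
        )

    def band_means_frame(self) -> pd.DataFrame:
        df = self.shift_summary.band_means.copy()
        df.insert(0, "range_id", self.range_id)
        return df

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable digest of the fitted range."""
        c = self.climate
        t, i = self.classification["total"], self.classification["intact"]
        lines = [
            f"Mountain range analysis: {self.range_id}",
            "=" * 58,
            f"cells (clipped)          {self.bands.total_count.sum():>12d}",
            f"elevation span           {self.bands.base_elev:>9.0f} - "
            f"{self.bands.peak_elev:.0f} m  (amplitude {self.bands.amplitude:.0f} m)",
            f"bands ({self.bands.band_width:.0f} m)             {self.bands.n_bands:>12d}",
            f"HFI threshold (intact <) {self.model.hfi_threshold:>12.1f}",
            f"overall intact prop      {self.profile.overall_intact_prop:>12.3f}",
            f"peak pressure elev       {self.profile.peak_pressure_elev:>10.1f} m "
            f"(relative position {self.profile.relative_position:.3f})",
            "-" * 58,
            f"class (total land)       {t.mclass.value:>12s}   "
            f"dip={t.dip:.4f} p={t.dip_p:.3f} g1={t.skewness:+.3f}",
            "class (intact land)      "
            + (
                f"{i.mclass.value:>12s}"
                + (
                    ""
                    if np.isnan(i.dip)
                    else f"   dip={i.dip:.4f} p={i.dip_p:.3f} g1={i.skewness:+.3f}"
                )
            ),
            "-" * 58,
            f"scenario                 {c.scenario:>12s}   ({c.n_models} models)",
            f"warming                  {c.warming:>10.3f} C",
            f"lapse rate               {c.lapse_rate:>10.6f} C/m (se {c.lapse_se:.2g})",
            f"isotherm shift           {c.shift_m:>10.0f} m",
            f"species modeled          {self.n_species:>12d}",
            f"prop(intact >= total)    {self.shift_summary.prop_intact_ge_total:>12.3f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean percentage area change per starting band, one curve per case."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"total": "0.3", "intact": "tab:red"}
        for case, sub in self.shift_summary.band_means.groupby("case"):
            sub = sub.sort_values("band_lo")
            ax.plot(sub["band_lo"], sub["mean_pct"], label=case, color=colors[case])
            ax.fill_between(
                sub["band_lo"],
                sub["mean_pct"] - sub["se_pct"],
                sub["mean_pct"] + sub["se_pct"],
                alpha=0.25,
                color=colors[case],
            )
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_xlabel("pre-shift lower limit (m)")
        ax.set_ylabel("% change in area")
        ax.set_title(self.range_id)
        ax.legend()
        return ax
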