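"""Seeded synthetic mountain ranges: DEM, HFI, and temperature grids.

Emulates the analysis inputs — an elevation raster, a 0–50 human-footprint
composite, and current/future mean-annual-temperature layers — for ranges with
*known* topography class, pressure profile, lapse rate, and per-model warming
offsets, so that every pipeline stage can be tested end-to-end without the
global data downloads.

Elevation values are drawn from a class-specific distribution (right-skewed
unimodal → pyramid; symmetric unimodal → diamond; well-separated two-component
mixture → hourglass; left-skewed unimodal → inverse pyramid), truncated to
[base, base + amplitude] by rejection, and laid out on the grid by descending
distance from the grid center so the map looks like a mountain (outermost
cells lowest).  The spatial arrangement is a convenience only: every statistic
downstream depends solely on the clipped value multiset.

The HFI is generated directly on the composite 0–50 scale.  (The real index
sums eight weighted threat layers — built environment 0/10, population
density and night lights 0–10, crops 0/7, pasture 0/4, roads 0–8, railways
0/8, navigable waterways 0–4 — which this generator does not simulate
threat-by-threat.)  Temperature is linear in elevation with Gaussian noise;
each "climate model" future layer is the current layer plus a constant
offset, so the ensemble-mean warming is exactly the mean of the offsets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box

from .errors import ConfigError
from .raster import Grid, RangeBoundary, write_boundary, write_geotiff

__all__ = [
    "LogisticDecline",
    "PeakedPressure",
    "ConstantPressure",
    "SyntheticRangeConfig",
    "SyntheticRange",
    "make_dem",
    "make_hfi",
    "make_temperature",
    "make_boundary",
    "make_range",
]

_TARGET_CLASSES = ("pyramid", "diamond", "hourglass", "inverse_pyramid")


# ---------------------------------------------------------------------------
# expected-HFI-versus-elevation profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticDecline:
    """Pressure high at the base, declining logistically with elevation.

    ``midpoint_rel`` is the relative elevation (0 = base, 1 = peak) where the
    expected HFI is halfway between ``hfi_base`` and ``hfi_top``.
    """

    hfi_base: float = 12.0
    hfi_top: float = 1.0
    midpoint_rel: float = 0.35
    steepness: float = 8.0
    kind: str = "logistic_decline"

    def expected(self, elev, base_elev: float, amplitude: float) -> np.ndarray:
        rel = (np.asarray(elev, dtype=float) - base_elev) / amplitude
        drop = 1.0 / (1.0 + np.exp(-self.steepness * (rel - self.midpoint_rel)))
        return self.hfi_base + (self.hfi_top - self.hfi_base) * drop


@dataclass(frozen=True)
class PeakedPressure:
    """Pressure peaking (Gaussian bump) at a chosen elevation."""

    center_elev: float = 1000.0
    width_m: float = 300.0
    hfi_peak: float = 12.0
    hfi_background: float = 1.0
    kind: str = "peaked"

    def expected(self, elev, base_elev: float, amplitude: float) -> np.ndarray:
        z = np.asarray(elev, dtype=float)
        bump = np.exp(-0.5 * ((z - self.center_elev) / self.width_m) ** 2)
        return self.hfi_background + (self.hfi_peak - self.hfi_background) * bump


@dataclass(frozen=True)
class ConstantPressure:
    """Spatially uniform expected pressure."""

    level: float = 0.0
    kind: str = "constant"

    def expected(self, elev, base_elev: float, amplitude: float) -> np.ndarray:
        return np.full_like(np.asarray(elev, dtype=float), self.level)


_PROFILE_KINDS = {
    "logistic_decline": LogisticDecline,
    "peaked": PeakedPressure,
    "constant": ConstantPressure,
}


def profile_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    try:
        cls = _PROFILE_KINDS[kind]
    except KeyError:
        raise ConfigError(f"unknown pressure profile kind {kind!r}") from None
    return cls(**d)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticRangeConfig:
    """Everything needed to generate one synthetic mountain range.

    Defaults describe a mid-sized, strongly base-pressured tropical range:
    3000-m amplitude on a 70×70 grid of 1-km cells (4900 cells), an
    environmental lapse rate of −6.5 °C/km, and a five-member ensemble of
    warming offsets averaging +3.0 °C (an end-of-century high-emissions
    magnitude).
    """

    target_class: str = "diamond"
    base_elev: float = 0.0
    amplitude: float = 3000.0
    grid_shape: tuple[int, int] = (70, 70)
    pressure: LogisticDecline | PeakedPressure | ConstantPressure = field(
        default_factory=LogisticDecline
    )
    pressure_noise_sd: float = 1.0
    lapse_rate: float = -0.0065  # °C per m
    sea_level_temp: float = 25.0  # °C
    gcm_offsets: tuple[float, ...] = (2.0, 2.6, 3.0, 3.4, 4.0)
    temp_noise_sd: float = 0.5
    gen_skewness: float = 1.2  # generating skew for (inverse) pyramid targets
    hourglass_modes_rel: tuple[float, float] = (0.2, 0.8)
    hourglass_sd_rel: float = 0.05
    cell_size: float = 1000.0
    seed: int = 0
    range_id: str = "synthetic-range"
    name: str = ""

    def __post_init__(self) -> None:
        if self.target_class not in _TARGET_CLASSES:
            raise ConfigError(
                f"target_class must be one of {_TARGET_CLASSES}, got "
                f"{self.target_class!r}"
            )
        if self.amplitude < 100:
            raise ConfigError("amplitude must be at least 100 m")
        if not self.gcm_offsets:
            raise ConfigError("at least one GCM warming offset is required")
        if self.pressure_noise_sd < 0 or self.temp_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")
        if self.gen_skewness <= 0.5:
            raise ConfigError(
                "generating skewness must exceed the 0.5 classification cut "
                "for a recoverable (inverse) pyramid target"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pressure"] = asdict(self.pressure)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticRangeConfig":
        d = dict(d)
        d["pressure"] = profile_from_dict(d["pressure"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["gcm_offsets"] = tuple(d["gcm_offsets"])
        d["hourglass_modes_rel"] = tuple(d["hourglass_modes_rel"])
        return cls(**d)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _rng(config: SyntheticRangeConfig, stream: int) -> np.random.Generator:
    # independent substreams per layer so each generator is a pure function
    # of (config, seed)
    return np.random.default_rng([int(config.seed), stream])


def _draw_elevations(config: SyntheticRangeConfig, n: int) -> np.ndarray:
    rng = _rng(config, 1)
    a = config.amplitude
    cls = config.target_class

    def rejection(draw):
        out = np.empty(0)
        while out.size < n:
            cand = draw(2 * (n - out.size) + 16)
            out = np.concatenate([out, cand[(cand >= 0) & (cand <= a)]])
        return out[:n]

    if cls in ("pyramid", "inverse_pyramid"):
        k = (2.0 / config.gen_skewness) ** 2  # gamma shape: skew = 2/sqrt(k)
        scale = a / (k + 4.0 * np.sqrt(k))  # mean + 4 sd spans the amplitude
        vals = rejection(lambda m: rng.gamma(k, scale, size=m))
        if cls == "inverse_pyramid":
            vals = a - vals
    elif cls == "diamond":
        vals = rng.beta(5.0, 5.0, size=n) * a
    else:  # hourglass: well-separated two-component normal mixture
        m1, m2 = (r * a for r in config.hourglass_modes_rel)
        sd = config.hourglass_sd_rel * a

        def draw(m):
            comp = rng.random(m) < 0.5
            return np.where(comp, rng.normal(m1, sd, m), rng.normal(m2, sd, m))

        vals = rejection(draw)
    return config.base_elev + vals


def make_dem(config: SyntheticRangeConfig) -> Grid:
    """Class-targeted elevation grid, radially sorted (center highest)."""
    rows, cols = config.grid_shape
    n = rows * cols
    elev = np.sort(_draw_elevations(config, n))
    r, c = np.indices((rows, cols))
    dist = np.hypot(r - (rows - 1) / 2.0, c - (cols - 1) / 2.0).ravel()
    # outermost cells take the lowest elevations; ties broken by flat index
    order = np.lexsort((np.arange(n), -dist))
    values = np.empty(n)
    values[order] = elev
    return Grid(
        values=values.reshape(rows, cols),
        nodata_mask=np.zeros((rows, cols), dtype=bool),
        cell_size=config.cell_size,
        origin=(0.0, rows * config.cell_size),
        crs_tag="synthetic-local",
    )


def make_hfi(dem: Grid, config: SyntheticRangeConfig) -> Grid:
    """Human-footprint grid: expected profile of elevation plus noise, 0–50."""
    rng = _rng(config, 2)
    expected = config.pressure.expected(
        dem.values, config.base_elev, config.amplitude
    )
    noise = (
        rng.normal(0.0, config.pressure_noise_sd, size=dem.shape)
        if config.pressure_noise_sd > 0
        else 0.0
    )
    hfi = np.clip(expected + noise, 0.0, 50.0)
    return Grid(
        values=hfi,
        nodata_mask=dem.nodata_mask.copy(),
        cell_size=dem.cell_size,
        origin=dem.origin,
        crs_tag=dem.crs_tag,
    )


def make_temperature(
    dem: Grid, config: SyntheticRangeConfig
) -> tuple[Grid, list[Grid]]:
    """Current temperature (linear in elevation + noise) and one future layer
    per model offset."""
    rng = _rng(config, 3)
    t = config.sea_level_temp + config.lapse_rate * dem.values
    if config.temp_noise_sd > 0:
        t = t + rng.normal(0.0, config.temp_noise_sd, size=dem.shape)
    current = Grid(
        values=t,
        nodata_mask=dem.nodata_mask.copy(),
        cell_size=dem.cell_size,
        origin=dem.origin,
        crs_tag=dem.crs_tag,
    )
    futures = [
        Grid(
            values=t + off,
            nodata_mask=dem.nodata_mask.copy(),
            cell_size=dem.cell_size,
            origin=dem.origin,
            crs_tag=dem.crs_tag,
        )
        for off in config.gcm_offsets
    ]
    return current, futures


def make_boundary(dem: Grid, config: SyntheticRangeConfig) -> RangeBoundary:
    """Rectangular boundary enclosing every cell center of the grid."""
    xmin, ymin, xmax, ymax = dem.extent
    return RangeBoundary(
        polygon=box(xmin - 1.0, ymin - 1.0, xmax + 1.0, ymax + 1.0),
        name=config.name or config.range_id,
        id=config.range_id,
    )


@dataclass
class SyntheticRange:
    """One generated range: all grids, the boundary, and its config."""

    config: SyntheticRangeConfig
    dem: Grid
    hfi: Grid
    temp_current: Grid
    temp_futures: list[Grid]
    boundary: RangeBoundary

    def write(self, out_dir: str | Path) -> Path:
        """Write GeoTIFFs, the GeoJSON boundary, and a manifest recording the
        generating config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_geotiff(self.dem, out / "dem.tif")
        write_geotiff(self.hfi, out / "hfi.tif")
        write_geotiff(self.temp_current, out / "temp_current.tif")
        future_files = []
        for i, g in enumerate(self.temp_futures):
            fname = f"temp_future_{i:02d}.tif"
            write_geotiff(g, out / fname)
            future_files.append(fname)
        write_boundary(self.boundary, out / "boundary.geojson")
        manifest = {
            "config": self.config.to_dict(),
            "files": {
                "dem": "dem.tif",
                "hfi": "hfi.tif",
                "temp_current": "temp_current.tif",
                "temp_futures": future_files,
                "boundary": "boundary.geojson",
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def make_range(config: SyntheticRangeConfig) -> SyntheticRange:
    """Generate the full input bundle for one synthetic range."""
    dem = make_dem(config)
    hfi = make_hfi(dem, config)
    current, futures = make_temperature(dem, config)
    return SyntheticRange(
        config=config,
        dem=dem,
        hfi=hfi,
        temp_current=current,
        temp_futures=futures,
        boundary=make_boundary(dem, config),
    )
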