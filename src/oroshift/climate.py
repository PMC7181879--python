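"""Per-range warming rates, temperature lapse rates, and upslope shift distance.

The lapse rate is the ordinary least-squares slope of mean annual temperature
(°C) on elevation (m) over a range's cells — typically around −0.005 to
−0.0065 °C/m.  The warming rate is the mean over climate models of the
per-model mean pixel-wise (future − current) temperature difference.  Their
quotient ΔT/|Γ| is the upslope displacement of isotherms, snapped to the
50-m band grid on which all area bookkeeping happens (half-up rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, TemperatureInversionError
from .hypsography import DEFAULT_BAND_WIDTH

__all__ = ["ClimateSummary", "lapse_rate", "warming_rate", "shift_distance"]


@dataclass
class ClimateSummary:
    lapse_rate: float  # °C per m (expected negative)
    lapse_se: float
    warming: float  # °C, ensemble-mean warming for the scenario
    shift_m: float  # m, nonnegative multiple of the band width
    scenario: str = "RCP8.5"
    n_models: int = 1


def lapse_rate(temps, elevs) -> tuple[float, float]:
    """OLS slope (and its standard error) of temperature on elevation."""
    t = np.asarray(temps, dtype=float).ravel()
    z = np.asarray(elevs, dtype=float).ravel()
    if t.size != z.size:
        raise ValueError("temps and elevs must be paired")
    if t.size < 3:
        raise DegenerateSampleError("lapse rate requires at least 3 paired values")
    if np.ptp(z) == 0:
        raise DegenerateSampleError("lapse rate undefined for constant elevation")
    fit = stats.linregress(z, t)
    se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return float(fit.slope), se


def warming_rate(current, futures) -> float:
    """Mean over models of the mean pixel-wise (future − current) difference."""
    cur = np.asarray(current, dtype=float).ravel()
    futures = [np.asarray(f, dtype=float).ravel() for f in futures]
    if not futures:
        raise ValueError("at least one future temperature layer is required")
    for f in futures:
        if f.shape != cur.shape:
            raise ValueError("future layers must be co-registered with the current layer")
    return float(np.mean([np.mean(f - cur) for f in futures]))


def shift_distance(
    warming: float, lapse_rate: float, band_width: float = DEFAULT_BAND_WIDTH
) -> float:
    """Upslope shift ΔT/|Γ| in meters, snapped to the band grid (ties up).

    Raises :class:`TemperatureInversionError` for a non-negative lapse rate:
    a downslope shift is outside the model and is aborted per range.
    """
    if warming < 0:
        raise ValueError("warming must be nonnegative (shifts are upslope only)")
    if lapse_rate >= 0:
        raise TemperatureInversionError(
            f"fitted lapse rate {lapse_rate:+.6g} °C/m is non-negative; "
            "upslope shift undefined (temperature inversion)"
        )
    raw = warming / abs(lapse_rate)
    return float(np.floor(raw / band_width + 0.5) * band_width)
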