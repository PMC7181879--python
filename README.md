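# oroshift

Mountain topography, human pressure, and elevational range shifts under
climate warming.

As climates warm, montane species track their isotherms upslope. How much
land they find there depends on two things at once: the *shape* of the
mountain range — how land area is distributed over elevation — and how much
of that land is still **intact**, i.e. not under intense human pressure.
`oroshift` implements a per-range analysis pipeline for exactly this
question, for conservation scientists and climate-change biogeographers:

1. **Hypsography.** Elevation values clipped to a range boundary are binned
   into 50-m bands, once for all land and once for the intact subset — cells
   whose Human Footprint Index (HFI, a 0–50 composite of cumulative human
   pressure) falls below a threshold (default `HFI < 4`, with 3 and 7 as
   sensitivity settings).
2. **Topography classification.** Each value distribution is classified from
   two scale-free statistics — Hartigan's dip `D` (sup-norm distance from the
   empirical CDF to the nearest unimodal CDF) and the moment skewness
   `g1 = m3 / m2^{3/2}`:
   *hourglass* if `D > 0.01` and bootstrap `p < 0.05`; otherwise *pyramid*
   if `g1 ≥ 0.5`, *inverse pyramid* if `g1 ≤ −0.5`, else *diamond*; and
   *intensified* if no intact land remains at all.
3. **Pressure over elevation.** Per-band intact proportions, the elevation
   of peak pressure (band with the minimum intact proportion, median on
   ties), and its position scaled 0 (base) – 1 (peak).
4. **Climate.** Per-range lapse rate Γ (OLS slope of temperature on
   elevation, °C/m), ensemble-mean warming ΔT (mean over climate models of
   mean pixel-wise future − current difference), and the isotherm shift
   `ΔT/|Γ|` snapped to the 50-m band grid.
5. **Range-shift simulation.** A suite of hypothetical species — every
   window of size 100 m … min(amplitude, 4000 m) in 100-m increments,
   starting every 50 m from the base, fully contained in the gradient — is
   displaced upslope by the shift, and the percentage change in area

   ```
   %Δarea = ((Area_projected / Area_baseline) − 1) × 100
   ```

   is computed under the total-land and intact-land cases (−100 % marks
   local extinction; a zero intact baseline is undefined and excluded).
   Summaries report per-band and per-size-class means ± SE and the
   proportion of the gradient where the intact-case change equals or
   exceeds the total-case change.

A seeded synthetic-range generator (`oroshift.synthetic`) produces DEM, HFI
and temperature GeoTIFFs with known class, pressure profile, lapse rate and
warming offsets, so every stage is testable without global data downloads.

## Worked example

```python
from oroshift import MountainRangeModel, SyntheticRangeConfig

cfg = SyntheticRangeConfig(target_class="pyramid", seed=7, range_id="demo-pyramid")
res = MountainRangeModel.from_synthetic(cfg).fit(n_boot=499, seed=1)
print(res.summary())
```

```
Mountain range analysis: demo-pyramid
==========================================================
cells (clipped)                  4900
elevation span                  31 - 2990 m  (amplitude 2959 m)
bands (50 m)                       60
HFI threshold (intact <)          4.0
overall intact prop             0.152
peak pressure elev            500.0 m (relative position 0.158)
----------------------------------------------------------
class (total land)            pyramid   dip=0.0029 p=1.000 g1=+1.009
class (intact land)           pyramid   dip=0.0118 p=0.740 g1=+0.949
----------------------------------------------------------
scenario                       RCP8.5   (5 models)
warming                       3.000 C
lapse rate                -0.006492 C/m (se 1.4e-05)
isotherm shift                  450 m
species modeled                   870
prop(intact >= total)           1.000
==========================================================
```

Reading the output: the generated range is right-skewed (`g1 ≈ +1.0`,
dip far from significant), hence a *pyramid* — most land sits at low
elevations. Human pressure is concentrated near the base (peak pressure at
0.16 of the gradient; only 15 % of cells are intact overall). The recovered
lapse rate (−6.49 °C/km) and ensemble warming (+3.0 °C) imply isotherms
shifting 450 m upslope. Across all 870 modeled species, the mean intact-case
area change equals or exceeds the total-case change in every starting band
(`prop = 1.0`): because pressure is base-concentrated, species restricted to
intact land tend to *gain* relative area by shifting away from it. Per-band
curves are available via `res.plot()` and the full tables via
`res.outcomes_frame()` etc.

The same analysis runs from rasters on disk
(`MountainRangeModel.from_files(...)`) or from the command line:

```sh
oroshift synth --target-class pyramid --seed 7 --out fixture/
oroshift shift --dem fixture/dem.tif --hfi fixture/hfi.tif \
    --boundary fixture/boundary.geojson --current fixture/temp_current.tif \
    --future fixture/temp_future_00.tif --out results/
oroshift run-all --config run.json
```

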