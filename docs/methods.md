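# Methods

This note documents the models, conventions and numerical choices behind
`oroshift`, in the order the pipeline applies them.

## Scope and data model

The unit of analysis is one mountain range: a boundary polygon plus
co-registered single-band rasters of elevation (m), Human Footprint Index
(HFI, dimensionless 0–50), and mean annual temperature (°C; one current
layer and one future layer per climate model). All grids are assumed
co-registered after a single bilinear resampling pass
(`align_bilinear`), mirroring the usual practice of resampling a fine DEM
once onto the ~1-km HFI grid; there is no on-the-fly reprojection. A cell
belongs to a range iff its **center** lies inside the polygon — the common
raster-clip convention; how boundary-straddling cells are treated is a
genuine free choice and this one is deterministic and documented. Masked
(nodata) cells are excluded from every count and fit; they never count as
intact or as intense. Each cell contributes one unit of area; every
statistic in the pipeline is ratio-based, so area units cancel.

Boundaries are read from GeoJSON. GeoTIFF I/O is deliberately minimal
(single band, pixel-scale/tiepoint/nodata tags) — sufficient for
pre-co-registered analysis rasters and the synthetic fixtures.

## Elevational bands

Elevations are binned into 50-m bands: fine enough for accurate
area–elevation curves, and matching the decadal-scale shift distances
reported for montane species. Bands are half-open `[lo, lo+50)` and anchored
at `floor(min/50)·50`, so band edges are reproducible across runs and ranges
rather than floating with the sample minimum; the top band is closed so the
range maximum falls inside it. Under this convention a gradient spanning
1000–4000 m has exactly 60 bands. Negative elevations are legal anchors
(coastal ranges dip below sea level).

Intactness is `HFI < threshold`, strictly; the default threshold 4 marks
land converted to at least pasture as intense, with 3 (stricter — excludes
any pasture-level development) and 7 (looser — only cropland-level
conversion and above counts as intense) as the sensitivity settings. Values
outside the documented 0–50 scale warn but do not fail.

The elevation of **peak human pressure** is the midpoint of the band with
the lowest intact proportion; bands holding no cells are skipped (the
proportion is undefined there). When several bands tie, the *median of the
tied bands' midpoints* is used — for an even tie count, the mean of the two
central midpoints. Its **relative position** is
`(peak − base)/(peak_elev − base_elev)`, clamped to [0, 1]; a half-band
overshoot can otherwise occur because the peak is a band midpoint.

## Topography classification

Classes are assigned from two location/scale-free statistics of the
elevation-value distribution:

* **Hartigan's dip** `D`: the minimax (sup-norm) distance between the
  empirical CDF and the nearest unimodal CDF. It is computed exactly by the
  iterative greatest-convex-minorant / least-concave-majorant construction
  on the unique values with multiplicities: within the current interval the
  gcm is fitted to the lower step corners and the lcm to the upper ones, the
  candidate modal interval shrinks to where their gap is largest, and sup
  deviations on the discarded flanks accumulate; the dip is half the largest
  of these quantities. An atom is permitted at the mode (a point mass is
  unimodal), so a constant sample has `D = 0`; any sample with ≥ 2 distinct
  values has `D ≥ 1/(2n)`. The implementation is validated in the test suite
  against an independent linear-programming oracle that optimizes over
  piecewise-linear unimodal CDFs mode-by-mode (exact for knot-modal fits,
  which lose no generality).
* **Type-I skewness** `g1 = m3 / m2^{3/2}` — the plain moment coefficient,
  no small-sample bias correction.

The **p-value** of the dip is bootstrapped against uniform(0, 1) samples of
matched size — the standard calibration null for the test — with an add-one
correction `(k+1)/(n_boot+1)`; `n_boot` defaults to 999 and is seeded. Null
tables depend only on `(n, n_boot, seed)`, not on the data, and are cached.
`classify` skips the bootstrap when `D ≤ 0.01`, where the class cannot
depend on it.

Decision rule, boundaries exactly as stated: *hourglass* if `D > 0.01`
(strict) **and** `p < 0.05`, irrespective of skew; otherwise *pyramid* if
`g1 ≥ 0.5` (inclusive), *inverse pyramid* if `g1 ≤ −0.5`, else *diamond*.
The procedure is run twice per range — on all values (total case) and on the
intact subset — and an empty intact sample yields the *intensified* class.
A nonempty but degenerate intact sample (< 4 values, or zero variance)
cannot support either screen; it falls to the remainder (diamond) class with
a warning. Classification uses all clipped values, no subsampling: at 1-km
resolution even the largest ranges stay within ordinary memory (≈ 26 M cells
globally ⇒ a few hundred MB of doubles at worst for a single huge range).
Near the `p = 0.05` boundary, results can differ marginally from other dip
implementations with different bootstrap counts or nulls.

## Climate

The **lapse rate** Γ is the OLS slope of temperature on elevation over the
range's cells, with its standard error (degenerate fits — constant
elevation, < 3 cells — are errors). The **warming rate** ΔT is the mean over
models of the per-model mean pixel-wise (future − current) difference; model
identity is a label only. The **isotherm shift** is `ΔT/|Γ|` m, snapped to
the nearest multiple of the band width with half-up rounding — the analysis
operates on bands, so sub-band shifts are not representable; whether to snap
or interpolate areas at arbitrary offsets is a free choice and snapping is
the declared convention. One scalar shift per range per scenario. A fitted
non-negative slope (temperature inversion) aborts the shift for that range
with an explicit error rather than producing a downslope shift.

## Species suite and shift simulation

Range sizes run 100 m … min(amplitude, 4000 m) in 100-m steps; lower limits
start at the range base and advance 50 m at a time; windows extending beyond
the gradient are never generated. The enumeration is ordered (size, lower)
ascending and is the ground truth for the closed-form counts; with `b = a/50`
bands the even/odd-`b` closed forms for `a ≤ 4000` and the even-`b` form for
`a > 4000` agree exactly with enumeration, while the odd-`b`, `a > 4000`
form undercounts enumeration by a constant 20 under this band convention —
`species_count_closed_form` reports the printed formula and the discrepancy
is documented rather than patched.

Baseline window `[lower, upper)`, projected window shifted up by the
isotherm shift; a window's area is the sum of counts over bands fully inside
it. Projected windows are clipped implicitly at the mountain top (bands
beyond it hold no area) but never at the base — warming is required to be
non-negative, so shifts are upslope only. Percentage change follows
`((proj/base) − 1)·100`; it is ≥ −100 always, equals −100 exactly when no
projected area remains (local extinction), and is *undefined* when the
baseline is zero (possible in the intact case). Undefined outcomes are
first-class: they are excluded from all summaries and counted per case,
since including them would make the statistic meaningless.

Summaries index species by their **pre-shift lower limit**. Per band and per
size class, the mean and standard error (sample SD/√n, 0 when n = 1) of the
percentage change are reported per case. The proportion of the gradient
where the intact-case mean equals or exceeds the total-case mean is computed
over bands where both means are defined, with an absolute tolerance of 1e−9
on the equality arm of the floating-point comparison.

## Synthetic ranges

The generator emulates the analysis inputs with known ground truth:

* **DEM** — n values drawn per target class: gamma (shape `(2/γ₁)²`, scale
  chosen so mean + 4 sd spans the amplitude; default generating skewness 1.2)
  for *pyramid*, its mirror image for *inverse pyramid*, Beta(5, 5) for
  *diamond*, and an equal two-component normal mixture (modes at 0.2/0.8 of
  the amplitude, sd 0.05·amplitude) for *hourglass*; all truncated to
  [base, base + amplitude] by rejection so the amplitude used by the species
  enumeration is controlled. Values are laid out by descending distance from
  the grid center (outermost lowest) so the raster looks like a mountain;
  every downstream statistic depends only on the clipped value multiset, so
  no further spatial realism is attempted.
* **HFI** — an expected-pressure profile of elevation (logistic decline from
  ~12 at the base to ~1 at the top by default, or a Gaussian bump peaked at
  a chosen elevation, or a constant) plus Gaussian noise, clipped to the
  0–50 scale. Generated directly on the composite scale; the real index's
  eight weighted threat layers are not simulated individually.
* **Temperature** — `T = T₀ + Γ·z` plus Gaussian noise (default sd 0.5 °C);
  each future layer adds one constant per-model offset, so the noiseless
  lapse fit returns Γ exactly and the warming rate returns the offset mean
  exactly. Defaults: Γ = −6.5 °C/km, five offsets averaging +3.0 °C (an
  end-of-century high-emissions magnitude).

Every generator output is a pure function of (config, seed), via per-layer
seeded substreams. Default problem size is a 70×70 grid (4 900 cells,
≈ 1-km resolution, 3 000-m amplitude) — large enough for stable dip/skew
statistics, small enough that multi-range suites run in seconds.

What the synthetic data does **not** emulate: spatially autocorrelated
terrain and pressure, elevation-dependent temperature noise, disagreements
among climate models beyond a constant offset, nodata structure, and
boundary shapes more complex than a rectangle. Passing tests therefore
demonstrate correctness of the *computations* under controlled conditions,
not fidelity of any empirical global numbers, which require the real global
rasters and boundary inventory.

## Pipeline conventions

`run_all` isolates failures per range (an error in one range is logged with
its id and never disturbs the others), writes all tables as CSV with floats
at 10 significant digits so reruns are byte-identical, and records seed,
bootstrap count and thresholds in a JSON run log — the bootstrap near the
`p = 0.05` boundary being the one stochastic element worth auditing.
Sensitivity analyses (HFI threshold 3/4/7, scenario label, size classes) are
pure re-runs with changed config fields; no code paths differ.

## Known limitations

* Area amount only, not configuration/connectivity of intact land along the
  gradient.
* Species are assumed to track isotherms exactly: no lags, disequilibrium
  dynamics, or extinction debt; shifts are uniform and upslope only.
* Temperature is the only climate driver (no precipitation).
* One scalar shift per range; within-range spatial variation in warming and
  lapse rate is averaged away.
* ESRI shapefile boundaries are not read (GeoJSON only); multi-band imagery
  and CRS reprojection are out of scope.
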