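# Methods

## Decay and dose model

The fallout mixture is seven radionuclides in fixed order: Te-129m,
Te-129, I-131, Te-132, I-132, Cs-134, Cs-137. Each carries a physical
half-life and an initial surface β dose rate `d0` (μSv/h, 70 μm dose
equivalent, per 1000 kBq/m² of that nuclide's own deposition, sources
distributed in the top soil layer). Two conventions shape the model:

- **Equilibrium daughters.** Te-129 (70 min) and I-132 (2.3 h) are far
  shorter-lived than their parents and are sustained by them, so their
  activity ratios to Cs-137 stay at fixed multiples of the parent's
  ratio (0.7 and 8.3 respectively) and their *time decay is governed by
  the parent's half-life*. This is encoded by a `decay_parent` field;
  every half-life used in decay or correction is parent-resolved.
- **Two-ratio parameterization.** The deposition-ratio vector is
  `f = (r_T, 0.7 r_T, r_I, 8.3 r_T, 8.3 r_T, 1, 1)`, so the whole
  mixture is described by r_I = I-131/Cs-137 and r_T = Te-129m/Cs-137
  at the deposition date.

The dose rate is `Σ fᵢ d0ᵢ 2^(−t/Tᵢ)` and the cumulative dose over a
horizon H has the closed form
`(1/1000) Σ fᵢ d0ᵢ (Tᵢ/ln 2)(1 − 2^(−H/Tᵢ))` (mSv). The closed form is
cross-checked against adaptive quadrature of the rate to ≤1e−10
relative in the tests. Because `f` is affine in (r_I, r_T), the
cumulative dose is *exactly* affine in the ratios; this is asserted to
1e−12 relative as a property test over random coefficient vectors.

## Calibration and identifiability

The published analysis reports only the fitted dose surface
`D(r_I, r_T) = a·r_I + slope_b·r_T + intercept_b` with constants
(1.1165, 31.032, 50.009), not the per-nuclide `d0` values (those come
from a separate Monte Carlo transport calculation that is out of scope
here — its results enter only through these fitted constants).
`calibrate_coefficients` inverts the surface back onto `d0`:

- the iodine slope identifies `d0(I-131)` exactly:
  `1000·a / [(T/ln2)(1 − 2^(−H/T))]` ≈ 4.02 μSv/h;
- `slope_b` identifies only two *group composites* — the 33.6-d group
  `d0(Te-129m) + 0.7·d0(Te-129)` and the 3.204-d group
  `8.3·(d0(Te-132) + d0(I-132))` — partitioned by `te_split`
  (default 0.5);
- `intercept_b` is partitioned between Cs-134 and Cs-137 by `cs_split`
  (default 0.5); within each group the composite is divided equally.

The splits are not identifiable from the surface, but every choice
reproduces the same cumulative dose (the round-trip guarantee, tested
to 1e−9 relative on a 20×20 ratio grid), so downstream results do not
depend on them.

## Units, constants and dates

- `d0` in μSv/h; cumulative doses in mSv (explicit 1/1000 factor);
  Gy→Sv conversion factor fixed at 1 for β rays.
- Half-lives: Te-129m 33.6 d, I-131 8.021 d, Te-132 3.204 d; Cs-134
  2.0652 y and Cs-137 30.07 y from standard nuclear data (configurable
  through the TOML nuclide configuration).
- One year = 365.25 d = 8766 h; the alternative 365 d changes only the
  caesium term, by <0.1%.
- Dates are calendar dates at day resolution; decay intervals are whole
  days converted to hours. The deposition reference date defaults to
  2011-03-15; records without a sampling date fall back to a
  configurable global default (2011-07-01, the middle of the summer
  survey window) and the fallback is logged.

## Survey pipeline

Stages: (1) decay-correct each record's activity ratios to the
reference date; (2) fill missing r_T by multilevel B-spline
interpolation of the measured ones; (3) evaluate the unit dose either
from the linear surface or from the calibrated forward model (the two
agree by the round trip; a flag selects); (4) scale by the Cs-137
deposition density; (5) optionally rasterize the doses. Every input
record appears exactly once in the output; records excluded from dose
output (by default those without an I-131 ratio, mirroring the source
analysis, which had detectable I-131 at only a fraction of locations)
carry an explicit reason. An opt-in flag interpolates r_I as well; it
is off by default because only the tellurium ratio field is smooth
enough to have been mapped this way in the source analysis.

Records may carry pre-corrected ratios (`r_i`, `r_t` columns). Such
records are taken as already referred to the deposition date —
including their deposition density — because published per-location
tables report exactly that form. For raw records the measured Cs-137
activity is decay-corrected back to the deposition date before the
dose scaling (a ~0.6% effect over three months).

## Multilevel B-spline approximation

The scattered-data stage uses the standard BA/MBA scheme with uniform
cubic tensor-product B-splines:

- **BA step.** For each data point, candidate coefficients over its
  4×4 control neighbourhood are `w·z/Σw²`; overlapping candidates are
  blended with weights `w²`; untouched coefficients are 0. A single
  isolated point is reproduced exactly (algebraic identity).
- **Multilevel step.** BA is applied coarse-to-fine on the residuals of
  the previous level, halving the lattice spacing each time; evaluation
  sums all levels. Residuals at the data points are non-increasing
  across levels.

Defaults: 4×4-cell base lattice, 6 levels (finest cell ≈ 1/256 of the
domain). A hierarchy whose finest cell would fall below 1e−6 of the
domain is rejected. Convergence at the data points requires the lattice
to refine past the minimum point separation — near-coincident points
with different values are averaged, not interpolated.

Geographic coordinates are normalized to the unit square over a
bounding box. Longitude is scaled by cos(mean latitude) to define the
local planar metric; because the unit-square map is per-axis, the
cosine cancels in the coordinates themselves and is recorded as the
box's metric aspect ratio in the normalization metadata (at ~37.5°
latitude a degree of longitude is ~0.79 of a degree of latitude).
Queries outside the data hull decay toward 0 (unsupported coefficients
stay 0) and queries outside the unit square are evaluated at the
clamped position and flagged rather than masked, since the published
maps are full-field. Negative interpolated ratios are clamped to 0 and
counted; measured values are never altered. Rasters use the plain-text
ESRI ASCII grid dialect (single-space `key value` header lines in the
order ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value;
rows north to south; sentinel −9999).

## Synthetic survey generator

The generator emulates a ~2-km-mesh deposition survey with known
truth. It is a statistical stand-in, not dispersion physics:

- **Deposition**: an anisotropic exponential ridge
  `peak·exp(−|along|/L_along − |cross|/L_cross)` along a northwest
  bearing plus a weaker southern lobe (weights normalized so the source
  cell equals the configured peak), times lognormal field noise
  (default GSD 1.3).
- **r_I**: base 9.2 at the source with a latitudinal gradient (default
  −30 per degree, rising toward the south, matching the reported
  south-coastal iodine enrichment), Gaussian noise, floored at 0.
- **r_T**: base 1.2 plus a smooth sinusoidal term (default wavelength
  50 km, amplitude 0.8), noise, floored at 0.
- **Sampling**: one record per mesh node; dates uniform over
  June–August 2011; activities decayed per nuclide to the record's
  date; multiplicative lognormal measurement noise (default GSD 1.15,
  chosen for positivity — the source reports no error model); I-131
  censored below a detection limit (default 0.3 kBq/m² at the sampling
  date, which reproduces the reported flavor of ~20–25% detection
  three months after deposition).

All randomness flows from `numpy.random.default_rng` seeded from the
config (separate streams for field and sampling), so surveys are
reproducible bit-for-bit. The synthetic ratio fields are smooth by
construction, which flatters interpolation relative to real fallout
heterogeneity; passing recovery tests demonstrate correctness of the
pipeline mechanics, not real-world interpolation accuracy.

## Bundled tables

Two text fixtures ship with the package: the fitted-intercept table
b(r_T) (six rows; the r_T = 50 row is stored as 1601.6 with a
provenance note — the printed value dropped a leading digit, as the
table's own fit shows — and re-fits that must match the published
coefficients use only the four unambiguous rows r_T ∈ {0.1, 0.5, 1, 5})
and the 72 representative survey locations with activities,
decay-corrected ratios and doses. The location table's ratios are
printed at ~2 significant figures, so surface evaluation at the printed
ratios deviates from the printed unit dose by ~0.8% at the median; the
printed dose columns are mutually coherent (D·A/1000 within 0.5 mSv of
the printed absolute dose on every row).

## Problem sizes and determinism

The test suite and the acceptance script run the synthetic pipeline at
~250 locations (noise-free round trip) and ~500 locations (noisy
recovery), the interpolation experiments at 300 scatter points with
30% masking, and the round-trip/linearity checks on 20×20 ratio grids
and 100 random configurations — sizes at which every check completes in
seconds while exercising the full code path. Identical inputs and seeds
give byte-identical outputs (tables and rasters), which is asserted in
the tests.

## Known limitations

- Per-nuclide `d0` values are only identified up to the group
  composites above; analyses needing true per-nuclide dose splits must
  supply `d0` directly in the nuclide configuration.
- The dose-rate model is a pure sum of decaying exponentials and is
  therefore monotonically non-increasing in time; transient ingrowth
  effects are outside the model.
- The 70 μm dose equivalent at the soil surface is a skin/biota dose
  for organisms at the ground; it is not a human effective dose and
  assumes continuous outdoor exposure.
- No uncertainty propagation on fitted coefficients (the source
  analysis reports none); no kriging/IDW alternatives; no map
  reprojection beyond the cosine metric factor.
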