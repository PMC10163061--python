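# Methods

## Model overview

`cotgrow` describes a cotton season on normalised axes. The independent
variable is a *relative cumulative driver*: either thermal time (growing
degree days, CGDD) or reference crop evapotranspiration (CET_O), each
accumulated daily over the season and divided by its season total so the
growing period maps onto [0, 1]. The dependent variable is a *relative
growth index*: plant height, leaf area index (LAI) or above-ground dry
matter, each divided by its theoretical seasonal maximum. On these axes
cotton development is well described by logistic curves:

- height and dry matter: `R = 1/(1 + exp(a + b·x))`, monotone sigmoids,
  so growth curves carry `b < 0`;
- LAI: `R = 1/(1 + exp(a + b·x + c·x²))`, which with `c > 0` rises and
  then falls, peaking at `x = −b/(2c)`.

The exponent is kept in this published sign convention rather than the
textbook `L/(1 + e^{−k(x−x₀)})` form so that published coefficient tables
are usable verbatim.

### Thermal time

Daily increments are `max(min((T_max+T_min)/2, T_upper), T_base) − T_base`
with cotton limits `T_base = 10 °C`, `T_upper = 40 °C`. Only the daily
mean is clamped, not the extremes individually; the published piecewise
definition is circular as printed (its conditions are expressed on the
quantity being defined) and this compute-then-clamp reading matches the
printed cases. Increments are therefore in [0, 30] °C·d and the cumulative
series is monotone.

### Reference evapotranspiration

Daily ET_O uses the FAO-56 Penman–Monteith equation with its standard
constants (0.408, 900, 273, 0.34). The auxiliary psychrometric quantities
are the standard FAO-56 forms: Δ from the Tetens saturation-pressure curve,
γ = 0.000665·P with P = 101.3 kPa at sea level or the FAO-56 elevation
formula when an elevation is given, e_s as the mean of saturation pressures
at T_max and T_min, and e_a from mean relative humidity when vapour
pressures are not supplied. Soil heat flux defaults to 0 at the daily step.
Rare radiation-deficit days can yield a negative daily ET_O; accumulation
clamps such days to zero so the cumulative driver stays monotone (required
for the relative logistic forms), while the raw signed value remains
available from `daily_eto`. The season window is simply the supplied
record's first to last day; choosing sowing-to-harvest boundaries is the
caller's responsibility, and relative drivers normalise by that window's
total.

### Normalisation of growth indices

Observed seasonal maxima undersample the true peak, so the theoretical
maximum inflates the observed maximum by a factor conventionally within
[1.01, 1.05]; factors outside the range are rejected unless explicitly
overridden. LAI is stored as a dimensionless area ratio (values up to ~9
imply leaf area per unit ground area).

## Fitting

Parameters are estimated by unweighted least squares on the original scale
(Levenberg–Marquardt via `scipy.optimize.curve_fit`, iteration cap 800
evaluations, xtol 1e-10). Starting values come from ordinary least squares
on the logit transform `ln(1/y − 1)`, linear or quadratic in x; for
noise-free data that initialiser is already exact, which is why noise-free
recovery tests demand agreement to 1e-6. Observations with y exactly 0 or 1
are clipped inward by 1e-6 for the initialiser only — the main objective
sees the raw values. Fitting is deterministic and invariant to observation
order; pooled ("Total") fits concatenate regions without weighting.

Diagnostics follow the conventions of the source tables: R² is the squared
Pearson correlation between predictions and observations; RMSE is on the
scale of y; RE is the ratio of residual sum of squares to the sum of
squared measured values, reported in percent. A scalar variant
`|calculated − fitted|/|fitted|` measures the deviation between a directly
fitted coefficient and its algebraic reconstruction. Recomputing the full
published deviation table from its printed coefficient pairs matches every
cell to within 5e-4; most cells agree at printed precision, and the residual
slack reflects unrounded internal values behind the published table.

## Driver linkage and parameter conversion

Within a region the two relative drivers are nearly affinely related,
`R_CETo = m·R_CGDD + n` with `m > 0`; on simulated seasons the linear fit
achieves R² > 0.99. A cubic link form is provided for evaluation only — its
parameter transformations are impractically heavy, which is exactly why the
linear link is used. Substituting the link into a logistic exponent gives
the closed-form conversions

    d = a − b·n/m            e = b/m
    f = c/m²                 e = (b·m − 2c·n)/m²     d = a − (b·m·n − c·n²)/m²

and the inverse direction reuses the same routines with the inverted link
`(1/m, −n/m)`. Published tables list parameter pairs but not per-region
links, so the shipped link registry back-solves `m = b/e`,
`n = (a − d)·m/b` from each region's height row (dry-matter or LAI rows
where height is absent; the quadratic back-solve uses `m = √(c/f)`). Links
recovered independently from different indices of the same region agree to
about 1e-3 in both m and n, supporting the assumption of one shared link
per region.

## Yield, irrigation and IWUE

Seed-cotton yield responds concavely to maximum LAI, and maximum LAI
responds concavely to seasonal irrigation; both responses ship as frozen
quadratic presets with provenance, and new responses can be fitted to
binned data with the same least-squares machinery. Binning follows a
half-open `[lo, hi)` convention with the final bin closed (a deterministic
choice the source procedure leaves unstated), with out-of-range points
dropped and counted.

Closed forms: the vertex `(−q₁/(2q₂), q₀ − q₁²/(4q₂))` gives the
yield-optimal LAI_max (6.043, worth 7171.7 kg/ha) and the irrigation at
which LAI_max saturates (573.541 mm). Inverting the irrigation response at
a target LAI_max is a quadratic root; the ASCENDING (smaller) root is the
default branch because it is the water-economical solution (518.793 mm for
the yield-optimal target, below saturation). Targets above the response
maximum raise an explicit error; a discriminant within 1e-12 of zero is
treated as the vertex. The reported optimum propagates the LAI_max target
at its quoted 3-decimal precision (6.043); `laimax_decimals=None` propagates
full precision instead, which shifts the required irrigation to 518.818 mm.
The quoted-precision default matches how the figure is conventionally
propagated downstream.

Two IWUE modes are deliberate. Composing the two quadratics exactly gives a
quartic in W whose printed form rounds the W³ coefficient (1.47279e-3 →
0.0015); at W ≈ 519 mm that rounding is worth ~7 kg/(ha·mm). `AS_PRINTED`
evaluates the published quartic verbatim and reproduces the published
21.153 kg/(ha·mm); `COMPOSED` evaluates `Y(LAI_max(W))/W` exactly
(≈13.824, which equals vertex yield / required irrigation). Outputs are
always labelled with their mode; the package does not guess which the
original intent was. Relatedly, the published pairing of the irrigation
vertex with LAI_max 4.938 does not follow from the published coefficients
(which give 6.438 at the vertex) and is treated as an erratum.

## Synthetic seasons

The generator produces April 10 – October 20 daily weather from a climate
profile: temperatures as a sinusoidal annual cycle peaking mid-July plus
lag-1 autocorrelated noise (ρ = 0.6, a synoptic-persistence fixture choice),
a diurnal range splitting the mean into extremes, net radiation as its own
seasonal sinusoid floored at zero, vapour pressures from mean relative
humidity, and log-normal wind. Two profiles ship: `arid-continental`
(mean annual 10 °C, amplitude 15 °C, dry and sunny — season thermal time
≈1700 °C·d, inside the 1400–2000 °C·d band typical of such regions) and
`warm-temperate-monsoon` (13 °C, amplitude 13 °C, humid and cloudier).
Growth observations are the true logistic curve sampled at evenly spaced
quantiles of the season's relative driver plus additive Gaussian noise
clipped into (0, 1) by 1e-6 — the simplest structure consistent with
multi-study scatter. Everything is bitwise reproducible from (profile,
year, seed).

What the generator does *not* emulate: precipitation (the models never
consume it; irrigation amounts are treated as design inputs on the
400–700 mm grid), heteroscedastic or systematic digitisation error,
inter-annual persistence, or any specific station's record. Passing tests
therefore demonstrate correct model algebra and estimator behaviour under
the assumed noise structure, not validation against real field data.

## Problem sizes and defaults

Default simulated experiments use one 194-day season per region, 50
observations at noise sd 0.02 for linear-model recovery (expected within
±5%), 60 at sd 0.03 for quadratic-peak recovery (within ±0.03), and
two-region sets for linkage checks — sizes at which the whole suite runs in
seconds while leaving the estimators non-trivially stressed. All headline
yield/irrigation numbers are closed-form and independent of any seed.

## Known limitations

- Hourly ET_O, crop-coefficient adjustment to actual evapotranspiration and
  radiation estimation from sunshine hours are out of scope.
- No parameter uncertainty (bootstrap/CIs) is provided.
- The preset coefficients are empirical fits to Chinese cotton regions;
  applying them elsewhere extrapolates beyond their support, and model
  evaluation outside x ∈ [0, 1] warns accordingly.
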