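# Methods

## Attenuation parameterization

The package models the ratio of a material's linear attenuation
coefficient to that of water with a stoichiometric cross-section
parameterization: each element contributes `(w/A)(Z + Z^2.86 k1 + Z^4.62 k2)`,
the three terms standing for incoherent scattering, coherent scattering,
and the photoelectric effect, with the exponents fixed and only the two
mixing coefficients free. The denominator is the same sum evaluated for
water (11.19 % H, 88.81 % O, ρ = 1 g/cm³), so water's ratio is exactly 1
for any (k1, k2) — an identity the code preserves to machine precision and
the tests assert.

CT numbers follow from the ratio in one of two ways:

* **two-parameter model** — `H = 1000 (μ/μ_w − 1)`; air is structurally
  pinned near −1000 HU;
* **three-parameter model** — `H = 1000 α (μ/μ_w − 1)`; the extra scale α
  absorbs the scanner-dependent air level (air ≈ −1000 α HU) while water
  remains exactly 0 HU for any α. The inverse map is
  `μ/μ_w = H/(1000 α) + 1`, and the round-trip identity between the two
  is property-tested.

Both fits minimize squared residuals **in μ/μ_w space**, not HU space.
The two are not equivalent: a μ-space residual weighs a 10-HU error the
same everywhere, whereas an HU-space fit scaled by α would not. The water
measurement is excluded from the three-parameter fit automatically
(detected as a composition whose μ/μ_w is parameter-independent), because
its residual constrains nothing; the audit phantom still carries a water
insert so the measured water CT number can be checked against 0 ± 5 HU.

## Parameters

| parameter | meaning | default / initialization |
|---|---|---|
| k1 | coherent-scattering coefficient (dimensionless) | 1.24×10⁻³ |
| k2 | photoelectric coefficient (dimensionless) | 3.06×10⁻⁵ |
| α | HU scale; −1000 α is the modeled air CT number | 1.0 |

k1 and k2 are unbounded (slightly negative values are legitimate on noisy
data); α is kept positive by an internal log-parameterization.

## Optimizer behaviour and the under-determined audit fit

The fits use `scipy.optimize.least_squares` (trust-region reflective) with
`x_scale` set to the characteristic parameter magnitudes
(1.24×10⁻³, 3.06×10⁻⁵, 0.05 in log α) and tolerances of 10⁻¹⁵. The scaling
matters for the audit scenario, where three parameters are fitted to only
two informative materials: the objective then has a one-dimensional flat
valley, and scaled minimum-norm steps make the optimizer converge to the
point of the zero-residual manifold nearest the initialization instead of
drifting along the valley. Consequences, all covered by tests:

* the fitted materials' CT numbers are reproduced exactly (residuals ~10⁻¹⁶);
* predictions for other tissues are anchored partly by the initialization.
  Perturbing all three starting values by ±10 % moves most tissue
  predictions by under ~5 HU but the densest (tooth, hydroxyapatite) by up
  to ~18 HU, because the initialization's k1 component lies in the fit's
  null space and dense tissues are the most k1-sensitive. The audit bands
  stop at 1.25 g/cm³, well below that regime;
* a `FitResult` is flagged `identifiable` only when the number of materials
  is at least the number of free parameters **and** the materials jointly
  span ≥ 6 distinct elements — three hydrocarbons cannot determine (k1, k2)
  no matter how many of them are scanned.

A coarse grid search over (k1, k2, α) serves as an independent oracle in
the tests; the optimizer's sum of squares must never exceed the grid
minimum.

## Compositions and electron densities

Weight fractions plus any residual term must sum to 1. Sums within ±0.5 %
are normalized silently (the bundled hydroxyapatite row prints 99.73 % and
is the motivating case), within ±5 % with a warning, and beyond that the
composition is rejected. Minor elements (Na, Mg, S, Cl, K, Fe, I, …) may be
lumped into a single pseudo-element with weight `w_res`, mean atomic number
`Z̄res`, and atomic mass `2.1·Z̄res` — a good approximation for trace
elements in tissue, where Z/A ≈ 1/2.1. In the electron sum the lump
contributes exactly `w_res/2.1` regardless of `Z̄res`; in the attenuation
model `Z̄res` does matter through the Z-power terms. Compositions that list
their minor elements explicitly (the measured audit-phantom materials) keep
them explicit. Atomic masses are IUPAC 2021 standard atomic weights; with
these, all eleven bundled tissue REDs reproduce their published values to
the printed precision.

## Calibration tables and the audit

Each tissue contributes one breakpoint (theoretical HU, MD) and
(theoretical HU, RED). Tables are sorted by HU, breakpoints closer than
0.5 HU are merged, evaluation is piecewise-linear with end clamping (the
segment-table convention of commercial RTPSs), and export rounds HU to one
decimal. The air breakpoint is computed from the air composition — about
−999 α HU, not pinned to −1000 α — which is precisely the point of the
three-parameter model.

The audit samples the difference (audit table − RTPS table) on the union
of both tables' breakpoints plus 10-HU steps over their common span; both
curves being piecewise linear, verdicts are stable under grid refinement
(asserted at 10 vs 1 HU). Band membership uses the mass density the audit
MD table assigns to each grid HU, including for RED audits. Bands are
half-open `[low, high)` and the 0.8–0.9 g/cm³ gap is deliberately outside
every band. A band fails when |mean difference| exceeds its tolerance
level; the fraction of individual samples beyond the level is reported as
an exceedance rate and yields at most an "investigate" verdict, since
isolated excursions do not imply a calibration error. Tolerance levels for
a dose budget other than 2 % are obtained by linear rescaling rounded to
3 decimals (1.4 % → 0.031 / 0.015 / 0.031); the alternative adipose lower
bound 0.95 g/cm³ is selectable.

## Synthetic scanner

The simulator renders a 2-D slice: each pixel takes the theoretical CT
number of the material at its centre under ground-truth (k1, k2, α), plus
i.i.d. Gaussian noise (default SD 5 HU, matching typical in-phantom water
SDs of ≈3–7 HU), deterministic per seed. ROI means use centre-in-circle
pixel membership with no partial-volume weighting, and the default ROI
diameter is 0.7 of the insert diameter. What the simulator deliberately
omits: beam hardening and phantom-size effects (an optional per-band HU
bias could emulate them but is off by default), reconstruction-filter
texture and correlated noise, partial-volume edges, and any 3-D/slice
averaging. Passing tests therefore demonstrate the self-consistency and
numerical correctness of the calibration chain, not robustness to those
physical effects; with real scans the residual between measured and
predicted CT numbers also carries beam-hardening and size mismatch.

With the noiseless simulated audit phantom, the closed loop
simulate → measure → fit → build tables reproduces tables built directly
from the ground truth exactly when the truth coincides with the fit
initialization, and to ~4×10⁻⁴ g/cm³ in-band when the truth α is 0.97
(the fit recovers truth only up to the two-material null space) — roughly
50× below even the stricter tolerance set. Under SD-5 noise, the median
|α error| of the 11-material fit is below 0.005 across 200 replicates.

## Problem sizes

Tests simulate 150×150 mm phantoms at 1 mm pixels, run 200-replicate
noise studies for the α-recovery property, and use a 21³ grid for the
optimizer oracle; the whole suite completes in a few seconds.

## Known limitations

* The attenuation parameterization is single-spectrum; dual-energy or
  spectral CT is out of scope.
* High-Z doped substitutes (e.g. barium-loaded bone surrogates) violate
  the Z-power parameterization and should not be used for fitting.
* DICOM support is deliberately minimal: single-frame CT with rescale
  slope/intercept; vendor RTPS export formats are not parsed.
* The tolerance levels are taken as given constants of the audit
  protocol; the dose calculations behind them are not reproduced.
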