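# Methods

This note documents the models, estimators and numerical choices behind
`ctcspectro`, and what the synthetic-data generators do and do not emulate.

## 1:1 complexation equilibrium

All binding-related generators rest on the exact 1:1 mass-action model
`K = [DA] / ([D]·[A])` with totals D₀ = [D] + [DA] and A₀ = [A] + [DA].
The complex concentration is the physical root of
`c² − (D₀ + A₀ + 1/K)·c + D₀A₀ = 0`, evaluated as

```
c = 2·D₀·A₀ / (b + sqrt(b² − 4·D₀·A₀)),   b = D₀ + A₀ + 1/K
```

rather than the textbook `(b − sqrt(...))/2`, because the subtraction form
loses all significant digits at weak binding (`4·D₀A₀ ≪ b²`). The
rationalized form agrees with a bisection root of the mass-action equation
to 10⁻¹² relative across eight orders of magnitude in K and six in the
totals (property-tested). `K = 0` short-circuits to `c = 0`.

## Benesi–Hildebrand

For a donor titration at fixed acceptor total, the linearization

```
[A₀]/A = 1/(ε·l) + 1/(K·ε·l) · 1/[D₀]
```

is fitted by unweighted OLS; ε = 1/(intercept·l), K = intercept/slope.
Non-positive slope or intercept raise an explicit model-inapplicability
error instead of returning a sign-flipped K.

The linearization is exact only in the limit where the complex consumes a
negligible fraction of the acceptor, which requires K·A₀ ≪ 1 — *not* merely
a large acceptor excess. The titration generator therefore has two modes:
`equilibrium` (absorbances from the exact solver; carries the linearization
bias, which grows like K·A₀/(1 + K·A₀) and is measured at ~1.5% in K for
K·A₀ = 0.0075) and `bh_exact` (points placed exactly on the B–H line, so
the downstream fit must recover any (K, ε) to float tolerance). Recovery
tests use `bh_exact`; the bias mode exists precisely to quantify what the
linearization costs on exact chemistry.

## Tauc band-gap extraction

For a direct allowed transition the absorption edge obeys
`(αhν)² = B·(hν − E_g)` above the gap. The estimator scans every contiguous
window of at least `window_min_points` (default 5) points of the
transformed data and applies a two-part linearity gate:

1. positive slope and R² ≥ `r2_min` (default 0.99);
2. the OLS slopes of the window's two halves agree within
   `4·√2 · min(SE₁, SE₂)`, with a relative floor of 10⁻⁶ to absorb float
   rounding on exact data.

Among qualifying windows the longest wins; ties go to the larger slope and
then the lower-energy start. E_g is the x-intercept `−intercept/slope`.

The design is driven by two failure modes that a pure R² gate cannot
handle. First, R² barely reacts when a long window drags in the flat
below-edge foot, which biases the intercept low; the equal-slope test
rejects such windows because the foot depresses the first half's slope, and
the tolerance is set by the *cleaner* half's standard error precisely so a
curved half cannot widen its own acceptance band. Second, under noise,
5-point windows pass R² ≥ 0.99 by chance with wildly inflated slopes, so
any selection keyed primarily on slope magnitude is unstable; preferring
window length makes the estimate come from the longest stretch consistent
with a straight line. On exact edges the full above-edge region is selected
and E_g is recovered to ~10⁻¹⁵; at 1% relative noise on α the mean absolute
error over 50 seeds is ≈0.012 eV (slightly conservative: the gate trims a
few near-edge points, giving a small negative bias well inside the 0.05 eV
recovery budget).

## Job's method

The continuous-variation series fixes C = D₀ + A₀ and varies the donor mole
fraction x; the complex (hence absorbance) is maximal at the stoichiometric
fraction. The estimator takes the 5 grid points centred on the empirical
maximum (window clamped at the grid ends; ties toward lower x), fits a
parabola and returns the vertex x\* and ratio x\*/(1−x\*), with a label
among {1:2, 1:1, 2:1} when x\* is within 0.1 of 1/3, 1/2 or 2/3. A
boundary maximum or non-concave peak raises an error. A parabola vertex is
preferred over the classical two-tangent intersection because it is stable
on the coarse 8–9-point grids typical of microwell Job experiments; the
estimator is scale-invariant in absorbance by construction.

## Electronic constants

* Photon energy: E(eV) = 1239.84/λ(nm); wavenumber ν̄ = 10⁷/λ cm⁻¹.
* Ionization potential (empirical CT-band relation):
  I_p = 5.76 + 1.53×10⁻⁴·ν̄.
* ΔG⁰ = −RT·ln K, reported in kJ/mol; T defaults to 298 K (ambient;
  298.15 K moves the CLA-scenario value by 0.01 kJ/mol).
* f = 4.32×10⁻⁹·ε_max·Δν½, μ = 0.0958·√(ε_max·Δν½/ν̄_max),
  R_N = hν_CT − I_p + (EA + W). The half-bandwidth Δν½, electron affinity
  EA and Coulomb term W are mandatory caller inputs: they must be measured
  or sourced per acceptor, and silently defaulting them would fabricate
  band-intensity descriptors. Missing inputs raise an "insufficient data"
  error.

## Donor-site ranking

A site's score is |Σ signed partial charges| over its atom numbers, read
from a bundled table of computed charges for the donor molecule. The signed
sum (not a sum of magnitudes) is what makes a two-atom site with charges
−0.567 and −0.168 score 0.735 and outrank the single pyrrole-type nitrogen
at −0.7068, reproducing the assignment of the pyrimidinyl-pyrazole moiety
as the donor site. Ranking is invariant to table row order.

## Microwell validation statistics

Calibration is unweighted OLS (absorbance on µg/mL), requiring ≥ 5 distinct
levels. SDa in LOD = 3.3·SDa/b and LOQ = 10·SDa/b is read as the OLS
standard error of the intercept (the conventional ICH interpretation of
"standard deviation of the intercept"); LOQ/LOD ≡ 10/3.3 follows
identically. RSD uses the sample (n−1) standard deviation because replicate
counts are small (n = 3–6). Unknowns are inverted through the line,
C = (A − a)/b, and flagged — never clipped — when outside the fitted range.
Blank wells are optional; when present, the mean blank is subtracted from
the whole plate once, before both fitting and quantitation, so the two
stages stay consistent. Throughput is the plain product
plates × wells × rounds/hour.

## Eco-Scale

Score = max(100 − Σ penalty points, 0), classified excellent (> 75),
acceptable (> 50), else inadequate. The floor at zero is a convention
choice (negative greenness scores are never reported in practice). Amount
penalties come from volume bands (< 1 mL → 1, 1–10 mL → 2, > 10 mL → 3 per
sample); hazard penalties are GHS pictogram count × signal-word multiplier
(none 0, warning 1, danger 2). The ledger also accepts directly asserted
penalty points, since published tables often state per-item penalties as
outcomes; the bundled microwell-assay ledger totals 12 points (score 88,
excellent). Merging ledgers sums their points (additivity is
property-tested). GAPI and AGREE assessments are pass-through report
fields only.

## Synthetic data: what it emulates, and what it does not

Generators produce Gaussian absorption bands on a wavelength grid
(Beer–Lambert additive mixtures), titrations and Job series from the exact
equilibrium, direct-transition edges `α = √(B(hν − E_g))/hν`, and 96-well
calibration plates filled row-major. The noise model is
`x → x(1 + N(0, σ_rel)) + N(0, σ_abs)` with defaults σ_abs = 0.002 AU and
σ_rel = 0.5%, chosen to keep 3-replicate RSDs in the ≤ 2% range expected
of a plate reader; any non-zero noise requires an explicit seed and the
generators are pure functions of (parameters, seed).

Deliberately **not** emulated: reaction kinetics (only endpoint absorbances
are modeled, so time-optimization studies are out of scope), baseline drift
and stray-light artifacts (no baseline-correction stage exists, matching
the clean traces generated), solvent effects on band shape, well-to-well
optical-path variation (the microwell effective path is an explicit
parameter, default 1.0 cm, not a distribution), and degradation impurities.
Bands are parameterized in the wavelength domain, not wavenumber, for
simplicity. Passing recovery tests on this synthetic data therefore
demonstrates estimator correctness — not robustness to the instrumental
artifacts real spectra carry.

## Degenerate inputs and tie-breaks

Flat spectra yield an empty maxima list (not an error); band-maximum
parabolic refinement falls back to the grid point when curvature is
non-negative, with ties toward shorter wavelength. Spectrum CSVs in
descending order are sorted with a warning flag; duplicate wavelengths and
non-numeric rows are format errors naming the line. The Tauc scan reports
its best R² when no window qualifies. Reports serialize with sorted keys so
identical inputs, config and seed give byte-identical JSON.

## Known limitations

* The B–H estimator inherits the linearization bias on exact-equilibrium
  data whenever K·A₀ is not small; a nonlinear isotherm refit is
  intentionally out of scope.
* The oscillator-strength/dipole/resonance-energy formulas are only as good
  as the caller-supplied Δν½, EA and W.
* Job's-ratio snapping considers only the three small-integer ratios common
  for CT complexes (1:2, 1:1, 2:1).
* The Tauc gate assumes a single linear region above the edge; spectra with
  multiple allowed transitions in-window would need segmentation first.
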