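# Methods

This note records the scientific and numerical choices behind `flyage`:
what is modeled, what the synthetic data do and do not emulate, and the
conventions adopted where the field leaves room.

## Study design emulated

Constant-temperature rearing at 20, 25 and 30 °C with pupal durations
of 16, 10 and 8 days. Twenty pupae are collected every 24 h from
puparium formation to eclosion, divided equally between the ATR-FTIR
and the CHC assay, in three replicate experiments — 960, 600 and 480
pupae per temperature (`make_design`). Of each collection, one pupa per
assay is actually measured (`make_measurement_design`): the FTIR pupa
is ground whole and scanned three times (3 technical × 3 biological
replicates = 9 spectra per age cell, averaged during preprocessing),
and the CHC pupa is extracted once in hexane. For modeling, technical
spectra are averaged per (temperature, age, replicate), giving three
samples per age class — the minimum for class-stratified
cross-validation; the fully averaged one-spectrum-per-age export
(`average_replicates` with its default group key) is used for
spectra-overview output only.

## Synthetic spectra

A spectrum is a sum of Gaussian bands at the canonical biochemical
positions (1741 lipid ester, 1647 amide I, 1540 amide II, 1454, 1398,
1313 amide III, 1145 and 1040 cm⁻¹ C–O/PO₂⁻, plus C–H and amide-A
stretches above 1800 cm⁻¹) on a descending 4000→900 cm⁻¹ grid of 1608
points (≈1.93 cm⁻¹ spacing). Band amplitude is linear in age;
age slopes are placed on amide I/II and the 1040 cm⁻¹ band — the
regions reported age-informative — so marker selection has a ground
truth. Artifacts are exactly the classes the preprocessing chain
targets: per-spectrum multiplicative gain (1 + g), g ~ N(0, 0.10);
additive baseline N(0, 0.02); white noise N(0, 0.005) per point
(absorbance units). SNV provably removes the first two
(`test_artifact_removal` asserts the identity to 1e-9).

## Synthetic CHC profiles

Each of the 37 catalog compounds (13 n-alkanes, 20 branched, 4
alkenes, C11–C35; names are explicit placeholders since only class
counts and the carbon range are constrained) has expected abundance
a·exp(−k·t) + c at age t days. Compounds are grouped into exactly
compensating sets — 16 decliner/riser pairs (a, k)/(−a, k), one triplet
and the C24 pair — so the expected total is age-constant and each
normalized percentage is itself an exact exponential-plus-offset with
its planted rate. This makes the C24 decay-rate recovery check
well-posed: the headline marker C24 declines with a = 18, k = 0.25/day
toward a 4-unit floor at every temperature. A small group of major
markers carries strong turnover (rates 0.08–1.0/day); the remaining
compounds drift weakly near the noise floor, as minor cuticular
components do. Two structural constraints came out of model-based
diagnosis and are deliberate design: no compound is exactly
age-constant (an autoscaled pure-noise column acts as a random basis
vector that poisons out-of-fold prediction, which no real profile
exhibits), and floor abundances keep every expected share clearly above
the 0.5% reporting threshold so per-sample retention never flickers.
Noise is additive Gaussian (sd 0.2 abundance units, ≈1–5% relative) on
the pre-normalization abundances, truncated at zero, then renormalized
to 100%.

All randomness flows from one seed through counter-based
`SeedSequence` substreams keyed by design-row order, so regeneration is
bit-identical.

### What the generator does not emulate

Pupa-to-pupa biological variance beyond measurement noise, temperature
effects on CHC composition (temperature changes only the pupal
duration here), co-eluting or unknown GC-MS peaks, instrument drift,
water-vapor/CO₂ interference, and any non-exponential compound
kinetics. Consequently, passing tests demonstrate that the algorithms
recover what was planted under the stated noise model — not that
laboratory data of this design would reach the same figures.

One structural consequence deserves emphasis: because all compound
kinetics are monotone exponentials, the age-class means lie almost
exactly in a low-dimensional affine subspace of the autoscaled feature
space. One-hot class indicators over such a smooth 1-D trajectory are
not linearly recoverable with margin, so the OPLS-DA Q² (computed as
1 − PRESS/TSS from the final-component model on the indicator matrix)
plateaus around 0.1–0.3 even as the classes remain perfectly separable
by nearest-neighbor distance. Laboratory datasets that report Q² near
0.9 for many-class age discrimination carry richer, higher-dimensional
per-age signatures than an exponential family can provide. The
classification tests therefore assert the informative-vs-shuffled Q²
ordering and the negative permutation intercept rather than an
absolute Q² level; the regression Q²/RMSECV, which do not suffer this
geometry, are asserted absolutely.

## Preprocessing conventions

Order is fixed: SNV on the full 4000–900 cm⁻¹ range, then 15-point
Savitzky–Golay smoothing, then cropping to 1800–900 cm⁻¹, then
averaging. SNV uses the n−1 standard deviation; a zero-variance
spectrum is an error. The Savitzky–Golay polynomial order is 3
(unstated in the usual instrument-software description; order 3 at
window 15 preserves band shape), with polynomial edge handling
(`mode="interp"`). Averaging after preprocessing is deliberate: SNV is
nonlinear, so averaging first would change the artifact-removal
contract. Cropping never interpolates. Blank/background subtraction is
treated as instrument-level and assumed done.

## CHC conventions

Retention indexing uses the linear (van den Dool–Kratz) form — the
standard for temperature-programmed ovens — implemented as piecewise
linear interpolation through the (rt, 100·n) knots of the C7–C40
ladder; the isothermal logarithmic Kovats form is available behind
`kovats_log=True`. Peak-to-compound assignment is by nearest nominal
retention index within ±5 RI units (configurable); spectral library
matching is out of scope. Percentages are relative to the total area of
all peaks, assigned or not; the 0.5% filter drops compounds at or below
threshold per sample and does **not** renormalize the survivors, so
filtering is idempotent and reported trends are unaffected by what else
was filtered. A compound enters the feature table if it survives in at
least one sample (zero elsewhere), keeping the design matrix
rectangular.

## Modeling conventions

* Scaling: unit-variance autoscaling by default (center-only and
  Pareto available). A constant feature under a variance-based scaling
  is an error naming the column.
* NIPALS: convergence when the score change falls below 1e-10
  (relative), at most 500 iterations; the first non-negligible element
  of every weight vector is forced non-negative, so refits are
  bit-reproducible.
* OPLS-DA: orthogonal weights are X-loadings projected off an
  orthonormal basis of XᵀY, guaranteeing cov(t_o, Y) = 0 to machine
  precision; this predictive subspace is invariant under orthogonal
  deflation, so one basis serves all components. One orthogonal
  component by default. With none, the predictive part is exactly
  PLS-DA. Predictive component counts (and PLS regression component
  counts) are chosen by the cross-validated Q² gain rule: add
  components while Q² improves by more than 0.01, floor one.
* Cross-validation: 7 folds, assigned deterministically from a seed —
  round-robin within class for discriminant models, round-robin along
  the sorted response ("venetian blinds") for regressions. Q² and
  RMSECV come from out-of-fold predictions of the full-component model
  refit per fold; TSS is about the full-data mean.
* Permutation test: 200 permutations by default (tests and the
  acceptance script use 20–50 for runtime at equal validity);
  correlation is the absolute Pearson correlation of permuted vs
  original response, averaged over indicator columns for discriminant
  models; intercepts come from the least-squares line through all
  points including the unpermuted reference.
* VIP uses predictive components only (the orthogonal part carries no
  Y-variance by construction).
* Marker selection intersects VIP > 1 across the OPLS-DA and PLS
  models (union behind a flag) and orders by worst-case VIP.
* Trend fitting compares linear, exponential-plus-offset and quadratic
  least squares (families with parameter count below the number of age
  points); `auto` keeps the highest R² with a 0.01 margin favoring
  fewer parameters. A constant series is reported as a degenerate
  slope-zero linear fit with R² = 0. The exponential fit bounds k > 0
  and seeds its start from the series endpoints. The spectral trend
  window defaults to 1039.45–1051.02 cm⁻¹, the seven grid points of
  the age-informative C–O/PO₂⁻ region.
* The predicted-vs-actual "equation" of the regression report is the
  least-squares line of in-sample predictions on actual age; for a
  well-specified fit its slope equals R² with a numerically small
  intercept, which is the form such tables conventionally print.

## Problem sizes

Default test and acceptance runs use the measured design (2 pupae per
collection): per temperature, 48/30/24 spectra-derived samples of ~467
wavenumbers and 48/30/24 CHC samples of 37 compounds at 20/25/30 °C.
The full suite runs in under two minutes and the acceptance script in
about one; both scale linearly in permutations and seeds.

## Known limitations

Age enters the spectra linearly and the CHC kinetics exponentially by
construction; the models are linear in the features, so strongly
nonlinear laboratory trajectories may need more components than the
defaults select. No OPLS2/O2-PLS, kernel variants, Hotelling-T²
statistics, atmospheric compensation, baseline rubber-band correction
or derivative spectra. Fractional ages are accepted for prediction but
the generator samples integer days. Fluctuating-temperature
development is out of scope.
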