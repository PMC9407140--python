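# Methods

`teaspec` implements a complete visible/NIR hyperspectral chemometrics
workflow for black-tea processing: raw digital numbers (DN) are corrected
to reflectance against black/white references, region-of-interest (ROI)
mean spectra are preprocessed (MSC, first derivative, Savitzky–Golay),
characteristic wavelengths are selected (SPA, CARS, UVE), and PLS / SVR /
random-forest models predict three quality components — tea polyphenols
(TPs), free amino acids (FAA) and caffeine (CAF), all as dry-mass-fraction
percent. Predicted content trajectories drive a plateau rule that judges
withering and fermentation degree. Because no public dataset accompanies
the workflow, a first-class synthetic generator supplies data with the
statistical structure the analysis assumes.

## Reflectance correction and cube I/O

A scene is a `height x width x 360` DN stack over 391–1010 nm. The
correction is

    R = dn_max * (R0 - B) / (W - B)

with `W` the whiteboard image, `B` the dark-current image and
`dn_max = 65,552` (kept verbatim as the sensor's stated DN ceiling even
though it differs from 2^16 − 1; it is configurable). Pixels where
`W = B` are masked invalid; out-of-range corrected values (specular
highlights) are *retained* and counted, never clipped — clipping would
bias the ROI mean. Cubes round-trip through a deliberately minimal ENVI
dialect: text `.hdr` plus raw binary, band-sequential, little-endian,
unsigned 16/32-bit; no other interleave or dtype is accepted, and header
defects produce distinct errors.

## Assay computations

FAA and CAF absorbances are inverted through linear standard curves
(`A = slope·C + intercept`; R² is the squared Pearson correlation). The
content formulas are implemented with their printed dilution constants:

    TPs = A1 · 1.957 · 2 / 1000 · (V1/V2) / (m·ω) · 100
    FAA = C1/1000 · (V1/V2) / (m·ω) · 100
    CAF = C2 · V1/1000 · (100/10) · (50/25) / (m·ω) · 100

Units: `C1` is mg theanine in the measured aliquot, `C2` mg/mL caffeine,
`V1/V2` total/aliquot volumes (mL), `m` sample mass (g), `ω` dry-matter
fraction on (0, 1]. All three formulas are homogeneous of degree 1 in the
absorbance/concentration input and −1 in `m` and `ω`, which the tests
exercise as a randomized scaling law.

## Preprocessing

The default chain is `msc → d1 → sg`, operating on absorbance
`A = −log R` (reflectance floored at 1e−6 before the log; a
reflectance-domain switch exists).

* **MSC** regresses each spectrum on a reference (OLS,
  `x_i ≈ a_i·ref + b_i`) and returns `(x_i − b_i)/a_i`. The reference
  defaults to the column mean; inside the pipeline it is frozen at the
  *training-set* mean so the test set never leaks into preprocessing.
  MSC removes per-sample affine distortion exactly and is idempotent for
  a fixed reference.
* **d1** is the plain forward difference `(y_{i+1} − y_i)/Δλ` (per nm).
  It is deliberately distinct from the Savitzky–Golay derivative (also
  available); the output axis moves to interval midpoints so selected
  bands are located without bias, and the band count drops by one.
* **S-G** smoothing uses local least-squares polynomials
  (window 11, polyorder 3 by default; the window is a free choice, kept
  small enough not to blunt the ~35–80 nm synthetic features). Edges are
  handled by evaluating the boundary polynomial fits, so polynomials up
  to the polyorder are reproduced exactly everywhere.

Step order is configurable; the applied steps are recorded on the matrix
and serialized into its CSV header.

## Band selection

All three selectors consume the preprocessed training matrix only and
return sorted unique band indices plus diagnostics; identical seeds give
identical selections.

**SPA.** For every start band, a chain grows by successive projections:
the next band maximises the residual norm after projecting out the span
of the chain so far (columns mean-centered). Every (start, size) chain
with sizes 5–30 is scored by 5-fold RMSECV of an OLS fit; the minimum
wins, ties toward smaller size then smaller start index. The evaluation
computes all prefix fits of a chain from a single QR per fold
(triangular inverse + cumulative sums), which keeps the 360-start sweep
to a couple of seconds.

**CARS.** 50 Monte Carlo runs. Run *i* fits PLS on a random 80% sample
subset restricted to the surviving bands, ranks bands by |coefficient|,
keeps the top `ceil(p·r_i)` where `r_i = a·e^(−k·i)` is calibrated so run
1 retains all `p` bands and run N retains 2 (`a = (p/2)^{1/(N−1)}`,
`k = ln(p/2)/(N−1)`), then performs adaptive reweighted sampling: `p`
draws with replacement, probability proportional to |coefficient|,
unique survivors kept. Drawing `p` times (rather than the retained
count) matters: it leaves the exponential schedule, not the resampling,
in control of the contraction rate. Each run's survivor set is scored by
5-fold PLS RMSECV on all training samples; the minimum-RMSECV set is
returned (ties toward fewer bands). The ARS stage can be disabled for a
fully schedule-driven, deterministic run.

**UVE.** The matrix is augmented with as many uniform noise bands as
real ones, scaled to 1e−10. PLS models are fitted across a
leave-one-out scheme and each coefficient's stability
`c_j = mean(b_j)/sd(b_j)` is computed over folds. The cutoff is the 99th
percentile of the |stability| of the *noise* bands; real bands above the
cutoff are retained. Noise bands can never be retained by construction.
Zero fold-variance coefficients get signed-infinite stability and are
logged.

**PLS component count inside selectors** is chosen by 5-fold inner CV
with the one-standard-error rule: the smallest count whose RMSECV is
within one SE of the minimum. The plain argmin occasionally prefers a
component that improves RMSECV marginally while adding fold-to-fold
coefficient jitter, which degrades UVE's stability statistic; one-SE is
the standard parsimony rule for exactly this situation and is the
package default everywhere components are auto-selected (plain argmin
available via a flag).

## Models and evaluation

PLS is implemented in-repo (single-response NIPALS with X/y centering,
closed-form per-component extraction, coefficient path for all
truncations; equals OLS at full rank — asserted against both a least
squares oracle and an independent reference implementation). SVR and RF
are thin contracts over scikit-learn: SVR with RBF kernel, `C = 10`,
`ε = 0.1`, on standardised features *and* target (ε is then in SD
units, which keeps the default robust across analytes of different
scales); RF with 300 trees, seeded.

The 4:1 split draws `round(n/5)` test samples uniformly (116 → 93/23).
Metrics per grid cell: RC²/RMSEC on the training set, RMSECV from seeded
5-fold CV on the training set, RP²/RMSEP on the test set, and
`RPD = sd(y_test, ddof=1)/RMSEP`. R² is `1 − SSE/SST` throughout. RPD
below 1.4 flags a cell as poor; an (numerically) exact fit flags RPD as
undefined rather than infinite. The identity `RPD·RMSEP = sd(y_test)`
holds to 1e−12 on every row and is asserted in the tests.

Band selection and model fitting see training rows only; a leakage-guard
test permutes the test-set chemistry and asserts that no selected band
changes.

## Degree judgment

Withering watches FAA, fermentation watches TPs. A time point is
*moderate* when the trailing window of `w = 3` points spans no more than
5% of the overall series range; once reached, the verdict stays moderate.
Two times are reported: `detected_at`, the first time point whose
trailing window is stable, and `plateau_onset_h`, the start of that
window — the plateau's beginning. On the noise-free default
trajectories, withering's plateau onset is 16 h (detection at 18 h, when
three stable points have accumulated) and fermentation's is 3 h
(detection at 4 h).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study layout exactly: 19 hourly withering
points and 10 half-hourly fermentation points, 4 replicates each — 116
samples by 360 bands.

**Trajectories** are linear ramps with plateaus: withering TPs
12.90 → 10.70% over 1–16 h then flat; withering FAA 4.30 → 5.95% with
its maximum at 16 h then flat; fermentation TPs 10.70 → 6.40% over
0–3 h then flat; CAF constant at 4.85%; fermentation FAA constant at
5.00%. Replicate variation (leaf-to-leaf, present in the spectra) has SD
0.35 / 0.15 / 0.25% for TPs/FAA/CAF; assay measurement error (present
only in the reported chemistry) has SD 0.25 / 0.05 / 0.10%. The split
into two noise layers is what gives each analyte a realistic,
analyte-specific R² ceiling (TPs highest, CAF lowest): a model can at
best recover the true content, never the assay error. All values are
clipped to the observed envelopes (TPs [6.00, 13.28], FAA [4.11, 6.13],
CAF [4.21, 5.52]%; clipping is logged, or raises in strict mode).

**Spectra** follow Beer–Lambert mixing of synthetic Gaussian
absorptivity profiles. Three design features matter:

* Each analyte's profile height is set so that its *concentration
  variation* contributes a comparable absorbance signal (~0.05–0.1 AU);
  since CAF varies by only ~0.25% against TPs' ~2%, CAF's per-percent
  absorptivity is several times larger. The signatures are synthetic —
  nothing in the workflow depends on their placements, only on their
  linear independence (the profile matrix is well-conditioned).
* A strong structured leaf-matrix background (~1–1.4 AU, three broad
  Gaussians, per-sample concentration uniform in [0.97, 1.03]) dominates
  the mean spectrum. This is both physically sensible (leaf water,
  pigments and structure dwarf minor constituents) and necessary for the
  preprocessing model: MSC divides by a fitted slope, and when the mean
  spectrum is dominated by the analytes themselves that division mixes
  the dominant analyte's variation into every band and buries the weak
  ones. With a background-dominated reference the distortion is second
  order.
* Sensor noise is i.i.d. on reflectance with SD 5e−5 mid-spectrum,
  rising quadratically to 2× at the range edges (detector quantum
  efficiency rolloff). The tiny magnitude reflects that each spectrum is
  an ROI mean over thousands of pixels; the edge rolloff is what makes
  band selection non-trivial — edge bands are genuinely harmful after
  the derivative step, so selectors that drop them beat the full
  spectrum.

Per-sample distortions (multiplicative slope 0.97–1.03, additive offset
±0.05 AU, linear drift ±1e−4 AU/nm) are applied in absorbance, then
`R = exp(−A)` clipped to [0, 1], then noise, floored at a small positive
reflectance. With all ranges degenerate and zero noise the map is
exactly linear in absorbance — the tests assert superposition and exact
OLS recovery of concentrations.

What the generator does **not** emulate: real tea spectral signatures,
radiative transfer or leaf optics, spatial texture, drying, or
wavelength-dependent instrument line shape. Passing tests therefore
demonstrate that the *pipeline machinery* recovers known structure under
the stated noise model — not that the specific wavelengths it selects
would be the chemically meaningful ones for real tea.

**Cubes** invert the correction formula: given a reflectance spectrum on
the DN scale, the raw cube is `round(B + r/dn_max·(W−B))` against
emitted references (defaults `W = dn_max`, `B = 0`, under which the
per-pixel round-trip error is at most 0.5 DN; narrower reference spans
scale the bound by `dn_max/(W−B)`).

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; per-task seeds are derived
  deterministically and kept below 2³¹. Same config + seed ⇒
  byte-identical grids.
* MSC raises (naming the sample) when a spectrum is flat against the
  reference; the reference itself must be non-constant.
* PLS stops extracting components when the deflated matrix carries no
  covariance with the residual response; zero-variance responses raise.
* SPA chains truncate (with a log note) on rank deficiency; rank-deficient
  OLS prefixes score as +inf rather than producing unstable fits.
* CARS stops early if the survivor set collapses below two bands and
  evaluates what exists; UVE falls back to the single most stable band
  if nothing clears the cutoff.
* The grid isolates failures per cell: an error is recorded in the
  report row and the remaining cells proceed.

## Problem sizes

Default runs use the study-sized dataset (116 × 360). A full
3-analyte × 3-selector × 3-model grid takes roughly half a minute on one
CPU; the repeated-seed robustness checks in the test suite run reduced
grids (two analytes, PLS only) to stay quick.

## Known limitations

* The RMSE columns of the evaluation report are on the natural percent
  scale; published tables of this kind sometimes print them on an
  undocumented fractional scale, so only the RPD identity — not RMSE
  magnitudes — is meaningful for cross-study comparison.
* Whether published RP² figures mean squared correlation or
  `1 − SSE/SST` is often ambiguous; this package uses the latter
  definition consistently.
* CARS returns the global minimum-RMSECV run; with low noise the CV
  estimate is flat across set sizes and the returned count can
  occasionally be large. This is inherent to the argmin rule, not a
  defect of the schedule.
* SVR and RF hyperparameters are sensible fixed defaults, not tuned per
  dataset; no hyperparameter search is performed beyond the PLS
  component count.
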