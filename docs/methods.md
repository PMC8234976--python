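# Methods

## Forward model

A measured absorbance spectrum of filtered seawater in a b-cm cuvette is
modelled as

    A(λ) = b · (ε_NO3(λ) C_NO3 + ε_NO2(λ) C_NO2 + ε_salt(λ) S) + A_CDOM(λ) + noise

with concentrations in mol/L (the API takes µM), salinity S in psu, and the
chromophoric-dissolved-organic-matter background

    A_CDOM(λ) = a₀ e^{S_cdom (λ₀ − λ)} + k,   λ₀ = 300 nm.

The CDOM term is itself an absorbance measured through the same cuvette and
therefore sits outside the pathlength factor; `simulate_spectrum` offers the
alternative placement inside b for sensitivity analysis (off by default).
The offset k absorbs cuvette scattering and instrument drift.

## PLS calibration

`PLSRegressor` implements NIPALS on mean-centred X and Y: for each factor,
power iteration on the (X, Y residual) pair yields a weight vector w (unit
norm), scores t = X w, Y-loadings q = Yᵀt/tᵀt, and deflation X ← X − t pᵀ,
Y ← Y − t qᵀ with p = Xᵀt/tᵀt. Iteration starts from the residual-Y column
of largest variance (deterministic), converges on the score vector to 1e-12
with a 500-iteration cap, and stops extracting factors when either residual
is numerically exhausted. Regression coefficients are B = W (PᵀW)⁻¹ Qᵀ,
built incrementally so a single decomposition yields coefficients at every
truncation level. With a single response the inner iteration is exact in one
pass (PLS1). No unit-variance scaling is applied to Y: pooled PLS2 error
sums must remain in original response units so that the pooled PRESS equals
the sum of the per-response PRESS values.

## Factor selection

`loo_cv` leaves out one sample at a time, re-centres the remaining n−1
samples (anything else leaks the held-out sample), refits, and accumulates
PRESS_h per factor count; RESS_h is the full-data fitted residual. A factor
count is significant while

    Q²_h = 1 − PRESS_h / RESS_{h−1} ≥ 0.0975   (= 1 − 0.95², p ≤ 0.05).

`select_factors` scans h = 2, 3, … and keeps the **last significant h**,
tolerating insignificant values before the first significant one and
stopping at the first insignificant value after it. The tolerance for
leading failures matters in practice: a response whose first factor is spent
modelling a co-varying interferent can have Q²₂ below threshold yet gain
sharply at h = 3–4, and the published reference sequences (nitrite: 0.02,
0.48, 0.95, −1.30, …) have exactly this shape — the rule returns 4 on all
four published sequences. When RESS_{h−1} is already at numerical zero
(noiseless synthetic data), further factors are declared insignificant
rather than dividing by ~0.

## CDOM correction

`fit_cdom` estimates (a₀, S_cdom, k) by nonlinear least squares over
275–295 nm, where nitrate, nitrite and sea salt are transparent;
initialisation is a log-linear regression of A − k₀ (k₀ slightly below the
window minimum) and refinement uses trust-region-reflective least squares.
Two bounds stabilise the fit: S_cdom ∈ [0.001, 0.1] nm⁻¹ (prevents
divergence on noise-only windows) and |k| ≤ 0.01 AU (a scattering/drift
offset is physically a few mAU; left free, k trades off against a₀ and
S_cdom on the narrow fit window and roughly doubles the extrapolation
error). The fitted curve, including k, is subtracted over the analysis
window; small negative corrected absorbances are kept. Correction is applied
to every spectrum — standards and unknowns alike — because realistic
calibration standards are spiked natural seawater and contain CDOM. Spectra
with no decaying signal in the fit window raise a degenerate-fit error and
pass through uncorrected.

**Intrinsic extrapolation variance.** The three-parameter exponential fitted
on 21 points of a 275–295 nm window and extrapolated 35–80 nm into the deep
UV has, at a noise floor of 5×10⁻⁴ AU, a Cramér–Rao prediction standard
deviation of ~0.01 AU at 240 nm and ~0.03–0.07 AU at 215 nm for typical
coastal CDOM (a₀ 0.01–0.1 AU at 300 nm, slope 0.014–0.03 nm⁻¹). This
residual — not the photometric noise — is what limits salinity and nitrite
prediction accuracy in the corrected window, and no per-sample unbiased fit
can do better. The tests assert the measured achievable residual (median
max-residual ≤ 0.025 AU over 215–240 nm for a mid-range background), about
an order of magnitude below the uncorrected background.

## Wavelength selection (iPLS)

`ipls_intervals` screens sliding 16-point (15 nm) windows advancing 10 nm
over 200–300 nm, the final window clipped to end exactly at 300 nm (…,
270–285, 285–300) — reproducing the conventional irregular last interval.
Each window is scored by calibrating inside it (factor count from the Q²
rule) and evaluating RMSEP, R² and mean relative error on the prediction
set; because µM and psu are incommensurable, the pooled score is the mean
over responses of RMSEP divided by that response's calibration range. A
config flag substitutes inner cross-validation for the prediction set if a
leakage-free score is wanted. `refine_window` then hill-climbs the two
boundaries at 1 nm steps, alternately proposing ±1 nm moves of the low and
high edge and accepting a move only if the pooled score strictly decreases,
with a 5-point minimum width; the full audit trail of accepted windows is
returned and is monotone by construction.

## CLS baseline

`fit_cls` fits the full forward model — three known absorptivity curves plus
the CDOM exponential and offset — to a *raw* spectrum (the CDOM term lives
inside the CLS model, so no prior correction is applied). Only the CDOM
slope enters nonlinearly, so the problem is separable: for each candidate
slope on a 46-point grid over [0.005, 0.05] nm⁻¹ the remaining five
parameters are an exact linear least-squares solve, and the best bracket is
polished by bounded scalar minimisation — deterministic, no multistart.
Concentrations are deliberately unconstrained: a slightly negative estimate
is an honest statement about a near-zero analyte and mirrors the PLS side.
`build_library_from_standards` estimates the absorptivity curves per
wavelength by zero-intercept least squares of absorbance/pathlength against
known standard compositions. The default CLS window equals the PLS window
(215–240 nm) for comparability; 200–240 nm conditions the fit better and is
available.

## Synthetic data generator

`synth` emulates the measurement campaign the calibration assumes: the
embedded reference design (34 calibration samples spanning 0–85.62 µM NO₃⁻,
0–20.12 µM NO₂⁻, 0–33.9 psu; 20 prediction samples inside those ranges),
Beer–Lambert mixing at a 3.0 cm pathlength, per-sample CDOM draws
(a₀ ~ U(0.01, 0.1) AU, slope ~ U(0.014, 0.03) nm⁻¹, k ~ U(0, 0.005) AU —
the coastal/estuarine literature range), additive homoscedastic Gaussian
noise of 5×10⁻⁴ AU (typical dual-beam photometric noise), and optionally an
unmodelled Gaussian interferent band (default 225 nm centre, 10 nm sd),
standing in for substances such as hydrogen sulfide that real seawater
contributes but no calibration model includes.

The absorptivity curves are parametric surrogates — Gaussian bands at
205 nm (sd 11, peak 9600 L mol⁻¹ cm⁻¹) and 210 nm (sd 13, peak 5400) for
nitrate and nitrite, an exponential decay (scale 8 nm, 0.02 psu⁻¹ cm⁻¹ at
200 nm) for sea salt — chosen so the three components overlap strongly over
200–240 nm, reproducing the deconvolution difficulty the method addresses.
They are not calibrated physical constants, and every validation criterion
is a recovery of known simulated truth, never a check of the surrogates.

**What the generator does not emulate**, and what passing tests therefore do
not show about real data: detector nonlinearity, stray light and the
photometric-error blowup at high absorbance; temperature dependence of the
bromide spectrum; turbidity; wavelength-calibration error. One consequence
is structural: in real measurements the 200–215 nm region is degraded by
absorbance saturation (salt + CDOM + nitrate push A beyond 2–4 in a 3 cm
cell), which is why published wavelength optimisation lands at 215–240 nm.
In the linear, homoscedastic synthetic world that region keeps its full
information content, so iPLS screening on generator output legitimately
anchors windows at 200 nm. The wavelength-selection machinery is therefore
validated on data whose truth-bearing bands are confined to ~212–243 nm,
where it correctly brackets the informative region.

## Numerical choices

- NIPALS tolerance 1e-12 on the score vector, 500 iterations per factor;
  early stop when residual X or Y variance falls below 1e-28 of its start.
- Q² denominators below 1e-14 of the response variance mark the factor
  insignificant instead of dividing.
- CDOM optimiser: trf, xtol/ftol/gtol 1e-13, max 5000 evaluations; bounds as
  above; convergence flag from optimiser status.
- CLS slope polish: bounded Brent on the bracketing grid interval, xatol
  1e-10; design matrices with condition number above 1e10 raise with a
  diagnostic rather than returning garbage.
- Windows are inclusive: "215–240 nm" is 26 points at 1 nm spacing. Bounds
  must lie on the grid; nothing snaps silently. Descending instrument
  exports are re-sorted on read (logged).
- Replicate precision uses the n−1 sample standard deviation; relative
  error uses per-term absolute values by default (signed mode available)
  and excludes true-zero samples with an explicit count.

## Problem sizes

Tests and validation runs use the embedded 34 + 20 reference design at
101 wavelengths; Monte-Carlo checks use 20–100 noise draws, the
window-selection study 20 seeds, and the PLS-vs-CLS contrast 50 paired
simulations of the prediction design — sizes at which every statistic
reported stabilises to well inside its test tolerance.

## Known limitations

- Salinity (and to a lesser degree nitrite) accuracy is bounded by the CDOM
  extrapolation variance discussed above; a wider or second fit window, or
  shrinkage of per-sample slopes toward a campaign mean, would reduce it but
  changes the published procedure.
- The Q² rule stops at the first insignificant factor after a significant
  one; it will not discover a later PRESS minimum (by design).
- Spectra mixing pathlengths must be rescaled explicitly before modelling;
  the containers refuse to build a matrix across cuvettes.
- CLS assumes the absorptivity library and the unknown share one instrument
  and temperature; no bromide temperature correction is applied.
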