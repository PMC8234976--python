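# uvnitro

Reagent-free, simultaneous determination of nitrate (NO₃⁻), nitrite (NO₂⁻)
and salinity in seawater from a single deep-UV absorbance scan (200–300 nm),
by partial-least-squares (PLS) calibration with exponential CDOM background
correction.

## The problem

All three major UV absorbers in seawater — nitrate, nitrite and sea salt
(bromide/chloride) — absorb in the same 200–240 nm region, and chromophoric
dissolved organic matter (CDOM) adds a smoothly decaying background on top.
Classical single-wavelength UV nitrate methods fail in estuarine and coastal
water for exactly this reason. `uvnitro` resolves the overlap
chemometrically, which makes a plain spectrophotometer (or an in-situ UV
sensor) a nutrient analyser with no Griess reagents, no cadmium columns and
no waste stream. Its audience is marine biogeochemists and sensor builders.

## The method

For a calibration set of n spectra, X (n × m absorbances) and Y (n × 3
responses: NO₃⁻ µM, NO₂⁻ µM, salinity psu) are mean-centred and decomposed
by NIPALS as

    X = T Pᵀ + E,    Y = U Qᵀ + F,

with scores chosen to maximise the T–U covariance. Prediction is
Ŷ = (X − x̄) B + ȳ with B = W (PᵀW)⁻¹ Qᵀ. PLS2 shares one factor set across
the three responses; PLS1 fits each response separately.

The factor count h is selected by leave-one-out cross-validation: with
PRESS_h the sum of squared LOO prediction errors at h factors and RESS_{h−1}
the full-data residual at h−1 factors,

    Q²_h = 1 − PRESS_h / RESS_{h−1},

and a factor is kept while Q²_h ≥ 0.0975 (= 1 − 0.95², significance at
p ≤ 0.05). On the published reference study's cross-validation sequences
this rule selects **4 factors** for PLS1 on each response and for PLS2.

Before calibration, each spectrum's CDOM background

    A_CDOM(λ) = a₀ e^{S(λ₀−λ)} + k,    λ₀ = 300 nm

is fitted over 275–295 nm (where the analytes are transparent) and
subtracted from the analysis window, by default 215–240 nm. An interval-PLS
(iPLS) screen of sliding 16-point windows plus greedy boundary refinement is
provided for wavelength selection, and a classical-least-squares (CLS)
baseline fits the full Beer–Lambert model with known absorptivity curves
directly. A Beer–Lambert forward simulator with CDOM and instrument noise
stands in for the spectrophotometer.

## Worked example

Simulate the reference spiked-seawater design (34 calibration + 20
prediction samples, per-sample CDOM, 5×10⁻⁴ AU noise), calibrate, predict
and evaluate:

```bash
uvnitro simulate --design reference --seed 7 --out sim
uvnitro calibrate --spectra sim/calibration_spectra.csv \
    --compositions sim/calibration_compositions.csv \
    --window 215:240 --out model.json
uvnitro predict --model model.json \
    --spectra sim/prediction_spectra.csv --out predictions.csv
uvnitro evaluate --predictions predictions.csv \
    --actual sim/prediction_compositions.csv --out metrics.csv
```

The calibrate step prints the cross-validated factor choice:

```
selected 4 factor(s); PRESS=[7762.4   7864.753 2074.056   25.354   26.172   33.829   46.639]
```

PRESS drops by two orders of magnitude up to 4 factors and rises again
beyond — adding a 5th factor only models noise. Evaluation against the known
compositions prints per-response prediction-set statistics:

```
response    rmsep       r2       re  re_excluded  n
     no3 0.454062 0.999584 0.053978            0 20
     no2 0.329341 0.993999 0.146878            0 20
salinity 0.994255 0.988452 0.060407            0 20
```

i.e. nitrate recovered to ±0.45 µM over a 0–86 µM range (R² > 0.999),
nitrite to ±0.33 µM over 0–20 µM, salinity to ±1 psu over 0–34 psu. The
residual salinity error is dominated by the variance of the CDOM
extrapolation from the 275–295 nm fit window into the deep UV (see
`docs/methods.md`). `predictions.csv` carries one row per unknown with
replicate mean ± SD when several scans share a `sample_id`.

The same steps are available as library calls (`uvnitro.calibrate`,
`uvnitro.predict_set`, `uvnitro.run_pipeline`) on `SpectraSet` objects, and
the estimators `PLSRegressor` / `CLSRegressor` follow scikit-learn
conventions (`fit`/`predict`/`get_params`).

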