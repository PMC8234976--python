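"""Reference spiked-seawater calibration study: design and CV summaries.

The published reference study for this method prepared 34 calibration and 20
prediction samples by spiking estuarine seawater with nitrate and nitrite
standards, spanning 0-85.62 uM nitrate, 0-20.12 uM nitrite and 0-33.90 psu
salinity, and reported the leave-one-out cross-validation summaries (PRESS and
Q-squared per factor count, 215-240 nm window) for PLS1 on each response and
for PLS2. Those printed values are carried here verbatim: the design drives
the synthetic generator, and the Q-squared rows exercise the factor-selection
rule against its published outcome (4 factors for every model).
"""

from __future__ import annotations

import numpy as np

from .spectra import Composition

__all__ = [
    "reference_design",
    "REFERENCE_Q2",
    "REFERENCE_PRESS",
    "REFERENCE_SELECTED_FACTORS",
]

# (no3_uM, no2_uM, salinity_psu), calibration samples 1..34
_CALIBRATION = [
    (0.00, 0.00, 0.00),
    (0.50, 0.00, 0.00),
    (1.98, 0.00, 0.00),
    (9.92, 0.00, 0.00),
    (49.61, 0.00, 0.00),
    (0.00, 0.50, 0.00),
    (0.00, 2.01, 0.00),
    (0.00, 10.06, 0.00),
    (0.00, 20.12, 0.00),
    (0.00, 0.00, 6.78),
    (0.00, 0.00, 16.95),
    (0.00, 0.00, 27.12),
    (0.00, 0.00, 33.90),
    (4.75, 0.96, 0.00),
    (20.89, 5.30, 0.00),
    (55.12, 0.00, 15.07),
    (9.45, 0.00, 25.83),
    (0.97, 0.00, 33.24),
    (0.00, 9.15, 12.33),
    (0.00, 1.93, 26.08),
    (0.00, 0.50, 33.56),
    (4.75, 0.96, 32.44),
    (20.89, 5.30, 26.76),
    (0.95, 0.97, 26.08),
    (5.25, 1.06, 17.94),
    (11.67, 2.96, 19.94),
    (8.27, 1.05, 14.13),
    (25.44, 10.32, 13.91),
    (4.75, 0.96, 8.11),
    (11.81, 2.40, 10.09),
    (20.89, 5.30, 8.92),
    (52.22, 10.59, 8.92),
    (85.62, 2.22, 1.51),
    (26.85, 6.69, 8.86),
]

# prediction samples 1..20 (randomly designed within the calibration ranges)
_PREDICTION = [
    (9.23, 1.17, 12.61),
    (0.49, 0.49, 33.24),
    (4.61, 2.34, 25.23),
    (11.02, 2.79, 30.13),
    (27.54, 7.95, 9.32),
    (34.20, 6.65, 12.59),
    (43.52, 8.50, 10.06),
    (39.12, 14.60, 11.25),
    (23.24, 4.26, 29.32),
    (9.68, 4.05, 11.23),
    (67.18, 11.04, 7.04),
    (71.87, 4.86, 20.69),
    (66.87, 5.07, 20.54),
    (18.66, 0.52, 9.58),
    (32.56, 15.97, 3.56),
    (12.35, 8.68, 23.98),
    (29.95, 3.76, 32.00),
    (56.71, 3.56, 12.54),
    (18.11, 2.83, 23.65),
    (35.90, 2.91, 26.57),
]


def reference_design() -> tuple[list[Composition], list[Composition]]:
    """The reference study's calibration (34) and prediction (20) compositions."""
    cal = [Composition(*row) for row in _CALIBRATION]
    pred = [Composition(*row) for row in _PREDICTION]
    return cal, pred


#: published Q-squared sequences for factor counts h = 2..7 ('-' at h=1)
REFERENCE_Q2: dict[str, np.ndarray] = {
    "pls1_no3": np.array([0.17, 0.77, 0.99, -0.36, -0.75, -2.13]),
    "pls1_no2": np.array([0.02, 0.48, 0.95, -1.30, -2.59, -2.35]),
    "pls1_salinity": np.array([0.72, 0.92, 0.77, -0.53, -0.78, -1.00]),
    "pls2": np.array([0.47, 0.80, 0.95, -0.68, -0.95, -0.91]),
}

#: published PRESS sequences for factor counts h = 1..7 (original response units,
#: pooled across the three responses for the PLS2 row)
REFERENCE_PRESS: dict[str, np.ndarray] = {
    "pls1_no3": np.array([1962.0, 1391.0, 327.6, 2.39, 2.51, 2.53, 3.96]),
    "pls1_no2": np.array([614.3, 504.6, 191.7, 7.24, 8.11, 9.13, 5.81]),
    "pls1_salinity": np.array([3552.0, 951.9, 61.34, 9.64, 11.67, 12.01, 11.67]),
    "pls2": np.array([7432.0, 3651.0, 543.4, 19.27, 21.89, 23.17, 18.79]),
}

#: factor count the reference study selected for every model
REFERENCE_SELECTED_FACTORS = 4
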