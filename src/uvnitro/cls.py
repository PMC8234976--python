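"""Classical least squares (CLS) baseline on the Beer-Lambert forward model.

CLS fits a measured spectrum directly as

    A(lambda) = b * (eps_no3 C_no3 + eps_no2 C_no2 + eps_salt S)
                + a0 exp(s (lambda0 - lambda)) + k

with known absorptivity curves and all five free parameters (three
concentrations plus the two-parameter-plus-offset CDOM background) fitted
jointly. Unlike the PLS route, the raw (uncorrected) spectrum is used: the
CDOM term lives inside the CLS model itself.

Only the spectral slope ``s`` enters nonlinearly, so the fit is separable
(variable projection): for each candidate slope the remaining parameters are
an exact linear least-squares solve; a coarse slope grid plus bounded scalar
minimisation locates the global minimum deterministically, without multistart
heuristics. Concentrations are intentionally unconstrained -- a slightly
negative fitted concentration is an honest statement of a near-zero analyte,
mirroring the PLS predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .spectra import AbsorbanceSpectrum, Composition, SpectraSet
from .synth import CDOMParams, ComponentLibrary

__all__ = [
    "CLSResult",
    "build_library_from_standards",
    "fit_cls",
    "CLSRegressor",
]

DEFAULT_WINDOW = (215.0, 240.0)
DEFAULT_SLOPE_BOUNDS = (0.005, 0.05)  # nm^-1
_COND_LIMIT = 1e10


@dataclass(frozen=True)
class CLSResult:
    """Joint CLS fit of one spectrum: composition + CDOM coefficients."""

    composition: Composition  # may be negative (unconstrained fit)
    cdom: CDOMParams
    rss: float
    converged: bool


def build_library_from_standards(standards: SpectraSet) -> ComponentLibrary:
    """Estimate absorptivity curves from standard-solution spectra.

    Per wavelength, zero-intercept least squares of absorbance/pathlength
    against the known compositions. Standards are typically single-component
    solutions in deionized water (blanks allowed), but any full-rank design
    works. Raises if some component never appears at a nonzero level.
    """
    C = standards.Y.copy()
    C[:, :2] *= 1e-6  # uM -> mol/L so curves come out in L mol^-1 cm^-1
    for j, name in enumerate(Composition.names()):
        if np.all(C[:, j] == 0):
            raise ValueError(f"no nonzero standard for component {name!r}")
    A = standards.X / standards.pathlength
    if np.linalg.matrix_rank(C) < 3:
        raise ValueError("standards design is rank-deficient; components not separable")
    eps, *_ = np.linalg.lstsq(C, A, rcond=None)
    eps = np.clip(eps, 0.0, None)  # noise can push transparent regions < 0
    return ComponentLibrary(standards.grid, eps[0], eps[1], eps[2])


def fit_cls(
    s: AbsorbanceSpectrum,
    lib: ComponentLibrary,
    window: tuple[float, float] = DEFAULT_WINDOW,
    slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
    slope_grid: int = 46,
    lambda0: float = 300.0,
) -> CLSResult:
    """Separable CLS fit of one raw spectrum over ``window``.

    A grid of ``slope_grid`` candidate CDOM slopes over ``slope_bounds`` is
    scanned, solving the linear subproblem in (C_no3, C_no2, salinity, a0, k)
    exactly at each; the best bracket is polished by bounded scalar
    minimisation. Returns concentrations in uM / psu.
    """
    lo, hi = window
    sw = s.window(lo, hi)
    libw = lib.window(lo, hi)
    lam = libw.grid.values
    b = s.pathlength
    base = np.column_stack(
        [
            b * libw.eps_no3 * 1e-6,  # per uM
            b * libw.eps_no2 * 1e-6,
            b * libw.eps_salt,
            np.zeros_like(lam),  # CDOM exp column, filled per slope
            np.ones_like(lam),
        ]
    )
    y = sw.absorbance

    def solve(slope: float) -> tuple[float, np.ndarray]:
        M = base.copy()
        M[:, 3] = np.exp(slope * (lambda0 - lam))
        cond = np.linalg.cond(M)
        if cond > _COND_LIMIT:
            raise np.linalg.LinAlgError(
                f"CLS design matrix is ill-conditioned in window {window} "
                f"(cond = {cond:.3g}); widen the window"
            )
        theta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ theta
        return float(r @ r), theta

    slopes = np.linspace(slope_bounds[0], slope_bounds[1], slope_grid)
    rss_grid = np.array([solve(sl)[0] for sl in slopes])
    i = int(np.argmin(rss_grid))
    lo_s = slopes[max(i - 1, 0)]
    hi_s = slopes[min(i + 1, slope_grid - 1)]
    res = minimize_scalar(
        lambda sl: solve(sl)[0],
        bounds=(lo_s, hi_s),
        method="bounded",
        options={"xatol": 1e-10},
    )
    s_best = float(res.x) if res.fun <= rss_grid[i] else float(slopes[i])
    rss, theta = solve(s_best)
    return CLSResult(
        composition=Composition(float(theta[0]), float(theta[1]), float(theta[2])),
        cdom=CDOMParams(a0=float(theta[3]), s=s_best, k=float(theta[4]), lambda0=lambda0),
        rss=rss,
        converged=bool(res.success),
    )


class CLSRegressor(RegressorMixin, BaseEstimator):
    """Estimator wrapper over the separable CLS fit.

    ``fit`` builds the absorptivity library from standard spectra (or accepts
    a pre-measured one); ``predict`` fits each raw spectrum jointly with its
    own CDOM background and returns the composition matrix in uM/psu.
    """

    def __init__(
        self,
        window: tuple[float, float] = DEFAULT_WINDOW,
        slope_bounds: tuple[float, float] = DEFAULT_SLOPE_BOUNDS,
        slope_grid: int = 46,
        lambda0: float = 300.0,
        library: ComponentLibrary | None = None,
    ):
        self.window = window
        self.slope_bounds = slope_bounds
        self.slope_grid = slope_grid
        self.lambda0 = lambda0
        self.library = library

    def fit(self, standards: SpectraSet | None = None, y=None) -> "CLSRegressor":
        if standards is not None:
            self.library_ = build_library_from_standards(standards)
        elif self.library is not None:
            self.library_ = self.library
        else:
            raise ValueError("provide standards or a pre-measured library")
        return self

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        if not hasattr(self, "library_"):
            raise ValueError("CLSRegressor is not fitted")
        self.results_ = [
            fit_cls(
                s,
                self.library_,
                window=self.window,
                slope_bounds=self.slope_bounds,
                slope_grid=self.slope_grid,
                lambda0=self.lambda0,
            )
            for s in spectra
        ]
        return np.vstack([r.composition.as_array() for r in self.results_])
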