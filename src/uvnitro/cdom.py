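"""CDOM background estimation and subtraction.

Chromophoric dissolved organic matter absorbs throughout the UV with an
approximately exponential decay in wavelength. Nitrate, nitrite and sea salt
are transparent above ~270 nm, so the 275-295 nm region isolates the CDOM
signal: an exponential

    A_cdom(lambda) = a0 * exp(s * (lambda0 - lambda)) + k,    lambda0 = 300 nm

is fitted there and extrapolated into the deep-UV analysis window, where it
is subtracted before multivariate calibration.

The additive offset k breaks log-linearity, so the fit is nonlinear least
squares (trust-region reflective), initialised from a log-linear regression
of A - k0 with k0 slightly below the window minimum. The slope is bounded to
[0.001, 0.1] nm^-1 to prevent divergence on noise-only windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import AbsorbanceSpectrum, SpectraSet
from .synth import CDOMParams, cdom_absorbance

logger = logging.getLogger(__name__)

__all__ = ["CDOMFit", "DegenerateFitError", "fit_cdom", "subtract_cdom", "correct_set"]

DEFAULT_FIT_RANGE = (275.0, 295.0)
DEFAULT_LAMBDA0 = 300.0
_S_BOUNDS = (1e-3, 0.1)  # nm^-1
#: |k| cap (AU). k absorbs cuvette scattering and instrument drift, which are
#: a few milli-AU on a dual-beam instrument; leaving k free lets it trade off
#: against (a0, s) on the narrow fit window and destabilises the deep-UV
#: extrapolation by an order of magnitude.
DEFAULT_K_BOUND = 0.01


class DegenerateFitError(RuntimeError):
    """The window carries no decaying signal to fit; skip the correction."""


@dataclass(frozen=True)
class CDOMFit:
    """Fitted exponential background over [fit_lo, fit_hi]."""

    params: CDOMParams
    fit_lo: float
    fit_hi: float
    rss: float
    converged: bool


def fit_cdom(
    s: AbsorbanceSpectrum,
    fit_lo: float = DEFAULT_FIT_RANGE[0],
    fit_hi: float = DEFAULT_FIT_RANGE[1],
    lambda0: float = DEFAULT_LAMBDA0,
    k_bound: float = DEFAULT_K_BOUND,
) -> CDOMFit:
    """Least-squares fit of the exponential CDOM model over [fit_lo, fit_hi].

    The slope is bounded to [0.001, 0.1] nm^-1 and the offset to
    [-k_bound, k_bound] AU; both prevent the near-collinear (a0, s, k)
    trade-off on the narrow fit window from corrupting the extrapolation.
    """
    sl = s.grid.window_slice(fit_lo, fit_hi)
    lam = s.grid.values[sl]
    a = s.absorbance[sl]
    if lam.size < 5:
        raise ValueError(f"need >= 5 points in [{fit_lo}, {fit_hi}], got {lam.size}")
    span = float(a.max() - a.min())
    if a.max() <= 0 or span <= 0:
        raise DegenerateFitError(
            f"sample {s.sample_id!r}: no positive dynamic range in "
            f"[{fit_lo}, {fit_hi}]; skip CDOM correction"
        )
    # log-linear initialiser: regress ln(A - k0) on (lambda0 - lambda)
    k0 = float(np.clip(a.min() - 0.05 * span, -0.999 * k_bound, 0.999 * k_bound))
    z = np.log(np.maximum(a - k0, 1e-12))
    x = lambda0 - lam
    slope, intercept = np.polyfit(x, z, 1)
    s0 = float(np.clip(slope, *_S_BOUNDS))
    a0_init = max(float(np.exp(intercept)), 1e-12)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a0, sl_, k = theta
        return a0 * np.exp(sl_ * x) + k - a

    res = least_squares(
        residuals,
        x0=np.array([a0_init, s0, k0]),
        bounds=(
            np.array([0.0, _S_BOUNDS[0], -k_bound]),
            np.array([np.inf, _S_BOUNDS[1], k_bound]),
        ),
        method="trf",
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
        max_nfev=5000,
    )
    a0, s_hat, k = (float(v) for v in res.x)
    converged = bool(res.status > 0) and s_hat > 0
    return CDOMFit(
        params=CDOMParams(a0=a0, s=s_hat, k=k, lambda0=lambda0),
        fit_lo=float(fit_lo),
        fit_hi=float(fit_hi),
        rss=float(np.sum(res.fun**2)),
        converged=converged,
    )


def subtract_cdom(
    s: AbsorbanceSpectrum,
    fit: CDOMFit,
    target_lo: float | None = None,
    target_hi: float | None = None,
) -> AbsorbanceSpectrum:
    """Subtract the fitted background over [target_lo, target_hi].

    Defaults to the full grid. Wavelengths outside the target window are left
    unchanged; small negative corrected absorbances are not clipped.
    """
    if not fit.converged:
        raise ValueError(
            f"CDOM fit for sample {s.sample_id!r} did not converge; refusing to subtract"
        )
    if target_lo is None:
        target_lo = s.grid.lo
    if target_hi is None:
        target_hi = s.grid.hi
    sl = s.grid.window_slice(target_lo, target_hi)
    corrected = s.absorbance.copy()
    corrected[sl] = corrected[sl] - cdom_absorbance(fit.params, s.grid.values[sl])
    return AbsorbanceSpectrum(
        s.grid, corrected, pathlength=s.pathlength, sample_id=s.sample_id
    )


def correct_set(
    sset: SpectraSet,
    fit_lo: float = DEFAULT_FIT_RANGE[0],
    fit_hi: float = DEFAULT_FIT_RANGE[1],
    lambda0: float = DEFAULT_LAMBDA0,
    target: tuple[float, float] | None = None,
) -> tuple[SpectraSet, list[CDOMFit | None]]:
    """Fit-and-subtract every spectrum of a set (standards and unknowns alike).

    Spectra with no CDOM signal (degenerate fit window) are passed through
    uncorrected and logged; the returned fit list holds None for them.
    """
    out = []
    fits: list[CDOMFit | None] = []
    t_lo, t_hi = target if target is not None else (None, None)
    for spec in sset:
        try:
            fit = fit_cdom(spec, fit_lo, fit_hi, lambda0)
        except DegenerateFitError as exc:
            logger.info("%s", exc)
            out.append(spec)
            fits.append(None)
            continue
        out.append(subtract_cdom(spec, fit, t_lo, t_hi))
        fits.append(fit)
    return sset.with_spectra(out), fits
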