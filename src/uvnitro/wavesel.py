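"""Interval PLS (iPLS) wavelength screening and boundary refinement.

The 200-300 nm acquisition range is screened with sliding 16-point (15 nm
span) windows advancing 10 nm; each window is scored by calibrating a PLS
model inside it (factor count from the Q2 rule) and evaluating RMSEP, R2 and
RE on the prediction set. The screened sequence keeps the instrument
convention of clipping the final window so it ends exactly at the range end
(..., 270-285, 285-300). The best window is then refined by a greedy
alternating-edge hill-climb at 1 nm steps: a boundary move is accepted only
if the pooled score strictly decreases, and the full audit trail is kept.

RMSEP values for nitrate/nitrite (uM) and salinity (psu) are incommensurable,
so the pooled window score is the mean over responses of RMSEP divided by
that response's calibration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .pls import Q2_SIGNIFICANCE, PLSRegressor, loo_cv
from .spectra import SpectraSet

__all__ = [
    "WindowScore",
    "RefinementResult",
    "ipls_intervals",
    "score_window",
    "screen_windows",
    "refine_window",
    "select_window",
]


@dataclass(frozen=True)
class WindowScore:
    """Per-window prediction-set performance."""

    lo: float
    hi: float
    rmsep: np.ndarray  # per response, response units
    r2: np.ndarray
    re: np.ndarray  # mean absolute relative error, fraction
    pooled_score: float  # mean over responses of rmsep / calibration range
    n_factors: int


@dataclass
class RefinementResult:
    lo: float
    hi: float
    trail: list[WindowScore] = field(default_factory=list)


def ipls_intervals(
    lo: float, hi: float, width_points: int = 16, step: float = 10.0, spacing: float = 1.0
) -> list[tuple[float, float]]:
    """Sliding screening windows of ``width_points`` grid points.

    Windows advance by ``step`` nm; if the regular sequence does not end at
    ``hi``, the final window is replaced by one clipped to end exactly there.
    """
    span = (width_points - 1) * spacing
    if span <= 0 or span > hi - lo:
        raise ValueError(
            f"window span {span} nm is not usable on the range [{lo}, {hi}]"
        )
    starts = np.arange(lo, hi - span + 1e-9, step)
    wins = [(float(s), float(s + span)) for s in starts]
    if wins[-1][1] < hi - 1e-9:
        wins[-1] = (float(hi - span), float(hi))
    return wins


def score_window(
    cal: SpectraSet,
    pred: SpectraSet,
    w: tuple[float, float],
    mode: str = "pls2",
    threshold: float = Q2_SIGNIFICANCE,
    h_max: int = 7,
) -> WindowScore:
    """Calibrate inside window ``w`` and score on the prediction set.

    Both sets must already carry any background correction. The factor count
    is chosen by the Q2 rule inside the window; RMSEP/R2/RE are computed per
    response on the prediction set.
    """
    lo, hi = w
    cal_w = cal.window(lo, hi)
    if len(cal_w.grid) < 2:
        raise ValueError(f"window {w} holds fewer than 2 grid points")
    pred_w = pred.window(lo, hi)
    Xc, Yc = cal_w.X, cal_w.Y
    cv = loo_cv(Xc, Yc, h_max=h_max, mode=mode, threshold=threshold)
    h = cv.selected_h if not isinstance(cv, list) else max(c.selected_h for c in cv)
    model = PLSRegressor(n_components=h, mode=mode, window=(lo, hi)).fit(Xc, Yc)
    Yhat = model.predict(pred_w.X)
    Yact = pred_w.Y
    k = Yact.shape[1]
    rmsep = np.array([_metrics.rmsep(Yact[:, j], Yhat[:, j]) for j in range(k)])
    r2 = np.array([_metrics.r_squared(Yact[:, j], Yhat[:, j]) for j in range(k)])
    re = np.array(
        [_metrics.relative_error(Yact[:, j], Yhat[:, j], mode="absolute") for j in range(k)]
    )
    ranges = np.ptp(Yc, axis=0)
    if np.any(ranges <= 0):
        raise ValueError("a response has zero range in the calibration set")
    return WindowScore(
        lo=lo,
        hi=hi,
        rmsep=rmsep,
        r2=r2,
        re=re,
        pooled_score=float(np.mean(rmsep / ranges)),
        n_factors=h,
    )


def screen_windows(
    cal: SpectraSet,
    pred: SpectraSet,
    width_points: int = 16,
    step: float = 10.0,
    mode: str = "pls2",
    threshold: float = Q2_SIGNIFICANCE,
    h_max: int = 7,
) -> list[WindowScore]:
    """Score every iPLS screening window over the shared grid."""
    g = cal.grid
    wins = ipls_intervals(g.lo, g.hi, width_points, step, g.spacing)
    return [score_window(cal, pred, w, mode, threshold, h_max) for w in wins]


def refine_window(
    cal: SpectraSet,
    pred: SpectraSet,
    w0: tuple[float, float],
    step: float = 1.0,
    mode: str = "pls2",
    threshold: float = Q2_SIGNIFICANCE,
    h_max: int = 7,
    min_points: int = 5,
) -> RefinementResult:
    """Greedy alternating-edge hill-climb around a screened window.

    Alternately proposes moving the low edge then the high edge by +-step,
    accepting a move only if the pooled score strictly decreases; terminates
    when a full pass leaves both edges unchanged. Deterministic; the audit
    trail (every accepted window with its score) is returned.
    """
    g = cal.grid
    current = score_window(cal, pred, w0, mode, threshold, h_max)
    trail = [current]

    def valid(lo: float, hi: float) -> bool:
        if lo < g.lo - 1e-9 or hi > g.hi + 1e-9 or lo >= hi:
            return False
        return int(round((hi - lo) / g.spacing)) + 1 >= min_points

    improved = True
    while improved:
        improved = False
        for edge in ("lo", "hi"):
            best_move = None
            for delta in (-step, +step):
                lo, hi = current.lo, current.hi
                if edge == "lo":
                    lo = lo + delta
                else:
                    hi = hi + delta
                if not valid(lo, hi):
                    continue
                cand = score_window(cal, pred, (lo, hi), mode, threshold, h_max)
                if cand.pooled_score < current.pooled_score and (
                    best_move is None or cand.pooled_score < best_move.pooled_score
                ):
                    best_move = cand
            if best_move is not None:
                current = best_move
                trail.append(current)
                improved = True
    return RefinementResult(lo=current.lo, hi=current.hi, trail=trail)


def select_window(
    cal: SpectraSet,
    pred: SpectraSet,
    width_points: int = 16,
    step: float = 10.0,
    refine: bool = True,
    mode: str = "pls2",
    threshold: float = Q2_SIGNIFICANCE,
    h_max: int = 7,
) -> tuple[tuple[float, float], list[WindowScore], RefinementResult | None]:
    """iPLS screening plus optional refinement.

    Returns the selected (lo, hi) window, all screening scores, and the
    refinement audit (None when ``refine`` is False).
    """
    scores = screen_windows(cal, pred, width_points, step, mode, threshold, h_max)
    best = min(scores, key=lambda s: s.pooled_score)
    if not refine:
        return (best.lo, best.hi), scores, None
    ref = refine_window(cal, pred, (best.lo, best.hi), 1.0, mode, threshold, h_max)
    return (ref.lo, ref.hi), scores, ref
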