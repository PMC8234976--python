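"""Prediction-set statistics and method-performance figures.

RMSEP is the root of the mean squared prediction error; R2 the squared
Pearson correlation between predicted and actual values; RE the mean
relative prediction error (per-term absolute value by default, signed mode
available for bias analysis; samples with a true value of zero are excluded
and counted). LOD is k (default 3) times the sample standard deviation of
replicate analyses of a low-nutrient sample; RSD the percent relative
standard deviation of replicates; recovery the found concentration as a
percentage of the expected total in a spiked sample. Replicate precision
uses the n-1 sample standard deviation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedMetricError",
    "MetricsReport",
    "rmsep",
    "r_squared",
    "relative_error",
    "lod",
    "rsd",
    "recovery",
    "metrics_report",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (zero variance/mean/actuals)."""


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} actual vs {p.size} predicted")
    if a.size < 1:
        raise ValueError("empty input")
    return a, p


def rmsep(actual, predicted) -> float:
    """Root mean squared error of prediction, in response units."""
    a, p = _pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual, predicted) -> float:
    """Squared Pearson correlation between actual and predicted values."""
    a, p = _pair(actual, predicted)
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    da, dp = a - a.mean(), p - p.mean()
    va, vp = float(da @ da), float(dp @ dp)
    if va == 0 or vp == 0:
        raise UndefinedMetricError("zero variance in actual or predicted values")
    return float((da @ dp) ** 2 / (va * vp))


def relative_error(actual, predicted, mode: str = "absolute") -> float:
    """Mean relative prediction error (C_hat - C)/C.

    ``mode='absolute'`` (default) averages |C_hat - C|/C; ``mode='signed'``
    keeps the sign of each term. Samples with actual exactly zero are
    excluded from the mean.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    a, p = _pair(actual, predicted)
    keep = a != 0
    if not np.any(keep):
        raise UndefinedMetricError("all actual values are zero; RE undefined")
    terms = (p[keep] - a[keep]) / a[keep]
    if mode == "absolute":
        terms = np.abs(terms)
    return float(np.mean(terms))


def n_excluded_from_re(actual) -> int:
    """How many samples a relative-error computation drops (actual == 0)."""
    a = np.asarray(actual, dtype=float).ravel()
    return int(np.sum(a == 0))


def lod(replicate_predictions, k: float = 3.0) -> float:
    """Detection limit: k times the sample SD of replicate analyses."""
    r = np.asarray(replicate_predictions, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("LOD needs at least 2 replicates")
    return float(k * np.std(r, ddof=1))


def rsd(replicates) -> float:
    """Relative standard deviation of replicates, percent."""
    r = np.asarray(replicates, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("RSD needs at least 2 replicates")
    m = float(np.mean(r))
    if m == 0:
        raise UndefinedMetricError("zero replicate mean; RSD undefined")
    return float(100.0 * np.std(r, ddof=1) / m)


def recovery(expected_total: float, found: float) -> float:
    """Spike recovery: 100 x found / expected total, percent."""
    if not expected_total > 0:
        raise ValueError(f"expected total must be > 0, got {expected_total}")
    return float(100.0 * found / expected_total)


@dataclass(frozen=True)
class MetricsReport:
    """Per-response prediction-set report."""

    names: tuple[str, ...]
    rmsep: np.ndarray
    r2: np.ndarray
    re: np.ndarray
    re_excluded: np.ndarray  # zero-actual samples dropped from RE, per response
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": list(self.names),
                "rmsep": self.rmsep,
                "r2": self.r2,
                "re": self.re,
                "re_excluded": self.re_excluded,
                "n": self.n,
            }
        )


def metrics_report(
    actual: np.ndarray,
    predicted: np.ndarray,
    names: tuple[str, ...] = ("no3", "no2", "salinity"),
) -> MetricsReport:
    """RMSEP/R2/RE per response column for a prediction set."""
    a = np.atleast_2d(np.asarray(actual, dtype=float))
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {p.shape}")
    if a.shape[0] < 2:
        raise ValueError("a prediction-set report needs n >= 2 samples")
    k = a.shape[1]
    if len(names) != k:
        raise ValueError(f"{len(names)} names for {k} responses")
    return MetricsReport(
        names=tuple(names),
        rmsep=np.array([rmsep(a[:, j], p[:, j]) for j in range(k)]),
        r2=np.array([r_squared(a[:, j], p[:, j]) for j in range(k)]),
        re=np.array([relative_error(a[:, j], p[:, j]) for j in range(k)]),
        re_excluded=np.array([n_excluded_from_re(a[:, j]) for j in range(k)]),
        n=a.shape[0],
    )
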