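"""PLS calibration, leave-one-out cross-validation and factor selection.

The calibration model decomposes the mean-centred absorbance matrix X (n
samples x m wavelengths) and response matrix Y (n x k) as

    X = T P' + E,        Y = U Q' + F,

with scores T, U chosen to maximise their covariance (NIPALS). PLS2 extracts
one common factor set for all responses; PLS1 runs the decomposition per
response. Prediction is linear: Yhat = (X - x_mean) B + y_mean with
B = W (P' W)^-1 Q'.

The factor count h is chosen by leave-one-out cross-validation. For each h,

    PRESS_h = sum_i (C_i - Chat_h(-i))^2          (LOO prediction errors)
    RESS_h  = sum_i (C_i - Chat_h,i)^2            (full-data fit residuals)
    Q2_h    = 1 - PRESS_h / RESS_{h-1},

pooled over responses in original units for PLS2, per response for PLS1. A
factor is significant (p <= 0.05) while Q2_h >= 0.0975 (= 1 - 0.95^2); the
scan keeps the last significant factor count, tolerating insignificant
factors before the first significant one and stopping at the first
insignificant factor after it.

Mean-centring only -- no unit-variance scaling of Y in PLS2: pooled PRESS in
original units must equal the sum of the per-response PRESS values. LOO
refits re-centre within each fold so the held-out sample never leaks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Q2_SIGNIFICANCE",
    "PLSRegressor",
    "CVResult",
    "fit_pls",
    "predict",
    "loo_cv",
    "select_factors",
    "cumulative_contribution",
]

#: significance cutoff on Q2 (= 1 - 0.95^2): a factor is significant at
#: p <= 0.05 while PRESS_h <= 0.95^2 RESS_{h-1}
Q2_SIGNIFICANCE = 0.0975


def _nipals(
    Xc: np.ndarray,
    Yc: np.ndarray,
    n_components: int,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> dict[str, np.ndarray]:
    """NIPALS decomposition of centred X, Y; returns weights/loadings/scores.

    Starts each factor from the residual-Y column of largest variance
    (deterministic). Stops early if X or Y residual variance is exhausted.
    """
    n, m = Xc.shape
    k = Yc.shape[1]
    X = Xc.copy()
    Y = Yc.copy()
    x_tot = float(np.sum(Xc**2))
    y_tot = float(np.sum(Yc**2))
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((k, n_components))
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    a = 0
    for a in range(n_components):
        if np.sum(X**2) <= max(x_tot, 1e-30) * 1e-28:
            break
        if np.sum(Y**2) <= max(y_tot, 1e-30) * 1e-28:
            break
        u = Y[:, int(np.argmax(np.var(Y, axis=0)))].copy()
        w = t = q = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = Y.T @ t / tt
            if k == 1:
                break  # single response: one pass is exact
            qq = float(q @ q)
            if qq == 0:
                break
            u_new = Y @ q / qq
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        if w is None or t is None or q is None or float(t @ t) == 0:
            break
        tt = float(t @ t)
        p = X.T @ t / tt
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, p, q, t, u
        a += 1
    h = a
    W, P, Q, T, U = W[:, :h], P[:, :h], Q[:, :h], T[:, :h], U[:, :h]
    # R = W (P'W)^-1, built incrementally; B_h = R[:, :h] Q[:, :h]'
    R = np.zeros_like(W)
    for j in range(h):
        R[:, j] = W[:, j] - R[:, :j] @ (P[:, :j].T @ W[:, j])
    return {"W": W, "P": P, "Q": Q, "T": T, "U": U, "R": R}


def _coef_at(d: dict[str, np.ndarray], h: int) -> np.ndarray:
    """Regression coefficients using the first h factors (h may exceed the
    number actually extracted; the decomposition is then used in full)."""
    h = min(h, d["R"].shape[1])
    return d["R"][:, :h] @ d["Q"][:, :h].T


class PLSRegressor(RegressorMixin, BaseEstimator):
    """PLS1/PLS2 regression of compositions on absorbance spectra.

    Parameters
    ----------
    n_components : int
        Number of latent factors h.
    mode : {"pls2", "pls1"}
        "pls2" extracts one common factor set for all responses; "pls1" fits
        a separate decomposition per response column.
    tol, max_iter : float, int
        NIPALS convergence tolerance on the score vector and iteration cap.
    window : tuple or None
        Optional (lo, hi) nm metadata naming the wavelength window the
        columns of X span; used in error messages and serialization.
    """

    def __init__(
        self,
        n_components: int = 4,
        mode: str = "pls2",
        tol: float = 1e-12,
        max_iter: int = 500,
        window: tuple[float, float] | None = None,
    ):
        self.n_components = n_components
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter
        self.window = window

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSRegressor":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError(f"incompatible shapes X{X.shape}, Y{Y.shape}")
        n, m = X.shape
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise ValueError("X and Y must be finite")
        if self.mode not in ("pls1", "pls2"):
            raise ValueError(f"mode must be 'pls1' or 'pls2', got {self.mode!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        h_cap = min(n - 1, m)
        if self.n_components > h_cap:
            raise ValueError(
                f"n_components={self.n_components} exceeds the attainable maximum "
                f"min(n-1, m) = {h_cap}"
            )
        if np.any(np.ptp(X, axis=0) == 0):
            warnings.warn(
                "constant absorbance column(s) in X; centred to zero weight",
                stacklevel=2,
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        self.n_features_in_ = m
        self.n_responses_ = Y.shape[1]
        if self.mode == "pls2" or Y.shape[1] == 1:
            d = _nipals(Xc, Yc, self.n_components, self.tol, self.max_iter)
            self._fits_ = [d]
            self.x_weights_ = d["W"]
            self.x_loadings_ = d["P"]
            self.y_loadings_ = d["Q"]
            self.x_scores_ = d["T"]
            self.y_scores_ = d["U"]
            self.coef_ = _coef_at(d, self.n_components)
        else:  # pls1 on each response column
            self._fits_ = [
                _nipals(Xc, Yc[:, j : j + 1], self.n_components, self.tol, self.max_iter)
                for j in range(Y.shape[1])
            ]
            self.coef_ = np.column_stack(
                [_coef_at(d, self.n_components)[:, 0] for d in self._fits_]
            )
            self.x_weights_ = [d["W"] for d in self._fits_]
            self.x_loadings_ = [d["P"] for d in self._fits_]
            self.y_loadings_ = [d["Q"] for d in self._fits_]
            self.x_scores_ = [d["T"] for d in self._fits_]
            self.y_scores_ = [d["U"] for d in self._fits_]
        self.n_components_ = min(self.n_components, self._fits_[0]["T"].shape[1])
        self._x_center_ss_ = float(np.sum(Xc**2))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("PLSRegressor is not fitted")
        X = np.asarray(X, dtype=float)
        one_dim = X.ndim == 1
        if one_dim:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            win = f" (window {self.window[0]}-{self.window[1]} nm)" if self.window else ""
            raise ValueError(
                f"X has {X.shape[1]} wavelengths, model expects "
                f"{self.n_features_in_}{win}"
            )
        out = (X - self.x_mean_) @ self.coef_ + self.y_mean_
        return out[0] if one_dim else out

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        if not hasattr(self, "coef_"):
            raise ValueError("PLSRegressor is not fitted")

        def enc(v):
            if isinstance(v, list):
                return [np.asarray(a).tolist() for a in v]
            return np.asarray(v).tolist()

        payload = {
            "schema": "uvnitro.pls/1",
            "params": {
                "n_components": self.n_components,
                "mode": self.mode,
                "tol": self.tol,
                "max_iter": self.max_iter,
                "window": list(self.window) if self.window else None,
            },
            "x_mean": enc(self.x_mean_),
            "y_mean": enc(self.y_mean_),
            "coef": enc(self.coef_),
            "x_weights": enc(self.x_weights_),
            "x_loadings": enc(self.x_loadings_),
            "y_loadings": enc(self.y_loadings_),
            "n_components_fitted": int(self.n_components_),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PLSRegressor":
        payload = json.loads(text)
        if payload.get("schema") != "uvnitro.pls/1":
            raise ValueError(f"unsupported model schema {payload.get('schema')!r}")
        p = payload["params"]
        model = cls(
            n_components=p["n_components"],
            mode=p["mode"],
            tol=p["tol"],
            max_iter=p["max_iter"],
            window=tuple(p["window"]) if p["window"] else None,
        )

        def dec(v):
            if v and isinstance(v[0], list) and v and isinstance(v[0][0], list):
                return [np.asarray(a, dtype=float) for a in v]
            return np.asarray(v, dtype=float)

        model.x_mean_ = np.asarray(payload["x_mean"], dtype=float)
        model.y_mean_ = np.asarray(payload["y_mean"], dtype=float)
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        if model.mode == "pls1" and isinstance(payload["x_weights"][0][0], list):
            model.x_weights_ = dec(payload["x_weights"])
            model.x_loadings_ = dec(payload["x_loadings"])
            model.y_loadings_ = dec(payload["y_loadings"])
        else:
            model.x_weights_ = np.asarray(payload["x_weights"], dtype=float)
            model.x_loadings_ = np.asarray(payload["x_loadings"], dtype=float)
            model.y_loadings_ = np.asarray(payload["y_loadings"], dtype=float)
        model.n_components_ = payload["n_components_fitted"]
        model.n_features_in_ = model.x_mean_.size
        model.n_responses_ = model.y_mean_.size
        return model


def fit_pls(X, Y, h: int, mode: str = "pls2", window=None) -> PLSRegressor:
    """Fit a PLS model with h factors (thin wrapper over PLSRegressor)."""
    return PLSRegressor(n_components=h, mode=mode, window=window).fit(X, Y)


def predict(model: PLSRegressor, X) -> np.ndarray:
    return model.predict(X)


@dataclass
class CVResult:
    """Leave-one-out CV summary over factor counts 1..h_max.

    All arrays are indexed by factor count h-1 (i.e. entry 0 is h=1); q2 is
    NaN at h=1 where RESS_0 has no preceding model. ``per_response_press``
    (h_max x k) holds the per-response split whose row sums give ``press``
    for a pooled PLS2 run.
    """

    factors: np.ndarray
    press: np.ndarray
    ress: np.ndarray
    ress0: float
    q2: np.ndarray
    selected_h: int
    cumulative_contribution: np.ndarray
    per_response_press: np.ndarray | None = None
    response: str | None = None


def select_factors(cv, threshold: float = Q2_SIGNIFICANCE) -> int:
    """Factor count from the Q2 significance rule.

    ``cv`` is a CVResult or a Q2 sequence for h = 2, 3, ... Scanning upward,
    a factor count is retained while its Q2 is significant (>= threshold);
    insignificant values before the first significant one are tolerated, and
    the first insignificant value after a significant one ends the scan.
    Returns the last significant h, or 1 if none is.
    """
    if isinstance(cv, CVResult):
        q2 = cv.q2[1:]  # h = 2..h_max
    else:
        q2 = np.asarray(cv, dtype=float)
    best = 1
    for idx, val in enumerate(q2):
        h = idx + 2
        if np.isfinite(val) and val >= threshold:
            best = h
        elif best > 1:
            break
    return best


def _xvar_cumulative(d: dict[str, np.ndarray], x_center_ss: float) -> np.ndarray:
    tt = np.sum(d["T"] ** 2, axis=0)
    pp = np.sum(d["P"] ** 2, axis=0)
    if x_center_ss <= 0:
        return np.ones_like(tt)
    return np.cumsum(tt * pp) / x_center_ss


def cumulative_contribution(model: PLSRegressor, X=None) -> np.ndarray:
    """Cumulative fraction of centred-X variance explained by factors 1..h.

    Returns an (h,) vector for PLS2 (or single-response) models and a (k, h)
    array for PLS1 with k responses.
    """
    if not hasattr(model, "_fits_"):
        raise ValueError("model must be fitted (in this session) first")
    rows = [_xvar_cumulative(d, model._x_center_ss_) for d in model._fits_]
    return rows[0] if len(rows) == 1 else np.vstack(rows)


def loo_cv(
    X,
    Y,
    h_max: int = 7,
    mode: str = "pls2",
    threshold: float = Q2_SIGNIFICANCE,
):
    """Leave-one-out cross-validation over factor counts 1..h_max.

    Returns a CVResult (pooled over responses, original units) for PLS2 or a
    single-response Y; for PLS1 with k > 1 responses, a list of k CVResults.
    ``h_max`` larger than the data can support is clipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    k = Y.shape[1]
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 samples")
    if mode == "pls1" and k > 1:
        return [
            loo_cv(X, Y[:, j : j + 1], h_max=h_max, mode="pls1", threshold=threshold)
            for j in range(k)
        ]
    cap = min(n - 2, m)
    if h_max > cap:
        warnings.warn(f"h_max={h_max} clipped to {cap} (n={n}, m={m})", stacklevel=2)
        h_max = cap

    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    full = _nipals(X - xm, Y - ym, h_max)
    ress = np.empty(h_max)
    for h in range(1, h_max + 1):
        fitted = (X - xm) @ _coef_at(full, h) + ym
        ress[h - 1] = float(np.sum((Y - fitted) ** 2))
    ress0 = float(np.sum((Y - ym) ** 2))

    per_resp = np.zeros((h_max, k))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, Yi = X[keep], Y[keep]
        xmi, ymi = Xi.mean(axis=0), Yi.mean(axis=0)  # re-centred per fold
        di = _nipals(Xi - xmi, Yi - ymi, h_max)
        xc = X[i] - xmi
        for h in range(1, h_max + 1):
            e = Y[i] - (xc @ _coef_at(di, h) + ymi)
            per_resp[h - 1] += e**2
    press = per_resp.sum(axis=1)

    q2 = np.full(h_max, np.nan)
    tiny = max(ress0, 1e-30) * 1e-14
    for h in range(2, h_max + 1):
        prev = ress[h - 2]
        if prev > tiny:
            q2[h - 1] = 1.0 - press[h - 1] / prev
        # else: previous model already fits to numerical noise -> insignificant

    cv = CVResult(
        factors=np.arange(1, h_max + 1),
        press=press,
        ress=ress,
        ress0=ress0,
        q2=q2,
        selected_h=1,
        cumulative_contribution=_xvar_cumulative(full, float(np.sum((X - xm) ** 2))),
        per_response_press=per_resp if k > 1 else None,
        response=None,
    )
    cv.selected_h = select_factors(cv, threshold)
    return cv
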