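"""End-to-end calibration/prediction workflow and run configuration.

Chains background correction -> windowing -> factor selection -> PLS fit ->
prediction -> replicate reporting, with one resolved, loggable configuration
object so any run is reproducible from its config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import cdom as _cdom
from .cls import CLSRegressor
from .metrics import MetricsReport, metrics_report
from .pls import Q2_SIGNIFICANCE, CVResult, PLSRegressor, loo_cv
from .spectra import SpectraSet

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "calibrate", "predict_set", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Resolved run configuration (all tunables in one place).

    window: modeling window, nm (the recommended deconvolution window is
    215-240 nm). mode: 'pls2' (recommended) or 'pls1'. q2_threshold: the
    factor-significance cutoff (0.0975 = 1 - 0.95^2). cdom_*: background fit
    range (275-295 nm), reference wavelength (300 nm), whether to apply the
    correction, and the subtraction target (None = whole grid). noise_sd /
    seed / pathlength parametrise simulation runs.
    """

    window: tuple[float, float] = (215.0, 240.0)
    mode: str = "pls2"
    q2_threshold: float = Q2_SIGNIFICANCE
    max_factors: int = 7
    cdom_apply: bool = True
    cdom_fit_range: tuple[float, float] = (275.0, 295.0)
    cdom_lambda0: float = 300.0
    cdom_target: tuple[float, float] | None = None
    noise_sd: float = 5e-4
    seed: int = 0
    pathlength: float = 3.0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("window", "cdom_fit_range", "cdom_target"):
            if raw.get(key) is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("window", "cdom_fit_range", "cdom_target"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _correct(sset: SpectraSet, config: RunConfig, stage: str) -> SpectraSet:
    if not config.cdom_apply:
        return sset
    try:
        corrected, fits = _cdom.correct_set(
            sset,
            fit_lo=config.cdom_fit_range[0],
            fit_hi=config.cdom_fit_range[1],
            lambda0=config.cdom_lambda0,
            target=config.cdom_target,
        )
    except Exception as exc:
        raise StageError(f"{stage}: CDOM correction failed: {exc}") from exc
    for sid, fit in zip(sset.sample_ids, fits):
        if fit is not None:
            logger.info(
                "%s: sample %s CDOM a0=%.4g s=%.4g k=%.4g rss=%.3g",
                stage, sid, fit.params.a0, fit.params.s, fit.params.k, fit.rss,
            )
    return corrected


def calibrate(cal: SpectraSet, config: RunConfig) -> tuple[PLSRegressor, CVResult | list[CVResult]]:
    """Background-correct, window, pick the factor count, and fit.

    Returns the fitted model and the cross-validation result(s) behind the
    selected factor count.
    """
    if cal.compositions is None:
        raise StageError("calibrate: calibration set carries no compositions")
    corrected = _correct(cal, config, "calibrate")
    cal_w = corrected.window(*config.window)
    X, Y = cal_w.X, cal_w.Y
    try:
        cv = loo_cv(X, Y, h_max=config.max_factors, mode=config.mode,
                    threshold=config.q2_threshold)
    except Exception as exc:
        raise StageError(f"calibrate: cross-validation failed: {exc}") from exc
    h = cv.selected_h if isinstance(cv, CVResult) else max(c.selected_h for c in cv)
    logger.info("calibrate: selected %d factor(s) (config %s)", h, config.digest)
    model = PLSRegressor(n_components=h, mode=config.mode, window=config.window).fit(X, Y)
    return model, cv


def predict_set(
    model: PLSRegressor, unknowns: SpectraSet, config: RunConfig
) -> pd.DataFrame:
    """Predict compositions for a set; replicates (shared sample_id) are
    aggregated to mean +- sample SD."""
    corrected = _correct(unknowns, config, "predict")
    Xw = corrected.window(*config.window).X
    Yhat = model.predict(Xw)
    per_scan = pd.DataFrame(Yhat, columns=["no3_uM", "no2_uM", "salinity_psu"])
    per_scan.insert(0, "sample_id", unknowns.sample_ids)
    g = per_scan.groupby("sample_id", sort=False)
    out = g.mean()
    sds = g.std(ddof=1)
    for col in ("no3_uM", "no2_uM", "salinity_psu"):
        out[col + "_sd"] = sds[col]
    out["n_replicates"] = g.size()
    return out.reset_index()


def run_pipeline(
    config: RunConfig,
    cal: SpectraSet,
    unknowns: SpectraSet,
    method: str = "pls",
) -> tuple[pd.DataFrame, MetricsReport | None]:
    """Full calibrate-then-predict run.

    With ``method='cls'`` the calibration set is used as standards to build
    the absorptivity library and each unknown is CLS-fitted on its raw
    spectrum. If the unknowns carry compositions, a metrics report is
    computed against them (replicate-averaged predictions are not used for
    the report; it is per-scan).
    """
    if method == "pls":
        model, _ = calibrate(cal, config)
        report = predict_set(model, unknowns, config)
        corrected = _correct(unknowns, config, "evaluate")
        Yhat = model.predict(corrected.window(*config.window).X)
    elif method == "cls":
        try:
            reg = CLSRegressor(window=config.window).fit(cal)
            Yhat = reg.predict(unknowns)
        except Exception as exc:
            raise StageError(f"cls: {exc}") from exc
        report = pd.DataFrame(Yhat, columns=["no3_uM", "no2_uM", "salinity_psu"])
        report.insert(0, "sample_id", unknowns.sample_ids)
    else:
        raise ValueError(f"unknown method {method!r}")
    metrics = None
    if unknowns.compositions is not None:
        metrics = metrics_report(unknowns.Y, Yhat)
    return report, metrics
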