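"""Model metrics, qualitative interpretation bands, and map rendering.

Metrics follow NIR-calibration convention: coefficient of determination
R^2 = 1 - SSres/SStot (not squared Pearson correlation), root mean
square errors for calibration / cross-validation / prediction, and the
residual predictive deviation RPD = SD(prediction-set reference values,
n-1 denominator) / RMSEP.  Interpretation bands: an RPD under 2 marks a
model unusable for prediction, 2-2.5 usable, 2.5-3 good, above 3
excellent; R^2 under 0.61 unusable, 0.61-0.81 usable, 0.81-0.9 good,
above 0.9 excellent.

Prediction maps are per-flower, not per-pixel: each segmented flower's
mean preprocessed spectrum is predicted once and the value broadcast to
all of that flower's pixels (quality sorting operates on whole
flowers).  Pseudocolor renderings stack three min-max scaled band
planes (1000 / 1200 / 1400 nm by default) as RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .hypercube import Hypercube, nearest_band
from .preprocessing import PreprocessSpec, region_mean_spectrum
from .segmentation import SampleRegion

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "interpret",
    "EvaluationReport",
    "evaluate_model",
    "PredictionMap",
    "render_prediction_map",
    "render_pseudocolor",
    "save_map_png",
]

DEFAULT_PSEUDOCOLOR_BANDS_NM = (1000.0, 1200.0, 1400.0)

_LEVELS = ["unusable", "usable", "good", "excellent"]


def rmse(y_true, y_pred) -> float:
    """Root mean square error; homogeneous of degree 1 in its inputs."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rpd(reference_sd: float, rmsep: float) -> float:
    """Residual predictive deviation: prediction-set reference SD / RMSEP.

    The SD is the prediction set's reference-value standard deviation
    with n-1 denominator.  A zero RMSEP is flagged rather than returned
    as infinity.
    """
    if reference_sd <= 0:
        raise ValueError("reference_sd must be positive")
    if rmsep < 0:
        raise ValueError("rmsep must be nonnegative")
    if rmsep == 0:
        raise ZeroDivisionError("RMSEP is zero: RPD is infinite")
    return reference_sd / rmsep


def _r2_band(r2: float) -> str:
    if r2 > 0.9:
        return "excellent"
    if r2 >= 0.81:
        return "good"
    if r2 >= 0.61:
        return "usable"
    return "unusable"


def _rpd_band(value: float) -> str:
    if value > 3.0:
        return "excellent"
    if value > 2.5:
        return "good"
    if value >= 2.0:
        return "usable"
    return "unusable"


def interpret(r2: float | None = None,
              rpd_value: float | None = None) -> dict:
    """Qualitative labels for R^2 and/or RPD, plus the conservative
    overall label (the weaker of the two when both are given)."""
    out: dict = {}
    if r2 is not None:
        out["r2"] = _r2_band(r2)
    if rpd_value is not None:
        out["rpd"] = _rpd_band(rpd_value)
    if not out:
        raise ValueError("provide r2 and/or rpd_value")
    out["overall"] = min(out.values(), key=_LEVELS.index)
    return out


@dataclass
class EvaluationReport:
    """One model's calibration / cross-validation / prediction metrics."""

    family: str                # "pls" | "lssvm"
    chain: str                 # preprocessing tag, e.g. "wt-snv"
    analyte: str
    params: dict
    r2c: float
    rmsec: float
    r2cv: float
    rmsecv: float
    r2p: float
    rmsep: float
    rpd: float
    n_prediction: int
    interpretation: str = field(init=False)

    def __post_init__(self) -> None:
        self.interpretation = interpret(self.r2p, self.rpd)["overall"]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "family", "chain", "analyte", "params", "r2c", "rmsec",
            "r2cv", "rmsecv", "r2p", "rmsep", "rpd", "n_prediction",
            "interpretation")}
        return d

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path


def evaluate_model(model, X_pred, y_pred_ref, *, family: str,
                   chain: str, analyte: str, params: dict) -> EvaluationReport:
    """Score a fitted model on the held-out prediction set.

    Calibration and cross-validation diagnostics are read off the
    fitted estimator; prediction-set metrics and the RPD are computed
    here from the model's predictions.
    """
    y_pred_ref = np.asarray(y_pred_ref, float)
    yhat = model.predict(X_pred)
    rmsep = rmse(y_pred_ref, yhat)
    sd = float(y_pred_ref.std(ddof=1))
    return EvaluationReport(
        family=family, chain=chain, analyte=analyte, params=params,
        r2c=model.r2c_, rmsec=model.rmsec_,
        r2cv=model.r2cv_, rmsecv=model.rmsecv_,
        r2p=r_squared(y_pred_ref, yhat), rmsep=rmsep,
        rpd=rpd(sd, rmsep), n_prediction=y_pred_ref.size,
    )


@dataclass
class PredictionMap:
    """Per-flower constituent map: one value per flower, NaN background."""

    values: np.ndarray            # 2-D float array, NaN = no data
    flower_values: pd.DataFrame   # label, area_px, value
    analyte: str
    vmin: float
    vmax: float


def render_prediction_map(cube: Hypercube, regions: list[SampleRegion],
                          model, spec: PreprocessSpec,
                          analyte: str = "",
                          value_range: tuple | None = None) -> PredictionMap:
    """Predict each flower's content and broadcast it over its pixels.

    The model must have been trained on spectra preprocessed with the
    same chain as ``spec``; the per-flower mean spectrum here goes
    through that chain before prediction.
    """
    shape = cube.data.shape[:2]
    values = np.full(shape, np.nan)
    rows = []
    for region in regions:
        mean_spec = region_mean_spectrum(cube, region, spec)
        pred = float(model.predict(mean_spec[None, :])[0])
        values[region.coords[:, 0], region.coords[:, 1]] = pred
        rows.append({"label": region.label, "area_px": region.area_px,
                     "value": pred})
    table = pd.DataFrame(rows)
    if value_range is not None:
        vmin, vmax = value_range
    elif len(table):
        vmin, vmax = float(table.value.min()), float(table.value.max())
    else:
        vmin = vmax = float("nan")
    return PredictionMap(values, table, analyte, vmin, vmax)


def render_pseudocolor(cube: Hypercube,
                       band_nms=DEFAULT_PSEUDOCOLOR_BANDS_NM) -> np.ndarray:
    """RGB image from three band planes, each min-max scaled to [0, 1]
    over valid pixels (a zero-range channel maps to 0)."""
    if len(band_nms) != 3:
        raise ValueError("exactly three bands required")
    channels = []
    valid = cube.valid_mask
    for nm in band_nms:
        plane = cube.band(nearest_band(cube.axis, nm)).astype(float)
        vals = plane[valid]
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            scaled = np.clip((plane - lo) / (hi - lo), 0.0, 1.0)
        else:
            scaled = np.zeros_like(plane)
        scaled = np.where(valid, scaled, 0.0)
        channels.append(scaled)
    return np.stack(channels, axis=-1)


def save_map_png(pmap: PredictionMap, path: str, cmap: str = "jet") -> str:
    """Write the prediction map with a colorbar (background rendered
    neutral grey)."""
    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    masked = np.ma.masked_invalid(pmap.values)
    im = ax.imshow(masked, cmap=cmap, vmin=pmap.vmin, vmax=pmap.vmax)
    im.cmap.set_bad("0.85")
    ax.set_axis_off()
    title = f"{pmap.analyte} content (% w/w)" if pmap.analyte else "content (% w/w)"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    return path
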