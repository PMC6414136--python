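"""HU-to-density calibration: predict a material's physical density from its
mean CT number via a scanner calibration curve and score the prediction
against the density measured from mass and dimensions.

The curve is a piecewise-linear map through ordered (HU, density) knots —
the form treatment planning systems use — with linear extrapolation beyond
the end knots, floored at zero density.  Percent error uses the measured
("true") density as the denominator.

A representative generic 120 kVp curve ships as a packaged fixture
(``boluscap.calibration.default_curve``); scanner-specific curves are read
from delimited text (two columns: hu, density; header optional).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
import os

import numpy as np
import pandas as pd

from .errors import CalibrationError


@dataclasses.dataclass(frozen=True)
class CalibrationCurve:
    """Ordered (HU, density g/cm^3) knots of a piecewise-linear calibration."""

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "density", density)
        if hu.ndim != 1 or hu.shape != density.shape:
            raise CalibrationError("hu and density must be equal-length 1D arrays")
        if hu.size < 2:
            raise CalibrationError("a calibration curve needs at least 2 knots")
        if np.any(np.diff(hu) <= 0):
            raise CalibrationError("knot HU values must be strictly increasing")
        if np.any(density <= 0):
            raise CalibrationError("knot densities must be positive")

    @classmethod
    def from_file(cls, path: str | os.PathLike | io.IOBase) -> "CalibrationCurve":
        table = pd.read_csv(path, sep=None, engine="python", comment="#")
        if table.shape[1] < 2:
            raise CalibrationError("curve file needs two columns: hu, density")
        # tolerate headerless files: if the header parsed as numbers, keep it
        try:
            extra = [[float(c) for c in table.columns[:2]]]
        except (TypeError, ValueError):
            extra = []
        values = np.vstack(extra + [table.iloc[:, :2].to_numpy(dtype=float)])
        order = np.argsort(values[:, 0])
        return cls(hu=values[order, 0], density=values[order, 1])


@dataclasses.dataclass(frozen=True)
class MaterialSample:
    """A printed test strip: its CT statistics and caliper/scale density."""

    name: str
    mean_hu: float
    hu_sd: float
    measured_density: float  # g/cm^3, from mass and dimensions

    def __post_init__(self) -> None:
        if self.measured_density <= 0:
            raise CalibrationError("measured density must be positive")


def default_curve() -> CalibrationCurve:
    """The packaged generic 120 kVp HU -> physical density curve."""
    ref = importlib.resources.files("boluscap.data") / "ct_calibration_curve.tsv"
    with ref.open("rb") as fh:
        return CalibrationCurve.from_file(fh)


def predict_density(curve: CalibrationCurve, hu) -> float | np.ndarray:
    """Piecewise-linear density (g/cm^3) at the given HU; linear
    extrapolation beyond the end knots, floored at 0."""
    x = np.asarray(hu, dtype=float)
    y = np.interp(x, curve.hu, curve.density)
    lo_slope = (curve.density[1] - curve.density[0]) / (curve.hu[1] - curve.hu[0])
    hi_slope = (curve.density[-1] - curve.density[-2]) / (curve.hu[-1] - curve.hu[-2])
    y = np.where(x < curve.hu[0], curve.density[0] + (x - curve.hu[0]) * lo_slope, y)
    y = np.where(x > curve.hu[-1], curve.density[-1] + (x - curve.hu[-1]) * hi_slope, y)
    y = np.maximum(y, 0.0)
    return float(y) if np.isscalar(hu) else y


def density_percent_error(predicted: float, measured: float) -> float:
    """100 * |predicted - measured| / measured."""
    if measured <= 0:
        raise CalibrationError("measured density must be positive")
    return 100.0 * abs(predicted - measured) / measured


def evaluate_sample(curve: CalibrationCurve, sample: MaterialSample) -> tuple[float, float]:
    """Predicted density of a sample and its percent error vs measurement."""
    pred = predict_density(curve, sample.mean_hu)
    return pred, density_percent_error(pred, sample.measured_density)
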