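"""Calibration, LOD/LOQ estimation and surrogate-standard quantification.

Calibration lines are ordinary least squares fits of peak area versus
standard concentration (ug/mL).  Detection limits follow the baseline
noise convention: LOD and LOQ are the concentrations whose predicted peak
*height* equals 3x and 10x the baseline noise SD, so LOQ/LOD = 10/3 by
construction.  The calibration intercept is excluded from the LOD signal:
the signal is the analyte response above baseline, height = slope * conc
* height_per_area, with height_per_area the peak-shape constant
1/(sigma*sqrt(2*pi)) of a Gaussian peak.

Measured areas invert to concentrations through the compound's own or its
family surrogate's line, and concentration converts to dry-sample content
as content [mg/kg] = conc [ug/mL] * elution_volume [mL] / sample_mass [g]
(a factor of 20 for the default 0.5 g / 10 mL preparation).  Contents
below the LOQ are reported missing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "QuantResult",
    "DegenerateCalibrationError",
    "fit_calibration",
    "estimate_lod_loq",
    "quantify",
    "content_conversion",
    "save_calibration_csv",
    "load_calibration_csv",
]

DEFAULT_SAMPLE_MASS = 0.5      # g
DEFAULT_ELUTION_VOLUME = 10.0  # mL
LOD_SNR = 3.0
LOQ_SNR = 10.0


class DegenerateCalibrationError(ValueError):
    """The calibration data carry no usable concentration response."""


@dataclass
class CalibrationModel:
    """A fitted line area = slope * conc + intercept with its figures of merit."""

    compound: str
    slope: float                      # counts*min per (ug/mL)
    intercept: float                  # counts*min
    r_squared: float
    linear_range: tuple[float, float]  # ug/mL
    lod: float = 0.0                  # ug/mL
    loq: float = 0.0                  # ug/mL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DegenerateCalibrationError(
                f"{self.compound}: non-positive calibration slope")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")
        if self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, area: float) -> float:
        return max((area - self.intercept) / self.slope, 0.0)


@dataclass
class QuantResult:
    """Quantification of one compound in one run."""

    compound: str
    area: float                # counts*min
    concentration: float       # ug/mL
    content: float | None      # mg/kg dry sample; None when below LOQ
    below_loq: bool
    surrogate_used: str

    def __post_init__(self) -> None:
        if self.below_loq and self.content is not None:
            raise ValueError("below-LOQ results must report missing content")


def fit_calibration(levels: Sequence[float], areas: Sequence[float],
                    compound: str = "") -> CalibrationModel:
    """Ordinary least squares calibration line with R^2 = 1 - SSres/SStot."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("levels and areas must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(compound=compound, slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=max(min(r2, 1.0), 0.0),
                            linear_range=(float(x.min()), float(x.max())))


def estimate_lod_loq(model: CalibrationModel, noise: float,
                     height_per_area: float) -> tuple[float, float]:
    """Concentrations whose predicted peak height is 3x / 10x the noise SD."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if height_per_area <= 0:
        raise ValueError("height_per_area must be positive")
    if noise == 0:
        warnings.warn("zero baseline noise: LOD and LOQ degenerate to 0",
                      stacklevel=2)
        return 0.0, 0.0
    lod = LOD_SNR * noise / (model.slope * height_per_area)
    loq = LOQ_SNR * noise / (model.slope * height_per_area)
    return lod, loq


def with_limits(model: CalibrationModel, noise: float,
                height_per_area: float) -> CalibrationModel:
    """A copy of the model with LOD/LOQ estimated from baseline noise."""
    lod, loq = estimate_lod_loq(model, noise, height_per_area)
    return replace(model, lod=lod, loq=loq)


def content_conversion(concentration: float, sample_mass: float = DEFAULT_SAMPLE_MASS,
                       elution_volume: float = DEFAULT_ELUTION_VOLUME) -> float:
    """Extract concentration (ug/mL) -> dry-sample content (mg/kg)."""
    if sample_mass <= 0 or elution_volume <= 0:
        raise ValueError("sample mass and elution volume must be positive")
    return concentration * elution_volume / sample_mass


def quantify(area: float, model: CalibrationModel, surrogate: str | None = None,
             compound: str | None = None,
             sample_mass: float = DEFAULT_SAMPLE_MASS,
             elution_volume: float = DEFAULT_ELUTION_VOLUME) -> QuantResult:
    """Invert a measured area to concentration and dry-sample content."""
    if area < 0:
        raise ValueError("area must be >= 0")
    conc = model.invert(area)
    below = conc < model.loq
    content = None if below else content_conversion(conc, sample_mass, elution_volume)
    return QuantResult(compound=compound or model.compound, area=float(area),
                       concentration=conc, content=content, below_loq=below,
                       surrogate_used=surrogate or model.compound)


_CAL_COLS = ["compound", "lod_ug_ml", "loq_ug_ml", "slope", "intercept",
             "r_squared", "range_lo_ug_ml", "range_hi_ug_ml"]


def save_calibration_csv(models: Sequence[CalibrationModel], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CAL_COLS)
        for m in models:
            w.writerow([m.compound, repr(m.lod), repr(m.loq), repr(m.slope),
                        repr(m.intercept), repr(m.r_squared),
                        repr(m.linear_range[0]), repr(m.linear_range[1])])


def load_calibration_csv(path) -> list[CalibrationModel]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(l for l in fh if not l.startswith("#")))
    return [CalibrationModel(compound=r["compound"], slope=float(r["slope"]),
                             intercept=float(r["intercept"]),
                             r_squared=float(r["r_squared"]),
                             linear_range=(float(r["range_lo_ug_ml"]),
                                           float(r["range_hi_ug_ml"])),
                             lod=float(r["lod_ug_ml"]), loq=float(r["loq_ug_ml"]))
            for r in rows]
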