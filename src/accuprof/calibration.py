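"""Per-series linear calibration and inverse prediction (back-calculation).

Each series (day) gets its own calibration curve fitted to that day's
calibration standards; validation standards are back-calculated against the
same day's curve, which keeps day-to-day effects estimable downstream.
The response variable is the internal-standard-normalised peak-area ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable

import numpy as np
import statsmodels.api as sm

from .exceptions import DesignError, SingularFitError
from .io import MeasurementRecord, MeasurementSet

__all__ = [
    "CalibrationFit",
    "CalibrationModel",
    "fit_calibration",
    "back_calculate",
    "back_calculate_dataset",
]

WEIGHTINGS = ("none", "one_over_x", "one_over_x2")


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted straight-line calibration for one analyte in one series.

    ``response = intercept + slope * conc``; inverse prediction is exact:
    ``conc = (response - intercept) / slope``.
    """

    analyte: str
    series: int
    intercept: float
    slope: float
    residual_sd: float
    n_points: int
    weighting: str = "none"
    model: str = "linear"

    def predict(self, conc):
        """Forward model: expected response at a concentration."""
        return self.intercept + self.slope * np.asarray(conc, dtype=float)

    def back_calculate(self, response):
        """Inverse prediction; see :func:`back_calculate`."""
        return back_calculate(self, response)


class CalibrationModel:
    """Weighted straight-line calibration model for one series.

    Parameters
    ----------
    conc : array-like
        Nominal concentrations (ng/mL).
    response : array-like
        Instrument response ratios.
    weighting : {"none", "one_over_x", "one_over_x2"}
        Regression weights as a function of nominal concentration.

    ``fit()`` returns a :class:`CalibrationFit`.
    """

    def __init__(self, conc, response, weighting: str = "none",
                 analyte: str = "", series: int = 1):
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        self.weighting = weighting
        self.analyte = analyte
        self.series = series
        if self.conc.shape != self.response.shape or self.conc.ndim != 1:
            raise DesignError("conc and response must be 1-D arrays of equal length")
        if len(np.unique(self.conc)) < 2:
            raise DesignError(
                "calibration needs at least 2 distinct concentration levels"
            )

    def fit(self) -> CalibrationFit:
        if self.weighting == "none":
            w = np.ones_like(self.conc)
        elif self.weighting == "one_over_x":
            w = 1.0 / self.conc
        else:
            w = 1.0 / self.conc**2
        X = sm.add_constant(self.conc)
        res = sm.WLS(self.response, X, weights=w).fit()
        intercept, slope = float(res.params[0]), float(res.params[1])
        if slope == 0.0 and float(np.var(self.response)) == 0.0:
            raise SingularFitError(
                "all responses identical: zero slope with zero response variance"
            )
        dof = len(self.conc) - 2
        rss = float(np.sum(w * (self.response - (intercept + slope * self.conc)) ** 2))
        residual_sd = math.sqrt(rss / dof) if dof > 0 else 0.0
        return CalibrationFit(
            analyte=self.analyte,
            series=self.series,
            intercept=intercept,
            slope=slope,
            residual_sd=residual_sd,
            n_points=len(self.conc),
            weighting=self.weighting,
        )


def fit_calibration(cs_records: Iterable[MeasurementRecord],
                    weighting: str = "none") -> CalibrationFit:
    """Fit one series' calibration curve from its CS records.

    All records must share analyte and series and carry a response.
    """
    records = list(cs_records)
    if not records:
        raise DesignError("no calibration records supplied")
    analytes = {r.analyte for r in records}
    series = {r.series for r in records}
    if len(analytes) != 1 or len(series) != 1:
        raise DesignError(
            f"calibration records must share one analyte and one series, "
            f"got analytes={sorted(analytes)}, series={sorted(series)}"
        )
    if any(r.response is None for r in records):
        raise DesignError("all calibration records must carry a response")
    model = CalibrationModel(
        conc=[r.nominal_conc for r in records],
        response=[r.response for r in records],
        weighting=weighting,
        analyte=analytes.pop(),
        series=series.pop(),
    )
    return model.fit()


def back_calculate(fit: CalibrationFit, response) -> float:
    """Inverse prediction: ``(response - intercept) / slope``.

    May return a negative concentration; callers decide how to handle it
    (clipping would bias low-level statistics).
    """
    if fit.slope == 0:
        raise SingularFitError("cannot back-calculate with zero slope")
    out = (np.asarray(response, dtype=float) - fit.intercept) / fit.slope
    return float(out) if out.ndim == 0 else out


def back_calculate_dataset(vs_records, fits: Dict[int, CalibrationFit]) -> MeasurementSet:
    """Back-calculate every VS record against its own series' fit.

    Records that already carry a concentration pass through unchanged (a
    warning is emitted).  A series without a fit is an error.
    """
    if isinstance(vs_records, MeasurementSet):
        balanced = vs_records.balanced
        records = vs_records.records
    else:
        records = list(vs_records)
        balanced = True
    missing = sorted({r.series for r in records} - set(fits))
    if missing:
        raise DesignError(f"no calibration fit for series {missing}")
    out = []
    preset = 0
    for r in records:
        if r.conc is not None:
            preset += 1
            out.append(r)
        else:
            out.append(replace(r, conc=back_calculate(fits[r.series], r.response)))
    if preset:
        warnings.warn(
            f"{preset} record(s) already carried a concentration; passed through",
            stacklevel=2,
        )
    return MeasurementSet(records=out, balanced=balanced)
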