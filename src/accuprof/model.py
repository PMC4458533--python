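"""statsmodels-style model/results objects for assay validation.

:class:`MethodValidation` is constructed from back-calculated validation-
standard concentrations (or from a published summary table); ``fit()``
estimates the per-level variance components and tolerance intervals and
returns a :class:`ValidationResults` carrying the accuracy profile, the
validated range and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, DesignError
from .io import MeasurementRecord, MeasurementSet
from .profile import AccuracyProfile, build_profile, plot_profile, profile_plot_data
from .stats import LevelStats, level_statistics, level_statistics_from_summary

__all__ = ["MethodValidation", "ValidationResults"]


class MethodValidation:
    """Total-error accuracy-profile validation of one quantitative assay.

    Parameters
    ----------
    data : pandas.DataFrame
        Raw mode: one row per replicate with columns ``series``,
        ``nominal_conc`` and ``conc`` (back-calculated, ng/mL).  The design
        must be balanced within each level.
    beta : float
        Tolerance-interval coverage probability (default 0.95).
    lambda_pct : float
        Acceptance limit, % of nominal (default 15, i.e. ±15%).
    analyte : str
        Label used in outputs.

    Use :meth:`from_summary` to validate from a printed per-level
    (bias, RSD_r, RSD_IP) table instead of raw replicates.
    """

    def __init__(self, data: pd.DataFrame, beta: float = 0.95,
                 lambda_pct: float = 15.0, analyte: str = ""):
        required = {"series", "nominal_conc", "conc"}
        missing = required - set(data.columns)
        if missing:
            raise DataValidationError(f"data is missing columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.beta = float(beta)
        self.lambda_pct = float(lambda_pct)
        self.analyte = analyte
        self._summary_table: Optional[pd.DataFrame] = None
        self._pn: Optional[tuple] = None

    @classmethod
    def from_records(cls, records: Iterable[MeasurementRecord], beta: float = 0.95,
                     lambda_pct: float = 15.0, analyte: str = "") -> "MethodValidation":
        """Build from measurement records whose ``conc`` is already filled."""
        if isinstance(records, MeasurementSet):
            records = records.records
        rows = [
            {"series": r.series, "nominal_conc": r.nominal_conc, "conc": r.conc}
            for r in records
            if analyte in ("", r.analyte)
        ]
        if not rows:
            raise DataValidationError("no matching records")
        if any(row["conc"] is None for row in rows):
            raise DataValidationError(
                "records must carry back-calculated concentrations; "
                "run back_calculate_dataset first"
            )
        return cls(pd.DataFrame(rows), beta=beta, lambda_pct=lambda_pct,
                   analyte=analyte)

    @classmethod
    def from_summary(cls, table: pd.DataFrame, p: int, n: int, beta: float = 0.95,
                     lambda_pct: float = 15.0, analyte: str = "") -> "MethodValidation":
        """Build from per-level summary triples (no raw data needed).

        ``table`` needs columns ``nominal_conc``, ``bias_pct``, ``rsd_r_pct``,
        ``rsd_ip_pct``; ``p``/``n`` are the series count and replicates per
        series of the original design.
        """
        required = {"nominal_conc", "bias_pct", "rsd_r_pct", "rsd_ip_pct"}
        missing = required - set(table.columns)
        if missing:
            raise DataValidationError(f"summary table missing columns {sorted(missing)}")
        if len(table) == 0:
            raise DataValidationError("summary table is empty")
        model = cls.__new__(cls)
        model.data = None
        model.beta = float(beta)
        model.lambda_pct = float(lambda_pct)
        model.analyte = analyte
        model._summary_table = table.reset_index(drop=True)
        model._pn = (int(p), int(n))
        return model

    def _level_matrices(self):
        """Yield (nominal_conc, p x n matrix) per level, checking balance."""
        for nominal, grp in self.data.groupby("nominal_conc", sort=True):
            counts = grp.groupby("series").size()
            if counts.nunique() != 1:
                raise DesignError(
                    f"level {nominal}: unequal replicates per series "
                    f"{dict(counts)}; balanced design required"
                )
            mat = (
                grp.sort_values("series")
                .groupby("series")["conc"]
                .apply(list)
                .tolist()
            )
            yield float(nominal), np.asarray(mat, dtype=float)

    def fit(self) -> "ValidationResults":
        """Compute per-level statistics and the accuracy-profile decision."""
        if self._summary_table is not None:
            p, n = self._pn
            level_stats = [
                level_statistics_from_summary(
                    row.nominal_conc, row.bias_pct, row.rsd_r_pct, row.rsd_ip_pct,
                    p=p, n=n, beta=self.beta,
                )
                for row in self._summary_table.itertuples()
            ]
        else:
            level_stats = [
                level_statistics(mat, nominal, beta=self.beta)
                for nominal, mat in self._level_matrices()
            ]
        profile = build_profile(level_stats, beta=self.beta,
                                lambda_pct=self.lambda_pct, analyte=self.analyte)
        return ValidationResults(self, profile)


class ValidationResults:
    """Results of an accuracy-profile validation fit.

    Attributes
    ----------
    profile : AccuracyProfile
        Ordered levels with tolerance limits, validity flags and LLOQ/ULOQ.
    levels : tuple of LevelStats
    validated : bool
        True iff every tested level is valid at ±λ.
    lloq, uloq : float or None
        Limits of the validated concentration range (ng/mL).
    """

    def __init__(self, model: MethodValidation, profile: AccuracyProfile):
        self.model = model
        self.profile = profile

    @property
    def levels(self):
        return self.profile.levels

    @property
    def validated(self) -> bool:
        return self.profile.validated

    @property
    def lloq(self):
        return self.profile.lloq

    @property
    def uloq(self):
        return self.profile.uloq

    def to_frame(self) -> pd.DataFrame:
        """Per-level statistics as a DataFrame (one row per level)."""
        rows = []
        for ls, ok in zip(self.profile.levels, self.profile.valid_flags):
            rows.append(
                {
                    "nominal_conc": ls.nominal_conc,
                    "grand_mean": ls.grand_mean,
                    "bias_pct": ls.bias_pct,
                    "rsd_r_pct": ls.rsd_r_pct,
                    "rsd_ip_pct": ls.rsd_ip_pct,
                    "dof_int": ls.dof_int,
                    "k_tol": ls.k_tol,
                    "tol_lower_pct": ls.tol_lower_pct,
                    "tol_upper_pct": ls.tol_upper_pct,
                    "valid": bool(ok),
                }
            )
        return pd.DataFrame(rows)

    def plot_data(self) -> pd.DataFrame:
        return profile_plot_data(self.profile)

    def plot(self, ax=None):
        return plot_profile(self.profile, ax=ax)

    def summary(self) -> str:
        """Human-readable validation summary table."""
        p = self.profile
        name = p.analyte or "assay"
        head = [
            f"Accuracy-profile validation — {name}",
            f"beta = {p.beta:g}, acceptance limits = ±{p.lambda_pct:g}%",
        ]
        table = self.to_frame()
        body = table.to_string(
            index=False,
            float_format=lambda v: f"{v:10.4f}",
            columns=["nominal_conc", "bias_pct", "rsd_r_pct", "rsd_ip_pct",
                     "tol_lower_pct", "tol_upper_pct", "valid"],
        )
        if self.validated:
            tail = (
                f"VALIDATED over {p.lloq:g}–{p.uloq:g} ng/mL "
                f"(LLOQ = {p.lloq:g} ng/mL)"
            )
        elif p.lloq is not None:
            tail = (
                f"NOT fully validated; limits stay within ±{p.lambda_pct:g}% "
                f"over {p.lloq:g}–{p.uloq:g} ng/mL"
            )
        else:
            tail = "NOT validated at any tested level"
        rule = "=" * 72
        return "\n".join([rule, *head, rule, body, rule, tail, rule])

    def __repr__(self):
        status = "validated" if self.validated else "not validated"
        return (f"<ValidationResults: {len(self.levels)} levels, {status}, "
                f"lloq={self.lloq}, uloq={self.uloq}>")
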