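"""Domain types and delimited-text I/O for method-validation datasets.

The on-disk interchange format is comma-separated UTF-8 with a header row
and '.' as the decimal separator.  Series and level indices are 1-based in
files, matching the usual presentation of validation tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from .exceptions import DataValidationError, SchemaError

__all__ = [
    "ValidationDesign",
    "MeasurementRecord",
    "RecoveryRecord",
    "MeasurementSet",
    "read_measurements",
    "read_recovery",
    "write_measurements",
    "write_profile",
    "read_profile",
]


@dataclass(frozen=True)
class ValidationDesign:
    """Balanced calibration/validation design.

    Parameters
    ----------
    n_series : int
        Number of series (days), ``p``.  At least 2.
    n_cs_reps : int
        Replicates per calibration-standard level per series.
    n_vs_reps : int
        Replicates per validation-standard level per series, ``n``.  At least 2.
    cs_levels, vs_levels : sequence of float
        Nominal concentrations (ng/mL), strictly increasing and positive.
    beta : float
        Coverage probability of the tolerance interval, in (0, 1).
    lambda_pct : float
        Symmetric acceptance limit as % of nominal (e.g. 15 for ±15%).
    """

    n_series: int
    n_cs_reps: int
    n_vs_reps: int
    cs_levels: tuple
    vs_levels: tuple
    beta: float = 0.95
    lambda_pct: float = 15.0

    def __post_init__(self):
        object.__setattr__(self, "cs_levels", tuple(float(c) for c in self.cs_levels))
        object.__setattr__(self, "vs_levels", tuple(float(c) for c in self.vs_levels))
        if self.n_series < 2:
            raise DataValidationError("n_series must be >= 2")
        if self.n_vs_reps < 2:
            raise DataValidationError("n_vs_reps must be >= 2")
        if self.n_cs_reps < 1:
            raise DataValidationError("n_cs_reps must be >= 1")
        for name, levels in (("cs_levels", self.cs_levels), ("vs_levels", self.vs_levels)):
            if len(levels) == 0:
                raise DataValidationError(f"{name} must be non-empty")
            if any(c <= 0 for c in levels):
                raise DataValidationError(f"{name} must be positive")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise DataValidationError(f"{name} must be strictly increasing")
        if not 0.0 < self.beta < 1.0:
            raise DataValidationError("beta must lie in (0, 1)")
        if self.lambda_pct <= 0:
            raise DataValidationError("lambda_pct must be positive")


@dataclass(frozen=True)
class MeasurementRecord:
    """One replicate observation of a calibration or validation standard.

    Either ``response`` (instrument response ratio, analyte area / IS area) or
    ``conc`` (back-calculated concentration, ng/mL) must be present.
    """

    analyte: str
    role: str  # "CS" or "VS"
    series: int  # 1-based day index
    level: int  # 1-based concentration-level index
    nominal_conc: float  # ng/mL
    response: Optional[float] = None
    conc: Optional[float] = None

    def __post_init__(self):
        if self.nominal_conc <= 0:
            raise DataValidationError(
                f"nominal_conc must be positive, got {self.nominal_conc}"
            )
        if self.response is None and self.conc is None:
            raise DataValidationError("record needs at least one of response/conc")
        if self.role not in ("CS", "VS"):
            raise DataValidationError(f"role must be 'CS' or 'VS', got {self.role!r}")
        if self.series < 1:
            raise DataValidationError("series index is 1-based and must be >= 1")


@dataclass(frozen=True)
class RecoveryRecord:
    """Extracted vs. non-extracted peak areas for one recovery determination."""

    analyte: str
    level: int
    series: int
    area_extracted: float
    area_reference: float

    def __post_init__(self):
        if self.area_extracted <= 0 or self.area_reference <= 0:
            raise DataValidationError("peak areas must be positive")


@dataclass
class MeasurementSet:
    """An ordered collection of records with a balance flag.

    ``balanced`` is False when the series x level replicate counts are ragged;
    downstream variance-component statistics reject unbalanced sets.
    """

    records: list = field(default_factory=list)
    balanced: bool = True

    def __iter__(self) -> Iterator[MeasurementRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


_MEAS_REQUIRED = ["analyte", "role", "series", "level", "nominal_conc"]


def _check_balance(records: Sequence[MeasurementRecord]) -> bool:
    counts = {}
    for r in records:
        counts.setdefault((r.analyte, r.role, r.level), {}).setdefault(r.series, 0)
        counts[(r.analyte, r.role, r.level)][r.series] += 1
    for per_series in counts.values():
        if len(set(per_series.values())) > 1:
            return False
    return True


def read_measurements(path, role: Optional[str] = None) -> MeasurementSet:
    """Read a measurement CSV into validated records, preserving row order.

    Parameters
    ----------
    path : path-like
        CSV with columns analyte, role, series, level, nominal_conc and at
        least one of response / conc.
    role : {"CS", "VS"}, optional
        If given, keep only rows with this role.

    Raises
    ------
    SchemaError
        A required column is missing.
    DataValidationError
        A row violates an invariant (message names the offending row).
    """
    df = pd.read_csv(path)
    for col in _MEAS_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if "response" not in df.columns and "conc" not in df.columns:
        raise SchemaError(f"need a 'response' or 'conc' column in {path}")
    records = []
    for i, row in df.iterrows():
        if role is not None and str(row["role"]) != role:
            continue
        try:
            records.append(
                MeasurementRecord(
                    analyte=str(row["analyte"]),
                    role=str(row["role"]),
                    series=int(row["series"]),
                    level=int(row["level"]),
                    nominal_conc=float(row["nominal_conc"]),
                    response=_opt_float(row.get("response")),
                    conc=_opt_float(row.get("conc")),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"row {i + 2} of {path}: {exc}") from exc
    balanced = _check_balance(records)
    if not balanced:
        warnings.warn(
            f"{path}: ragged design (unequal replicates per series x level)",
            stacklevel=2,
        )
    return MeasurementSet(records=records, balanced=balanced)


def _opt_float(v) -> Optional[float]:
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def read_recovery(path) -> list:
    """Read a recovery CSV (analyte, level, series, area_extracted, area_reference)."""
    df = pd.read_csv(path)
    required = ["analyte", "level", "series", "area_extracted", "area_reference"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                RecoveryRecord(
                    analyte=str(row["analyte"]),
                    level=int(row["level"]),
                    series=int(row["series"]),
                    area_extracted=float(row["area_extracted"]),
                    area_reference=float(row["area_reference"]),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"row {i + 2} of {path}: {exc}") from exc
    return out


def write_measurements(records, path) -> None:
    """Write measurement records to CSV in the canonical schema."""
    if isinstance(records, MeasurementSet):
        records = records.records
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, index=False)


_PROFILE_COLUMNS = [
    "level",
    "nominal_conc",
    "bias_pct",
    "rsd_r_pct",
    "rsd_ip_pct",
    "tol_lower_pct",
    "tol_upper_pct",
    "valid",
]


def write_profile(profile, path) -> None:
    """Write an accuracy profile as CSV: ``# key=value`` metadata then one row per level.

    Floats are written with 17 significant digits so that a read round-trips
    every statistic to better than 1e-9.
    """
    if len(profile.levels) == 0:
        raise DataValidationError("refusing to write an empty profile")
    path = Path(path)
    lines = [
        f"# analyte={profile.analyte}",
        f"# beta={profile.beta!r}",
        f"# lambda_pct={profile.lambda_pct!r}",
        f"# p={profile.levels[0].p}",
        f"# n={profile.levels[0].n}",
        ",".join(_PROFILE_COLUMNS),
    ]
    for i, (ls, ok) in enumerate(zip(profile.levels, profile.valid_flags), start=1):
        nums = [ls.nominal_conc, ls.bias_pct, ls.rsd_r_pct, ls.rsd_ip_pct,
                ls.tol_lower_pct, ls.tol_upper_pct]
        lines.append(
            f"{i}," + ",".join(f"{v:.17g}" for v in nums) + f",{str(bool(ok)).lower()}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_profile(path):
    """Read a profile CSV written by :func:`write_profile`.

    Returns
    -------
    (pandas.DataFrame, dict)
        Per-level statistics table and the header metadata.
    """
    path = Path(path)
    meta = {}
    rows = []
    header = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        elif header is None:
            header = line.split(",")
        elif line.strip():
            rows.append(line.split(","))
    if header != _PROFILE_COLUMNS:
        raise SchemaError(f"unexpected profile header in {path}: {header}")
    df = pd.DataFrame(rows, columns=header)
    for col in _PROFILE_COLUMNS[:-1]:
        df[col] = df[col].astype(float)
    df["valid"] = df["valid"].map({"true": True, "false": False})
    for key in ("beta", "lambda_pct"):
        if key in meta:
            meta[key] = float(meta[key])
    for key in ("p", "n"):
        if key in meta:
            meta[key] = int(meta[key])
    return df, meta
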