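"""Trueness, precision and β-expectation tolerance intervals per concentration level.

The statistical model is a balanced one-way random-effects ANOVA on the
back-calculated concentrations x_ij of one validation level measured over
p series (days) with n replicates each:

    x_ij = mu + tau_i + e_ij,   tau_i ~ N(0, s2_between),  e_ij ~ N(0, s2_within)

Repeatability variance is s2_within; intermediate-precision variance is
s2_within + s2_between.  The between-series component uses the unconstrained
ANOVA estimator and is deliberately NOT truncated at zero: published
validation tables routinely show intermediate-precision RSD below the
repeatability RSD, and only the untruncated convention reproduces their
tolerance limits.

The β-expectation tolerance interval for a single future result is of the
Mee type:

    bias_pct -/+ k * RSD_IP,
    k = t_{(1+beta)/2, floor(nu)} * sqrt(1 + 1/(p n B^2)),
    B^2 = (R+1)/(nR+1),   R = s2_between / s2_within,

with nu the Satterthwaite effective degrees of freedom of the
intermediate-precision variance, floored to an integer (minimum 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import stats as sps

from .exceptions import DataValidationError, DesignError
from .io import RecoveryRecord

__all__ = [
    "VarianceComponents",
    "ToleranceInterval",
    "LevelStats",
    "RecoveryStats",
    "variance_components",
    "satterthwaite_dof",
    "tolerance_interval",
    "level_statistics",
    "level_statistics_from_summary",
    "recovery_statistics",
]


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA variance components of a balanced p x n one-way layout.

    ``s2_between`` may be negative (unconstrained estimator); the identity
    ``s2_ip == s2_within + s2_between`` holds exactly by construction.
    """

    s2_within: float
    s2_between: float
    p: int
    n: int

    @property
    def s2_ip(self) -> float:
        return self.s2_within + self.s2_between


@dataclass(frozen=True)
class ToleranceInterval:
    lower_pct: float
    upper_pct: float
    dof: float
    dof_int: int
    k: float


@dataclass(frozen=True)
class LevelStats:
    """Validation statistics for one concentration level.

    Relative quantities (bias, RSDs, tolerance limits) are percentages of the
    nominal concentration.  The tolerance interval is symmetric about the bias.
    """

    nominal_conc: float
    grand_mean: float
    bias_pct: float
    rsd_r_pct: float
    rsd_ip_pct: float
    p: int
    n: int
    dof: float
    dof_int: int
    k_tol: float
    tol_lower_pct: float
    tol_upper_pct: float
    variance_components: Optional[VarianceComponents] = None


@dataclass(frozen=True)
class RecoveryStats:
    """Extraction-recovery summary: per-level means and their overall mean/SD (%)."""

    per_level_pct: Dict[int, float]
    overall_mean_pct: float
    overall_sd_pct: float


def variance_components(x) -> VarianceComponents:
    """Estimate within/between-series variances from a balanced p x n matrix.

    Rows are series (days), columns replicates.  Uses the method-of-moments
    ANOVA estimator; ``s2_between`` is not truncated at zero.

    Raises
    ------
    DesignError
        Fewer than 2 series or 2 replicates, or missing cells.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DesignError("expected a 2-D series x replicate matrix")
    p, n = x.shape
    if p < 2 or n < 2:
        raise DesignError(f"need p >= 2 series and n >= 2 replicates, got {p} x {n}")
    if not np.all(np.isfinite(x)):
        raise DesignError("matrix has missing or non-finite cells; design must be balanced")
    series_means = x.mean(axis=1)
    grand = x.mean()
    ms_between = n * float(np.sum((series_means - grand) ** 2)) / (p - 1)
    ms_within = float(np.sum((x - series_means[:, None]) ** 2)) / (p * (n - 1))
    return VarianceComponents(
        s2_within=ms_within,
        s2_between=(ms_between - ms_within) / n,
        p=p,
        n=n,
    )


@lru_cache(maxsize=4096)
def _t_quantile(q: float, df: int) -> float:
    # cached: Monte-Carlo loops hit the same (q, df) pairs repeatedly
    return float(sps.t.ppf(q, df))


def satterthwaite_dof(R: float, p: int, n: int) -> float:
    """Satterthwaite effective df of the intermediate-precision variance.

    ``R`` is the between/within variance ratio (may be negative).
    """
    return (R + 1.0) ** 2 / (
        (R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n)
    )


def tolerance_interval(bias_pct: float, rsd_r_pct: float, rsd_ip_pct: float,
                       p: int, n: int, beta: float = 0.95) -> ToleranceInterval:
    """β-expectation tolerance interval of the relative error (%) for one level.

    Computed from summary statistics alone, so published validation tables can
    be reproduced without raw data.  The variance ratio
    ``R = (RSD_IP^2 - RSD_r^2) / RSD_r^2`` is used as-is (possibly negative);
    if ``nR + 1 <= 0`` the interval falls back to ``R = 0`` with a warning.

    Returns
    -------
    ToleranceInterval
        Limits (``bias -/+ k * RSD_IP``), real and integer-floored Satterthwaite
        df, and the coverage factor ``k``.
    """
    if not 0.0 < beta < 1.0:
        raise DataValidationError("beta must lie in (0, 1)")
    if p < 2 or n < 2:
        raise DesignError(f"need p >= 2 and n >= 2, got p={p}, n={n}")
    if rsd_r_pct <= 0:
        raise DataValidationError(
            "rsd_r_pct must be positive; for degenerate (zero-variance) levels "
            "use level_statistics, which handles them directly"
        )
    R = (rsd_ip_pct**2 - rsd_r_pct**2) / rsd_r_pct**2
    if n * R + 1.0 <= 0.0:
        warnings.warn(
            f"nR+1 = {n * R + 1.0:.3g} <= 0 (strongly negative between-series "
            "variance); falling back to R = 0",
            stacklevel=2,
        )
        R = 0.0
    B2 = (R + 1.0) / (n * R + 1.0)
    dof = satterthwaite_dof(R, p, n)
    dof_int = max(1, math.floor(dof))
    k = _t_quantile((1.0 + beta) / 2.0, dof_int) * math.sqrt(
        1.0 + 1.0 / (p * n * B2)
    )
    half = k * rsd_ip_pct
    return ToleranceInterval(
        lower_pct=bias_pct - half,
        upper_pct=bias_pct + half,
        dof=dof,
        dof_int=dof_int,
        k=k,
    )


def level_statistics(x, nominal_conc: float, beta: float = 0.95) -> LevelStats:
    """Full per-level statistics from a balanced p x n concentration matrix.

    Bias and RSDs are expressed relative to the nominal concentration.  A level
    with zero within- and between-series variance gets the degenerate interval
    ``[bias, bias]``.
    """
    if nominal_conc <= 0:
        raise DataValidationError("nominal_conc must be positive")
    vc = variance_components(x)
    grand = float(np.asarray(x, dtype=float).mean())
    bias_pct = 100.0 * (grand - nominal_conc) / nominal_conc
    rsd_r_pct = 100.0 * math.sqrt(vc.s2_within) / nominal_conc
    if vc.s2_ip < 0:
        raise DataValidationError("negative intermediate-precision variance")
    rsd_ip_pct = 100.0 * math.sqrt(vc.s2_ip) / nominal_conc
    if rsd_r_pct == 0.0:
        # all replicates identical within series: degenerate interval at the bias
        dof = float(vc.p * vc.n - 1)
        ti = ToleranceInterval(bias_pct, bias_pct, dof, max(1, math.floor(dof)), 0.0)
    else:
        ti = tolerance_interval(bias_pct, rsd_r_pct, rsd_ip_pct, vc.p, vc.n, beta)
    return LevelStats(
        nominal_conc=float(nominal_conc),
        grand_mean=grand,
        bias_pct=bias_pct,
        rsd_r_pct=rsd_r_pct,
        rsd_ip_pct=rsd_ip_pct,
        p=vc.p,
        n=vc.n,
        dof=ti.dof,
        dof_int=ti.dof_int,
        k_tol=ti.k,
        tol_lower_pct=ti.lower_pct,
        tol_upper_pct=ti.upper_pct,
        variance_components=vc,
    )


def level_statistics_from_summary(nominal_conc: float, bias_pct: float,
                                  rsd_r_pct: float, rsd_ip_pct: float,
                                  p: int, n: int, beta: float = 0.95) -> LevelStats:
    """Per-level statistics from a printed (bias, RSD_r, RSD_IP) summary triple.

    This is the entry point that reproduces published validation tables
    directly, with no raw replicate data.
    """
    if rsd_r_pct == 0.0 and rsd_ip_pct == 0.0:
        dof = float(p * n - 1)
        ti = ToleranceInterval(bias_pct, bias_pct, dof, max(1, math.floor(dof)), 0.0)
    else:
        ti = tolerance_interval(bias_pct, rsd_r_pct, rsd_ip_pct, p, n, beta)
    return LevelStats(
        nominal_conc=float(nominal_conc),
        grand_mean=float(nominal_conc) * (1.0 + bias_pct / 100.0),
        bias_pct=float(bias_pct),
        rsd_r_pct=float(rsd_r_pct),
        rsd_ip_pct=float(rsd_ip_pct),
        p=int(p),
        n=int(n),
        dof=ti.dof,
        dof_int=ti.dof_int,
        k_tol=ti.k,
        tol_lower_pct=ti.lower_pct,
        tol_upper_pct=ti.upper_pct,
    )


def recovery_statistics(records: Iterable[RecoveryRecord]) -> RecoveryStats:
    """Extraction recovery: per-level mean %, then the mean and SD over levels.

    Each record contributes ``100 * area_extracted / area_reference``; the
    overall figure is the unweighted mean of the per-level means, its SD the
    sample standard deviation of those means.
    """
    per_level: Dict[int, List[float]] = {}
    for r in records:
        if r.area_reference <= 0:
            raise DataValidationError("zero or negative reference area")
        per_level.setdefault(r.level, []).append(
            100.0 * r.area_extracted / r.area_reference
        )
    if not per_level:
        raise DataValidationError("no recovery records supplied")
    means = {lvl: float(np.mean(v)) for lvl, v in sorted(per_level.items())}
    vals = np.array(list(means.values()))
    overall_sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RecoveryStats(
        per_level_pct=means,
        overall_mean_pct=float(vals.mean()),
        overall_sd_pct=overall_sd,
    )
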