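"""Accuracy-profile assembly, acceptance decision and quantification limits.

A level is valid when its whole β-expectation tolerance interval lies inside
the acceptance limits ±λ (boundary equality counts as valid: the acceptance
rule is a non-strict inequality).  The validated range is the contiguous run
of valid levels; where a tolerance-limit curve crosses ±λ between adjacent
levels, the crossing concentration is located by linear interpolation on the
concentration axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import pandas as pd

from .exceptions import DataValidationError
from .stats import LevelStats

__all__ = [
    "AccuracyProfile",
    "build_profile",
    "determine_limits_of_quantification",
    "profile_plot_data",
    "plot_profile",
]


@dataclass(frozen=True)
class AccuracyProfile:
    """Ordered per-level statistics plus the acceptance decision.

    ``valid_flags[i]`` is True iff level i's tolerance interval is contained in
    [-lambda_pct, +lambda_pct]; ``validated`` is True iff every level is valid,
    in which case the validated range spans the full set of levels.
    """

    analyte: str
    beta: float
    lambda_pct: float
    levels: Tuple[LevelStats, ...]
    valid_flags: Tuple[bool, ...]
    lloq: Optional[float]
    uloq: Optional[float]
    validated: bool


def _level_valid(ls: LevelStats, lambda_pct: float) -> bool:
    return max(abs(ls.tol_lower_pct), abs(ls.tol_upper_pct)) <= lambda_pct


def build_profile(level_stats: Iterable[LevelStats], beta: float,
                  lambda_pct: float, analyte: str = "") -> AccuracyProfile:
    """Assemble level statistics into an accuracy profile with the ±λ decision.

    Levels are sorted by nominal concentration; duplicate nominal
    concentrations are an error.
    """
    levels = tuple(sorted(level_stats, key=lambda ls: ls.nominal_conc))
    if not levels:
        raise DataValidationError("profile needs at least one level")
    nominals = [ls.nominal_conc for ls in levels]
    if len(set(nominals)) != len(nominals):
        raise DataValidationError("duplicate nominal concentrations in profile")
    if lambda_pct <= 0:
        raise DataValidationError("lambda_pct must be positive")
    flags = tuple(_level_valid(ls, lambda_pct) for ls in levels)
    profile = AccuracyProfile(
        analyte=analyte,
        beta=beta,
        lambda_pct=lambda_pct,
        levels=levels,
        valid_flags=flags,
        lloq=None,
        uloq=None,
        validated=all(flags),
    )
    lloq, uloq = determine_limits_of_quantification(profile)
    return AccuracyProfile(
        analyte=analyte,
        beta=beta,
        lambda_pct=lambda_pct,
        levels=levels,
        valid_flags=flags,
        lloq=lloq,
        uloq=uloq,
        validated=all(flags),
    )


def _crossing(c0: float, y0: float, c1: float, y1: float, bound: float) -> float:
    # linear interpolation on the concentration axis
    return c0 + (c1 - c0) * (bound - y0) / (y1 - y0)


def determine_limits_of_quantification(profile: AccuracyProfile) -> Tuple[Optional[float], Optional[float]]:
    """Lowest/highest quantifiable concentration under the accuracy-profile rule.

    If every level is valid, the LLOQ/ULOQ are the lowest/highest nominal
    concentrations.  Otherwise the contiguous valid run ending at the highest
    valid level defines the range, and each tolerance-limit curve that violates
    ±λ at the adjacent invalid level is interpolated against its boundary; the
    LLOQ (ULOQ) is the innermost crossing.  Both are undefined when no level
    is valid.
    """
    levels, flags, lam = profile.levels, profile.valid_flags, profile.lambda_pct
    if not any(flags):
        return None, None
    if all(flags):
        return levels[0].nominal_conc, levels[-1].nominal_conc

    # contiguous valid run ending at the highest valid level
    hi = max(i for i, ok in enumerate(flags) if ok)
    lo = hi
    while lo > 0 and flags[lo - 1]:
        lo -= 1

    if lo == 0:
        lloq = levels[0].nominal_conc
    else:
        prev, first = levels[lo - 1], levels[lo]
        crossings = []
        if prev.tol_lower_pct < -lam:
            crossings.append(_crossing(prev.nominal_conc, prev.tol_lower_pct,
                                       first.nominal_conc, first.tol_lower_pct, -lam))
        if prev.tol_upper_pct > lam:
            crossings.append(_crossing(prev.nominal_conc, prev.tol_upper_pct,
                                       first.nominal_conc, first.tol_upper_pct, lam))
        lloq = max(crossings) if crossings else first.nominal_conc

    if hi == len(levels) - 1:
        uloq = levels[-1].nominal_conc
    else:
        last, nxt = levels[hi], levels[hi + 1]
        crossings = []
        if nxt.tol_lower_pct < -lam:
            crossings.append(_crossing(last.nominal_conc, last.tol_lower_pct,
                                       nxt.nominal_conc, nxt.tol_lower_pct, -lam))
        if nxt.tol_upper_pct > lam:
            crossings.append(_crossing(last.nominal_conc, last.tol_upper_pct,
                                       nxt.nominal_conc, nxt.tol_upper_pct, lam))
        uloq = min(crossings) if crossings else last.nominal_conc

    return lloq, uloq


def profile_plot_data(profile: AccuracyProfile) -> pd.DataFrame:
    """Plot-ready table: one row per level with bias, tolerance limits and ±λ."""
    return pd.DataFrame(
        {
            "concentration": [ls.nominal_conc for ls in profile.levels],
            "bias_pct": [ls.bias_pct for ls in profile.levels],
            "tol_lower_pct": [ls.tol_lower_pct for ls in profile.levels],
            "tol_upper_pct": [ls.tol_upper_pct for ls in profile.levels],
            "lambda_lower": -profile.lambda_pct,
            "lambda_upper": profile.lambda_pct,
        }
    )


def plot_profile(profile: AccuracyProfile, ax=None):
    """Draw the accuracy profile (bias, tolerance-limit curves, ±λ lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = profile_plot_data(profile)
    ax.plot(d["concentration"], d["bias_pct"], "o-", color="C0", label="relative bias")
    ax.plot(d["concentration"], d["tol_lower_pct"], "s--", color="C1",
            label=f"{profile.beta:.0%}-expectation tolerance limits")
    ax.plot(d["concentration"], d["tol_upper_pct"], "s--", color="C1")
    ax.axhline(profile.lambda_pct, color="C3", lw=1,
               label=f"acceptance limits ±{profile.lambda_pct:g}%")
    ax.axhline(-profile.lambda_pct, color="C3", lw=1)
    ax.axhline(0, color="0.6", lw=0.5)
    ax.set_xlabel("nominal concentration (ng/mL)")
    ax.set_ylabel("relative error (%)")
    if profile.analyte:
        ax.set_title(f"Accuracy profile — {profile.analyte}")
    ax.legend(loc="best", fontsize="small")
    return ax
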