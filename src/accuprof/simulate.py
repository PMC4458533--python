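"""Synthetic plasma-assay validation experiments.

The generator emulates the statistical structure the analysis assumes: a
day-level random effect shared by all replicates of a level within a series,
additive within-day error on the concentration scale, a linear
internal-standard-normalised response with multiplicative noise, and an
extraction-recovery factor drawn once per extraction batch (series x level).

Two modes are provided.  Concentration mode emits back-calculated
concentrations directly:

    x_ij = mu_T (1 + delta/100) + tau_i + eps_ij,
    tau_i ~ N(0, (sigma_B% mu_T / 100)^2),  eps_ij ~ N(0, (sigma_W% mu_T / 100)^2)

Response mode emits peak-area-ratio responses through the calibration line so
the full pipeline (fit -> back-calculate -> validate) can run end to end.

All randomness flows through one numpy Generator seeded from
``SimulationParams.seed``; identical parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import DataValidationError
from .io import MeasurementRecord, MeasurementSet, RecoveryRecord, ValidationDesign
from .stats import level_statistics

__all__ = [
    "SimulationParams",
    "SimulatedExperiment",
    "afatinib_like_params",
    "ibrutinib_like_params",
    "simulate_concentrations",
    "simulate_responses",
    "simulate_coverage",
]


def _per_level(value, n_levels: int, name: str) -> Tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),) * n_levels
    out = tuple(float(v) for v in value)
    if len(out) != n_levels:
        raise DataValidationError(
            f"{name} has {len(out)} entries for {n_levels} levels"
        )
    return out


@dataclass(frozen=True)
class SimulationParams:
    """True parameters of a simulated validation study.

    Per-level vectors (``true_bias_pct``, ``sigma_between_pct``,
    ``sigma_within_pct``) refer to the design's VS levels; scalars broadcast.
    ``sigma_*_pct`` are SDs as % of nominal; the calibration is
    ``response = intercept + slope * conc`` with multiplicative response noise
    of CV ``response_noise_cv``; ``recovery_mean`` is the true extraction
    yield as a fraction.
    """

    design: ValidationDesign
    true_bias_pct: Union[float, Sequence[float]] = 0.0
    sigma_between_pct: Union[float, Sequence[float]] = 1.0
    sigma_within_pct: Union[float, Sequence[float]] = 2.5
    calib_intercept: float = 0.01
    calib_slope: float = 0.004
    response_noise_cv: float = 0.01
    recovery_mean: float = 0.88
    recovery_cv: float = 0.025
    seed: int = 0
    analyte: str = "analyte"

    def __post_init__(self):
        k = len(self.design.vs_levels)
        object.__setattr__(self, "true_bias_pct",
                           _per_level(self.true_bias_pct, k, "true_bias_pct"))
        object.__setattr__(self, "sigma_between_pct",
                           _per_level(self.sigma_between_pct, k, "sigma_between_pct"))
        object.__setattr__(self, "sigma_within_pct",
                           _per_level(self.sigma_within_pct, k, "sigma_within_pct"))
        if any(s < 0 for s in self.sigma_between_pct):
            raise DataValidationError("sigma_between_pct must be >= 0")
        if any(s < 0 for s in self.sigma_within_pct):
            raise DataValidationError("sigma_within_pct must be >= 0")
        if not 0.0 < self.recovery_mean <= 1.2:
            raise DataValidationError("recovery_mean must lie in (0, 1.2]")
        if self.calib_slope <= 0:
            raise DataValidationError("calib_slope must be positive")


@dataclass
class SimulatedExperiment:
    """One simulated validation study plus the truth that generated it."""

    cs_records: MeasurementSet
    vs_records: MeasurementSet
    recovery_records: List[RecoveryRecord]
    truth: SimulationParams


def afatinib_like_params(seed: int = 0) -> SimulationParams:
    """Default scenario for the afatinib plasma assay.

    3 series x 6 levels over 5-250 ng/mL, CS in triplicate, VS four times per
    day; bias and day/within-day SDs set to the magnitudes of the published
    validation summaries; extraction yield 88% (CV 2.5%).
    """
    design = ValidationDesign(
        n_series=3, n_cs_reps=3, n_vs_reps=4,
        cs_levels=(5, 25, 75, 125, 175, 250),
        vs_levels=(5, 25, 75, 125, 175, 250),
        beta=0.95, lambda_pct=15.0,
    )
    return SimulationParams(
        design=design,
        true_bias_pct=(-0.24, 1.31, 0.63, 1.29, 0.56, -0.25),
        sigma_within_pct=(5.60, 5.54, 2.70, 2.23, 1.87, 1.63),
        sigma_between_pct=(0.75, 0.0, 0.0, 0.94, 0.0, 1.00),
        recovery_mean=0.88, recovery_cv=0.025,
        seed=seed, analyte="AFA",
    )


def ibrutinib_like_params(seed: int = 0) -> SimulationParams:
    """Default scenario for the ibrutinib plasma assay (5-400 ng/mL, yield 93%)."""
    design = ValidationDesign(
        n_series=3, n_cs_reps=3, n_vs_reps=4,
        cs_levels=(5, 75, 150, 250, 350, 400),
        vs_levels=(5, 75, 150, 250, 350, 400),
        beta=0.95, lambda_pct=15.0,
    )
    return SimulationParams(
        design=design,
        true_bias_pct=(-1.21, 7.63, 0.77, -0.47, 0.43, -0.07),
        sigma_within_pct=(5.83, 1.96, 1.85, 1.77, 2.02, 1.87),
        sigma_between_pct=(0.0, 0.0, 2.14, 2.98, 2.83, 1.25),
        recovery_mean=0.93, recovery_cv=0.097,
        seed=seed, analyte="IBR",
    )


def _vs_true_concentrations(params: SimulationParams, rng: np.random.Generator):
    """Draw the true-concentration array [level][series][rep] for VS samples."""
    d = params.design
    out = np.empty((len(d.vs_levels), d.n_series, d.n_vs_reps))
    for j, mu in enumerate(d.vs_levels):
        sb = params.sigma_between_pct[j] * mu / 100.0
        sw = params.sigma_within_pct[j] * mu / 100.0
        tau = rng.normal(0.0, sb, d.n_series) if sb > 0 else np.zeros(d.n_series)
        eps = (rng.normal(0.0, sw, (d.n_series, d.n_vs_reps)) if sw > 0
               else np.zeros((d.n_series, d.n_vs_reps)))
        out[j] = mu * (1.0 + params.true_bias_pct[j] / 100.0) + tau[:, None] + eps
    return out


def simulate_concentrations(params: SimulationParams) -> SimulatedExperiment:
    """Generate an experiment whose VS records carry concentrations directly.

    No calibration layer is simulated: this mode feeds the validation
    statistics in isolation.  CS records carry their nominal concentration
    (noise enters only through the VS model).
    """
    rng = np.random.default_rng(params.seed)
    d = params.design
    x = _vs_true_concentrations(params, rng)
    vs = []
    for j, mu in enumerate(d.vs_levels):
        for i in range(d.n_series):
            for r in range(d.n_vs_reps):
                vs.append(MeasurementRecord(
                    analyte=params.analyte, role="VS", series=i + 1,
                    level=j + 1, nominal_conc=mu, conc=float(x[j, i, r]),
                ))
    cs = [
        MeasurementRecord(analyte=params.analyte, role="CS", series=i + 1,
                          level=j + 1, nominal_conc=mu, conc=mu)
        for j, mu in enumerate(d.cs_levels)
        for i in range(d.n_series)
        for _ in range(d.n_cs_reps)
    ]
    return SimulatedExperiment(
        cs_records=MeasurementSet(cs),
        vs_records=MeasurementSet(vs),
        recovery_records=[],
        truth=params,
    )


def simulate_responses(params: SimulationParams) -> SimulatedExperiment:
    """Generate an experiment at the response (peak-area-ratio) level.

    Every sample passes through the extraction and the linear response
    function with multiplicative noise.  One recovery factor is drawn per
    extraction batch — all samples of one series (day) are extracted
    together — so the day-matched calibration absorbs the day's extraction
    yield, as it does in practice.  Matching non-extracted reference areas
    are emitted for the recovery records, consistent with the drawn recovery
    factors.  The output supports the full pipeline: per-series calibration
    fits, back-calculation and validation.
    """
    rng = np.random.default_rng(params.seed)
    d = params.design
    a0, a1, cv = params.calib_intercept, params.calib_slope, params.response_noise_cv

    def noisy(v):
        v = np.asarray(v, dtype=float)
        if cv > 0:
            return v * (1.0 + rng.normal(0.0, cv, v.shape))
        return v

    if params.recovery_cv > 0:
        day_recovery = rng.normal(params.recovery_mean,
                                  params.recovery_mean * params.recovery_cv,
                                  d.n_series)
    else:
        day_recovery = np.full(d.n_series, params.recovery_mean)

    cs = []
    for i in range(d.n_series):
        rec = float(day_recovery[i])
        for j, mu in enumerate(d.cs_levels):
            resp = noisy(np.full(d.n_cs_reps, a1 * mu * rec)) + a0
            for r in range(d.n_cs_reps):
                cs.append(MeasurementRecord(
                    analyte=params.analyte, role="CS", series=i + 1,
                    level=j + 1, nominal_conc=mu, response=float(resp[r]),
                ))

    x = _vs_true_concentrations(params, rng)
    vs = []
    recovery = []
    for i in range(d.n_series):
        rec = float(day_recovery[i])
        for j, mu in enumerate(d.vs_levels):
            resp = noisy(a1 * x[j, i, :] * rec) + a0
            for r in range(d.n_vs_reps):
                vs.append(MeasurementRecord(
                    analyte=params.analyte, role="VS", series=i + 1,
                    level=j + 1, nominal_conc=mu, response=float(resp[r]),
                ))
            # recovery determination: extracted vs non-extracted standard areas
            area_ext = noisy(np.full(d.n_vs_reps, a1 * mu * rec))
            area_ref = noisy(np.full(d.n_vs_reps, a1 * mu))
            for r in range(d.n_vs_reps):
                recovery.append(RecoveryRecord(
                    analyte=params.analyte, level=j + 1, series=i + 1,
                    area_extracted=float(area_ext[r]),
                    area_reference=float(area_ref[r]),
                ))

    return SimulatedExperiment(
        cs_records=MeasurementSet(cs),
        vs_records=MeasurementSet(vs),
        recovery_records=recovery,
        truth=params,
    )


def simulate_coverage(params: SimulationParams, n_experiments: int,
                      seed: Optional[int] = None, level_index: int = 0,
                      beta: Optional[float] = None) -> float:
    """Monte-Carlo coverage of the β-expectation interval for a future result.

    For each simulated experiment at one VS level, the tolerance interval is
    computed from that experiment's p x n concentration matrix; one fresh
    observation is then drawn from the same generating model and scored as
    covered if its relative error (%) lies inside the interval.  Returns the
    mean indicator, which the β-expectation property says should equal β up
    to Monte-Carlo error.
    """
    if n_experiments < 100:
        raise DataValidationError("n_experiments must be >= 100")
    d = params.design
    beta = d.beta if beta is None else beta
    mu = d.vs_levels[level_index]
    delta = params.true_bias_pct[level_index]
    sb = params.sigma_between_pct[level_index] * mu / 100.0
    sw = params.sigma_within_pct[level_index] * mu / 100.0
    p, n = d.n_series, d.n_vs_reps
    rng = np.random.default_rng(params.seed if seed is None else seed)
    center = mu * (1.0 + delta / 100.0)
    hits = 0
    for _ in range(n_experiments):
        tau = rng.normal(0.0, sb, p) if sb > 0 else np.zeros(p)
        x = center + tau[:, None] + rng.normal(0.0, sw, (p, n))
        ls = level_statistics(x, mu, beta=beta)
        future = center + (rng.normal(0.0, sb) if sb > 0 else 0.0) + rng.normal(0.0, sw)
        rel = 100.0 * (future - mu) / mu
        hits += int(ls.tol_lower_pct <= rel <= ls.tol_upper_pct)
    return hits / n_experiments
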