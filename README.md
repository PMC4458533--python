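# accuprof

Total-error **accuracy-profile** validation of quantitative bioanalytical
assays, for analysts who must decide whether a method (e.g. an LC plasma
assay for therapeutic drug monitoring) is fit for purpose over a
concentration range.

A method is acceptable at a concentration level when a single future
measurement *x* of a sample with true value *μ_T* satisfies

    P(|x − μ_T| < λ) ≥ β

for acceptance limits ±λ (here λ = 15 % of nominal) and coverage β (here
0.95). From a balanced validation design — *p* series (days) × *n*
replicates per level — the package estimates per-level trueness (relative
bias), repeatability and intermediate precision via one-way random-effects
variance components, and computes the **β-expectation tolerance interval**
of the relative error,

    bias ∓ k·RSD_IP,   k = t_{(1+β)/2, ⌊ν⌋} · √(1 + 1/(p·n·B²)),

with B² = (R+1)/(nR+1), R = σ²_B/σ²_W (not truncated at zero) and ν the
Satterthwaite degrees of freedom. A level is valid when the whole interval
lies inside ±λ; the accuracy profile assembles the per-level intervals,
flags validity, and reports the validated range and LLOQ/ULOQ.

The package also provides per-day linear calibration with inverse prediction
(back-calculation), extraction-recovery statistics, a synthetic experiment
generator (day random effects, within-day error, linear response with
internal-standard normalisation, extraction recovery) and a CLI
(`accuprof validate | summary | simulate | coverage`).

## Worked example

Validation summaries of a published afatinib plasma assay (3 days × 4
replicates per level) ship with the package. Tolerance limits are a
deterministic function of each printed (bias, RSD_r, RSD_IP) triple and the
design, so the published decision can be reproduced without raw data:

```python
from accuprof import MethodValidation
from accuprof.datasets import afatinib_summary

res = MethodValidation.from_summary(afatinib_summary(), p=3, n=4,
                                    analyte="AFA").fit()
print(res.summary())
```

```
========================================================================
Accuracy-profile validation — AFA
beta = 0.95, acceptance limits = ±15%
========================================================================
 nominal_conc   bias_pct  rsd_r_pct  rsd_ip_pct  tol_lower_pct  tol_upper_pct  valid
       5.0000    -0.2400     5.6000      5.6500       -13.3696        12.8896   True
      25.0000     1.3100     5.5400      4.9400        -9.9703        12.5903   True
      75.0000     0.6300     2.7000      2.6300        -5.4312         6.6912   True
     125.0000     1.2900     2.2300      2.4200        -4.5063         7.0863   True
     175.0000     0.5600     1.8700      1.6600        -3.2253         4.3453   True
     250.0000    -0.2500     1.6300      1.9100        -5.0960         4.5960   True
========================================================================
VALIDATED over 5–250 ng/mL (LLOQ = 5 ng/mL)
========================================================================
```

Every 95 %-expectation tolerance interval is inside ±15 %, so the assay is
validated over the full 5–250 ng/mL range and the lowest validated level
(5 ng/mL) is the LLOQ. `res.plot()` draws the accuracy profile;
`res.to_frame()` returns the table as a DataFrame.

The raw-replicate route runs the full pipeline instead:

```python
from accuprof import (afatinib_like_params, simulate_responses,
                      fit_calibration, back_calculate_dataset, MethodValidation)

exp = simulate_responses(afatinib_like_params(seed=7))          # synthetic study
fits = {s: fit_calibration([r for r in exp.cs_records if r.series == s],
                           weighting="one_over_x2") for s in (1, 2, 3)}
vs = back_calculate_dataset(exp.vs_records, fits)               # day-matched curves
print(MethodValidation.from_records(vs, analyte="AFA").fit().summary())
```

or from the shell: `accuprof simulate --analyte AFA --outdir run/ &&
accuprof validate --cs run/cs.csv --vs run/vs.csv --weighting one_over_x2
--outdir run/out`.

## Layout

- `accuprof.stats` — variance components, tolerance intervals, level and
  recovery statistics
- `accuprof.profile` — accuracy-profile assembly, decision rule, LLOQ/ULOQ
- `accuprof.calibration` — per-series (weighted) linear calibration,
  back-calculation
- `accuprof.model` — `MethodValidation` / `ValidationResults`
- `accuprof.simulate` — synthetic experiments and the coverage harness
- `accuprof.io` — domain types and CSV readers/writers
- `accuprof.cli` — command-line entry points

See `docs/methods.md` for the statistical model, estimator conventions
(negative variance components, floored Satterthwaite df, nominal-denominator
RSDs), the generator's assumptions and known limitations.
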