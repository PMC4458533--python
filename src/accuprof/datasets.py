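"""Example datasets: published validation summaries of two plasma assays.

Per-level trueness/precision summaries from a validation of UPLC-DAD plasma
assays for the tyrosine kinase inhibitors afatinib (5-250 ng/mL) and
ibrutinib (5-400 ng/mL): 3 series (days), 4 validation-standard replicates
per level per day, diclofenac as internal standard.  The summary triples
(relative bias, repeatability RSD, intermediate-precision RSD, each % of
nominal) are the inputs to summary-mode validation; no raw replicate data
were published.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["afatinib_summary", "ibrutinib_summary", "load_summary",
           "DESIGN_P", "DESIGN_N", "RECOVERY"]

# design of the published study: p days x n VS replicates
DESIGN_P = 3
DESIGN_N = 4

# overall extraction recovery, mean % +/- SD over levels
RECOVERY = {"AFA": (88.0, 2.2), "IBR": (93.0, 9.0)}

_AFA = [
    # nominal_conc, bias_pct, rsd_r_pct, rsd_ip_pct
    (5.0, -0.24, 5.60, 5.65),
    (25.0, 1.31, 5.54, 4.94),
    (75.0, 0.63, 2.70, 2.63),
    (125.0, 1.29, 2.23, 2.42),
    (175.0, 0.56, 1.87, 1.66),
    (250.0, -0.25, 1.63, 1.91),
]

_IBR = [
    (5.0, -1.21, 5.83, 5.22),
    (75.0, 7.63, 1.96, 1.89),
    (150.0, 0.77, 1.85, 2.83),
    (250.0, -0.47, 1.77, 3.47),
    (350.0, 0.43, 2.02, 3.48),
    (400.0, -0.07, 1.87, 2.25),
]

_COLUMNS = ["nominal_conc", "bias_pct", "rsd_r_pct", "rsd_ip_pct"]


def afatinib_summary() -> pd.DataFrame:
    """Afatinib per-level validation summary (6 levels, 5-250 ng/mL)."""
    return pd.DataFrame(_AFA, columns=_COLUMNS)


def ibrutinib_summary() -> pd.DataFrame:
    """Ibrutinib per-level validation summary (6 levels, 5-400 ng/mL)."""
    return pd.DataFrame(_IBR, columns=_COLUMNS)


def load_summary(analyte: str) -> pd.DataFrame:
    """Load a summary table by analyte code ('AFA' or 'IBR')."""
    key = analyte.upper()
    if key in ("AFA", "AFATINIB"):
        return afatinib_summary()
    if key in ("IBR", "IBRUTINIB"):
        return ibrutinib_summary()
    raise KeyError(f"unknown analyte {analyte!r}; use 'AFA' or 'IBR'")
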