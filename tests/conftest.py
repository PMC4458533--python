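import matplotlib

matplotlib.use("Agg")

import pandas as pd
import pytest

# Published per-level validation summaries of the two plasma assays
# (3 days x 4 VS replicates, beta = 0.95), with the printed tolerance limits.
# Columns: nominal, bias_pct, rsd_r_pct, rsd_ip_pct, printed_lower, printed_upper
AFA_TABLE = [
    (5.0, -0.24, 5.60, 5.65, -13.38, 12.90),
    (25.0, 1.31, 5.54, 4.94, -9.96, 12.58),
    (75.0, 0.63, 2.70, 2.63, -5.44, 6.71),
    (125.0, 1.29, 2.23, 2.42, -4.52, 7.09),
    (175.0, 0.56, 1.87, 1.66, -3.23, 4.36),
    (250.0, -0.25, 1.63, 1.91, -4.77, 4.27),  # anomalous: printed limits do not
    # follow from the printed summary triple (possible transcription error)
]

IBR_TABLE = [
    (5.0, -1.21, 5.83, 5.22, -12.96, 10.54),
    (75.0, 7.63, 1.96, 1.89, 3.28, 11.98),
    (150.0, 0.77, 1.85, 2.83, -7.94, 9.48),
    (250.0, -0.47, 1.77, 3.47, -12.89, 11.95),
    (350.0, 0.43, 2.02, 3.48, -11.94, 12.79),
    (400.0, -0.07, 1.87, 2.25, -6.00, 5.85),
]

DESIGN_P, DESIGN_N, BETA, LAMBDA = 3, 4, 0.95, 15.0

# the AFA 250 ng/mL row: its printed limits are inconsistent with its triple
ANOMALOUS = {("AFA", 250.0)}


def summary_frame(rows):
    return pd.DataFrame(
        [r[:4] for r in rows],
        columns=["nominal_conc", "bias_pct", "rsd_r_pct", "rsd_ip_pct"],
    )


@pytest.fixture
def afa_summary():
    return summary_frame(AFA_TABLE)


@pytest.fixture
def ibr_summary():
    return summary_frame(IBR_TABLE)
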