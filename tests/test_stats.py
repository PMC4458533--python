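import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from accuprof import (
    DataValidationError,
    DesignError,
    RecoveryRecord,
    level_statistics,
    level_statistics_from_summary,
    recovery_statistics,
    satterthwaite_dof,
    tolerance_interval,
    variance_components,
)
from conftest import AFA_TABLE, ANOMALOUS, BETA, DESIGN_N, DESIGN_P, IBR_TABLE


def brute_force_components(x):
    """Independent oracle: within = mean of per-series sample variances,
    between = variance of series means minus within/n."""
    x = np.asarray(x, dtype=float)
    p, n = x.shape
    s2w = float(np.mean([np.var(row, ddof=1) for row in x]))
    s2b = float(np.var(x.mean(axis=1), ddof=1)) - s2w / n
    return s2w, s2b


class TestVarianceComponents:
    def test_constant_matrix_has_zero_components(self):
        vc = variance_components(np.full((3, 4), 7.0))
        assert vc.s2_within == 0.0 and vc.s2_between == 0.0

    def test_hand_computed_two_by_two(self):
        # series means 1.5 / 3.5, grand 2.5: MSB = 4, MSW = 0.5
        vc = variance_components([[1, 2], [3, 4]])
        assert vc.s2_within == pytest.approx(0.5)
        assert vc.s2_between == pytest.approx(1.75)
        assert vc.s2_ip == pytest.approx(2.25)

    def test_matches_brute_force_exhaustively_on_small_matrices(self):
        # every 2x2 and 2x3 matrix with integer entries in [0, 3]
        for p, n in [(2, 2), (2, 3), (3, 2)]:
            for cells in itertools.product(range(4), repeat=p * n):
                x = np.array(cells, dtype=float).reshape(p, n)
                vc = variance_components(x)
                s2w, s2b = brute_force_components(x)
                assert vc.s2_within == pytest.approx(s2w, abs=1e-12)
                assert vc.s2_between == pytest.approx(s2b, abs=1e-12)

    def test_matches_brute_force_on_random_larger_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p, n = rng.integers(2, 5, 2)
            x = rng.normal(10, 3, (p, n))
            vc = variance_components(x)
            s2w, s2b = brute_force_components(x)
            assert vc.s2_within == pytest.approx(s2w, rel=1e-10)
            assert vc.s2_between == pytest.approx(s2b, abs=1e-10)

    def test_consistent_at_large_sample_size(self):
        rng = np.random.default_rng(12)
        p, n, sb, sw = 200, 50, 2.0, 3.0
        x = 10 + rng.normal(0, sb, (p, 1)) + rng.normal(0, sw, (p, n))
        vc = variance_components(x)
        # sampling SDs of the estimators: s2_b ~ sb^2 sqrt(2/(p-1)), s2_w tighter
        assert abs(vc.s2_between - sb**2) < 3 * sb**2 * math.sqrt(2 / (p - 1))
        assert vc.s2_within == pytest.approx(sw**2, rel=0.05)

    @pytest.mark.parametrize("bad", [np.ones((1, 4)), np.ones((3, 1))])
    def test_degenerate_designs_rejected(self, bad):
        with pytest.raises(DesignError):
            variance_components(bad)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 4))
        x[1, 2] = np.nan
        with pytest.raises(DesignError):
            variance_components(x)


ALL_ROWS = [("AFA", *row) for row in AFA_TABLE] + [("IBR", *row) for row in IBR_TABLE]


class TestToleranceInterval:
    @pytest.mark.parametrize(
        "analyte,nominal,bias,rr,rip,lo,hi",
        [r for r in ALL_ROWS if (r[0], r[1]) not in ANOMALOUS],
    )
    def test_reproduces_published_limits(self, analyte, nominal, bias, rr, rip, lo, hi):
        """11 of 12 published limit pairs follow from their summary triples
        within print rounding (the 12th is internally inconsistent)."""
        ti = tolerance_interval(bias, rr, rip, DESIGN_P, DESIGN_N, BETA)
        assert ti.lower_pct == pytest.approx(lo, abs=0.05)
        assert ti.upper_pct == pytest.approx(hi, abs=0.05)

    def test_anomalous_published_row_flagged(self):
        # the one published row whose limits do not follow from its triple
        ti = tolerance_interval(-0.25, 1.63, 1.91, DESIGN_P, DESIGN_N, BETA)
        assert abs(ti.lower_pct - (-4.77)) > 0.05

    def test_r_zero_closed_form(self):
        """With RSD_IP == RSD_r (R = 0) the interval has a closed form."""
        p, n, beta, s = 3, 4, 0.95, 4.0
        nu = 1.0 / ((1 / n**2) / (p - 1) + (1 - 1 / n) / (p * n))
        k = sps.t.ppf((1 + beta) / 2, math.floor(nu)) * math.sqrt(1 + 1 / (p * n))
        ti = tolerance_interval(0.0, s, s, p, n, beta)
        assert ti.lower_pct == pytest.approx(-k * s, abs=1e-12)
        assert ti.upper_pct == pytest.approx(k * s, abs=1e-12)
        assert ti.dof_int == math.floor(nu)

    def test_negative_ratio_not_truncated(self):
        # RSD_IP < RSD_r: R < 0 must flow through (narrower than the R=0 interval)
        ti_neg = tolerance_interval(0.0, 2.0, 1.9, 3, 4, 0.95)
        ti_zero = tolerance_interval(0.0, 1.9, 1.9, 3, 4, 0.95)
        assert ti_neg.upper_pct < ti_zero.upper_pct

    def test_strongly_negative_ratio_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            ti = tolerance_interval(1.0, 4.0, 2.0, 3, 4, 0.95)
        # fallback equals the R = 0 formula applied to the same RSD_IP
        nu = satterthwaite_dof(0.0, 3, 4)
        k = sps.t.ppf(0.975, math.floor(nu)) * math.sqrt(1 + 1 / 12)
        assert ti.upper_pct == pytest.approx(1.0 + k * 2.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        bias=st.floats(-20, 20),
        rr=st.floats(0.1, 10),
        ratio=st.floats(0.9, 3),
        p=st.integers(2, 6),
        n=st.integers(2, 8),
        beta=st.floats(0.5, 0.99),
    )
    def test_interval_symmetric_about_bias(self, bias, rr, ratio, p, n, beta):
        ti = tolerance_interval(bias, rr, rr * ratio, p, n, beta)
        assert ti.upper_pct - bias == pytest.approx(bias - ti.lower_pct, abs=1e-9)
        assert ti.lower_pct <= bias <= ti.upper_pct

    def test_k_strictly_increases_with_beta(self):
        ks = [
            tolerance_interval(0.0, 2.0, 2.5, 3, 4, b).k
            for b in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_input_validation(self):
        with pytest.raises(DataValidationError):
            tolerance_interval(0.0, 2.0, 2.0, 3, 4, beta=1.0)
        with pytest.raises(DataValidationError, match="rsd_r"):
            tolerance_interval(0.0, 0.0, 2.0, 3, 4, 0.95)
        with pytest.raises(DesignError):
            tolerance_interval(0.0, 2.0, 2.0, 1, 4, 0.95)


class TestLevelStatistics:
    def test_exact_measurements_give_degenerate_interval(self):
        ls = level_statistics(np.full((3, 4), 75.0), 75.0)
        assert ls.bias_pct == 0.0
        assert ls.rsd_r_pct == 0.0 and ls.rsd_ip_pct == 0.0
        assert (ls.tol_lower_pct, ls.tol_upper_pct) == (0.0, 0.0)

    def test_pure_proportional_bias(self):
        ls = level_statistics(np.full((3, 4), 75.0 * 1.05), 75.0)
        assert ls.bias_pct == pytest.approx(5.0, abs=1e-12)
        assert ls.rsd_r_pct == 0.0
        assert ls.tol_lower_pct == ls.tol_upper_pct == pytest.approx(5.0)

    def test_estimates_recover_generating_parameters(self):
        """Mean estimated bias and repeatability RSD over 1,000 experiments
        match the generating model (SD estimator carries its small-sample
        bias factor c4)."""
        rng = np.random.default_rng(99)
        mu, delta, sb, sw, p, n = 75.0, 1.0, 2.0, 2.5, 3, 4
        biases, rsds = [], []
        for _ in range(1000):
            x = (mu * (1 + delta / 100)
                 + rng.normal(0, sb * mu / 100, (p, 1))
                 + rng.normal(0, sw * mu / 100, (p, n)))
            ls = level_statistics(x, mu)
            biases.append(ls.bias_pct)
            rsds.append(ls.rsd_r_pct)
        assert np.mean(biases) == pytest.approx(1.0, abs=0.1)
        assert np.mean(rsds) == pytest.approx(2.5, abs=0.1)
        # sharper check on the unbiased (variance) scale
        assert np.mean(np.square(rsds)) == pytest.approx(sw**2, rel=0.05)

    def test_summary_entry_point_matches_matrix_entry_point(self):
        rng = np.random.default_rng(4)
        x = 75 + rng.normal(0, 2, (3, 4))
        full = level_statistics(x, 75.0)
        summ = level_statistics_from_summary(
            75.0, full.bias_pct, full.rsd_r_pct, full.rsd_ip_pct, 3, 4
        )
        assert summ.tol_lower_pct == pytest.approx(full.tol_lower_pct, abs=1e-9)
        assert summ.tol_upper_pct == pytest.approx(full.tol_upper_pct, abs=1e-9)


class TestRecovery:
    def _rec(self, level, ext, ref, series=1):
        return RecoveryRecord("A", level, series, ext, ref)

    def test_perfect_recovery(self):
        rs = recovery_statistics([self._rec(1, 5.0, 5.0), self._rec(2, 7.0, 7.0)])
        assert rs.overall_mean_pct == 100.0
        assert rs.overall_sd_pct == 0.0

    def test_two_level_mean_and_sd(self):
        rs = recovery_statistics(
            [self._rec(1, 86.0, 100.0), self._rec(2, 90.0, 100.0)]
        )
        assert rs.overall_mean_pct == pytest.approx(88.0)
        assert rs.overall_sd_pct == pytest.approx(math.sqrt(8.0))  # 2.828...

    def test_simulated_yield_recovered(self):
        rng = np.random.default_rng(21)
        recs = [
            self._rec(level, 100 * 0.88 * (1 + rng.normal(0, 0.025)), 100.0,
                      series=i % 3 + 1)
            for level in range(1, 7)
            for i in range(12)
        ]
        rs = recovery_statistics(recs)
        assert 85.0 <= rs.overall_mean_pct <= 91.0

    def test_positive_area_enforced(self):
        with pytest.raises(DataValidationError):
            RecoveryRecord("A", 1, 1, 5.0, 0.0)
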