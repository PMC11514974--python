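"""Coupling regression, gated paired tests, correlations, cohort summary."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroflux import dynamics as dyn
from neuroflux import synthdata as sd
from neuroflux.coupling import (
    PlaneMetrics,
    SubjectResult,
    choose_paired_test,
    correlate_sv,
    regress_coupling,
    summarize_cohort,
)
from neuroflux.types import PLANE_EXTRA, PLANE_INTRA


def _cb_curve(seed=0):
    truth = sd.make_subject_truth(sd.SubjectProfile(csf_noise_frac=0.0), seed=seed)
    return dyn.integrate_volume(truth.av(PLANE_INTRA), detrend=False, kind="CB_VC").samples


class TestRegressCoupling:
    def test_exact_negative_line(self):
        cb = _cb_curve()
        res = regress_coupling(cb, -0.7 * cb)
        assert res.slope == pytest.approx(-0.7, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-20

    def test_r_squared_equals_squared_pearson(self, rng):
        cb = rng.normal(0.0, 1.0, 32)
        csf = -0.5 * cb + rng.normal(0.0, 0.4, 32)
        res = regress_coupling(cb, csf)
        assert res.r_squared == pytest.approx(np.corrcoef(cb, csf)[0, 1] ** 2, abs=1e-12)

    def test_independent_noise_stays_below_null_quantile(self, rng):
        """Under independence R^2 ~ Beta(1/2, 15); check the 95% quantile."""
        cb = _cb_curve()
        q95 = scipy.stats.beta.ppf(0.95, 0.5, 15)
        r2 = np.array(
            [regress_coupling(cb, rng.normal(0.0, 1.0, 32)).r_squared
             for _ in range(400)]
        )
        frac_below = (r2 < q95).mean()
        assert frac_below == pytest.approx(0.95, abs=0.035)

    def test_calibrated_noise_recovers_r2_and_slope(self, rng):
        """csf = -0.74 cb + noise with var sig*(1-R2)/R2 gives E[R2] ~ 0.82."""
        cb = _cb_curve()
        signal = -0.74 * cb
        sd_noise = math.sqrt(signal.var() * (1 - 0.82) / 0.82)
        fits = [
            regress_coupling(cb, signal + rng.normal(0.0, sd_noise, 32))
            for _ in range(600)
        ]
        assert np.mean([f.r_squared for f in fits]) == pytest.approx(0.82, abs=0.02)
        assert np.mean([f.slope for f in fits]) == pytest.approx(-0.74, abs=0.02)

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_slope_equivariance_r2_invariance(self, a, b):
        cb = _cb_curve()
        rng = np.random.default_rng(7)
        csf = -0.6 * cb + rng.normal(0.0, 0.05, 32)
        base = regress_coupling(cb, csf)
        scaled = regress_coupling(b * cb, a * csf)
        assert scaled.slope == pytest.approx(base.slope * a / b, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant predictor"):
            regress_coupling(np.zeros(32), np.arange(32.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            regress_coupling(np.arange(32.0), np.arange(16.0))


class TestChoosePairedTest:
    def test_identical_samples_are_degenerate(self):
        x = np.arange(10.0)
        res = choose_paired_test(x, x)
        assert res.test_name == "degenerate"
        assert res.p_value == 1.0

    def test_type_one_error_near_nominal(self, rng):
        """Shapiro-gated t/Wilcoxon keeps ~5% size under the normal null."""
        hits = 0
        n_sims = 2000
        for _ in range(n_sims):
            x = rng.normal(0.0, 1.0, 38)
            y = rng.normal(0.0, 1.0, 38)
            if choose_paired_test(x, y).p_value < 0.05:
                hits += 1
        assert hits / n_sims == pytest.approx(0.05, abs=0.015)

    def test_heavy_tails_select_wilcoxon(self, rng):
        chosen = [
            choose_paired_test(rng.standard_cauchy(38), np.zeros(38)).test_name
            for _ in range(500)
        ]
        assert chosen.count("wilcoxon") > 250

    def test_normal_differences_select_t(self, rng):
        chosen = [
            choose_paired_test(rng.normal(0, 1, 38), np.zeros(38)).test_name
            for _ in range(200)
        ]
        assert chosen.count("paired t") > 150


class TestCorrelateSv:
    def test_identity_correlates_perfectly(self):
        x = np.arange(1.0, 11.0)
        res = correlate_sv(x, x)
        assert res.coefficient == pytest.approx(1.0)

    def test_independence_keeps_nominal_false_positive_rate(self, rng):
        hits = sum(
            correlate_sv(rng.normal(0, 1, 38), rng.normal(0, 1, 38)).p_value < 0.05
            for _ in range(500)
        )
        assert hits / 500 == pytest.approx(0.05, abs=0.03)

    def test_gaussian_copula_spearman_recovery(self, rng):
        """Rank dependence set via r = 2 sin(pi rho_s / 6) is recovered."""
        rho_s = 0.64
        r = 2 * math.sin(math.pi * rho_s / 6)
        cov = np.array([[1.0, r], [r, 1.0]])
        coefs = []
        for _ in range(300):
            z = rng.multivariate_normal([0, 0], cov, size=38)
            coefs.append(correlate_sv(z[:, 0], z[:, 1], method="spearman").coefficient)
        assert np.mean(coefs) == pytest.approx(rho_s, abs=0.04)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_sv(np.ones(10), np.arange(10.0))

    def test_method_gate_records_method(self, rng):
        x = rng.normal(0, 1, 38)
        y = x + rng.normal(0, 0.5, 38)
        res = correlate_sv(x, y)
        assert res.method in ("pearson", "spearman")


def _metrics(sv_cb=0.73, alpha=1.5, flagged=False, slope=-0.74, r2=0.82):
    from neuroflux.coupling import CouplingResult

    return PlaneMetrics(
        alpha=alpha,
        alpha_flagged=flagged,
        mean_arterial_flow=659.0,
        mean_venous_flow_measured=450.0,
        pi_arterial=0.81,
        pi_venous=0.25,
        sv_cb=sv_cb,
        sv_total=0.34,
        coupling=CouplingResult(r2, slope, 0.0, 1e-6, 32),
    )


def _subject(i, sv_cb_intra=0.73, sv_cb_extra=0.89, sv_csf=0.59, flagged=False):
    return SubjectResult(
        f"s{i}",
        {
            PLANE_INTRA: _metrics(sv_cb=sv_cb_intra),
            PLANE_EXTRA: _metrics(sv_cb=sv_cb_extra, flagged=flagged),
        },
        sv_csf,
        -sv_csf,
    )


class TestSummarizeCohort:
    def test_identical_subjects_have_zero_spread(self):
        summary = summarize_cohort([_subject(0), _subject(1)], correlation_method=None)
        row = summary.table.set_index("metric").loc["Amplitude CB_VC (ml/CC)"]
        assert row["intra_sd"] == 0.0
        assert row["intra_cv_pct"] == 0.0

    def test_cv_percent_matches_hand_calculation(self, rng):
        """Cohort of CB_VC amplitudes with mean 0.73 and SD 0.19 has CV 26%."""
        target_mean, target_sd = 0.73, 0.19
        vals = rng.normal(0, 1, 38)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * target_sd + target_mean
        subjects = [_subject(i, sv_cb_intra=v) for i, v in enumerate(vals)]
        summary = summarize_cohort(subjects)
        row = summary.table.set_index("metric").loc["Amplitude CB_VC (ml/CC)"]
        assert row["intra_cv_pct"] == pytest.approx(100 * 0.19 / 0.73, abs=0.05)
        assert round(row["intra_cv_pct"], 0) == 26.0

    def test_flagged_alpha_excluded_from_aggregation(self, rng):
        subjects = [_subject(i, sv_csf=0.5 + 0.01 * i) for i in range(6)]
        subjects.append(_subject(6, flagged=True))
        summary = summarize_cohort(subjects)
        assert summary.excluded_alpha_subjects == ["s6"]
        row = summary.table.set_index("metric").loc["Correction factor alpha"]
        assert row["extra_mean"] == pytest.approx(1.5)  # flagged subject dropped

    def test_sv_correlation_present_per_plane(self, rng):
        subjects = [
            _subject(i, sv_cb_intra=0.5 + 0.05 * i + rng.normal(0, 0.01),
                     sv_csf=0.4 + 0.04 * i + rng.normal(0, 0.01))
            for i in range(10)
        ]
        summary = summarize_cohort(subjects)
        assert summary.correlations[PLANE_INTRA].method == "spearman"
        assert summary.correlations[PLANE_INTRA].coefficient > 0.8

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize_cohort([_subject(0)])
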