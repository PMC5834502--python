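"""Cohort statistics against independent closed-form and simulation oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thzcoag.cohort import CohortConfig, subject_alpha, synthesize_cohort
from thzcoag.stats import (assign_stars, delta_spectrum, filter_subjects,
                           minute_average_alpha, pearson_correlation,
                           plt_stratified_shift, unpaired_ttest)


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, written from the formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = (a.mean() - b.mean()) / se
    df = na + nb - 2
    p = 2 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(0.975, df)
    return t, p, (a.mean() - b.mean() - tc * se, a.mean() - b.mean() + tc * se)


finite_group = st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=20)


class TestUnpairedTTest:
    @settings(derandomize=True, max_examples=60)
    @given(a=finite_group, b=finite_group)
    def test_matches_closed_form_oracle(self, a, b):
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            return
        res = unpaired_ttest(a, b)
        t, p, ci = _pooled_t_oracle(a, b)
        assert res.t_statistic == pytest.approx(t, rel=1e-10, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-10, abs=1e-12)
        assert res.ci_low == pytest.approx(ci[0], rel=1e-10, abs=1e-10)
        assert res.ci_high == pytest.approx(ci[1], rel=1e-10, abs=1e-10)
        assert res.ci_low <= res.mean_a - res.mean_b <= res.ci_high

    def test_identical_groups_are_null(self):
        res = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low < 0 < res.ci_high
        assert res.stars == "ns"

    def test_textbook_shifted_case(self):
        # hand-computed: t = -10/sqrt(2/3), df = 4
        res = unpaired_ttest([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.t_statistic == pytest.approx(-12.24744871391589, rel=1e-12)
        assert res.p_value == pytest.approx(2.552167494419268e-4, rel=1e-10)
        assert res.ci_low == pytest.approx(-12.266957935527518, rel=1e-9)
        assert res.ci_high == pytest.approx(-7.733042064472481, rel=1e-9)
        assert res.stars == "***"

    def test_zero_variance_conventions(self):
        same = unpaired_ttest([2.0, 2.0], [2.0, 2.0])
        assert same.p_value == 1.0 and same.degenerate
        apart = unpaired_ttest([2.0, 2.0], [3.0, 3.0])
        assert apart.p_value == 0.0 and apart.degenerate


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_constructed_orthogonal_inputs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # zero covariance with x
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_symmetry_and_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        a = pearson_correlation(x, y)
        b = pearson_correlation(y, x)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.r == pytest.approx(b.r, rel=1e-12)
        c = pearson_correlation(x, -y)
        assert c.r == pytest.approx(-a.r, rel=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.r)

    def test_mean_estimate_recovers_population_correlation(self, rng):
        """5000 bivariate-normal replicates at rho = 0.6, n = 18."""
        rho, n, reps = 0.6, 18, 5000
        z = rng.normal(size=(reps, n, 2))
        x = z[:, :, 0]
        y = rho * z[:, :, 0] + np.sqrt(1 - rho**2) * z[:, :, 1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        assert np.mean(r) == pytest.approx(rho, abs=0.02)
        sample = pearson_correlation(x[0], y[0])
        assert sample.r == pytest.approx(r[0], rel=1e-12)


class TestStars:
    @pytest.mark.parametrize("p,label,boundary", [
        (0.2, "ns", False), (0.049, "*", False), (0.011, "*", False),
        (0.0099, "**", False), (0.0011, "**", False), (0.0009, "***", False),
        (0.05, "ns", True), (0.01, "*", True), (0.001, "**", True),
        (0.051, "ns", False), (1.0, "ns", False), (1e-12, "***", False),
    ])
    def test_bins_partition_as_printed(self, p, label, boundary):
        got, flag = assign_stars(p)
        assert got == label
        assert flag is boundary


class TestFilterSubjects:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "rbc_M_per_uL", "plt_K_per_uL"])

    def test_boundaries_as_printed(self):
        frame = self._frame([("a", 4.0, 200.0), ("b", 5.0, 300.0), ("c", 4.5, 100.0)])
        kept = filter_subjects(frame)
        assert list(kept["subject_id"]) == ["b", "c"]  # 4.0 excluded, 5.0/300/100 kept

    def test_hand_enumerated_table(self):
        rows = [(f"s{i}", rbc, plt) for i, (rbc, plt) in enumerate([
            (3.9, 150), (4.01, 150), (4.5, 99), (4.5, 100), (4.5, 300),
            (4.5, 301), (5.0, 200), (5.1, 200), (4.2, 250), (4.8, 310)])]
        kept = filter_subjects(self._frame(rows))
        assert list(kept["subject_id"]) == ["s1", "s3", "s4", "s6", "s8"]

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            filter_subjects(self._frame([]), rbc_range=(5, 4))


class TestMinuteAverage:
    def test_identity_and_mean(self):
        a = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(minute_average_alpha([a]), a)
        np.testing.assert_allclose(minute_average_alpha([a, 3 * a]), 2 * a)

    def test_matches_streaming_oracle(self, rng):
        stack = rng.normal(size=(120, 50))
        running = np.zeros(50)
        for row in stack:  # independent streaming mean
            running += row / 120
        np.testing.assert_allclose(minute_average_alpha(stack), running, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minute_average_alpha([])


class TestDeltaSpectrum:
    FREQS = np.linspace(0.13, 1.02, 90)

    def test_identical_spectra_leave_transparency_undefined(self):
        alpha = np.full(self.FREQS.size, 100.0)
        d = delta_spectrum(alpha, alpha, self.FREQS)
        np.testing.assert_allclose(d.delta_over_alpha, 0.0, atol=1e-15)
        assert d.transparency_freq_thz is None

    def test_constructed_zero_crossing(self):
        alpha_blood = np.full(self.FREQS.size, 100.0)
        alpha_state = alpha_blood * (1 + 0.1 * (self.FREQS - 0.68))
        d = delta_spectrum(alpha_state, alpha_blood, self.FREQS)
        assert d.transparency_freq_thz == pytest.approx(0.68, abs=1e-10)
        assert d.fit_slope == pytest.approx(0.1, rel=1e-9)
        assert d.excess_defect(0.9) == "excess"
        assert d.excess_defect(0.2) == "defect"

    def test_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            delta_spectrum(np.ones(90), np.zeros(90), self.FREQS)


class TestPltStratifiedShift:
    FREQS = np.linspace(0.13, 1.02, 90)

    def _records(self, plts):
        return pd.DataFrame({"plt_K_per_uL": plts})

    def test_identical_bins_have_zero_shift(self):
        alpha_blood = np.full(self.FREQS.size, 100.0)
        alpha = alpha_blood * (1 + 0.1 * (self.FREQS - 0.6))
        res = plt_stratified_shift(self._records([150, 150, 250, 250]),
                                   np.vstack([alpha] * 4), self.FREQS, alpha_blood)
        assert res["shift_thz"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_red_shift_of_half_thz(self):
        alpha_blood = np.full(self.FREQS.size, 100.0)
        low = alpha_blood * (1 + 0.13 * (self.FREQS - 0.9))
        high = alpha_blood * (1 + 0.13 * (self.FREQS - 0.4))
        res = plt_stratified_shift(self._records([150, 150, 250, 250]),
                                   np.vstack([low, low, high, high]),
                                   self.FREQS, alpha_blood)
        assert res["shift_thz"] == pytest.approx(-0.5, abs=1e-9)
        assert res["bins"][0][2].transparency_freq_thz == pytest.approx(0.9, abs=1e-9)
        assert res["bins"][1][2].transparency_freq_thz == pytest.approx(0.4, abs=1e-9)

    def test_empty_bin_warns_and_skips(self):
        alpha_blood = np.full(self.FREQS.size, 100.0)
        alpha = alpha_blood * (1 + 0.1 * (self.FREQS - 0.6))
        with pytest.warns(UserWarning, match="empty"):
            res = plt_stratified_shift(self._records([150, 150]),
                                       np.vstack([alpha, alpha]),
                                       self.FREQS, alpha_blood)
        assert res["bins"][1][2] is None
        assert res["shift_thz"] is None


def test_transparency_estimator_rmse_decreases_with_cohort_size():
    """The fitted zero crossing converges on the generator's transparency
    frequency as the early-coagulated group grows (generator-level spectra)."""
    cfg = CohortConfig()
    freqs = np.linspace(0.13, 1.02, 90)
    truth = cfg.effect.transparency_freq_thz
    rng = np.random.default_rng(42)
    rmse = []
    for n in (9, 18, 36):
        errs = []
        for _ in range(200):
            plts = cfg.plt.sample(n, rng)
            scales = np.exp(rng.normal(0, cfg.subject_sigma, n))
            f_t = cfg.effect.transparency_frequency(plts)
            alpha_state = np.mean(
                scales[:, None] * (1 + cfg.effect.delta_slope_per_thz
                                   * (freqs[None, :] - f_t[:, None])), axis=0)
            base_scales = np.exp(rng.normal(0, cfg.subject_sigma, 28))
            alpha_blood = np.mean(base_scales)* np.ones_like(freqs)
            d = delta_spectrum(alpha_state * 100.0, alpha_blood * 100.0, freqs)
            errs.append(d.transparency_freq_thz - truth)
        rmse.append(np.sqrt(np.mean(np.square(errs))))
    assert rmse[0] > rmse[1] > rmse[2]


def test_default_cohort_shows_defect_below_and_excess_above(rng):
    """Early coagulation: negative delta-alpha at 200-270 GHz, positive at
    750-1020 GHz, relative to uncoagulated blood (generator-level)."""
    cfg = CohortConfig()
    cohort = synthesize_cohort(
        cfg.model_copy(update={"instrument": cfg.instrument.model_copy(
            update={"traces_per_minute": 1})}), 2)
    freqs = np.linspace(0.13, 1.02, 90)
    alphas = {g: [] for g in ("uncoagulated", "early_coagulated")}
    for rec in cohort.records:
        alphas[rec.group].append(
            subject_alpha(rec, cohort.kappa_scales[rec.subject_id], freqs, cfg))
    delta = np.mean(alphas["early_coagulated"], axis=0) - np.mean(alphas["uncoagulated"], axis=0)
    assert np.all(delta[(freqs >= 0.2) & (freqs <= 0.27)] < 0)
    assert np.mean(delta[(freqs >= 0.75) & (freqs <= 1.02)]) > 0
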