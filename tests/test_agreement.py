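"""Agreement statistics: ICC, Landis-Koch bands, Bland-Altman, Pearson,
paired comparison, normality, proportions, sample size."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from maxdex import (
    CorrelationResult,
    InputError,
    RatingsTable,
    SampleSizeSpec,
    bland_altman,
    icc,
    interpret_agreement,
    normality_test,
    paired_comparison,
    pearson,
    proportion_table,
    required_sample_size,
)
from maxdex.geometry import IndexMeasurement


def icc_oracle(x, model, unit):
    """Independent ANOVA mean-squares oracle: sums of squares computed cell by
    cell with explicit loops, then the Shrout-Fleiss ratios."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (np.mean(x[i, :]) - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (np.mean(x[:, j]) - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msw = (ss_tot - ss_rows) / (n * (k - 1))
    if model == "oneway_random":
        return (msr - msw) / (msr + (k - 1) * msw) if unit == "single" else (msr - msw) / msr
    if model == "twoway_random_absolute":
        if unit == "single":
            return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        return (msr - mse) / (msr + (msc - mse) / n)
    if unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / msr


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        t = RatingsTable(np.array([[0.6, 0.6], [0.7, 0.7], [0.8, 0.8]]))
        res = icc(t)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.band == "almost perfect"

    def test_matches_anova_oracle_on_structured_table(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(0, 0.05, size=6)
        vals = subj[:, None] + rng.normal(0, 0.05, size=(6, 2))
        t = RatingsTable(vals)
        for model in ("oneway_random", "twoway_random_absolute", "twoway_mixed_consistency"):
            for unit in ("single", "average"):
                res = icc(t, model=model, unit=unit)
                assert res.estimate == pytest.approx(
                    icc_oracle(vals, model, unit), abs=1e-10
                )

    def test_matches_pingouin(self):
        """Cross-check ICC(2,1)/ICC(3,1)/ICC(1,1) against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        vals = rng.normal(0.65, 0.065, size=8)[:, None] + rng.normal(0, 0.02, (8, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "value": vals.ravel(),
            }
        )
        pg = pingouin.intraclass_corr(long, "subject", "rater", "value").set_index("Type")
        t = RatingsTable(vals)
        assert icc(t, "oneway_random", "single").estimate == pytest.approx(
            pg.loc["ICC(1,1)", "ICC"], abs=1e-6
        )
        assert icc(t, "twoway_random_absolute", "single").estimate == pytest.approx(
            pg.loc["ICC(A,1)", "ICC"], abs=1e-6
        )
        assert icc(t, "twoway_mixed_consistency", "single").estimate == pytest.approx(
            pg.loc["ICC(C,1)", "ICC"], abs=1e-6
        )

    def test_zero_between_subject_variance_degenerate(self):
        t = RatingsTable(np.array([[0.5, 0.5], [0.5, 0.5]]))
        res = icc(t)
        assert res.estimate == 0.0
        assert res.degenerate

    def test_reported_band_matches_estimate(self):
        assert interpret_agreement(0.92) == "almost perfect"

    def test_incomplete_or_tiny_tables_rejected(self):
        with pytest.raises(InputError):
            RatingsTable(np.array([[0.5, 0.6]]))
        with pytest.raises(InputError):
            RatingsTable(np.array([[0.5], [0.6]]))
        with pytest.raises(InputError):
            RatingsTable(np.array([[0.5, np.nan], [0.6, 0.7]]))


class TestInterpretAgreement:
    @pytest.mark.parametrize(
        "estimate,band",
        [
            (-0.3, "poor"),
            (0.005, "poor"),
            (0.01, "slight"),
            (0.20, "slight"),
            (0.35, "fair"),
            (0.50, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_buckets(self, estimate, band):
        assert interpret_agreement(estimate) == band

    def test_above_one_rejected(self):
        with pytest.raises(InputError):
            interpret_agreement(1.01)

    @given(
        a=st.floats(-1, 1, allow_nan=False),
        b=st.floats(-1, 1, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_step_function(self, a, b):
        order = ["poor", "slight", "fair", "moderate", "substantial", "almost perfect"]
        lo, hi = sorted((a, b))
        assert order.index(interpret_agreement(lo)) <= order.index(interpret_agreement(hi))


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([0.6, 0.7, 0.8], [0.6, 0.7, 0.8])
        assert res.mean_diff == 0
        assert res.loa_low == res.loa_high == 0
        assert res.outlier_ids == ()

    def test_known_diffs(self):
        res = bland_altman([0.0, 0.1, 0.2], [0.1, 0.1, 0.1])
        assert res.mean_diff == pytest.approx(0.0, abs=1e-15)
        assert res.sd_diff == pytest.approx(0.1, abs=1e-12)
        assert res.loa_low == pytest.approx(-0.196, abs=1e-12)
        assert res.loa_high == pytest.approx(0.196, abs=1e-12)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.7, 0.1, 30), rng.normal(0.65, 0.1, 30)
        perm = rng.permutation(30)
        r1 = bland_altman(a, b)
        r2 = bland_altman(a[perm], b[perm])
        assert r1.mean_diff == pytest.approx(r2.mean_diff)
        assert r1.sd_diff == pytest.approx(r2.sd_diff)
        assert sorted(r1.outlier_ids) == sorted(perm[list(r2.outlier_ids)].tolist())

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            bland_altman([1, 2, 3], [1, 2])

    def test_within_sample_coverage_near_95_percent(self):
        """~5% of simulated differences fall outside the within-sample LoA."""
        rng = np.random.default_rng(1)
        b = rng.normal(0.65, 0.065, 5000)
        a = b + rng.normal(0.09, 0.1, 5000)
        res = bland_altman(a, b)
        frac_outside = len(res.outlier_ids) / res.n
        assert 0.035 <= frac_outside <= 0.055


class TestPearson:
    def test_r_squared_identity_with_printed_values(self):
        res = CorrelationResult(r=-0.595, p_value=0.0005, n=113)
        assert round(res.r_squared, 3) == 0.354

    def test_perfect_linearity(self):
        x = np.arange(10, dtype=float)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = pearson(x, y)
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * np.sqrt(8 / (1 - r_direct**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        slope=st.floats(0.1, 5),
        intercept=st.floats(-10, 10),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, slope, intercept):
        rng = np.random.default_rng(99)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = pearson(x, y).r
        assert pearson(slope * x + intercept, y).r == pytest.approx(base, abs=1e-9)
        assert pearson(-slope * x, y).r == pytest.approx(-base, abs=1e-9)


class TestPairedComparison:
    def test_identical_series_degenerate(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_zero_mean_diffs_give_p_one(self):
        b = np.zeros(6)
        a = np.array([1.0, -1.0, 2.0, -2.0, 0.0, 0.0])
        res = paired_comparison(a + b, b)
        if res.test == "paired_t":
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0, abs=1e-12)
        else:
            assert res.p_value > 0.9

    def test_power_under_true_shift(self):
        """A 0.09 shift at SD 0.1 and n=113 is detected decisively."""
        rng = np.random.default_rng(5)
        b = rng.normal(0.65, 0.065, 113)
        a = b + rng.normal(0.09, 0.1, 113)
        res = paired_comparison(a, b)
        assert res.p_value < 0.001


class TestNormality:
    def test_type_one_error_rate_for_gaussian_input(self):
        rng = np.random.default_rng(11)
        keep = 0
        for _ in range(200):
            x = rng.normal(0, 1, 500)
            _, p = normality_test(x, "shapiro_wilk")
            keep += p > 0.05
        assert keep >= 0.90 * 200

    def test_power_against_exponential(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(1.0, 500)
        for method in ("shapiro_wilk", "kolmogorov_smirnov"):
            _, p = normality_test(x, method)
            assert p < 0.05

    def test_near_constant_input_does_not_crash(self):
        x = 0.7 + 1e-9 * np.arange(10)
        for method in ("shapiro_wilk", "kolmogorov_smirnov"):
            stat, p = normality_test(x, method)
            assert np.isfinite(p)

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            normality_test([1.0, 2.0], "shapiro_wilk")
        with pytest.raises(InputError):
            normality_test([1.0, 2.0, 3.0, 4.0], "kolmogorov_smirnov")


def _meas(pid, value, threshold=0.7):
    return IndexMeasurement(
        patient_id=pid,
        rater_id="c",
        repeat_index=0,
        modality="MRI",
        value=value,
        ga=value,
        gh=1.0,
        classification="pathological" if value > threshold else "normal",
    )


class TestProportionTable:
    def test_printed_table_arithmetic(self):
        """12 males of 18 pathological -> 66.7%; 26 of 38 -> 68.4%."""
        sex = {}
        ms = []
        for i in range(18):
            pid = f"p{i}"
            ms.append(_meas(pid, 0.8))
            sex[pid] = "male" if i < 12 else "female"
        for i in range(18, 38):
            pid = f"p{i}"
            ms.append(_meas(pid, 0.8))
            sex[pid] = "male" if i < 18 + 14 else "female"
        # first table: 18 pathological, 12 male
        t = proportion_table(ms[:18], sex)
        assert t["pathological"]["male"]["n"] == 12
        assert t["pathological"]["male"]["percent"] == 66.7
        # second: 38 pathological, 26 male
        t = proportion_table(ms, sex)
        assert t["pathological"]["male"]["n"] == 26
        assert t["pathological"]["male"]["percent"] == 68.4

    def test_zero_group(self):
        sex = {"a": "male", "b": "female"}
        t = proportion_table([_meas("a", 0.5), _meas("b", 0.6)], sex)
        assert t["pathological"]["n"] == 0
        assert t["pathological"]["percent"] == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        sex = {}
        ms = []
        for i in range(57):
            pid = f"p{i}"
            ms.append(_meas(pid, float(rng.normal(0.68, 0.08))))
            sex[pid] = "male" if rng.random() < 0.6 else "female"
        t = proportion_table(ms, sex)
        assert t["pathological"]["percent"] + t["normal"]["percent"] == pytest.approx(
            100.0, abs=0.1
        )
        for cls in ("pathological", "normal"):
            if t[cls]["n"]:
                assert t[cls]["male"]["percent"] + t[cls]["female"]["percent"] == pytest.approx(
                    100.0, abs=0.1
                )

    def test_unknown_sex_rejected(self):
        with pytest.raises(InputError):
            proportion_table([_meas("a", 0.8)], {"a": "unknown"})


class TestSampleSize:
    def test_monotone_in_effect_size_and_power(self):
        n_small = required_sample_size(SampleSizeSpec(eta_squared=0.25))
        n_big = required_sample_size(SampleSizeSpec(eta_squared=0.14))
        assert n_small <= n_big
        n_80 = required_sample_size(SampleSizeSpec(eta_squared=0.14, power=0.8))
        assert n_big >= n_80

    def test_agrees_with_simulation_oracle(self):
        """The analytic n for eta^2=0.14, power 0.9 matches a brute-force
        Monte-Carlo power scan (5000 reps per candidate n) within +-2."""
        spec = SampleSizeSpec(eta_squared=0.14, power=0.9, alpha=0.05)
        n_analytic = required_sample_size(spec)
        f = np.sqrt(spec.eta_squared / (1 - spec.eta_squared))
        d = 2 * f  # two equal groups: means at +-f sigma
        rng = np.random.default_rng(42)

        def sim_power(n_total, reps=5000):
            n1 = n_total // 2
            n2 = n_total - n1
            x1 = rng.normal(0.0, 1.0, (reps, n1))
            x2 = rng.normal(d, 1.0, (reps, n2))
            t, p = stats.ttest_ind(x1, x2, axis=1)
            return np.mean(p <= spec.alpha)

        candidates = np.arange(max(6, n_analytic - 6), n_analytic + 7)
        powers = np.array([sim_power(int(n)) for n in candidates])
        reached = candidates[powers >= spec.power]
        assert reached.size > 0
        n_sim = int(reached.min())
        assert abs(n_sim - n_analytic) <= 2

    def test_invalid_spec_rejected(self):
        with pytest.raises(InputError):
            SampleSizeSpec(eta_squared=1.2)
        with pytest.raises(InputError):
            SampleSizeSpec(eta_squared=0.14, power=1.1)
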