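"""Assay arithmetic and statistics: normalization, oxidation, Seahorse,
rates, folds, Welch's t, ROUT, z-scores, five-number summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stellaquant import assays, synth
from stellaquant.types import SeahorseTrace


def t_pvalue_quadrature(t_stat, df, n_grid=400_000, span=400.0):
    """Two-sided p-value by direct numerical integration of the t density
    (lgamma-based pdf; independent of scipy.stats.t)."""
    x = np.linspace(abs(t_stat), abs(t_stat) + span, n_grid)
    logc = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi))
    pdf = np.exp(logc - (df + 1) / 2 * np.log1p(x**2 / df))
    return 2.0 * np.trapezoid(pdf, x)


class TestNormalizeProtein:
    def test_reference_identity_and_scaling(self):
        t = pd.DataFrame({"value": [8.0, 8.0], "protein_conc": [100.0, 50.0]})
        out = assays.normalize_protein(t)
        assert list(out["value"]) == [8.0, 16.0]

    def test_missing_protein_lists_rows(self):
        t = pd.DataFrame({"value": [1.0, 2.0], "protein_conc": [100.0, np.nan]})
        with pytest.raises(ValueError, match="1"):
            assays.normalize_protein(t)

    def test_idempotent_at_reference(self):
        t = pd.DataFrame({"value": [8.0], "protein_conc": [50.0]})
        once = assays.normalize_protein(t)
        once["protein_conc"] = 100.0
        twice = assays.normalize_protein(once)
        assert list(twice["value"]) == list(once["value"])


class TestOxidation:
    @pytest.mark.parametrize("co2,ca,uptake,frac",
                             [(2, 8, 10, 0.2), (0, 5, 5, 0.0), (5, 0, 5, 1.0)])
    def test_direct_formula(self, co2, ca, uptake, frac):
        r = assays.oxidation(co2, ca)
        assert (r.uptake, r.fractional_oxidation) == (uptake, frac)

    def test_zero_uptake_null_with_warning(self):
        with pytest.warns(UserWarning):
            r = assays.oxidation(0.0, 0.0)
        assert r.fractional_oxidation is None

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_fraction_bounded(self, co2, ca):
        if co2 + ca == 0:
            return
        r = assays.oxidation(co2, ca)
        assert 0.0 <= r.fractional_oxidation <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assays.oxidation(-1.0, 2.0)


def make_trace(ocr, marks, ecar=None):
    n = len(ocr)
    return SeahorseTrace(np.arange(n) * 8.0, np.array(ocr, float),
                         np.array(ecar if ecar is not None else ocr, float),
                         marks)


class TestSeahorse:
    def test_control_self_normalization_is_100(self):
        tr = make_trace([90, 100, 110, 95, 105, 300, 310],
                        {"oligomycin": 5})
        out = assays.seahorse_percent_baseline(tr, tr)
        assert out.ocr[:5].mean() == pytest.approx(100.0)

    def test_double_baseline_is_200(self):
        ctrl = make_trace([100] * 5 + [80] * 3, {"oligomycin": 5})
        tr = make_trace([200] * 8, {"oligomycin": 5})
        out = assays.seahorse_percent_baseline(tr, ctrl)
        assert np.all(out.ocr == 200.0)

    def test_planted_multipliers_recovered(self):
        # noise-free trace built from known basal/maximal multipliers
        base, fccp_mult, nonmito = 120.0, 1.8, 0.15
        ocr = [base] * 5 + [base * 0.4] * 3 + [base * fccp_mult] * 3 \
            + [base * nonmito] * 3
        tr = make_trace(ocr, {"oligomycin": 5, "fccp": 8, "rot_aa": 11})
        basal, maximal = assays.respiration_metrics(tr)
        assert basal == pytest.approx(base * (1 - nonmito), rel=0.01)
        assert maximal == pytest.approx(base * (fccp_mult - nonmito), rel=0.01)

    def test_constructed_arithmetic(self):
        ocr = [100] * 5 + [60] * 3 + [180] * 3 + [20] * 3
        tr = make_trace(ocr, {"oligomycin": 5, "fccp": 8, "rot_aa": 11})
        assert assays.respiration_metrics(tr) == (80.0, 160.0)

    def test_flat_trace_zero_metrics(self):
        tr = make_trace([100] * 14, {"oligomycin": 5, "fccp": 8, "rot_aa": 11})
        assert assays.respiration_metrics(tr) == (0.0, 0.0)

    def test_additive_offset_invariance(self):
        ocr = np.array([100] * 5 + [60] * 3 + [180] * 3 + [20] * 3, float)
        marks = {"oligomycin": 5, "fccp": 8, "rot_aa": 11}
        a = assays.respiration_metrics(make_trace(ocr, marks))
        b = assays.respiration_metrics(make_trace(ocr + 37.0, marks))
        assert a == pytest.approx(b)

    def test_missing_injection_rejected(self):
        tr = make_trace([100] * 8, {"oligomycin": 5})
        with pytest.raises(ValueError):
            assays.respiration_metrics(tr)

    def test_nonpositive_baseline_rejected(self):
        ctrl = make_trace([0.0] * 8, {"oligomycin": 5})
        with pytest.raises(ValueError):
            assays.seahorse_percent_baseline(ctrl, ctrl)


class TestRatesAndFolds:
    @pytest.mark.parametrize("value,hours,expected",
                             [(10, 48, 5), (10, 24, 10), (3, 72, 1)])
    def test_per_day_rate(self, value, hours, expected):
        assert assays.per_day_rate(value, hours) == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            assays.per_day_rate(1.0, 0.0)

    def test_va_content_ratio_printed_values(self):
        # pHSC mean 0.4602 µg/mL vs scHSC mean 1.290 µg/mL ≈ 36%
        assert round(assays.percentage_ratio(0.4602, 1.290)) == 36

    def test_fold_reference_and_inverse(self):
        folds = assays.fold_and_ratio({"Control": 2.0, "TGF-β": 5.0})
        assert folds["Control"] == 1.0
        a_vs_b = assays.fold_and_ratio({"Control": 2.0, "x": 5.0})["x"]
        b_vs_a = assays.fold_and_ratio({"Control": 5.0, "x": 2.0})["x"]
        assert a_vs_b * b_vs_a == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            assays.fold_and_ratio({"Control": 0.0, "x": 1.0})


class TestWelch:
    def test_identical_samples(self):
        r = assays.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p) == (0.0, pytest.approx(1.0))

    def test_closed_form_example_with_quadrature_p(self):
        r = assays.welch_ttest([1, 2, 3], [2, 3, 4])
        assert r.t == pytest.approx(-math.sqrt(1.5), abs=1e-12)
        assert r.df == pytest.approx(4.0, abs=1e-12)
        assert r.p == pytest.approx(t_pvalue_quadrature(r.t, r.df), abs=1e-6)

    def test_agrees_with_scipy_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 2, 8)
            r = assays.welch_ttest(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert r.t == pytest.approx(ref.statistic, abs=1e-12)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        x, y = [1.0, 2.0, 4.0, 5.5], [2.0, 3.5, 4.0]
        a = assays.welch_ttest(x, y)
        b = assays.welch_ttest([c * v for v in x], [c * v for v in y])
        assert a.t == pytest.approx(b.t, rel=1e-9)
        assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_both_zero_variance_equal_means(self):
        r = assays.welch_ttest([2.0, 2.0], [2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            assays.welch_ttest([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            assays.welch_ttest(rng.normal(size=4), rng.normal(size=4)).p <= 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestRout:
    def test_hand_traced_five_point_sample(self):
        # x = [1.0, 1.1, 0.9, 1.05, 50]: median 1.05; abs residuals
        # [0.05, 0.05, 0.15, 0, 48.95]; P68.27 (linear interp) = 0.123;
        # RSDR = 0.123 * 5/4 = 0.154; t(50) ≈ 318, p ≈ 1e-9 below
        # alpha_1 = 0.01·1/5 with df 4 -> removed; next point t ≈ 0.98,
        # p ≈ 0.38 > alpha_2 = 0.004 -> stop.
        kept, removed = assays.rout_outliers([1.0, 1.1, 0.9, 1.05, 50.0], 1.0)
        assert removed == [4]
        assert 50.0 not in kept

    def test_q_to_zero_removes_nothing(self):
        rng = np.random.default_rng(0)
        x = np.append(rng.normal(size=20), 6.0)
        _, removed = assays.rout_outliers(x, 1e-9)
        assert removed == []

    def test_small_sample_warns_no_removal(self):
        with pytest.warns(UserWarning):
            kept, removed = assays.rout_outliers([1.0, 2.0, 50.0], 1.0)
        assert removed == [] and len(kept) == 3

    def test_false_removal_rate_calibration(self):
        rng = np.random.default_rng(7)
        removed = sum(len(assays.rout_outliers(rng.normal(0, 1, 20), 1.0)[1])
                      for _ in range(1000))
        assert removed / (1000 * 20) <= 0.015

    def test_rerun_after_removal_is_stable(self):
        rng = np.random.default_rng(0)
        x = np.append(rng.normal(1, 0.1, 20), [50.0, -30.0])
        kept, removed = assays.rout_outliers(x, 1.0)
        assert {20, 21} <= set(removed)  # both planted outliers flagged
        _, removed2 = assays.rout_outliers(kept, 1.0)
        assert removed2 == []


class TestZscore:
    def test_population_convention_row(self):
        z, flagged = assays.zscore_matrix(np.array([[1.0, 2.0, 3.0]]))
        assert z[0] == pytest.approx([-math.sqrt(1.5), 0.0, math.sqrt(1.5)])
        assert flagged == []

    def test_constant_row_flagged(self):
        z, flagged = assays.zscore_matrix(np.array([[1.0, 1.0], [0.0, 2.0]]))
        assert flagged == [0]
        assert np.isnan(z[0]).all()

    def test_output_rows_standardized(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(20, 12))
        z, _ = assays.zscore_matrix(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1) - 1).max() < 1e-12

    def test_dataframe_round_trip(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 4)),
                          index=["ACTA2", "COL1A1", "LRAT"])
        z, flagged = assays.zscore_matrix(df)
        assert isinstance(z, pd.DataFrame)
        assert list(z.index) == ["ACTA2", "COL1A1", "LRAT"]


class TestFiveNumber:
    def test_one_to_five(self):
        assert assays.five_number([1, 2, 3, 4, 5]) == (1, 2, 3, 4, 5)

    def test_single_value(self):
        assert assays.five_number([7.0]) == (7, 7, 7, 7, 7)

    def test_median_equals_sort_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=101)
        fn = assays.five_number(x)
        assert fn[2] == sorted(x)[50]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_ordering_invariant(self, xs):
        mn, q1, q2, q3, mx = assays.five_number(xs)
        assert mn <= q1 <= q2 <= q3 <= mx

    def test_tukey_hinges_option(self):
        # classic example where hinges differ from linear interpolation
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        assert assays.five_number(x, method="tukey") == (1, 2.5, 4.5, 6.5, 8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assays.five_number([])


class TestWithSyntheticTables:
    def test_group_recovery_and_welch_pipeline(self):
        table, _ = synth.gen_assay_table(
            {"Control": (1.0, 0.1, 8), "TGF-β": (2.0, 0.1, 8)}, seed=0)
        x = table.loc[table.condition == "Control", "value"].to_numpy()
        y = table.loc[table.condition == "TGF-β", "value"].to_numpy()
        r = assays.welch_ttest(x, y, names=("Control", "TGF-β"))
        assert r.p < 1e-6
        assert r.group_summaries["Control"]["mean"] == pytest.approx(1.0, abs=0.2)

    def test_rout_removes_planted_outlier_from_table(self):
        table, gt = synth.gen_assay_table(
            {"Control": (1.0, 0.1, 20)}, outliers=[("Control", 50.0)], seed=1)
        vals = table["value"].to_numpy()
        _, removed = assays.rout_outliers(vals, 1.0)
        assert removed == gt.objects["outlier_indices"]
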