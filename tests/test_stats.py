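import numpy as np
import pandas as pd
import pytest

import openarms as oa
from openarms.errors import CollinearityError, DegenerateDataError, ValidationError
from openarms.stats import FEATURES, sidak_adjust


def cohort_frame(rng, n=33):
    df = pd.DataFrame({f: rng.normal(size=n) for f in FEATURES})
    return df


class TestAvoidanceRegression:
    def test_exact_linear_combination_gives_r2_one(self):
        rng = np.random.default_rng(0)
        df = cohort_frame(rng)
        df["time_in_open_pct"] = (2.0 * df[FEATURES[4]] - 0.5 * df[FEATURES[0]]
                                  + 10.0)
        res = oa.avoidance_regression(df)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        assert res.df_model == 5 and res.df_resid == 27

    def test_r2_equals_squared_correlation_of_fit(self):
        rng = np.random.default_rng(1)
        df = cohort_frame(rng)
        df["time_in_open_pct"] = df[FEATURES[4]] + rng.normal(size=len(df))
        res = oa.avoidance_regression(df)
        r = np.corrcoef(res.fitted, df["time_in_open_pct"])[0, 1]
        assert res.rsquared == pytest.approx(r * r, abs=1e-10)

    def test_null_response_r2_near_expectation(self):
        rng = np.random.default_rng(2)
        r2 = []
        for _ in range(300):
            df = cohort_frame(rng)
            df["time_in_open_pct"] = rng.normal(size=len(df))
            r2.append(oa.avoidance_regression(df).rsquared)
        assert np.mean(r2) == pytest.approx(5.0 / 32.0, abs=0.02)

    def test_driving_predictor_has_smallest_p(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(100):
            df = cohort_frame(rng)
            df["time_in_open_pct"] = (3.0 * df["n_movements_into_open"]
                                      + rng.normal(size=len(df)))
            res = oa.avoidance_regression(df)
            p = res.pvalues.drop("const")
            wins += p.idxmin() == "n_movements_into_open"
        assert wins > 95

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(4)
        df = cohort_frame(rng)
        df["total_distance"] = 2.0 * df["n_movements"]
        df["time_in_open_pct"] = rng.normal(size=len(df))
        with pytest.raises(CollinearityError) as err:
            oa.avoidance_regression(df)
        assert "n_movements" in str(err.value)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(5)
        df = cohort_frame(rng)
        df["total_distance"] = 7.0
        df["time_in_open_pct"] = rng.normal(size=len(df))
        with pytest.raises(CollinearityError):
            oa.avoidance_regression(df)


class TestPartialCorrelation:
    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        c = rng.normal(size=500)
        r_plain = np.corrcoef(x, y)[0, 1]
        r_part, _ = oa.partial_correlation(x, y, c)
        assert r_part == pytest.approx(r_plain, abs=0.02)

    def test_y_equal_to_control_degenerate(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        c = rng.normal(size=50)
        with pytest.raises(DegenerateDataError):
            oa.partial_correlation(x, c, c)

    def test_recovers_known_partial_correlation(self):
        # x and y share rho=0.6 given z, both loaded on z
        rng = np.random.default_rng(8)
        n = 200
        z = rng.normal(size=n)
        e1 = rng.normal(size=n)
        e2 = 0.6 * e1 + np.sqrt(1 - 0.36) * rng.normal(size=n)
        x, y = 1.5 * z + e1, -0.8 * z + e2
        r, p = oa.partial_correlation(x, y, z)
        se = (1 - 0.36) / np.sqrt(n - 3)
        assert abs(r - 0.6) < 3 * se
        assert p < 1e-6

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x, y, c = rng.normal(size=(3, 60))
        y = y + 0.4 * x + 0.3 * c
        r, p = oa.partial_correlation(x, y, c)
        ref = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y",
            covar="c")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


class TestRmAnova:
    def test_identical_periods_give_null_result(self):
        data = pd.DataFrame({"baseline": [1.0, 2.0, 3.0, 4.0],
                             "pre_movement": [1.0, 2.0, 3.0, 4.0],
                             "movement": [1.0, 2.0, 3.0, 4.0]})
        res = oa.rm_anova_periods(data)
        assert res.fvalue == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_shifted_movement_period_detected(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=8)
        data = pd.DataFrame({"baseline": base,
                             "pre_movement": base + rng.normal(0, 0.1, 8),
                             "movement": base + 5.0 + rng.normal(0, 0.1, 8)})
        res = oa.rm_anova_periods(data)
        assert res.pvalue < 1e-6
        row = res.pairwise.set_index(["a", "b"]).loc[("baseline", "movement")]
        assert row["p_sidak"] < 0.001

    def test_matches_pingouin_f_and_p(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        wide = pd.DataFrame(rng.normal(size=(12, 3)),
                            columns=["baseline", "pre_movement", "movement"])
        res = oa.rm_anova_periods(wide)
        long = wide.reset_index().melt(id_vars="index", var_name="period",
                                       value_name="dff")
        ref = pingouin.rm_anova(data=long, dv="dff", within="period",
                                subject="index")
        assert res.fvalue == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.pvalue == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_subject_excluded_listwise(self):
        rng = np.random.default_rng(12)
        wide = pd.DataFrame(rng.normal(size=(6, 3)),
                            columns=["baseline", "pre_movement", "movement"])
        wide.iloc[2, 1] = np.nan
        res = oa.rm_anova_periods(wide)
        assert res.n_subjects == 5 and res.n_excluded == 1

    def test_sidak_never_below_uncorrected(self):
        rng = np.random.default_rng(13)
        wide = pd.DataFrame(rng.normal(size=(9, 3)),
                            columns=["baseline", "pre_movement", "movement"])
        res = oa.rm_anova_periods(wide)
        assert (res.pairwise["p_sidak"] >= res.pairwise["p_uncorrected"]).all()
        p = np.linspace(0, 1, 11)
        assert np.all(sidak_adjust(p, 3) >= p)


class TestPairedOneTailed:
    def test_equal_inputs_give_half(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = oa.paired_onetailed(a, a.copy())
        assert t == 0.0 and p == 0.5

    def test_constant_shift_detected_in_matching_direction(self):
        rng = np.random.default_rng(14)
        b = rng.normal(size=10)
        a = b + 2.0 + rng.normal(0, 0.2, 10)
        t, p = oa.paired_onetailed(a, b, direction="greater")
        assert p < 0.05
        t2, p2 = oa.paired_onetailed(a, b, direction="less")
        assert p2 > 0.95

    def test_zero_variance_nonzero_diff_raises(self):
        with pytest.raises(DegenerateDataError):
            oa.paired_onetailed([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            oa.paired_onetailed([1.0, 2.0], [1.0])
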