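import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynfc.group_stats import (
    bonferroni,
    brain_behavior_correlations,
    cohen_d_paired,
    composite_cpt,
    correct_family,
    paired_t,
    predict_treatment_response,
    welch_t,
)


class TestPairedT:
    # printed paired statistics with n = 27: d = t / sqrt(n)
    @pytest.mark.parametrize(
        "t, expected_d",
        [(4.60, 0.89), (4.03, 0.78), (5.05, 0.97), (4.37, 0.84), (2.97, 0.57), (2.12, 0.41)],
    )
    def test_d_identity_from_printed_t(self, t, expected_d):
        assert round(cohen_d_paired(t, 27), 2) == expected_d

    def test_matches_scipy(self, rng):
        a = rng.normal(1, 1, 20)
        b = rng.normal(0, 1, 20)
        res = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 19

    def test_d_equals_t_over_sqrt_n(self, rng):
        a = rng.normal(0.5, 1, 30)
        b = rng.normal(0, 1, 30)
        res = paired_t(a, b)
        assert res.d == pytest.approx(res.t / np.sqrt(30), abs=1e-12)

    def test_identical_arrays_zero_variance(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(a, a)

    def test_null_differences_small_t(self, rng):
        a = rng.normal(size=40)
        res = paired_t(a, a + rng.normal(0, 1, 40))
        assert abs(res.t) < 5  # sanity; just must not error

    def test_order_invariance(self, rng):
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 15)
        perm = rng.permutation(15)
        assert paired_t(a, b).p_raw == pytest.approx(
            paired_t(a[perm], b[perm]).p_raw, abs=1e-12
        )


class TestWelchT:
    def test_equal_n_reduces_to_student(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.3, 2, 25)
        res = welch_t(x, y)
        student = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(student.statistic, abs=1e-9)

    def test_satterthwaite_df(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 3, 40)
        res = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.df == pytest.approx(ref.df)
        assert res.df < 58  # strictly less than pooled df with unequal variances

    def test_separation_tiny_p(self, rng):
        x = rng.normal(0, 0.01, 20)
        res = welch_t(x + 5.0, x)
        assert res.p_raw < 1e-20

    def test_type_one_error_calibration(self):
        hits = 0
        n_reps = 2000
        rng = np.random.default_rng(0)
        for _ in range(n_reps):
            x = rng.normal(size=15)
            y = rng.normal(size=25)
            if welch_t(x, y).p_raw < 0.05:
                hits += 1
        assert 0.035 < hits / n_reps < 0.065

    def test_both_effect_size_conventions(self, rng):
        x = rng.normal(1, 1, 30)
        y = rng.normal(0, 2, 50)
        res = welch_t(x, y)
        nx, ny = 30, 50
        sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
        assert res.d == pytest.approx((x.mean() - y.mean()) / sp)
        rms = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        assert res.d_unpooled == pytest.approx((x.mean() - y.mean()) / rms)

    def test_zero_variance_both_groups(self):
        with pytest.raises(ValueError):
            welch_t(np.ones(5), np.full(5, 2.0))


class TestBonferroni:
    def test_simple(self):
        assert bonferroni(0.02, 3)[0] == pytest.approx(0.06)

    def test_cap(self):
        assert bonferroni(0.5, 3)[0] == 1.0

    def test_boundary(self):
        assert bonferroni(1 / 3, 3)[0] == pytest.approx(1.0)

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02, 0.03], 2)

    def test_correct_family_inplace(self, rng):
        comps = [paired_t(rng.normal(1, 1, 10), rng.normal(0, 1, 10)) for _ in range(3)]
        correct_family(comps, m=3)
        for c in comps:
            assert c.p_bonferroni == pytest.approx(min(1.0, 3 * c.p_raw))


class TestCompositeCpt:
    def test_recomputation_matches(self, rng):
        table = pd.DataFrame(
            rng.normal(50, 10, size=(30, 4)),
            columns=["omission", "commission", "mean_rt", "rt_sd"],
        )
        comp = composite_cpt(table, ("omission", "commission", "mean_rt", "rt_sd"))
        z = (table - table.mean()) / table.std(ddof=1)
        assert np.allclose(comp, z.mean(axis=1))
        # standardized composite has mean zero by construction
        assert comp.mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_column(self):
        with pytest.raises(ValueError):
            composite_cpt(pd.DataFrame({"a": [1.0]}), ("a", "b"))


class TestBrainBehaviorCorrelations:
    def _table(self, rng, slope=2.0, noise=1.0, n=40):
        dwell = rng.uniform(10, 60, n)
        nii_sd = rng.normal(0.5, 0.2, n)
        return pd.DataFrame(
            {
                "mean_dwell_s": dwell,
                "nii_sd": nii_sd,
                "inattention": 40 + slope * dwell + rng.normal(0, noise, n),
                "hyperactivity": 40 + rng.normal(0, 5, n),
            }
        )

    def test_positive_loading_recovered(self):
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = self._table(rng, slope=0.5, noise=5.0)
            out = brain_behavior_correlations(
                table, ("mean_dwell_s",), ("inattention", "hyperactivity")
            )
            r = out.loc[out.clinical == "inattention", "r"].item()
            signs.append(r > 0)
        assert np.mean(signs) >= 0.95

    def test_perfect_linear(self, rng):
        table = self._table(rng, slope=1.0, noise=0.0)
        out = brain_behavior_correlations(table, ("mean_dwell_s",), ("inattention",))
        assert out["r"].item() == pytest.approx(1.0)

    def test_null_confidence_coverage(self):
        """95% Fisher CI for r covers 0 at roughly the nominal rate."""
        covered = 0
        n, reps = 40, 200
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            table = self._table(rng, slope=0.0, noise=5.0)
            out = brain_behavior_correlations(
                table, ("mean_dwell_s",), ("inattention",)
            )
            z = np.arctanh(out["r"].item())
            half = 1.96 / np.sqrt(n - 3)
            covered += abs(z) <= half
        assert 0.90 <= covered / reps <= 0.99

    def test_bonferroni_family_is_clinical_count(self, rng):
        table = self._table(rng)
        out = brain_behavior_correlations(
            table, ("mean_dwell_s", "nii_sd"), ("inattention", "hyperactivity")
        )
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, 2 * out["p_raw"])
        )

    def test_small_n_rejected(self, rng):
        table = self._table(rng, n=5)
        with pytest.raises(ValueError, match="complete cases"):
            brain_behavior_correlations(table, ("nii_sd",), ("inattention",))


class TestPredictTreatmentResponse:
    def _table(self, rng, n=27, slope=-26.57, noise=0.0):
        t = pd.DataFrame(
            {
                "nii_mean": rng.normal(0.2, 0.3, n),
                "nii_sd": rng.normal(0.5, 0.2, n),
                "age": rng.uniform(7, 15, n),
                "fsiq": rng.uniform(80, 120, n),
                "mean_fd": rng.uniform(0.03, 0.12, n),
            }
        )
        t["composite_change"] = (
            1.0 + slope * t["nii_sd"] + 0.1 * t["age"] + rng.normal(0, noise, n)
        )
        return t

    def test_noiseless_exact_recovery(self, rng):
        model = predict_treatment_response(self._table(rng))
        assert model.coef["nii_sd"] == pytest.approx(-26.57, abs=1e-8)
        assert model.coef["age"] == pytest.approx(0.1, abs=1e-8)
        assert model.coef["nii_mean"] == pytest.approx(0.0, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_negative_slope_detected_with_power(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            model = predict_treatment_response(self._table(rng, noise=3.0))
            hits += (model.coef["nii_sd"] < 0) and (model.pvalues["nii_sd"] < 0.05)
        assert hits >= 28

    def test_permuted_outcome_calibration(self):
        hits = 0
        reps = 200
        rng = np.random.default_rng(0)
        base = self._table(rng, slope=0.0, noise=3.0)
        for _ in range(reps):
            t = base.copy()
            t["composite_change"] = rng.permutation(t["composite_change"].to_numpy())
            model = predict_treatment_response(t)
            hits += model.pvalues["nii_sd"] < 0.05
        assert hits / reps < 0.11

    def test_rank_deficiency_names_columns(self, rng):
        t = self._table(rng)
        t["fsiq"] = 2 * t["age"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            predict_treatment_response(t)

    def test_too_few_cases(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            predict_treatment_response(self._table(rng, n=7))

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm

        t = self._table(rng, noise=2.0)
        model = predict_treatment_response(t)
        x = sm.add_constant(t[["nii_mean", "nii_sd", "age", "fsiq", "mean_fd"]])
        ref = sm.OLS(t["composite_change"], x).fit()
        assert model.coef["nii_sd"] == pytest.approx(ref.params["nii_sd"])
        assert model.r_squared == pytest.approx(ref.rsquared)
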