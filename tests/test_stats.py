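"""Normality gating, group tests, adjustment, stratified FDR, regressions."""
import numpy as np
import pandas as pd
import pytest

from aslquant.errors import ValidationError
from aslquant.stats import (adjust_age_sex, bh_fdr, cognition_regression,
                            compare_groups, correlate, normality_gate)
from aslquant.synthetic import CohortSpec, simulate_cohort


class TestNormalityGate:
    def test_heavy_tailed_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.standard_cauchy(100)
        assert normality_gate(x) == "non_normal"

    def test_gaussian_type_one_calibration(self):
        """Rejection rate of Gaussian samples sits near the nominal 5% level."""
        rejections = sum(
            normality_gate(np.random.default_rng(s).normal(size=100)) == "non_normal"
            for s in range(200))
        # Binomial(200, 0.05): mean 10, sd ~3.1
        assert rejections <= 10 + 4 * 3.1

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            normality_gate([1.0, 2.0])

    def test_constant_vector_warns_non_normal(self):
        with pytest.warns(UserWarning):
            assert normality_gate([3.0] * 10) == "non_normal"


class TestCompareGroups:
    def test_identical_groups_null(self):
        vals = list(np.random.default_rng(1).normal(size=20))
        res = compare_groups(vals + vals, ["a"] * 20 + ["b"] * 20)
        assert res.p_raw == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_planted_gm_cbf_effect_is_overwhelming(self):
        """A ~11.5-point mean gap at SD ~7.5 with n=89/42 gives p < 1e-4."""
        rng = np.random.default_rng(42)
        a = rng.normal(54.06, 7.78, 89)
        b = rng.normal(42.52, 7.13, 42)
        res = compare_groups(np.r_[a, b], ["SCA"] * 89 + ["control"] * 42)
        assert res.p_raw < 1e-4
        assert res.effect_size > 1.0

    def test_t_branch_matches_textbook_formula(self):
        # 6-point example, computed by hand with the pooled-variance t
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        res = compare_groups(np.r_[a, b], ["x"] * 3 + ["y"] * 3)
        sp2 = ((2 * 1.0) + (2 * 4.0)) / 4          # pooled variance = 2.5
        t_hand = (2.0 - 4.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.test == "student_t"
        assert res.statistic == pytest.approx(t_hand)

    def test_nonnormal_branch_uses_mann_whitney(self):
        rng = np.random.default_rng(3)
        a = np.exp(rng.normal(0, 1.5, 60))    # strongly lognormal
        b = np.exp(rng.normal(0.5, 1.5, 60))
        res = compare_groups(np.r_[a, b], ["x"] * 60 + ["y"] * 60)
        assert res.test == "mann_whitney_u"
        assert -1.0 <= res.effect_size <= 1.0

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                           ["a", "a", "a", "b", "b", "b"])


class TestAdjustAgeSex:
    def test_independent_feature_mean_preserved(self):
        rng = np.random.default_rng(11)
        y = rng.normal(10, 2, 200)
        age = rng.uniform(8, 30, 200)
        sex = rng.choice(["male", "female"], 200)
        adj = adjust_age_sex(y, age, sex)
        assert adj.mean() == pytest.approx(y.mean())
        assert np.corrcoef(adj, y)[0, 1] > 0.95

    def test_pure_age_effect_flattened_to_grand_mean(self):
        age = np.linspace(8, 30, 50)
        y = 2.0 * age
        sex = ["male", "female"] * 25
        adj = adjust_age_sex(y, age, sex)
        assert np.allclose(adj, y.mean(), atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        n = 80
        age = rng.uniform(8, 30, n)
        sex = rng.choice(["male", "female"], n)
        sex_num = (pd.Categorical(sex).codes).astype(float)
        y = 5 + 0.3 * age - 1.2 * sex_num + rng.normal(0, 1, n)
        adj = adjust_age_sex(y, age, sex)
        X = np.column_stack([np.ones(n), age, sex_num])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(adj, y - X @ beta + y.mean(), atol=1e-8)

    def test_single_sex_drops_sex_with_warning(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="single-sex"):
            adj = adjust_age_sex(y, rng.uniform(8, 30, 30), ["male"] * 30)
        assert np.isfinite(adj).all()

    def test_log_transform_requires_positive(self):
        with pytest.raises(ValidationError):
            adjust_age_sex([-1.0, 2.0, 3.0], [10, 20, 30],
                           ["male", "female", "male"], log_transform=True)


class TestCorrelate:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = correlate(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.5, 50)
        r1 = correlate(x, y, method="spearman").statistic
        r2 = correlate(np.exp(x), y, method="spearman").statistic
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1.0] * 10, list(range(10)))

    def test_planted_cao2_coupling_negative_in_all_regions(self):
        df = simulate_cohort(CohortSpec(seed=23))
        sca = df[df["group"] == "SCA"]
        for feat in ("cbf_sti_gm", "cbf_sti_wm", "cbf_sti_sinus"):
            adj = adjust_age_sex(sca[feat], sca["age"], sca["sex"])
            assert correlate(adj, sca["cao2"]).statistic < 0


def _bh_oracle(p):
    """Brute-force step-up definition: p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHFDR:
    def test_single_p_unchanged(self):
        df = pd.DataFrame({"p_raw": [0.03], "family": ["a"], "group": ["g"]})
        assert bh_fdr(df)["p_adj"].iloc[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        df = pd.DataFrame({"p_raw": [0.01, 0.02, 0.03, 0.04],
                           "family": ["f"] * 4, "group": ["g"] * 4})
        assert np.allclose(bh_fdr(df)["p_adj"], [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            m = rng.integers(1, 9)
            p = rng.random(m)
            df = pd.DataFrame({"p_raw": p, "family": ["f"] * m, "group": ["g"] * m})
            assert np.allclose(bh_fdr(df)["p_adj"], _bh_oracle(p))

    def test_adjustment_is_within_strata(self, rng):
        p = rng.random(12)
        fams = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        df = pd.DataFrame({"p_raw": p, "family": fams, "group": ["g"] * 12})
        out = bh_fdr(df)
        for fam in "abc":
            sel = out["family"] == fam
            assert np.allclose(out.loc[sel, "p_adj"],
                               _bh_oracle(p[np.asarray(fams) == fam]))

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        p = rng.random(20)
        df = pd.DataFrame({"p_raw": p, "family": ["f"] * 20, "group": ["g"] * 20})
        out = bh_fdr(df)
        assert np.all(out["p_adj"] >= out["p_raw"] - 1e-15)
        assert np.all(out["p_adj"] <= 1.0)

    def test_invalid_p_rejected(self):
        df = pd.DataFrame({"p_raw": [0.5, 1.5], "family": ["f", "f"],
                           "group": ["g", "g"]})
        with pytest.raises(ValidationError):
            bh_fdr(df)


class TestCognitionRegression:
    @staticmethod
    def _cohort(n=80, noise=1.0, seed=29):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "age": rng.uniform(8, 30, n),
            "male": rng.integers(0, 2, n).astype(float),
            "hydroxycarbamide": rng.integers(0, 2, n).astype(float),
            "transfusion": rng.integers(0, 2, n).astype(float),
            "sci_burden": rng.exponential(50, n),
            "etiv": rng.normal(1450, 100, n),
            "education_decile": rng.integers(1, 11, n).astype(float),
            "cbf_mti_sinus": np.exp(rng.normal(5.5, 0.8, n)),
        })
        df["iq"] = (100 - 3.94 * np.log(df["cbf_mti_sinus"]) - 0.2 * df["age"]
                    + 2.0 * df["male"] + rng.normal(0, noise, n))
        return df

    def test_near_exact_linear_outcome_recovered(self):
        df = self._cohort(noise=1e-9)
        rep = cognition_regression(df, "iq", ["cbf_mti_sinus"],
                                   covariates=("age", "male"),
                                   log_predictors=["cbf_mti_sinus"],
                                   enforce_gate=False)
        term = rep.term("log_cbf_mti_sinus")
        assert term.b == pytest.approx(-3.94, abs=1e-6)
        assert abs(term.partial_r) > 0.999999

    def test_standardised_beta_identity(self):
        df = self._cohort(noise=5.0)
        rep = cognition_regression(df, "iq", ["cbf_mti_sinus"],
                                   covariates=("age", "male"),
                                   log_predictors=["cbf_mti_sinus"],
                                   enforce_gate=False)
        term = rep.term("log_cbf_mti_sinus")
        sd_x = np.log(df["cbf_mti_sinus"]).std(ddof=1)
        assert term.beta == pytest.approx(term.b * sd_x / df["iq"].std(ddof=1))

    def test_partial_r_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = self._cohort(noise=8.0)
        df["log_sinus"] = np.log(df["cbf_mti_sinus"])
        rep = cognition_regression(df, "iq", ["log_sinus"],
                                   covariates=("age", "male"),
                                   enforce_gate=False)
        pc = pingouin.partial_corr(df, x="log_sinus", y="iq",
                                   covar=["age", "male"])
        assert rep.term("log_sinus").partial_r == pytest.approx(
            float(pc["r"].iloc[0]), abs=1e-6)

    def test_gate_enforced(self):
        rng = np.random.default_rng(31)
        df = self._cohort(noise=5.0)
        df["iq"] = rng.normal(100, 10, len(df))   # outcome unrelated to predictor
        with pytest.raises(ValidationError, match="gate"):
            cognition_regression(df, "iq", ["cbf_mti_sinus"],
                                 covariates=("age", "male"),
                                 log_predictors=["cbf_mti_sinus"])

    def test_too_few_cases_rejected(self):
        df = self._cohort(n=8)
        with pytest.raises(ValidationError):
            cognition_regression(df, "iq", ["cbf_mti_sinus"], enforce_gate=False)
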