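import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chorioquant import (
    CohortSimParams,
    NearWorkChangeModel,
    bland_altman,
    bonferroni,
    generate_cohort,
    group_contrast_ancova,
    icc_absolute_agreement,
    paired_change_test,
    percent_change,
    rm_anova_gg,
)


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert percent_change(250.0, 250.0) == 0.0

    def test_direct_arithmetic(self):
        assert percent_change(990.0, 970.8) == pytest.approx(100 * (970.8 - 990.0) / 990.0)
        assert percent_change(990.0, 970.8) == pytest.approx(-1.9394, abs=1e-4)

    def test_sign_follows_direction(self, rng):
        pre = rng.uniform(1, 100, 50)
        post = pre + rng.normal(0, 5, 50)
        assert np.all(np.sign(percent_change(pre, post)) == np.sign(post - pre))

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError, match="pre"):
            percent_change(0.0, 5.0)


class TestPairedTest:
    def test_symmetric_deltas_give_t_zero(self):
        t, p = paired_change_test([2.0, -2.0, 3.0, -3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_vector_matches_formula(self):
        """Brute-force oracle from the one-sample t formula and the t CDF."""
        d = np.array([-3.0, -1.0, -4.0, -2.0, -5.0])
        t, p = paired_change_test(d)
        n = len(d)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p_manual = 2 * sps.t.sf(abs(t_manual), n - 1)
        assert t == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            paired_change_test([1.0])

    def test_bonferroni_caps_at_one(self):
        assert bonferroni([0.4], m=3)[0] == 1.0
        out = bonferroni([0.01, 0.4], m=2)
        assert out[0] == pytest.approx(0.02)
        assert out[1] == pytest.approx(0.8)


class TestRmAnovaGG:
    def test_two_levels_epsilon_exactly_one(self, rng):
        x = rng.normal(size=(12, 2)) + [0.0, 0.5]
        r = rm_anova_gg(x)
        assert r.epsilon_gg == 1.0

    def test_constant_subjects_give_zero_f(self):
        offsets = np.arange(8, dtype=float)[:, None]
        x = np.repeat(offsets, 3, axis=1)  # flat over time, subject offsets
        r = rm_anova_gg(x)
        assert r.F == 0.0
        assert r.p == 1.0

    def test_compound_symmetry_epsilon_near_one(self, rng):
        n, k = 300, 4
        subj = rng.normal(0, 2, (n, 1))
        x = subj + rng.normal(0, 1, (n, k))
        r = rm_anova_gg(x)
        assert abs(r.epsilon_gg - 1.0) <= 0.05

    def test_epsilon_respects_bounds_on_random_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 20))
            k = int(rng.integers(2, min(n, 6)))
            x = rng.normal(size=(n, k)) * rng.uniform(0.5, 3)
            r = rm_anova_gg(x)
            assert 1.0 / (k - 1) <= r.epsilon_gg <= 1.0
            assert 0.0 <= r.p <= 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n, k = 40, 3
        x = rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (n, k)) + [0, 0.4, 0.1]
        r = rm_anova_gg(x)
        df = pd.DataFrame({
            "y": x.ravel(),
            "s": np.repeat(np.arange(n), k),
            "t": np.tile(np.arange(k), n),
        })
        aov = pg.rm_anova(data=df, dv="y", within="t", subject="s", correction=True)
        assert r.F == pytest.approx(float(aov["F"].iloc[0]))
        assert r.epsilon_gg == pytest.approx(float(aov["eps"].iloc[0]))
        assert r.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]))

    def test_missing_cells_rejected(self):
        x = np.ones((6, 3))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_gg(x)


class TestGroupContrast:
    def test_identical_groups_give_null_difference(self, rng):
        changes = rng.normal(0, 1, 100)
        group = np.array(["adult"] * 50 + ["child"] * 50)
        al = np.tile(rng.normal(24.8, 0.9, 50), 2)
        res = group_contrast_ancova(changes, group, al)
        assert abs(res.adjusted_mean_difference) <= 3 * res.se

    def test_recovers_injected_offset(self, rng):
        n = 200
        al = np.tile(rng.normal(24.8, 0.9, n), 2)  # same AL values in both groups
        delta = 1.5
        changes = np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)])
        group = np.array(["adult"] * n + ["child"] * n)
        res = group_contrast_ancova(changes, group, al)
        assert res.adjusted_mean_difference == pytest.approx(delta, abs=0.3)
        assert res.groups == ("adult", "child")

    def test_coefficients_match_normal_equations_on_toy_design(self):
        """8-row oracle: OLS coefficients from an explicit least-squares solve."""
        changes = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 2.5, 3.5, 4.0])
        group = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        al = np.array([24.0, 25.0, 24.5, 26.0, 24.2, 25.5, 24.8, 26.1])
        model = NearWorkChangeModel(changes, group, al)
        res = model.fit()
        X = np.column_stack([np.ones(8), (group == "b").astype(float), al])
        beta = np.linalg.lstsq(X, changes, rcond=None)[0]
        assert res.contrast.adjusted_mean_difference == pytest.approx(beta[1])
        assert res.params.iloc[0] == pytest.approx(beta[0])

    def test_collinear_al_dropped_with_warning(self):
        changes = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 3.0])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        al = np.full(6, 24.5)
        with pytest.warns(UserWarning, match="zero variance"):
            res = group_contrast_ancova(changes, group, al)
        assert "al_mm" not in res.covariates

    def test_from_dataframe_roundtrip(self):
        df = generate_cohort(CohortSimParams(n_per_group=12, seed=3))
        res = NearWorkChangeModel.from_dataframe(df, "SFCT").fit()
        assert np.isfinite(res.contrast.adjusted_mean_difference)
        assert res.contrast.se >= 0
        assert "coef" in str(res.summary()).lower()


class TestRepeatability:
    def test_identical_series_perfect_agreement(self):
        s = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        assert icc_absolute_agreement(s, s) == pytest.approx(1.0)
        bias, lo, hi = bland_altman(s, s)
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset_shows_as_bias(self):
        s = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        bias, lo, hi = bland_altman(s + 2.0, s)
        assert bias == pytest.approx(2.0)
        assert hi - lo == pytest.approx(0.0)

    def test_icc_matches_variance_components(self, rng):
        """Closed form sigma_b^2 / (sigma_b^2 + sigma_e^2) = 9/10."""
        n = 500
        b = rng.normal(0, 3, n)
        s1 = b + rng.normal(0, 1, n)
        s2 = b + rng.normal(0, 1, n)
        assert icc_absolute_agreement(s1, s2) == pytest.approx(0.9, abs=0.05)

    def test_icc_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 60
        b = rng.normal(0, 2, n)
        s1 = b + rng.normal(0, 1, n)
        s2 = b + 0.3 + rng.normal(0, 1, n)
        mine = icc_absolute_agreement(s1, s2)
        df = pd.DataFrame({
            "target": np.tile(np.arange(n), 2),
            "rater": ["r1"] * n + ["r2"] * n,
            "score": np.concatenate([s1, s2]),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = pg.intraclass_corr(data=df, targets="target", raters="rater", ratings="score")
        ref = float(tab.loc[tab["Type"] == "ICC(A,1)", "ICC"].iloc[0]) \
            if (tab["Type"] == "ICC(A,1)").any() else float(tab.loc[tab["Type"] == "ICC2", "ICC"].iloc[0])
        assert mine == pytest.approx(ref, abs=1e-9)

    def test_zero_variance_rejected(self):
        s = np.full(5, 3.0)
        with pytest.raises(ValueError, match="variance"):
            icc_absolute_agreement(s, s)
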