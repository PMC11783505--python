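"""Genotype grouping, IQR outlier rule, genotype x age model, Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from eventconn.genostats import (
    GenotypeAgeModel,
    TERMS,
    bayes_factor_null,
    flag_outliers_iqr,
    group_genotypes,
)


def _cohort(counts: dict[str, int]) -> pd.DataFrame:
    rows = [(f"s{i}", g) for i, g in enumerate(
        g for g, n in counts.items() for _ in range(n)
    )]
    return pd.DataFrame(rows, columns=["subject_id", "genotype"])


class TestGroupGenotypes:
    def test_study_class_sizes_reproduce_group_counts(self):
        cohort = _cohort({"e3/e4": 126, "e4/e4": 8, "e3/e3": 291, "e2_carrier": 74})
        grouped = group_genotypes(cohort)
        assert (grouped["group"] == "e4+").sum() == 134
        assert (grouped["group"] == "e3/e3").sum() == 291
        assert len(grouped) == 425

    def test_only_e2_carriers_gives_empty_cohort(self):
        grouped = group_genotypes(_cohort({"e2/e3": 5, "e2_carrier": 2}))
        assert grouped.empty

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="e5"):
            group_genotypes(_cohort({"e5/e5": 1}))


def _fence_oracle(resid: np.ndarray) -> np.ndarray:
    """Brute-force quartile/fence computation via manual interpolation."""
    s = np.sort(resid)
    n = s.size

    def quantile(q):
        pos = q * (n - 1)
        lo, frac = int(np.floor(pos)), pos - np.floor(pos)
        return s[lo] if frac == 0 else s[lo] * (1 - frac) + s[lo + 1] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return (resid < q1 - 1.5 * iqr) | (resid > q3 + 1.5 * iqr)


class TestOutlierFlags:
    def test_identical_values_never_flagged(self):
        y = np.full(20, 3.0)
        age = np.linspace(20, 80, 20)
        assert not flag_outliers_iqr(y, age).any()

    def test_single_extreme_point_flagged_matches_hand_fences(self):
        y = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        age = np.full(5, 50.0)  # constant age: polynomial collapses to the mean
        mask = flag_outliers_iqr(y, age)
        assert mask.tolist() == [False, False, False, False, True]

    def test_matches_bruteforce_fences_on_random_vectors(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            age = rng.uniform(18, 88, n)
            y = rng.standard_normal(n) + 0.02 * age
            X = np.column_stack([np.ones(n), age, age**2])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            expected = _fence_oracle(y - X @ beta)
            assert np.array_equal(flag_outliers_iqr(y, age), expected)

    def test_symmetric_under_residual_negation(self, rng):
        age = rng.uniform(18, 88, 60)
        y = rng.standard_normal(60)
        X = np.column_stack([np.ones(60), age, age**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ beta
        reflected = 2 * fit - y  # negates residuals, keeps the fit
        assert np.array_equal(flag_outliers_iqr(y, age), flag_outliers_iqr(reflected, age))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers_iqr(np.zeros(4), np.arange(4.0))


def _simulate(rng, n=120, effect=0.0):
    age = rng.uniform(18, 88, n)
    group = np.where(rng.random(n) < 0.3, "e4+", "e3/e3")
    y = rng.standard_normal(n) + effect * (group == "e4+")
    return pd.DataFrame({"y": y, "age": age, "group": group})


class TestGenotypeAgeModel:
    def test_matches_normal_equations_on_hand_dataset(self):
        # ten-point dataset small enough to solve by explicit normal equations
        age = np.array([20, 25, 30, 40, 45, 55, 60, 70, 80, 85], dtype=float)
        group = np.array(["e3/e3", "e4+"] * 5)
        y = np.array([1.0, 2.0, 0.5, 1.5, 2.5, 0.0, 1.0, 3.0, -1.0, 2.0])
        res = GenotypeAgeModel(y, age, group, remove_outliers=False).fit()
        z = (age - age.mean()) / age.std()
        z2 = (z**2 - (z**2).mean()) / (z**2).std()
        g = (group == "e4+").astype(float)
        X = np.column_stack([np.ones(10), z, z2, g, g * z, g * z2])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        df = 10 - 6
        sigma2 = resid @ resid / df
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        adj_r2 = 1 - (1 - r2) * (10 - 1) / df
        assert np.allclose(res.params["estimate"], beta, atol=1e-10)
        assert np.allclose(res.params["se"], se, atol=1e-10)
        assert res.adj_r2 == pytest.approx(adj_r2, abs=1e-10)
        assert res.df_resid == df

    def test_zscored_regressors_have_mean_zero_sd_one(self, rng):
        data = _simulate(rng)
        res = GenotypeAgeModel.from_dataframe(data).fit()
        kept = data.loc[~res.outlier_mask]
        z = (kept["age"] - kept["age"].mean()) / kept["age"].std(ddof=0)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_p_values_invariant_to_affine_rescaling_of_y(self, rng):
        data = _simulate(rng)
        res1 = GenotypeAgeModel.from_dataframe(data).fit()
        data2 = data.assign(y=5.0 * data["y"] - 11.0)
        res2 = GenotypeAgeModel.from_dataframe(data2).fit()
        # every term except the intercept (which absorbs the shift)
        terms = [t for t in TERMS if t != "intercept"]
        assert np.allclose(res1.params.loc[terms, "p"], res2.params.loc[terms, "p"], atol=1e-10)

    def test_group_main_effect_recovered(self, rng):
        ests = [
            GenotypeAgeModel.from_dataframe(_simulate(rng, n=400, effect=0.5))
            .fit()
            .params.loc["apoe", "estimate"]
            for _ in range(40)
        ]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_single_group_rejected(self, rng):
        data = _simulate(rng).assign(group="e3/e3")
        with pytest.raises(ValueError):
            GenotypeAgeModel.from_dataframe(data)

    def test_summary_mentions_terms_and_fit(self, rng):
        res = GenotypeAgeModel.from_dataframe(_simulate(rng)).fit()
        text = res.summary()
        assert "apoe_x_age2" in text and "adj R2" in text
        assert list(res.params.index) == list(TERMS)


def _bf01_trapz_oracle(t, n, df, r):
    """JZS BF01 by dense trapezoid quadrature on a log-spaced g grid."""
    g = np.logspace(-8, 6, 40_000)
    like = (1 + n * g) ** -0.5 * (1 + t * t / ((1 + n * g) * df)) ** (-(df + 1) / 2)
    prior = r / np.sqrt(2 * np.pi) * g**-1.5 * np.exp(-(r * r) / (2 * g))
    alt = np.trapezoid(like * prior, g)
    null = (1 + t * t / df) ** (-(df + 1) / 2)
    return null / alt


class TestBayesFactor:
    @pytest.mark.parametrize("t", [0.0, 0.8, 2.5, 5.0])
    def test_matches_quadrature_oracle_within_5_percent(self, t):
        got = bayes_factor_null(t, n=400, df=394)
        oracle = _bf01_trapz_oracle(t, 400, 394, np.sqrt(2) / 2)
        assert got == pytest.approx(oracle, rel=0.05)

    def test_strong_effect_yields_strong_evidence_against_null(self, rng):
        # standardized effect 1.0, n=400 -> t ~ 20: BF01 far below 1/3
        hits = 0
        for _ in range(50):
            t = rng.standard_normal() + 1.0 * np.sqrt(400)
            if bayes_factor_null(t, n=400, df=398) < 1 / 3:
                hits += 1
        assert hits >= 48

    def test_bf01_grows_with_n_under_the_null(self, rng):
        medians = []
        for n in (100, 400, 1600):
            bfs = [
                bayes_factor_null(rng.standard_normal(), n=n, df=n - 6)
                for _ in range(60)
            ]
            medians.append(np.median(bfs))
        assert medians[0] < medians[1] < medians[2]

    def test_savage_dickey_agrees_with_quadrature(self):
        jzs = bayes_factor_null(1.2, n=300, df=294)
        sd = bayes_factor_null(1.2, n=300, df=294, method="savage_dickey", seed=5, n_iter=12_000)
        assert sd == pytest.approx(jzs, rel=0.2)

    def test_savage_dickey_is_seed_deterministic(self):
        a = bayes_factor_null(0.5, 200, 195, method="savage_dickey", seed=9, n_iter=2000)
        b = bayes_factor_null(0.5, 200, 195, method="savage_dickey", seed=9, n_iter=2000)
        assert a == b
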