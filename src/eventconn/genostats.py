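"""Genotype x age models with Bayes-factor evidence for the null.

Each boundary-derived dependent variable (a univariate ROI response or a
pairwise coactivation beta) is modelled across subjects as

    y ~ b0 + b1*z(age) + b2*z(age^2) + b3*group + b4*group*z(age) + b5*group*z(age^2)

with ``group`` coding APOE e4 carriership (e3/e3 = 0, e4+ = 1) and both age
regressors z-scored on the analysed sample (the quadratic term is the square
of z-scored age, itself re-z-scored). Outliers are removed beforehand by the
1.5 x IQR rule on residuals from the age polynomial. Each term gets a
two-tailed t-test (uncorrected) and a Bayes factor BF01 quantifying evidence
for the term-absent model, computed under a Jeffreys–Zellner–Siow Cauchy
prior on the standardized effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "TERMS",
    "group_genotypes",
    "flag_outliers_iqr",
    "bayes_factor_null",
    "GenotypeAgeModel",
    "GenotypeAgeResults",
]

logger = logging.getLogger(__name__)

#: Model terms, in design-matrix order.
TERMS = ("intercept", "age_lin", "age_quad", "apoe", "apoe_x_age", "apoe_x_age2")

_E4_PLUS = {"e3/e4", "e4/e3", "e4/e4"}
_E3_REF = {"e3/e3"}
_E2 = {"e2_carrier", "e2/e2", "e2/e3", "e2/e4"}


def group_genotypes(cohort: pd.DataFrame, genotype_col: str = "genotype") -> pd.DataFrame:
    """Collapse APOE genotypes into the two-level analysis factor.

    e3/e4 and e4/e4 become ``e4+``; e3/e3 is the reference group; any e2
    carrier is dropped (count logged). Unknown genotype strings raise.
    """
    geno = cohort[genotype_col].astype(str)
    known = _E4_PLUS | _E3_REF | _E2
    unknown = sorted(set(geno) - known)
    if unknown:
        raise ValueError(f"unknown genotype value(s): {unknown}")
    is_e2 = geno.isin(_E2)
    if is_e2.any():
        logger.info("dropping %d e2 carrier(s) from the cohort", int(is_e2.sum()))
    kept = cohort.loc[~is_e2].copy()
    kept["group"] = np.where(kept[genotype_col].isin(_E4_PLUS), "e4+", "e3/e3")
    return kept


def flag_outliers_iqr(y: np.ndarray, age: np.ndarray) -> np.ndarray:
    """1.5 x IQR outlier mask on residuals from the age polynomial.

    Residuals come from OLS of y on [1, age, age^2]; a point is flagged when
    its residual lies strictly outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR]. With a
    zero IQR the fences collapse and nothing is flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    age = np.asarray(age, dtype=float).ravel()
    if y.size != age.size or y.size < 5:
        raise ValueError("need matched y and age with n >= 5")
    X = np.column_stack([np.ones_like(age), age, age**2])
    if np.linalg.matrix_rank(X) < (3 if np.unique(age).size >= 3 else np.unique(age).size):
        raise ValueError("degenerate age design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    return (resid < q1 - 1.5 * iqr) | (resid > q3 + 1.5 * iqr)


def _jzs_integrand(g: np.ndarray, t: float, n: int, df: float, r: float) -> np.ndarray:
    """Marginal likelihood integrand of the JZS alternative, up to the null factor."""
    g = np.asarray(g, dtype=float)
    like = (1 + n * g) ** -0.5 * (1 + t * t / ((1 + n * g) * df)) ** (-(df + 1) / 2)
    # g ~ InverseGamma(1/2, r^2/2)  <=>  standardized effect ~ Cauchy(0, r)
    prior = r / np.sqrt(2 * np.pi) * g**-1.5 * np.exp(-r * r / (2 * g))
    return like * prior


def bayes_factor_null(
    t: float,
    n: int,
    df: float,
    prior_scale: float = np.sqrt(2) / 2,
    method: str = "jzs",
    n_iter: int = 20000,
    seed: int | None = None,
) -> float:
    """BF01 for a single regression coefficient from its t statistic.

    ``jzs`` (default): Zellner–Siow Cauchy prior with scale ``prior_scale``
    on the standardized effect, marginal likelihood integrated over the
    g-prior mixture by adaptive quadrature. ``savage_dickey``: seeded
    random-walk Metropolis sampling of the standardized effect under the same
    Cauchy prior, with BF01 as the ratio of posterior to prior density at 0.
    """
    if method == "jzs":
        null_like = (1 + t * t / df) ** (-(df + 1) / 2)
        alt_like, err = integrate.quad(
            _jzs_integrand, 0, np.inf, args=(float(t), int(n), float(df), prior_scale)
        )
        if not np.isfinite(alt_like) or alt_like <= 0:
            raise FloatingPointError("non-finite JZS marginal likelihood")
        return float(null_like / alt_like)
    if method == "savage_dickey":
        return _savage_dickey_bf01(float(t), int(n), float(df), prior_scale, n_iter, seed)
    raise ValueError(f"unknown method {method!r}")


def _savage_dickey_bf01(
    t: float, n: int, df: float, r: float, n_iter: int, seed: int | None
) -> float:
    rng = np.random.default_rng(seed)

    def log_post(delta: float) -> float:
        return stats.nct.logpdf(t, df, delta * np.sqrt(n)) + stats.cauchy.logpdf(
            delta, scale=r
        )

    delta = t / np.sqrt(n)
    lp = log_post(delta)
    step = 2.0 / np.sqrt(n)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        prop = delta + step * rng.standard_normal()
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            delta, lp = prop, lp_prop
        draws[i] = delta
    draws = draws[n_iter // 5 :]  # burn-in
    post_at_zero = stats.gaussian_kde(draws)(0.0)[0]
    return float(post_at_zero / stats.cauchy.pdf(0.0, scale=r))


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


@dataclass
class GenotypeAgeResults:
    """Fitted genotype x age model for one dependent variable.

    Attributes
    ----------
    params : pandas.DataFrame
        One row per term in :data:`TERMS`: estimate, se, t, p, bf01.
    adj_r2, df_resid : float
        Full-model fit statistics.
    outlier_mask : numpy.ndarray
        Boolean over the input rows; True = excluded by the IQR rule.
    group_age_fits : pandas.DataFrame
        Quadratic age-polynomial coefficients fitted separately per group,
        for reporting/plotting.
    """

    params: pd.DataFrame
    adj_r2: float
    df_resid: float
    n_obs: int
    outlier_mask: np.ndarray
    group_age_fits: pd.DataFrame
    dependent: str = "y"
    _data: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Genotype x age model: {self.dependent}",
            f"n = {self.n_obs} (outliers removed: {int(self.outlier_mask.sum())}), "
            f"adj R2 = {self.adj_r2:.4f}, df = {self.df_resid:.0f}",
            "",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format term table (one row per term) for report assembly."""
        out = self.params.reset_index(names="term")
        out.insert(0, "dependent_variable", self.dependent)
        out["adj_r2"] = self.adj_r2
        out["df"] = self.df_resid
        return out

    def plot_age_fits(self, ax=None):
        """Scatter y against age by group with per-group quadratic fits."""
        import matplotlib.pyplot as plt

        if self._data is None:
            raise ValueError("fit data were not retained")
        if ax is None:
            _, ax = plt.subplots()
        for grp, color in (("e3/e3", "tab:blue"), ("e4+", "tab:red")):
            sub = self._data[self._data["group"] == grp]
            ax.scatter(sub["age"], sub["y"], s=10, alpha=0.5, color=color, label=grp)
            c = self.group_age_fits.loc[grp]
            grid = np.linspace(sub["age"].min(), sub["age"].max(), 100)
            ax.plot(grid, c["b0"] + c["b1"] * grid + c["b2"] * grid**2, color=color)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(self.dependent)
        ax.legend()
        return ax


class GenotypeAgeModel:
    """OLS model of a boundary-derived phenotype on age, age^2 and APOE group.

    Parameters
    ----------
    y, age : array-like
        Dependent variable and age in years, one entry per subject.
    group : array-like
        Genotype group labels, ``"e3/e3"`` or ``"e4+"`` (see
        :func:`group_genotypes`).
    remove_outliers : bool
        Apply :func:`flag_outliers_iqr` before fitting (default True).
    bf_method, bf_prior_scale, bf_seed
        Bayes-factor settings passed to :func:`bayes_factor_null`.
    """

    def __init__(
        self,
        y,
        age,
        group,
        remove_outliers: bool = True,
        bf_method: str = "jzs",
        bf_prior_scale: float = np.sqrt(2) / 2,
        bf_seed: int | None = None,
        dependent: str = "y",
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        self.age = np.asarray(age, dtype=float).ravel()
        self.group = np.asarray(group).astype(str).ravel()
        if not (self.y.size == self.age.size == self.group.size):
            raise ValueError("y, age and group must have equal length")
        bad = sorted(set(self.group) - {"e3/e3", "e4+"})
        if bad:
            raise ValueError(f"unexpected group label(s): {bad}")
        if len(set(self.group)) < 2:
            raise ValueError("both genotype groups must be represented")
        self.remove_outliers = remove_outliers
        self.bf_method = bf_method
        self.bf_prior_scale = bf_prior_scale
        self.bf_seed = bf_seed
        self.dependent = dependent

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        y: str = "y",
        age: str = "age",
        group: str = "group",
        **kwargs,
    ) -> "GenotypeAgeModel":
        kwargs.setdefault("dependent", y)
        return cls(data[y], data[age], data[group], **kwargs)

    def fit(self) -> GenotypeAgeResults:
        import statsmodels.api as sm

        mask = (
            flag_outliers_iqr(self.y, self.age)
            if self.remove_outliers
            else np.zeros(self.y.size, dtype=bool)
        )
        y = self.y[~mask]
        age = self.age[~mask]
        grp = (self.group[~mask] == "e4+").astype(float)
        n_params = len(TERMS)
        if y.size < n_params + 2:
            raise ValueError(f"too few observations after outlier removal (n={y.size})")
        z_age = _zscore(age)
        z_age2 = _zscore(z_age**2)
        X = np.column_stack(
            [np.ones_like(y), z_age, z_age2, grp, grp * z_age, grp * z_age2]
        )
        ols = sm.OLS(y, X).fit()
        bf01 = [
            bayes_factor_null(
                float(ols.tvalues[k]),
                n=y.size,
                df=float(ols.df_resid),
                prior_scale=self.bf_prior_scale,
                method=self.bf_method,
                seed=self.bf_seed,
            )
            for k in range(n_params)
        ]
        params = pd.DataFrame(
            {
                "estimate": ols.params,
                "se": ols.bse,
                "t": ols.tvalues,
                "p": ols.pvalues,
                "bf01": bf01,
            },
            index=list(TERMS),
        )
        fits = {}
        for label, sel in (("e3/e3", grp == 0), ("e4+", grp == 1)):
            A = np.column_stack([np.ones(sel.sum()), age[sel], age[sel] ** 2])
            b, *_ = np.linalg.lstsq(A, y[sel], rcond=None)
            fits[label] = b
        group_age_fits = pd.DataFrame(fits, index=["b0", "b1", "b2"]).T
        data = pd.DataFrame({"y": y, "age": age, "group": np.where(grp == 1, "e4+", "e3/e3")})
        return GenotypeAgeResults(
            params=params,
            adj_r2=float(ols.rsquared_adj),
            df_resid=float(ols.df_resid),
            n_obs=int(y.size),
            outlier_mask=mask,
            group_age_fits=group_age_fits,
            dependent=self.dependent,
            _data=data,
        )
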