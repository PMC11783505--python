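"""Boundary-locked activation and coactivation metrics.

Two per-subject dependent variables come out of this module. The univariate
boundary response of an ROI is the mean signal difference between transition
and within-event volumes (or, optionally, an HRF-convolved GLM beta). The
pairwise coactivation is the interaction coefficient of a logistic model
predicting the transition indicator from the two z-scored ROI signals and
their product — a PPI-style index of boundary-locked coupling change. The
group-mean coactivation matrix also drives ROI definition: parcels merge into
a super-region only if all their pairwise coactivations, and each parcel's
coactivation with the hippocampus, are positive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .events import BoundaryVector
from .timeseries import RoiTimeSeries

__all__ = [
    "PpiResult",
    "CoactivationMatrix",
    "boundary_univariate_response",
    "ppi_coactivation",
    "coactivation_matrix",
    "select_coactive_cluster",
    "merge_rois",
    "hrf_double_gamma",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def hrf_double_gamma(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR."""
    t = np.arange(0, duration_s, tr_s)
    peak = t**5 * np.exp(-t) / np.exp(gammaln(6))
    under = t**15 * np.exp(-t) / np.exp(gammaln(16))
    h = peak - under / 6.0
    return h / h.max()


def boundary_univariate_response(
    ts_roi: np.ndarray,
    bvec: BoundaryVector,
    estimator: str = "window_mean",
) -> float:
    """Per-ROI boundary activation.

    ``window_mean`` (default): mean signal over transition volumes minus mean
    over within-event volumes. ``hrf_glm``: OLS beta of the series on the
    transition indicator convolved with a canonical double-gamma HRF.
    """
    y = np.asarray(ts_roi, dtype=float).ravel()
    ind = bvec.indicator
    if y.size != ind.size:
        raise ValueError("series and boundary vector lengths differ")
    if ind.sum() == 0 or ind.sum() == ind.size:
        raise ValueError(
            "boundary vector is degenerate: both transition and within-event "
            "volumes are required"
        )
    if estimator == "window_mean":
        return float(y[ind == 1].mean() - y[ind == 0].mean())
    if estimator == "hrf_glm":
        reg = np.convolve(ind.astype(float), hrf_double_gamma(bvec.tr_s))[: y.size]
        X = np.column_stack([np.ones_like(y), reg])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(beta[1])
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass(frozen=True)
class PpiResult:
    """Interaction (coactivation) coefficient of one pairwise logistic fit."""

    beta: float
    se: float
    penalized: bool = False


def _logistic_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray, penalty: float) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) - y*eta, numerically stable
    nll = np.logaddexp(0.0, eta).sum() - y @ eta
    return nll + penalty * (beta[1:] @ beta[1:]) / 2.0


def ppi_coactivation(
    z1: np.ndarray,
    z2: np.ndarray,
    bvec: BoundaryVector,
    penalty: float = 1.0,
) -> PpiResult:
    """Boundary-locked coactivation between two ROI signals.

    Fits ``transition ~ 1 + z1 + z2 + z1*z2`` by maximum-likelihood logistic
    regression, with both signals z-scored before the product term, and
    returns the interaction coefficient. If the fit separates or fails to
    converge, the model is refit with a small L2 penalty (``penalty`` on the
    non-intercept coefficients, excluded from the reported SE) and the result
    is flagged ``penalized``.
    """
    x1 = _zscore(np.asarray(z1, dtype=float).ravel())
    x2 = _zscore(np.asarray(z2, dtype=float).ravel())
    y = bvec.indicator.astype(float)
    if x1.size != y.size or x2.size != y.size:
        raise ValueError("series and boundary vector lengths differ")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("boundary vector is degenerate (single class)")
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse).all():
            return PpiResult(float(fit.params[3]), float(fit.bse[3]), False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        pass
    # separation / non-convergence: ridge-penalized refit
    res = minimize(
        _logistic_nll,
        np.zeros(4),
        args=(X, y, penalty),
        method="BFGS",
    )
    if not np.isfinite(res.x).all():
        raise RuntimeError("penalized logistic refit did not converge")
    beta = res.x
    # SE from the unpenalized observed information at the penalized estimate
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    info = (X * (p * (1 - p))[:, None]).T @ X
    cov = np.linalg.pinv(info)
    return PpiResult(float(beta[3]), float(np.sqrt(cov[3, 3])), True)


@dataclass
class CoactivationMatrix:
    """ROI x ROI symmetric matrix of PPI interaction betas (diagonal NaN)."""

    betas: pd.DataFrame
    subject_id: str | None = None
    penalized_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def roi_labels(self) -> list[str]:
        return [str(c) for c in self.betas.columns]

    def to_csv(self, path) -> None:
        self.betas.to_csv(path, index_label="roi")

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None) -> "CoactivationMatrix":
        return cls(pd.read_csv(path, index_col="roi"), subject_id)


def coactivation_matrix(ts: RoiTimeSeries, bvec: BoundaryVector) -> CoactivationMatrix:
    """All-pairs boundary coactivation; each unordered pair fit once."""
    labels = ts.roi_labels
    if len(labels) < 2:
        raise ValueError("coactivation needs >= 2 ROIs")
    X = ts.values
    mat = np.full((len(labels), len(labels)), np.nan)
    flagged: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        try:
            res = ppi_coactivation(X[:, i], X[:, j], bvec)
        except Exception as err:  # propagate with pair context
            raise RuntimeError(
                f"coactivation fit failed for pair ({labels[i]}, {labels[j]}): {err}"
            ) from err
        mat[i, j] = mat[j, i] = res.beta
        if res.penalized:
            flagged.append((labels[i], labels[j]))
    df = pd.DataFrame(mat, index=labels, columns=labels)
    return CoactivationMatrix(df, ts.subject_id, tuple(flagged))


def select_coactive_cluster(
    group_mean: pd.DataFrame,
    candidates: list[str],
    hippocampus: str,
) -> list[str]:
    """Largest all-positive coactivation subset of candidate parcels.

    Returns the maximal subset of ``candidates`` whose group-mean pairwise
    coactivations are all positive among each other and whose coactivation
    with the ``hippocampus`` label is positive. Exhaustive enumeration for up
    to 20 candidates; ties on size break toward the larger coactivation sum.
    Empty result (with a warning) when no parcel qualifies.
    """
    if not candidates:
        return []
    if len(candidates) > 20:
        raise ValueError("exhaustive subset search supports at most 20 candidates")
    M = group_mean
    ok = [c for c in candidates if M.loc[c, hippocampus] > 0]
    best: list[str] = []
    best_score = -np.inf
    for r in range(1, len(ok) + 1):
        for subset in itertools.combinations(ok, r):
            pairs = list(itertools.combinations(subset, 2))
            if all(M.loc[a, b] > 0 for a, b in pairs):
                score = sum(M.loc[a, b] for a, b in pairs) + sum(
                    M.loc[c, hippocampus] for c in subset
                )
                if r > len(best) or (r == len(best) and score > best_score):
                    best = list(subset)
                    best_score = score
    if not best:
        warnings.warn("no all-positive coactive subset found", stacklevel=2)
    return best


def merge_rois(ts: RoiTimeSeries, groups: dict[str, list[str]]) -> RoiTimeSeries:
    """Average member parcels into named super-region series, per volume."""
    missing = {m for members in groups.values() for m in members} - set(ts.roi_labels)
    if missing:
        raise ValueError(f"unknown ROI labels: {sorted(missing)}")
    merged = {
        name: ts.data[members].mean(axis=1) for name, members in groups.items()
    }
    return RoiTimeSeries(pd.DataFrame(merged), ts.tr_s, ts.subject_id)
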