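"""Confound regression, high-pass filtering, and prewhitening of ROI signals.

The nuisance model holds 32 columns: 8 base series (6 motion parameters plus
mean white-matter and CSF signals), their temporal derivatives, their squares
and the squared derivatives. High-pass filtering (0.008 Hz by default) enters
the same GLM as a discrete-cosine basis so that filtering and nuisance
regression happen simultaneously. Residual autocorrelation is modelled as a
white-noise component plus a nonnegative mixture of eight exponentials with
half-lives 0.5, 1, 2, ..., 64 TRs, and removed with the innovations
(inverse-Cholesky) filter of the implied stationary covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .timeseries import RoiTimeSeries

__all__ = [
    "ConfoundMatrix",
    "WhiteningModel",
    "HALF_LIVES_TR",
    "build_confound_matrix",
    "dct_basis",
    "clean_timeseries",
    "fit_autocorrelation_model",
    "whiten",
]

#: Exponential autocorrelation half-life grid, in TRs (0.5 doubling to 64).
HALF_LIVES_TR: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)

_BASE_LABELS = ("mot1", "mot2", "mot3", "mot4", "mot5", "mot6", "wm", "csf")


@dataclass
class ConfoundMatrix:
    """volumes x 32 nuisance design (base | derivatives | squares | sq. derivs)."""

    design: np.ndarray
    column_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2 or self.design.shape[1] != 32:
            raise ValueError(
                f"confound design must have 32 columns, got shape {self.design.shape}"
            )

    @property
    def n_vols(self) -> int:
        return self.design.shape[0]


def _backward_diff(x: np.ndarray) -> np.ndarray:
    # SPM-style backward difference, leading element zero
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = x[1:] - x[:-1]
    return d


def build_confound_matrix(motion: np.ndarray, wm: np.ndarray, csf: np.ndarray) -> ConfoundMatrix:
    """Expand 6 motion + WM + CSF series into the 32-column nuisance design.

    Parameters
    ----------
    motion : (n_vols, 6) array
        Rigid-body realignment parameters.
    wm, csf : (n_vols,) arrays
        Mean white-matter and cerebrospinal-fluid signals.
    """
    motion = np.asarray(motion, dtype=float)
    wm = np.asarray(wm, dtype=float).ravel()
    csf = np.asarray(csf, dtype=float).ravel()
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_vols, 6), got {motion.shape}")
    n = motion.shape[0]
    if n < 3 or wm.size != n or csf.size != n:
        raise ValueError("motion, wm and csf must share a length >= 3")
    base = np.column_stack([motion, wm, csf])
    deriv = np.apply_along_axis(_backward_diff, 0, base)
    design = np.column_stack([base, deriv, base**2, deriv**2])
    labels = (
        *(f"{b}" for b in _BASE_LABELS),
        *(f"{b}_deriv" for b in _BASE_LABELS),
        *(f"{b}_sq" for b in _BASE_LABELS),
        *(f"{b}_deriv_sq" for b in _BASE_LABELS),
    )
    return ConfoundMatrix(design, labels)


def dct_basis(n_vols: int, tr_s: float, cutoff_hz: float = 0.008) -> np.ndarray:
    """Discrete-cosine high-pass basis for inclusion in the cleaning GLM.

    Column ``k`` (k = 1..K) is ``cos(pi * k * (2t + 1) / (2 * n_vols))`` with
    frequency ``k / (2 * n_vols * tr_s)`` Hz; ``K = floor(2 * n_vols * tr_s *
    cutoff_hz)`` keeps every drift frequency up to the cutoff. Columns are
    unit-normalized and mutually orthogonal; the constant is excluded (the
    GLM carries its own intercept).
    """
    if cutoff_hz < 0:
        raise ValueError("cutoff_hz must be >= 0")
    n_k = int(np.floor(2 * n_vols * tr_s * cutoff_hz))
    t = np.arange(n_vols)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_vols)) for k in range(1, n_k + 1)]
    if not cols:
        return np.empty((n_vols, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def _design(n_vols: int, confounds: ConfoundMatrix | None, dct: np.ndarray | None) -> np.ndarray:
    parts = [np.ones((n_vols, 1))]
    if confounds is not None:
        if confounds.n_vols != n_vols:
            raise ValueError("confound row count does not match the time series")
        parts.append(confounds.design)
    if dct is not None and dct.size:
        if dct.shape[0] != n_vols:
            raise ValueError("DCT basis row count does not match the time series")
        parts.append(dct)
    return np.column_stack(parts)


def clean_timeseries(
    ts: RoiTimeSeries,
    confounds: ConfoundMatrix | None = None,
    dct: np.ndarray | None = None,
) -> RoiTimeSeries:
    """Residualize every ROI against [intercept | confounds | DCT] at once.

    Returns the least-squares residual series; residuals are orthogonal to
    every regressor. A rank-deficient design (collinear confounds) falls back
    to the minimum-norm solution with a warning — the residual is unaffected.
    """
    X = _design(ts.n_vols, confounds, dct)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "nuisance design is rank-deficient; collinear columns are redundant",
            stacklevel=2,
        )
    Y = ts.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return ts.with_values(Y - X @ beta)


@dataclass
class WhiteningModel:
    """White-noise + eight-exponential autocovariance model of the GLM error.

    ``acov(lag) = residual_variance * [lag == 0] + sum_h weights[h] * 0.5**(lag / h)``
    with ``h`` over :data:`HALF_LIVES_TR` (lags in TRs).
    """

    half_lives_tr: tuple[float, ...]
    weights: np.ndarray
    residual_variance: float
    max_lag: int = 128

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any() or self.residual_variance < 0:
            raise ValueError("mixture weights and residual variance must be >= 0")
        if len(self.half_lives_tr) != self.weights.size:
            raise ValueError("one weight per half-life required")

    def autocovariance(self, lags: np.ndarray) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        h = np.asarray(self.half_lives_tr)
        acov = (0.5 ** (lags[:, None] / h[None, :])) @ self.weights
        return acov + self.residual_variance * (lags == 0)


def _exp_basis(lags: np.ndarray) -> np.ndarray:
    """Columns: 8 exponential decays then the white-noise delta."""
    h = np.asarray(HALF_LIVES_TR)
    basis = 0.5 ** (lags[:, None] / h[None, :])
    return np.column_stack([basis, (lags == 0).astype(float)])


def fit_autocorrelation_model(
    residuals: RoiTimeSeries, max_lag: int = 128, per_roi: bool = False
) -> WhiteningModel | list[WhiteningModel]:
    """Fit the exponential-mixture error model to GLM residuals.

    The empirical autocovariance (lags 0..min(n_vols - 1, max_lag), biased
    estimator) is averaged over ROIs — one pooled model per subject — and
    regressed onto the exponential basis plus a white-noise component by
    nonnegative least squares. Set ``per_roi=True`` for one model per ROI.
    """
    if residuals.n_vols < 64:
        raise ValueError("autocorrelation fitting needs >= 64 volumes")
    Y = residuals.values
    if not np.isfinite(Y).all():
        raise ValueError("residuals contain non-finite values")
    n = residuals.n_vols
    p = min(n - 1, max_lag)
    lags = np.arange(p + 1)
    Yc = Y - Y.mean(axis=0)

    def _fit(acov: np.ndarray) -> WhiteningModel:
        coef, _ = nnls(_exp_basis(lags), acov)
        return WhiteningModel(HALF_LIVES_TR, coef[:-1], float(coef[-1]), max_lag=p)

    acovs = np.empty((Yc.shape[1], p + 1))
    for j in range(Yc.shape[1]):
        x = Yc[:, j]
        acovs[j] = [x[: n - k] @ x[k:] / n for k in lags]
    if per_roi:
        return [_fit(acovs[j]) for j in range(acovs.shape[0])]
    return _fit(acovs.mean(axis=0))


def _levinson_staircase(acov: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Levinson–Durbin: AR coefficients and innovation variances, orders 0..p."""
    p = acov.size - 1
    coefs: list[np.ndarray] = [np.empty(0)]
    v = np.empty(p + 1)
    v[0] = acov[0]
    a = np.empty(0)
    for m in range(1, p + 1):
        k = (acov[m] - (a @ acov[m - 1 : 0 : -1] if m > 1 else 0.0)) / v[m - 1]
        a_new = np.empty(m)
        a_new[-1] = k
        if m > 1:
            a_new[:-1] = a - k * a[::-1]
        v[m] = v[m - 1] * (1 - k * k)
        if v[m] <= 0:
            raise np.linalg.LinAlgError("autocovariance model is not positive definite")
        coefs.append(a_new)
        a = a_new
    return coefs, v


def whiten(
    residuals: RoiTimeSeries,
    model: WhiteningModel,
    ridge: float = 1e-6,
) -> RoiTimeSeries:
    """Remove modelled autocorrelation via the innovations filter.

    The model autocovariance is evaluated at lags 0..max_lag, ridge-regularized
    at lag 0 (``ridge * acov(0)``), and factored by the Levinson–Durbin
    recursion. The output at volume ``t`` is the normalized one-step prediction
    error using the order-``min(t, max_lag)`` predictor — exactly
    ``L^{-1} x`` for the Cholesky factor ``L`` of the implied covariance, so
    the transform is invertible and preserves length.
    """
    n = residuals.n_vols
    p = min(n - 1, model.max_lag)
    acov = model.autocovariance(np.arange(p + 1))
    acov = acov / acov[0] if acov[0] > 0 else acov  # work in correlation units
    acov[0] += ridge
    coefs, v = _levinson_staircase(acov)
    X = residuals.values
    out = np.empty_like(X)
    # staircase head: growing-order predictors
    for t in range(min(p, n)):
        a = coefs[t]
        pred = a @ X[t - 1 :: -1][: t] if t else 0.0
        out[t] = (X[t] - pred) / np.sqrt(v[t])
    if n > p:
        # steady state: order-p predictor, vectorized over t
        a = coefs[p][::-1]  # align oldest..newest
        windows = np.lib.stride_tricks.sliding_window_view(X, p + 1, axis=0)
        # windows: (n - p, n_rois, p + 1); predict last element from first p
        pred = windows[..., :-1] @ a
        out[p:] = (windows[..., -1] - pred) / np.sqrt(v[p])
    return residuals.with_values(out)
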