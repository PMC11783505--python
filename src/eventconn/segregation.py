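"""Whole-scan connectivity and functional system segregation (SyS).

System segregation summarizes how much more strongly regions correlate with
their own network than with other networks:

    SyS = (mean within-network r - mean between-network r) / mean within-network r

computed on whole-scan Pearson correlations after global signal regression
(removing the mean-over-ROIs series from every ROI to absorb vascular
effects). Raw correlations are averaged by default; Fisher-z averaging and
clipping of negative correlations are exposed as toggles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeries

__all__ = [
    "SegregationResult",
    "global_signal_regress",
    "connectivity_matrix",
    "system_segregation",
]


@dataclass(frozen=True)
class SegregationResult:
    mean_within: float
    mean_between: float
    sys: float
    partition_id: str = ""
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "mean_within": self.mean_within,
            "mean_between": self.mean_between,
            "sys": self.sys,
            "partition_id": self.partition_id,
            "defined": self.defined,
        }


def global_signal_regress(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Residualize every ROI against [1, mean-over-ROIs series]."""
    Y = ts.values
    g = Y.mean(axis=1)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return ts.with_values(Y - X @ beta)


def connectivity_matrix(ts: RoiTimeSeries) -> pd.DataFrame:
    """Whole-scan Pearson correlation matrix (unit diagonal, symmetric)."""
    if ts.n_vols < 3:
        raise ValueError("connectivity needs >= 3 volumes")
    Y = ts.values
    sd = Y.std(axis=0)
    if (sd == 0).any():
        flat = [ts.roi_labels[i] for i in np.where(sd == 0)[0]]
        warnings.warn(f"zero-variance ROI(s) {flat}: correlations undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=ts.roi_labels, columns=ts.roi_labels)


def system_segregation(
    conn: pd.DataFrame,
    partition: dict[str, str] | pd.Series,
    partition_id: str = "",
    fisher_z: bool = False,
    clip_negative: bool = False,
) -> SegregationResult:
    """SyS from a correlation matrix and an ROI -> network partition.

    ``mean_within`` averages off-diagonal correlations over same-network ROI
    pairs (each unordered pair once), ``mean_between`` over cross-network
    pairs. When ``mean_within <= 0`` the ratio is undefined and the result is
    flagged. Needs >= 2 networks, each contributing >= 2 ROIs.
    """
    part = pd.Series(partition)
    rois = [r for r in conn.index if r in part.index]
    nets = part.loc[rois]
    counts = nets.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 networks with >= 2 ROIs each")
    M = conn.loc[rois, rois].to_numpy(dtype=float).copy()
    if clip_negative:
        M = np.clip(M, 0.0, None)
    if fisher_z:
        with np.errstate(divide="ignore"):
            M = np.arctanh(np.clip(M, -1 + 1e-12, 1 - 1e-12))
    same = nets.to_numpy()[:, None] == nets.to_numpy()[None, :]
    iu = np.triu_indices(len(rois), k=1)
    within_vals = M[iu][same[iu]]
    between_vals = M[iu][~same[iu]]
    mean_within = float(np.nanmean(within_vals))
    mean_between = float(np.nanmean(between_vals))
    if fisher_z:
        mean_within = float(np.tanh(mean_within))
        mean_between = float(np.tanh(mean_between))
    if mean_within <= 0:
        warnings.warn("mean within-network connectivity <= 0; SyS undefined", stacklevel=2)
        return SegregationResult(mean_within, mean_between, np.nan, partition_id, False)
    sys_val = (mean_within - mean_between) / mean_within
    return SegregationResult(mean_within, mean_between, float(sys_val), partition_id, True)
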