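"""ROI time-series container shared by every pipeline stage.

A scan is a volumes x ROIs table sampled every ``tr_s`` seconds. Volume ``i``
is acquired at time ``i * tr_s`` (0-based). All stages consume and return
:class:`RoiTimeSeries`, so cleaning, whitening and metric extraction compose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RoiTimeSeries"]


@dataclass
class RoiTimeSeries:
    """BOLD signal averaged within regions of interest.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are volumes (0-based index), columns are ROI labels.
    tr_s : float
        Repetition time in seconds (sampling interval of the rows).
    subject_id : str, optional
        Carried through the pipeline for bookkeeping.
    """

    data: pd.DataFrame
    tr_s: float
    subject_id: str | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(np.asarray(self.data, dtype=float))
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_vols(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def roi_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def duration_s(self) -> float:
        """Total scan duration in seconds (n_vols * TR)."""
        return self.n_vols * self.tr_s

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "RoiTimeSeries":
        """Return a copy carrying new values but the same labels/metadata."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.data.shape:
            raise ValueError(
                f"shape {values.shape} does not match {self.data.shape}"
            )
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return RoiTimeSeries(df, self.tr_s, self.subject_id)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="volume")

    @classmethod
    def from_csv(cls, path, tr_s: float, subject_id: str | None = None) -> "RoiTimeSeries":
        df = pd.read_csv(path, index_col="volume")
        return cls(df, tr_s, subject_id)
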