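"""Event-boundary handling: observer consensus and transition vectors.

A continuous movie is segmented by human observers who press a key whenever
they feel one meaningful event has ended and another begun. Boundaries kept
for analysis are those marked consistently by at least a fixed proportion of
observers (50% of 16 in the emulated design). Each consensus onset is then
expanded into a *transition window* of +/- ``window_tr`` TRs around the
onset, shifted forward by ``lag_tr`` TRs (~5 s at TR = 2.47 s) to account for
hemodynamic lag, and binarized per volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationSet",
    "BoundarySet",
    "BoundaryVector",
    "consensus_boundaries",
    "transition_window",
    "build_transition_vector",
]


@dataclass
class AnnotationSet:
    """Observer key-press records: one row per (observer_id, onset_s)."""

    records: pd.DataFrame
    n_observers: int

    def __post_init__(self) -> None:
        req = {"observer_id", "onset_s"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"annotation records need columns {sorted(req)}")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if len(self.records) and (self.records["onset_s"] < 0).any():
            raise ValueError("annotation onsets must be >= 0")

    def to_csv(self, path) -> None:
        self.records[["observer_id", "onset_s"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_observers: int | None = None) -> "AnnotationSet":
        df = pd.read_csv(path)
        if n_observers is None:
            n_observers = df["observer_id"].nunique()
        return cls(df, n_observers)


@dataclass(frozen=True)
class BoundarySet:
    """Sorted consensus event-boundary onsets in seconds."""

    onsets_s: tuple[float, ...]

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets_s)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("boundary onsets must be strictly increasing")
        if onsets and onsets[0] < 0:
            raise ValueError("boundary onsets must be >= 0")
        object.__setattr__(self, "onsets_s", onsets)

    def __len__(self) -> int:
        return len(self.onsets_s)

    def to_csv(self, path) -> None:
        pd.DataFrame({"onset_s": list(self.onsets_s)}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BoundarySet":
        return cls(tuple(pd.read_csv(path)["onset_s"].tolist()))


@dataclass
class BoundaryVector:
    """Per-volume 0/1 indicator of event-transition periods."""

    indicator: np.ndarray
    tr_s: float
    window_tr: int = 2
    lag_tr: int = 2

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator values must be 0 or 1")
        self.indicator = ind.astype(int)

    @property
    def n_vols(self) -> int:
        return self.indicator.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"volume": np.arange(self.n_vols), "transition": self.indicator}
        ).to_csv(path, index=False)


def _cluster_sorted(onsets: np.ndarray, tol: float) -> list[slice]:
    """Single-linkage chains over sorted onsets: split where gap > tol."""
    if onsets.size == 0:
        return []
    breaks = np.where(np.diff(onsets) > tol)[0] + 1
    edges = [0, *breaks.tolist(), onsets.size]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def consensus_boundaries(
    annotations: AnnotationSet,
    threshold: float = 0.5,
    merge_tolerance_s: float = 2.47,
) -> BoundarySet:
    """Reduce observer annotations to consensus boundary onsets.

    Annotation onsets are grouped by single-linkage clustering (successive
    onsets within ``merge_tolerance_s`` chain into one candidate). A candidate
    survives if distinct observers contributing to it number at least
    ``ceil(threshold * n_observers)`` — e.g. 8 of 16 at the default 50% —
    and is reported as the mean onset of its cluster.

    Parameters
    ----------
    annotations : AnnotationSet
    threshold : float
        Required proportion of observers, in (0, 1].
    merge_tolerance_s : float
        Single-linkage gap tolerance in seconds (default one TR of the
        emulated design).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rec = annotations.records
    if rec.empty:
        return BoundarySet(())
    order = rec.sort_values("onset_s", kind="stable")
    onsets = order["onset_s"].to_numpy(dtype=float)
    observers = order["observer_id"].to_numpy()
    need = math.ceil(threshold * annotations.n_observers)
    kept: list[float] = []
    for sl in _cluster_sorted(onsets, merge_tolerance_s):
        if len(set(observers[sl].tolist())) >= need:
            kept.append(float(onsets[sl].mean()))
    return BoundarySet(tuple(sorted(kept)))


def transition_window(
    onset_s: float, tr_s: float, window_tr: int = 2
) -> tuple[float, float]:
    """Pre-shift transition window ``[onset - w*TR, onset + w*TR]`` in seconds.

    For an onset 30 s into a TR = 2.47 s scan with the default 2-TR half
    width this is (25.06, 34.94).
    """
    half = window_tr * tr_s
    return (onset_s - half, onset_s + half)


def build_transition_vector(
    boundaries: BoundarySet,
    tr_s: float,
    n_vols: int,
    window_tr: int = 2,
    lag_tr: int = 2,
) -> BoundaryVector:
    """Binarize boundary onsets into a per-volume transition indicator.

    For each onset the pre-shift window from :func:`transition_window` is
    shifted forward by ``lag_tr * tr_s`` (hemodynamic lag) and volume ``i``
    is marked 1 iff its onset time ``i * tr_s`` falls in the half-open
    applied window ``[start, end)``. Windows are clipped to the scan and
    overlapping windows are unioned.
    """
    if tr_s <= 0 or n_vols <= 0:
        raise ValueError("tr_s and n_vols must be positive")
    duration = n_vols * tr_s
    indicator = np.zeros(n_vols, dtype=int)
    times = np.arange(n_vols) * tr_s
    shift = lag_tr * tr_s
    for onset in boundaries.onsets_s:
        if not 0 <= onset < duration:
            raise ValueError(
                f"boundary onset {onset} s lies outside the scan [0, {duration}) s"
            )
        lo, hi = transition_window(onset, tr_s, window_tr)
        indicator[(times >= lo + shift) & (times < hi + shift)] = 1
    return BoundaryVector(indicator, tr_s, window_tr, lag_tr)
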