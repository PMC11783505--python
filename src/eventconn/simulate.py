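"""Synthetic cohort, annotation and ROI time-series generator.

Emulates the statistical structure of a movie-watching fMRI study in a
population-based adult-lifespan cohort: ~425 analysed subjects aged 18-88
genotyped for APOE (e4+ vs e3/e3, with a small e2-carrier fraction that the
analysis excludes), a TR = 2.47 s scan of 193 volumes, 12 consensus event
boundaries annotated by 16 observers, boundary-locked univariate responses
and coactivation increases, age-related decline, motion/WM/CSF confound
leakage, and AR(1) temporal noise. Defaults reproduce those design facts;
effect sizes are free parameters (a configurable genotype effect defaults to
zero, matching the null structure the analysis is designed to detect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .events import AnnotationSet, BoundarySet, build_transition_vector
from .timeseries import RoiTimeSeries

__all__ = ["SimConfig", "generate_cohort", "generate_observer_annotations",
           "generate_roi_timeseries", "simulate_dataset"]

#: Genotype frequencies among the genotyped pool (425 analysed of 499:
#: 291 e3/e3, 126 e3/e4, 8 e4/e4, remainder e2 carriers).
DEFAULT_GENOTYPE_FREQS = {
    "e3/e3": 291 / 499,
    "e3/e4": 126 / 499,
    "e4/e4": 8 / 499,
    "e2_carrier": 74 / 499,
}

#: Twelve consensus boundaries spread over the ~8-min scan (seconds).
DEFAULT_BOUNDARY_ONSETS = tuple(
    float(t) for t in np.linspace(30.0, 450.0, 12).round(2)
)

DEFAULT_ROI_LABELS = ("hippocampus", "left_ag", "right_ag", "pmc")


@dataclass
class SimConfig:
    """Study-design and effect parameters for the generator.

    Effect units: ``boundary_amplitude`` and ``genotype_effect`` are in
    signal units (noise SD = ``noise_sd``); age slopes are signal units per
    SD of age (applied to the boundary amplitude); correlations are
    instantaneous between-ROI noise correlations.
    """

    n_subjects: int = 425
    age_range: tuple[float, float] = (18.0, 88.0)
    genotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQS)
    )
    n_vols: int = 193
    tr_s: float = 2.47
    n_rois: int = len(DEFAULT_ROI_LABELS)
    roi_labels: tuple[str, ...] = DEFAULT_ROI_LABELS
    boundary_onsets_s: tuple[float, ...] = DEFAULT_BOUNDARY_ONSETS
    boundary_amplitude: float = 0.5
    boundary_coact_rho: float = 0.3
    baseline_rho: float = 0.1
    age_slope_linear: float = -0.1
    age_slope_quadratic: float = -0.05
    genotype_effect: float = 0.0
    noise_ar1: float = 0.3
    noise_sd: float = 1.0
    confound_weight: float = 0.3
    window_tr: int = 2
    lag_tr: int = 2
    hrf_convolve: bool = False
    network_partition: dict[str, str] = field(default_factory=dict)
    within_rho_gap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        total = sum(self.genotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype_freqs sum to {total}, not 1")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")
        duration = self.n_vols * self.tr_s
        bad = [t for t in self.boundary_onsets_s if not 0 <= t < duration]
        if bad:
            raise ValueError(f"boundary onsets outside [0, {duration}): {bad}")
        if self.n_rois != len(self.roi_labels):
            self.roi_labels = tuple(f"roi{i:02d}" for i in range(self.n_rois))

    @property
    def duration_s(self) -> float:
        return self.n_vols * self.tr_s


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a cohort table: subject_id, age, genotype, included, seed.

    Ages are uniform over ``age_range``; genotypes are drawn i.i.d. from
    ``genotype_freqs``. Each subject gets a child seed for reproducible
    standalone time-series generation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    genos = list(config.genotype_freqs)
    probs = np.array([config.genotype_freqs[g] for g in genos])
    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": rng.uniform(*config.age_range, size=n),
            "genotype": rng.choice(genos, size=n, p=probs),
            "included": True,
            "seed": rng.integers(0, 2**31 - 1, size=n),
        }
    )
    return cohort


def generate_observer_annotations(
    true_onsets,
    n_observers: int = 16,
    miss_rate: float = 0.1,
    jitter_sd: float = 1.0,
    seed: int = 0,
    duration_s: float = 193 * 2.47,
) -> AnnotationSet:
    """Simulate observer key presses around true boundary onsets.

    Each of ``n_observers`` marks each true onset with probability
    ``1 - miss_rate``, at a time jittered by N(0, jitter_sd^2) and clipped to
    ``[0, duration_s]``.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for obs in range(n_observers):
        for t in true_onsets:
            if rng.random() < miss_rate:
                continue
            onset = t + jitter_sd * rng.standard_normal()
            rows.append((f"obs-{obs + 1:02d}", float(np.clip(onset, 0.0, duration_s))))
    records = pd.DataFrame(rows, columns=["observer_id", "onset_s"])
    return AnnotationSet(records, n_observers)


def _confound_sources(rng: np.random.Generator, n_vols: int) -> np.ndarray:
    """6 motion + WM + CSF series as smoothed, standardized random walks."""
    walks = rng.standard_normal((n_vols, 8)).cumsum(axis=0)
    smooth = uniform_filter1d(walks, size=5, axis=0, mode="nearest")
    smooth = smooth - smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    return smooth / sd


def _corr_chol(config: SimConfig, rho: float) -> np.ndarray:
    """Cholesky factor of the between-ROI noise correlation at level ``rho``.

    Same-network ROI pairs (per ``network_partition``) get ``rho +
    within_rho_gap``, giving the noise a modular block structure when the
    gap is positive.
    """
    n = config.n_rois
    C = np.full((n, n), rho, dtype=float)
    if config.network_partition and config.within_rho_gap:
        nets = np.array(
            [config.network_partition.get(lbl) for lbl in config.roi_labels],
            dtype=object,
        )
        same = (nets[:, None] == nets[None, :]) & (nets[:, None] != None)  # noqa: E711
        C[same] += config.within_rho_gap
    np.fill_diagonal(C, 1.0)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "noise correlation settings do not form a positive-definite matrix"
        ) from err


def generate_roi_timeseries(
    subject: pd.Series,
    config: SimConfig,
    boundaries: BoundarySet | None = None,
) -> tuple[RoiTimeSeries, pd.DataFrame]:
    """One subject's ROI series plus its motion/WM/CSF confound sources.

    Signal model per ROI: a boundary-locked boxcar over the lag-shifted
    transition window with subject amplitude

        boundary_amplitude + age_slope_linear * z_age
        + age_slope_quadratic * z_age^2 + genotype_effect * [e4 carrier]

    (z_age standardizes age over the configured uniform range), plus
    correlated AR(1) noise whose instantaneous between-ROI correlation is
    ``boundary_coact_rho`` inside transition windows and ``baseline_rho``
    elsewhere, plus small random linear combinations of the confound series
    (weights uniform within +/- ``confound_weight * noise_sd``). With
    ``hrf_convolve`` the boxcar is convolved with a canonical double-gamma
    HRF instead.
    """
    if boundaries is None:
        boundaries = BoundarySet(config.boundary_onsets_s)
    bvec = build_transition_vector(
        boundaries, config.tr_s, config.n_vols, config.window_tr, config.lag_tr
    )
    rng = np.random.default_rng(int(subject["seed"]))
    n, r = config.n_vols, config.n_rois

    lo, hi = config.age_range
    # uniform(lo, hi) has SD (hi - lo) / sqrt(12)
    z_age = (subject["age"] - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))
    is_e4 = str(subject["genotype"]) in ("e3/e4", "e4/e3", "e4/e4")
    amplitude = (
        config.boundary_amplitude
        + config.age_slope_linear * z_age
        + config.age_slope_quadratic * z_age**2
        + (config.genotype_effect if is_e4 else 0.0)
    )
    stim = bvec.indicator.astype(float)
    if config.hrf_convolve:
        from .boundary import hrf_double_gamma

        stim = np.convolve(stim, hrf_double_gamma(config.tr_s))[:n]
    signal = amplitude * stim[:, None] * np.ones((1, r))

    # state-dependent instantaneous correlation, AR(1) temporal filtering
    chol_base = _corr_chol(config, config.baseline_rho)
    chol_bound = _corr_chol(config, config.boundary_coact_rho)
    innov = rng.standard_normal((n, r))
    e = np.where(
        (bvec.indicator == 1)[:, None], innov @ chol_bound.T, innov @ chol_base.T
    )
    phi = config.noise_ar1
    noise = np.empty_like(e)
    scale = np.sqrt(1 - phi**2)
    noise[0] = e[0]
    for t in range(1, n):
        noise[t] = phi * noise[t - 1] + scale * e[t]
    signal = signal + config.noise_sd * noise

    sources = _confound_sources(rng, n)
    weights = rng.uniform(-1.0, 1.0, size=(8, r)) * config.confound_weight * config.noise_sd
    signal = signal + sources @ weights

    ts = RoiTimeSeries(
        pd.DataFrame(signal, columns=list(config.roi_labels)),
        config.tr_s,
        str(subject["subject_id"]),
    )
    confounds = pd.DataFrame(
        sources,
        columns=["mot1", "mot2", "mot3", "mot4", "mot5", "mot6", "wm", "csf"],
    )
    return ts, confounds


def simulate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, AnnotationSet, dict[str, tuple[RoiTimeSeries, pd.DataFrame]]]:
    """Cohort + observer annotations + per-subject (series, confounds)."""
    cohort = generate_cohort(config)
    annotations = generate_observer_annotations(
        config.boundary_onsets_s,
        seed=config.seed + 1,
        duration_s=config.duration_s,
    )
    boundaries = BoundarySet(config.boundary_onsets_s)
    data = {
        row["subject_id"]: generate_roi_timeseries(row, config, boundaries)
        for _, row in cohort.iterrows()
    }
    return cohort, annotations, data
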