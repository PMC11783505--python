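"""End-to-end orchestration: simulate -> clean/whiten -> boundaries ->
metrics -> genotype statistics / classification / segregation.

A :class:`RunConfig` captures every stage parameter and seed; a fixed config
yields byte-identical output tables. The report table mirrors the shape of a
genotype-association results table: one row per dependent variable x model
term with estimate, SE, t, p, BF01, adjusted R2 and residual df.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary, classify, events, genostats, nuisance, segregation
from .simulate import SimConfig, simulate_dataset
from .timeseries import RoiTimeSeries

__all__ = ["RunConfig", "run_pipeline", "write_report", "read_report", "REPORT_COLUMNS"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "dependent_variable",
    "term",
    "estimate",
    "se",
    "t",
    "p",
    "bf01",
    "adj_r2",
    "df",
)

ALL_STAGES = (
    "simulate",
    "preprocess",
    "boundaries",
    "metrics",
    "genostats",
    "classify",
    "segregate",
)


@dataclass
class RunConfig:
    """Every knob of a pipeline run, serializable to/from YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    window_tr: int = 2
    lag_tr: int = 2
    consensus_threshold: float = 0.5
    merge_tolerance_s: float = 2.47
    cutoff_hz: float = 0.008
    whiten_max_lag: int = 128
    k_folds: int = 5
    n_perm: int = 5000
    bf_method: str = "jzs"
    bf_prior_scale: float = float(np.sqrt(2) / 2)
    partition: dict[str, str] = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["roi_labels"] = list(d["sim"]["roi_labels"])
        d["sim"]["boundary_onsets_s"] = list(d["sim"]["boundary_onsets_s"])
        d["sim"]["age_range"] = list(d["sim"]["age_range"])
        d["stages"] = list(d["stages"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        for key in ("roi_labels", "boundary_onsets_s", "age_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _default_partition(roi_labels: list[str]) -> dict[str, str]:
    """Even two-way split; empty (stage skipped) below 4 ROIs."""
    if len(roi_labels) < 4:
        return {}
    half = len(roi_labels) // 2
    return {
        r: ("netA" if i < half else "netB") for i, r in enumerate(roi_labels)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return (and optionally write) all outputs."""
    results: dict = {"config_hash": config.config_hash()}
    logger.info("pipeline start (config %s)", results["config_hash"])
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    stage = "simulate"
    try:
        if "simulate" not in config.stages:
            return results
        cohort, annotations, data = simulate_dataset(config.sim)
        results["cohort"] = cohort
        results["annotations"] = annotations

        stage = "boundaries"
        if "boundaries" in config.stages:
            bset = events.consensus_boundaries(
                annotations, config.consensus_threshold, config.merge_tolerance_s
            )
        else:
            bset = events.BoundarySet(config.sim.boundary_onsets_s)
        bvec = events.build_transition_vector(
            bset, config.sim.tr_s, config.sim.n_vols, config.window_tr, config.lag_tr
        )
        results["boundaries"] = bset
        results["boundary_vector"] = bvec

        stage = "preprocess"
        cleaned: dict[str, RoiTimeSeries] = {}
        for sid, (ts, conf_df) in data.items():
            if "preprocess" in config.stages:
                cm = nuisance.build_confound_matrix(
                    conf_df[[f"mot{i}" for i in range(1, 7)]].to_numpy(),
                    conf_df["wm"].to_numpy(),
                    conf_df["csf"].to_numpy(),
                )
                dct = nuisance.dct_basis(ts.n_vols, ts.tr_s, config.cutoff_hz)
                resid = nuisance.clean_timeseries(ts, cm, dct)
                model = nuisance.fit_autocorrelation_model(
                    resid, max_lag=config.whiten_max_lag
                )
                cleaned[sid] = nuisance.whiten(resid, model)
            else:
                cleaned[sid] = ts
        results["cleaned"] = cleaned

        stage = "metrics"
        grouped = genostats.group_genotypes(cohort).set_index("subject_id")
        analysed = [sid for sid in cleaned if sid in grouped.index]
        if "metrics" in config.stages:
            uni = pd.DataFrame(
                {
                    sid: [
                        boundary.boundary_univariate_response(
                            cleaned[sid].values[:, j], bvec
                        )
                        for j in range(cleaned[sid].n_rois)
                    ]
                    for sid in analysed
                },
                index=list(config.sim.roi_labels),
            ).T
            mats = [boundary.coactivation_matrix(cleaned[sid], bvec) for sid in analysed]
            feats = classify.vectorize_coactivation(mats)
            results["univariate"] = uni
            results["coactivation_features"] = feats

            stage = "genostats"
            if "genostats" in config.stages:
                rows = []
                dv_tables = pd.concat([uni, feats], axis=1)
                for dv in dv_tables.columns:
                    model = genostats.GenotypeAgeModel(
                        dv_tables[dv].to_numpy(),
                        grouped.loc[analysed, "age"].to_numpy(),
                        grouped.loc[analysed, "group"].to_numpy(),
                        bf_method=config.bf_method,
                        bf_prior_scale=config.bf_prior_scale,
                        bf_seed=config.seed,
                        dependent=str(dv),
                    )
                    rows.append(model.fit().to_frame())
                results["report"] = pd.concat(rows, ignore_index=True)[
                    list(REPORT_COLUMNS)
                ]

            stage = "classify"
            if "classify" in config.stages:
                labels = grouped.loc[analysed, "group"].to_numpy()
                perm = classify.permutation_test(
                    feats.to_numpy(),
                    labels,
                    n_perm=config.n_perm,
                    k=config.k_folds,
                    seed=config.seed,
                )
                results["classification"] = perm

        stage = "segregate"
        if "segregate" in config.stages:
            partition = (
                config.partition
                or config.sim.network_partition
                or _default_partition(list(config.sim.roi_labels))
            )
            if not partition:
                logger.warning(
                    "segregation skipped: no partition and too few ROIs for the default"
                )
            else:
                seg_rows = []
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", UserWarning)
                    for sid in analysed:
                        gsr = segregation.global_signal_regress(cleaned[sid])
                        conn = segregation.connectivity_matrix(gsr)
                        seg = segregation.system_segregation(conn, partition)
                        seg_rows.append({"subject_id": sid, **seg.to_dict()})
                seg_df = pd.DataFrame(seg_rows)
                n_undef = int((~seg_df["defined"]).sum())
                if n_undef:
                    logger.warning(
                        "SyS undefined (within-network mean <= 0) for %d of %d subjects",
                        n_undef,
                        len(seg_df),
                    )
                results["segregation"] = seg_df
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if outdir:
        _write_outputs(results, outdir)
    logger.info("pipeline done")
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    if "cohort" in results:
        results["cohort"].drop(columns=["seed"]).to_csv(
            outdir / "cohort.tsv", sep="\t", index=False
        )
    if "annotations" in results:
        results["annotations"].to_csv(outdir / "annotations.csv")
    if "boundaries" in results:
        results["boundaries"].to_csv(outdir / "boundaries.csv")
        results["boundary_vector"].to_csv(outdir / "boundary_vector.csv")
    if "univariate" in results:
        results["univariate"].to_csv(outdir / "univariate_responses.csv", index_label="subject_id")
    if "coactivation_features" in results:
        results["coactivation_features"].to_csv(
            outdir / "coactivation_features.csv", index_label="subject_id"
        )
    if "report" in results:
        write_report(results["report"], outdir / "genotype_report.csv")
    if "classification" in results:
        (outdir / "classification.json").write_text(
            json.dumps(results["classification"].to_dict(), indent=2)
        )
    if "segregation" in results:
        results["segregation"].to_csv(outdir / "segregation.csv", index=False)


def write_report(report: pd.DataFrame, path) -> None:
    """Write the term table; schema is exactly :data:`REPORT_COLUMNS`."""
    missing = set(REPORT_COLUMNS) - set(report.columns)
    if missing:
        raise ValueError(f"report is missing column(s): {sorted(missing)}")
    report[list(REPORT_COLUMNS)].to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if tuple(df.columns) != REPORT_COLUMNS:
        raise ValueError(f"unexpected report schema: {list(df.columns)}")
    return df
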