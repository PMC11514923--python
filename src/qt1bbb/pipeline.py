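"""End-to-end pipeline: simulate/load -> register -> delta -> normalize -> readout -> stats.

A :class:`PipelineConfig` (YAML-serializable) names either real
per-subject NIfTI inputs or a simulated cohort, plus the settings of
every stage.  :func:`run_subject` executes the imaging stages for one
subject and returns tidy biomarker rows; :func:`run_cohort` maps over
subjects (continuing past per-subject failures), joins covariates and
runs the statistical scenarios.  Runs are deterministic given the
config and seed, and the config snapshot written next to the results
replays to identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .bbb_mapping import compute_delta, normalize_by_sss, roi_readout
from .cohort_stats import ALL_SCENARIOS, run_group_analyses
from .phantom import PhantomSpec, simulate_sessions
from .registration import RegistrationSettings, rigid_register
from .relaxometry import QT1Volume

__all__ = ["PipelineConfig", "run_subject", "run_cohort", "CohortBundle"]

log = logging.getLogger("qt1bbb.pipeline")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "qt1_out"
    seed: int = 0
    #: simulated-cohort block: n_tle, n_etle, optional ``phantom`` overrides
    #: (PhantomSpec fields) and ``effects`` mapping group -> {roi: leakage}
    simulate: dict | None = None
    #: explicit-subject block: list of {id, group?, side?, covariates...,
    #: paths: {noncontrast, interictal, postictal?, labels}}
    subjects: list | None = None
    registration: dict = field(default_factory=dict)
    normalization_floor: float = 1e-6
    #: shrink ROI masks by this many voxels at readout (keeps the
    #: resampling partial-volume shell out of the summaries)
    readout_erode_voxels: int = 1
    scenarios: list = field(default_factory=lambda: list(ALL_SCENARIOS))
    keep_intermediates: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.subjects is None):
            raise ValueError("config needs exactly one of 'simulate' or 'subjects'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "subjects": self.subjects,
            "registration": self.registration,
            "normalization_floor": self.normalization_floor,
            "readout_erode_voxels": self.readout_erode_voxels,
            "scenarios": list(self.scenarios),
            "keep_intermediates": self.keep_intermediates,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    # ------------------------------------------------------------------
    def subject_ids(self) -> list[str]:
        if self.simulate is not None:
            n = int(self.simulate.get("n_tle", 4)) + int(self.simulate.get("n_etle", 4))
            return [f"sub-{i + 1:03d}" for i in range(n)]
        return [s["id"] for s in self.subjects]

    def _subject_seed(self, index: int) -> int:
        return int((self.seed * 100003 + 7919 * index + 1) % (2**31 - 1))

    def _simulated_subject(self, subject_id: str):
        idx = self.subject_ids().index(subject_id)
        sim = self.simulate
        n_tle = int(sim.get("n_tle", 4))
        group = "TLE" if idx < n_tle else "ETLE"
        seed = self._subject_seed(idx)
        rng = np.random.default_rng(seed)
        effects = sim.get("effects", {})
        leakage = dict(effects.get(group, {}))
        overrides = dict(sim.get("phantom", {}))
        overrides.setdefault("leakage_interictal", leakage)
        overrides.setdefault("leakage_postictal", dict(sim.get("effects_postictal", {}).get(group, {})))
        spec = PhantomSpec(seed=seed, **overrides)
        covariates = {
            "group": group,
            "side": str(rng.choice(["left", "right", "unknown"], p=[14 / 37, 14 / 37, 9 / 37])),
            "duration": float(np.clip(rng.lognormal(np.log(14.0), 0.55), 2.0, 44.0)),
            "latency_ii": float(np.clip(rng.lognormal(np.log(34.6), 0.5), 18.0, 266.0)),
            "latency_pi": float(np.clip(rng.lognormal(np.log(34.6), 0.5), 18.0, 266.0)),
            "verbal_memory": float(rng.normal(90.0, 12.0)),
            "figural_memory": float(rng.normal(88.0, 13.0)),
        }
        return spec, covariates

    def subject_inputs(self, subject_id: str):
        """Resolve (labels, sessions dict, covariates) for one subject."""
        if self.simulate is not None:
            spec, covariates = self._simulated_subject(subject_id)
            ses = simulate_sessions(spec)
            sessions = {
                "noncontrast": ses.noncontrast,
                "interictal": ses.interictal,
                "postictal": ses.postictal,
            }
            return ses.labels, sessions, covariates
        entry = next(s for s in self.subjects if s["id"] == subject_id)
        paths = entry["paths"]
        labels = qio.load_labels(paths["labels"])
        sessions = {}
        for name in QT1Volume.SESSIONS:
            if paths.get(name):
                sessions[name] = qio.load_qt1(paths[name], session=name)
        covariates = {k: v for k, v in entry.items() if k not in ("id", "paths")}
        return labels, sessions, covariates


def run_subject(config: PipelineConfig, subject_id: str) -> pd.DataFrame:
    """Imaging stages for one subject; returns tidy biomarker rows.

    Registers the post-contrast sessions onto the noncontrast grid,
    builds both subtraction maps, normalizes them by the SSS reference
    and reads out per-hemisphere ROI summaries.  A missing postictal
    session yields missing ``ip`` rows while the ``ni`` rows are still
    produced.  Idempotent given identical config and seed.
    """
    labels, sessions, covariates = config.subject_inputs(subject_id)
    if "noncontrast" not in sessions or "interictal" not in sessions:
        raise ValueError(f"{subject_id}: noncontrast and interictal sessions are required")
    nc = sessions["noncontrast"]
    settings = RegistrationSettings(**config.registration)
    sub_dir = Path(config.out_dir) / subject_id
    sub_dir.mkdir(parents=True, exist_ok=True)

    xf_ii, ii_reg = rigid_register(sessions["interictal"], nc, settings)
    maps = {}
    maps["ni"] = normalize_by_sss(
        compute_delta(nc, ii_reg, "ni"), labels, config.normalization_floor
    )
    pi_reg = None
    if "postictal" in sessions:
        xf_pi, pi_reg = rigid_register(sessions["postictal"], nc, settings)
        maps["ip"] = normalize_by_sss(
            compute_delta(ii_reg, pi_reg, "ip"), labels, config.normalization_floor
        )
    else:
        log.warning("%s: postictal session missing; ip rows marked missing", subject_id)

    frames = []
    for kind in ("ni", "ip"):
        for hemi in ("left", "right"):
            if kind in maps:
                df = roi_readout(maps[kind], labels, hemisphere=hemi, subject_id=subject_id,
                                 erode_voxels=config.readout_erode_voxels)
            else:
                df = roi_readout(maps["ni"], labels, hemisphere=hemi, subject_id=subject_id,
                                 erode_voxels=config.readout_erode_voxels)
                df[["mean", "sd", "sss_mean"]] = np.nan
                df["n_voxels"] = 0
                df["kind"] = "ip"
                df["normalized"] = False
            frames.append(df)
    table = pd.concat(frames, ignore_index=True).rename(columns={"mean": "value"})
    for key, val in covariates.items():
        table[key] = val
    log.info(
        "%s: sss_mean ni=%.4g%s",
        subject_id,
        maps["ni"].sss_mean,
        f" ip={maps['ip'].sss_mean:.4g}" if "ip" in maps else "",
    )

    if config.keep_intermediates:
        qio.save_labels(labels, sub_dir / "labels.nii.gz")
        qio.save_qt1(ii_reg, sub_dir / "interictal_reg.nii.gz")
        xf_ii.save(sub_dir / "interictal_reg.mat")
        if pi_reg is not None:
            qio.save_qt1(pi_reg, sub_dir / "postictal_reg.nii.gz")
            xf_pi.save(sub_dir / "postictal_reg.mat")
    table.to_csv(sub_dir / "summary.csv", index=False, float_format="%.10g")
    return table


@dataclass
class CohortBundle:
    """Everything one cohort run produced."""

    table: pd.DataFrame
    results: dict[str, pd.DataFrame]
    skipped: list
    failures: dict[str, str]
    out_dir: Path


def run_cohort(config: PipelineConfig) -> CohortBundle:
    """Run every subject, join the tables and run the analysis scenarios.

    Per-subject failures are recorded (machine-readable JSON) and the
    remaining subjects continue; if every subject fails a RuntimeError
    is raised.  Writes the cohort CSV, per-scenario result CSVs, a JSON
    results bundle, a log and a replayable config snapshot.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        frames, failures = [], {}
        for sid in config.subject_ids():
            try:
                frames.append(run_subject(config, sid))
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                log.error("%s failed: %s", sid, exc)
                failures[sid] = str(exc)
        if not frames:
            raise RuntimeError(f"all subjects failed: {failures}")
        table = pd.concat(frames, ignore_index=True)
        table = table.sort_values(
            ["subject", "kind", "roi", "hemisphere"], kind="mergesort"
        ).reset_index(drop=True)
        table.to_csv(out_dir / "cohort.csv", index=False, float_format="%.10g")

        stats_table = table.dropna(subset=["value"])
        results = run_group_analyses(stats_table, tuple(config.scenarios))
        for name, df in results.tables.items():
            df.to_csv(out_dir / f"results_{name}.csv", index=False, float_format="%.10g")
        bundle_json = {
            "seed": config.seed,
            "n_subjects": len(config.subject_ids()),
            "failures": failures,
            "skipped": results.skipped,
            "tables": {n: json.loads(df.to_json(orient="records")) for n, df in results.tables.items()},
        }
        (out_dir / "results.json").write_text(json.dumps(bundle_json, indent=2))
        if failures:
            (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
        config.to_yaml(out_dir / "config_snapshot.yaml")
        return CohortBundle(table, results.tables, results.skipped, failures, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()
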