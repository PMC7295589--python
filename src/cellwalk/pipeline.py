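"""Config-driven orchestration of the analysis stages.

A run is described by one flat YAML config (see :class:`RunConfig`);
``run`` executes the selected stages in dependency order, writes each
stage's CSV outputs under ``output_dir``, and records a manifest
(inputs, parameters, seed, SHA-256 of every output) sufficient to rerun
any stage.  Numeric outputs are deterministic for a fixed config+seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fccs, groupstats, simulate, stable, trajectories
from .errors import ConfigError

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate_walks", "tracks", "stable_fit", "simulate_fccs",
                "fccs_kd", "simulate_speeds", "tertiles", "scan")


@dataclass
class RunConfig:
    """Flat run configuration; unset stages are skipped.

    Input paths may point at files produced by earlier stages of the
    same run (the simulators write the exact CSV dialects the analysis
    stages read).
    """

    stages: list[str] = field(default_factory=list)
    output_dir: str = "cellwalk_out"
    seed: int = 0
    # tracks / kinematics
    tracks_csv: str | None = None
    frame_interval: float = 10.0
    min_speed: float = 2.5
    min_track_length: int = 2
    # stable fit
    steps_csv: str | None = None
    bootstrap_subsets: int = 100
    bootstrap_subset_size: int = 15000
    # fccs
    measurements_csv: str | None = None
    effective_volume: float = 0.57e-15
    ci_level: float = 0.95
    # tertiles
    speeds_csv: str | None = None
    reference_condition: str = "vehicle"
    # scan
    scan_alpha: float = 0.0001
    scan_treated: str = "dex"
    scan_vehicle: str = "vehicle"
    # simulators
    walk_n_cells: int = 100
    walk_n_frames: int = 25
    walk_shift_time: int = 0
    fccs_kd: float = 100.0
    fccs_n_cells: int = 30
    fccs_mode: str = "interacting"
    speeds_n_ref: int = 9149
    speeds_n_treated: int = 9669
    speeds_fast_shift: float = 1.05

    def validate(self) -> None:
        problems = []
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            problems.append(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed must be an integer")
        if self.min_speed < 0:
            problems.append("min_speed must be >= 0")
        if not (0 < self.ci_level < 1):
            problems.append("ci_level must be in (0, 1)")
        if self.effective_volume <= 0:
            problems.append("effective_volume must be > 0")
        if not (0 < self.scan_alpha < 1):
            problems.append("scan_alpha must be in (0, 1)")
        if problems:
            raise ConfigError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig | str | Path) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    tracks_csv = config.tracks_csv
    steps_csv = config.steps_csv
    measurements_csv = config.measurements_csv
    speeds_csv = config.speeds_csv

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g")
        outputs[name] = str(path)
        return path

    for stage in [s for s in KNOWN_STAGES if s in config.stages]:
        logger.info("stage %s", stage)
        if stage == "simulate_walks":
            cfg = simulate.WalkSimConfig(
                n_cells=config.walk_n_cells, n_frames=config.walk_n_frames,
                frame_interval=config.frame_interval,
                shift_time=config.walk_shift_time, seed=config.seed,
            )
            cohorts = simulate.simulate_levy_walk_cohort(cfg)
            frames = []
            for condition, trajs in cohorts.items():
                for tr in trajs:
                    frames.append(pd.DataFrame({
                        "track_id": tr.track_id, "t_min": tr.t,
                        "x_um": tr.x, "y_um": tr.y, "condition": condition,
                    }))
            path = _write(pd.concat(frames, ignore_index=True), "tracks.csv")
            tracks_csv = str(path)
            steps = {
                cond: np.concatenate(
                    [trajectories.step_lengths(tr).steps for tr in trajs])
                for cond, trajs in cohorts.items()
            }
            step_df = pd.concat([
                pd.DataFrame({"condition": c, "step_um": s}) for c, s in steps.items()
            ], ignore_index=True)
            steps_csv = str(_write(step_df, "steps.csv"))
        elif stage == "tracks":
            if tracks_csv is None:
                raise ConfigError("tracks stage needs tracks_csv (or simulate_walks)")
            trajs = trajectories.load_tracks(tracks_csv, config.frame_interval)
            kept, rejected = trajectories.filter_tracks(
                trajs, trajectories.TrackFilterConfig(
                    min_mean_speed=config.min_speed,
                    min_track_length=config.min_track_length))
            _write(trajectories.summaries_frame(kept), "kinematics.csv")
            _write(pd.DataFrame(
                [{"track_id": tr.track_id, "reason": why} for tr, why in rejected]
            ), "rejected_tracks.csv")
        elif stage == "stable_fit":
            if steps_csv is None:
                raise ConfigError("stable_fit stage needs steps_csv (or simulate_walks)")
            df = pd.read_csv(steps_csv)
            rows = []
            for condition, grp in df.groupby("condition", sort=True):
                model = stable.StableWalkModel(grp["step_um"].to_numpy(float))
                res = model.fit()
                boot = res.bootstrap(
                    n_subsets=config.bootstrap_subsets,
                    subset_size=config.bootstrap_subset_size, seed=config.seed)
                rows.append({
                    "condition": condition,
                    **dict(zip(("alpha", "beta", "gamma", "delta"),
                               res.params.astuple())),
                    **{f"{k}_sd": v for k, v in boot.sd.items()},
                    "n_obs": model.nobs, "n_subsets": boot.n_subsets,
                    "subset_size": boot.subset_size, "seed": config.seed,
                })
            _write(pd.DataFrame(rows), "stable_fits.csv")
        elif stage == "simulate_fccs":
            cfg = simulate.FccsSimConfig(
                kd=config.fccs_kd, n_cells=config.fccs_n_cells,
                control_mode=config.fccs_mode,
                effective_volume=config.effective_volume, seed=config.seed)
            _, table = simulate.simulate_fccs_experiment(cfg)
            measurements_csv = str(_write(table, "fccs_measurements.csv"))
        elif stage == "fccs_kd":
            if measurements_csv is None:
                raise ConfigError("fccs_kd stage needs measurements_csv (or simulate_fccs)")
            df = pd.read_csv(measurements_csv)
            processed = fccs.process_measurement_table(df, config.effective_volume)
            _write(processed, "fccs_processed.csv")
            meas = simulate.measurements_from_table(df, config.effective_volume)
            res = fccs.fit_kd(meas, ci_level=config.ci_level)
            lo, hi = res.conf_int()
            _write(pd.DataFrame([{
                "kd_nM": res.kd, "se_nM": res.se, "ci_level": config.ci_level,
                "ci_lower_nM": lo, "ci_upper_nM": hi,
                "n_fit": res.x.size, "n_excluded": len(res.excluded),
            }]), "kd_fit.csv")
            (out_dir / "kd_report.txt").write_text(res.summary() + "\n")
            outputs["kd_report.txt"] = str(out_dir / "kd_report.txt")
        elif stage == "simulate_speeds":
            table = simulate.simulate_growth_speeds(
                n_ref=config.speeds_n_ref, n_treated=config.speeds_n_treated,
                fast_tail_shift=config.speeds_fast_shift, seed=config.seed)
            speeds_csv = str(_write(table, "growth_speeds.csv"))
        elif stage == "tertiles":
            if speeds_csv is None:
                raise ConfigError("tertiles stage needs speeds_csv (or simulate_speeds)")
            events = pd.read_csv(speeds_csv)
            summary = groupstats.tertile_analysis(events, config.reference_condition)
            tidy = summary.counts.join(summary.medians, lsuffix="_count",
                                       rsuffix="_median").reset_index(names="condition")
            tidy["edge_slow_medium"] = summary.edges[0]
            tidy["edge_medium_fast"] = summary.edges[1]
            _write(tidy, "tertiles.csv")
        elif stage == "scan":
            if tracks_csv is None:
                raise ConfigError("scan stage needs tracks_csv (or simulate_walks)")
            df = pd.read_csv(tracks_csv)
            if "condition" not in df.columns:
                raise ConfigError("scan needs a 'condition' column in the track table")
            mats = {}
            for condition in (config.scan_vehicle, config.scan_treated):
                sub = df[df["condition"] == condition].drop(columns=["condition"])
                if sub.empty:
                    raise ConfigError(f"no tracks for condition {condition!r}")
                tmp = out_dir / f"_tracks_{condition}.csv"
                sub.to_csv(tmp, index=False)
                trajs = trajectories.load_tracks(tmp, config.frame_interval)
                tmp.unlink()
                mats[condition] = trajectories.cumulative_distance_matrix(
                    trajs, condition)
            scan_res = groupstats.rank_sum_scan(
                mats[config.scan_treated], mats[config.scan_vehicle],
                alpha=config.scan_alpha)
            _write(scan_res.table, "scan.csv")

    manifest = {
        "package": "cellwalk",
        "config": {k: v for k, v in config.__dict__.items()},
        "outputs": {name: {"path": p, "sha256": _sha256(Path(p))}
                    for name, p in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
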