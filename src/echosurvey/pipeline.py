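"""End-to-end runner: simulate -> detect -> track -> classify -> trends -> report.

Configuration is a flat YAML mapping; every key has a default so the
bundled demo runs with an empty file. Outputs per stage are written as
CSV/JSON into ``outdir``; a stage failure aborts with a stage-named error
and any half-written output keeps a ``.partial`` suffix. Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as esio
from .detection import DetectionParams, detect_all
from .echogram import apply_exclusions, detect_bottom
from .metrics import depth_summary, nv_profile
from .sizeclass import DEFAULT_SCHEME, tabulate_counts
from .simulate import SimConfig, build_population, demo_config, simulate_pings, simulate_target_level
from .tracking import TrackParams, build_tracks
from .trends import (
    abundance_ratio_per_halving,
    fit_all_declines,
    fits_to_frame,
    mean_loss_rate,
    survival,
)

log = logging.getLogger("echosurvey")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "echosurvey_out"
    seed: int = 0
    mode: str = "target"  # "target" (ideal-detector fast path) or "ping"
    start_date: str = "2011-07-26"
    surface_exclusion_m: float = 2.0
    deadzone_m: float = 0.55
    large_class_min_cm: float = 16.0
    sim: SimConfig = field(default_factory=lambda: demo_config())
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackParams = field(default_factory=TrackParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        kw = dict(raw)
        sim_kw = kw.pop("sim", {}) or {}
        det_kw = kw.pop("detection", {}) or {}
        trk_kw = kw.pop("tracking", {}) or {}
        cfg = cls(**kw)
        if sim_kw:
            cfg.sim = dataclasses.replace(demo_config(), **sim_kw)
        if det_kw:
            cfg.detection = dataclasses.replace(DetectionParams(), **det_kw)
        if trk_kw:
            cfg.tracking = dataclasses.replace(TrackParams(), **trk_kw)
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as e:
                raise PipelineStageError(name, e) from e

        return wrapped

    return deco


def _write(path, writer):
    tmp = str(path) + ".partial"
    try:
        writer(tmp)
    except Exception:
        raise
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and return the summary report (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    log.info("seed=%d mode=%s sim=%s", config.seed, config.mode, sim)
    start = pd.Timestamp(config.start_date)

    surveys = []
    all_targets = []
    for i, day in enumerate(sim.survey_days):
        sid = f"day{day:03d}"
        date = start + pd.Timedelta(days=int(day))
        surveys.append({"survey_id": sid, "date": date, "year": date.year, "day": int(day)})
        seed_i = np.random.SeedSequence([config.seed, int(day)]).generate_state(1)[0] % (2**31)
        all_targets.extend(_survey_targets(sim, config, day, i, sid, int(seed_i), date))

    _write(os.path.join(config.outdir, "targets.csv"), lambda p: esio.write_targets(all_targets, p))

    tracks = _track_stage(all_targets, config)
    _write(os.path.join(config.outdir, "tracks.csv"), lambda p: esio.write_tracks(tracks, p))

    counts = _classify_stage(tracks, surveys)
    _write(os.path.join(config.outdir, "counts.csv"), lambda p: esio.write_counts(counts, p))

    fits = _trend_stage(counts)
    trend_df = fits_to_frame(fits)
    _write(os.path.join(config.outdir, "trends.csv"), lambda p: trend_df.to_csv(p, index=False))

    metrics = _metrics_stage(all_targets, tracks, surveys, sim)
    _write(
        os.path.join(config.outdir, "metrics.json"),
        lambda p: _dump_json(metrics, p),
    )

    report = _summary(config, sim, fits, tracks, all_targets, counts, metrics)
    _write(os.path.join(config.outdir, "summary.json"), lambda p: _dump_json(report, p))
    return report


@_stage("simulate")
def _survey_targets(sim: SimConfig, config: PipelineConfig, day, survey_index, sid, seed, date):
    pop = build_population(sim, day)
    if config.mode == "target":
        return simulate_target_level(
            pop, sim, day, seed, params=config.detection, survey_id=sid,
            start_time=date.isoformat(),
        )
    pings = simulate_pings(pop, sim, seed, survey_id=sid, survey_index=survey_index,
                           start_time=date.isoformat())
    bottom = detect_bottom(pings, noise_floor_db=sim.noise_floor_db)
    apply_exclusions(
        pings, bottom, config.surface_exclusion_m, config.deadzone_m, sim.transducer_draft_m
    )
    return detect_all(pings, config.detection)


@_stage("track")
def _track_stage(targets, config):
    return build_tracks(targets, config.tracking)


@_stage("classify")
def _classify_stage(tracks, surveys):
    counts = tabulate_counts(tracks, surveys, DEFAULT_SCHEME)
    days = {s["survey_id"]: s["day"] for s in surveys}
    counts["day"] = counts["survey_id"].map(days)
    return counts


@_stage("trends")
def _trend_stage(counts):
    return fit_all_declines(counts)


@_stage("metrics")
def _metrics_stage(targets, tracks, surveys, sim: SimConfig):
    out = []
    by_sid: Dict[str, List] = {}
    for t in targets:
        by_sid.setdefault(t.survey_id, []).append(t)
    for i, s in enumerate(surveys):
        sid = s["survey_id"]
        tx = sim.transect_x_positions(i)
        total_len_m = len(tx) * sim.side_m
        tgts = by_sid.get(sid, [])
        ranges = [t.range_m for t in tgts]
        nv = nv_profile(ranges, total_len_m, sim)
        depths = [tr.depth_m for tr in tracks if tr.survey_id == sid]
        entry = {
            "survey_id": sid,
            "date": str(s["date"].date()),
            "coverage": float((total_len_m / 1e3) / np.sqrt(sim.basin_area_km2)),
            "n_targets": len(tgts),
            "max_nv": nv.max_nv,
        }
        if len(depths) >= 2:
            mean, half = depth_summary(depths)
            entry["mean_depth_m"] = mean
            entry["ci95_halfwidth_m"] = half
        out.append(entry)
    return out


def _summary(config, sim, fits, tracks, targets, counts, metrics) -> Dict:
    large = [
        lab for lab in DEFAULT_SCHEME.labels if float(lab) >= config.large_class_min_cm
    ]
    days = list(sim.survey_days)
    span = float(days[-1] - days[0])
    report: Dict = {
        "seed": config.seed,
        "mode": config.mode,
        "n_surveys": len(days),
        "stage_counts": {
            "targets_detected": len(targets),
            "targets_in_tracks": int(sum(tr.n_targets for tr in tracks)),
            "tracks": len(tracks),
            "tracks_classified": int(
                counts[[c for c in counts.columns if c.startswith("count_")]].to_numpy().sum()
            ),
        },
        "fits": [dataclasses.asdict(f) for f in fits],
        "surveys": metrics,
        "max_nv": max((m["max_nv"] for m in metrics), default=0.0),
    }
    try:
        rate = mean_loss_rate(fits, large)
        report["mean_loss_rate_large_per_day"] = rate
        report["summer_survival_large"] = survival(rate, span)
        report["summer_span_days"] = span
    except ValueError:
        pass
    try:
        report["abundance_ratio_per_halving"] = abundance_ratio_per_halving(fits)
    except ValueError:
        pass
    return report


def _dump_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, allow_nan=True)
        fh.write("\n")
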