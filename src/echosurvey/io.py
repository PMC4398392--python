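"""CSV serialization for every record stream in the pipeline.

All tables are RFC-4180 CSV with a header row; a ``.gz`` suffix gets
transparent gzip compression on both read and write. Readers validate the
schema and raise :class:`ParseError` naming the offending columns.
Timestamps are ISO-8601 UTC; coordinates WGS-84 decimal degrees; ranges
and depths metres; TS dB re 1 m^2.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import SingleTarget
from .echogram import BottomLine
from .simulate import PingRecord
from .tracking import FishTrack, tracks_to_frame


class ParseError(ValueError):
    pass


PING_SAMPLE_COLUMNS = [
    "survey_id",
    "transect_id",
    "ping_index",
    "time_iso8601",
    "lat",
    "lon",
    "range_m",
    "ts_uncomp_db",
    "ang_minor_deg",
    "ang_major_deg",
]

TARGET_COLUMNS = [
    "survey_id",
    "transect_id",
    "ping_index",
    "time",
    "lat",
    "lon",
    "range_m",
    "depth_m",
    "ts_uncomp_db",
    "beam_comp_db",
    "ts_comp_db",
    "angle_minor_deg",
    "angle_major_deg",
    "sd_minor_deg",
    "sd_major_deg",
    "norm_pulse_len",
]


def _read_checked(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as e:  # pandas reports the offending line number
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_pings(pings: Sequence[PingRecord], samples_path, index_path=None) -> None:
    """One row per range sample, plus an optional per-ping index table."""
    frames = []
    for p in pings:
        n = len(p.range_grid_m)
        frames.append(
            pd.DataFrame(
                {
                    "survey_id": p.survey_id,
                    "transect_id": p.transect_id,
                    "ping_index": p.ping_index,
                    "time_iso8601": p.time.isoformat(),
                    "lat": p.lat,
                    "lon": p.lon,
                    "range_m": p.range_grid_m,
                    "ts_uncomp_db": p.ts_uncomp_db,
                    "ang_minor_deg": p.angle_minor_deg,
                    "ang_major_deg": p.angle_major_deg,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PING_SAMPLE_COLUMNS)
    df.to_csv(samples_path, index=False)
    if index_path is not None:
        idx = pd.DataFrame(
            {
                "survey_id": [p.survey_id for p in pings],
                "transect_id": [p.transect_id for p in pings],
                "ping_index": [p.ping_index for p in pings],
                "time_iso8601": [p.time.isoformat() for p in pings],
                "lat": [p.lat for p in pings],
                "lon": [p.lon for p in pings],
                "n_samples": [len(p.range_grid_m) for p in pings],
                "bottom_range_m_true": [p.bottom_range_m_true for p in pings],
            }
        )
        idx.to_csv(index_path, index=False)


def read_pings(samples_path, index_path=None) -> List[PingRecord]:
    df = _read_checked(samples_path, PING_SAMPLE_COLUMNS)
    bottoms = {}
    if index_path is not None:
        idx = _read_checked(index_path, ["ping_index"])
        if "bottom_range_m_true" in idx.columns:
            bottoms = dict(zip(idx["ping_index"], idx["bottom_range_m_true"]))
    out = []
    for (sid, tid, pidx), g in df.groupby(["survey_id", "transect_id", "ping_index"], sort=True):
        g = g.sort_values("range_m")
        b = bottoms.get(pidx)
        out.append(
            PingRecord(
                survey_id=str(sid),
                transect_id=int(tid),
                ping_index=int(pidx),
                time=pd.Timestamp(g["time_iso8601"].iloc[0]),
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                range_grid_m=g["range_m"].to_numpy(dtype=float),
                ts_uncomp_db=g["ts_uncomp_db"].to_numpy(dtype=float),
                angle_minor_deg=g["ang_minor_deg"].to_numpy(dtype=float),
                angle_major_deg=g["ang_major_deg"].to_numpy(dtype=float),
                bottom_range_m_true=None if b is None or not np.isfinite(b) else float(b),
            )
        )
    out.sort(key=lambda p: (p.survey_id, p.transect_id, p.ping_index))
    return out


def targets_to_frame(targets: Sequence[SingleTarget]) -> pd.DataFrame:
    rows = [
        {
            "survey_id": t.survey_id,
            "transect_id": t.transect_id,
            "ping_index": t.ping_index,
            "time": t.time.isoformat(),
            "lat": t.lat,
            "lon": t.lon,
            "range_m": t.range_m,
            "depth_m": t.depth_m,
            "ts_uncomp_db": t.ts_uncomp_db,
            "beam_comp_db": t.beam_comp_db,
            "ts_comp_db": t.ts_comp_db,
            "angle_minor_deg": t.angle_minor_deg,
            "angle_major_deg": t.angle_major_deg,
            "sd_minor_deg": t.sd_minor_deg,
            "sd_major_deg": t.sd_major_deg,
            "norm_pulse_len": t.norm_pulse_len,
        }
        for t in targets
    ]
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def write_targets(targets: Sequence[SingleTarget], path) -> None:
    targets_to_frame(targets).to_csv(path, index=False)


def read_targets(path) -> List[SingleTarget]:
    df = _read_checked(path, TARGET_COLUMNS)
    return [
        SingleTarget(
            survey_id=str(r.survey_id),
            transect_id=int(r.transect_id),
            ping_index=int(r.ping_index),
            time=pd.Timestamp(r.time),
            lat=float(r.lat),
            lon=float(r.lon),
            range_m=float(r.range_m),
            depth_m=float(r.depth_m),
            ts_uncomp_db=float(r.ts_uncomp_db),
            beam_comp_db=float(r.beam_comp_db),
            ts_comp_db=float(r.ts_comp_db),
            angle_minor_deg=float(r.angle_minor_deg),
            angle_major_deg=float(r.angle_major_deg),
            sd_minor_deg=float(r.sd_minor_deg),
            sd_major_deg=float(r.sd_major_deg),
            norm_pulse_len=float(r.norm_pulse_len),
        )
        for r in df.itertuples(index=False)
    ]


def write_tracks(tracks: Sequence[FishTrack], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    return _read_checked(path, ["survey_id", "track_id", "n_targets", "ts_db", "depth_m"])


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    df = _read_checked(path, ["survey_id"])
    if not any(c.startswith("count_") for c in df.columns):
        raise ParseError(f"{path}: no count_<class> columns present")
    return df


def write_bottom(bottom: BottomLine, path) -> None:
    bottom.as_dataframe().to_csv(path, index=False)


def read_bottom(path) -> BottomLine:
    df = _read_checked(path, ["ping_index", "bottom_range_m", "source"])
    return BottomLine(
        ping_index=df["ping_index"].to_numpy(dtype=int),
        bottom_range_m=df["bottom_range_m"].to_numpy(dtype=float),
        source=df["source"].to_numpy(dtype=object),
    )
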