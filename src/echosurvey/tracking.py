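"""Fish tracking: grouping sequential single targets presumed to be one fish.

Greedy gated association: targets in successive pings join an open track
when the ping gap is within ``max_ping_gap`` and the range difference
within ``range_gate_m``; each target joins the nearest-in-range open
track. A track's TS is the maximum compensated TS over its members (the
convention for sequences of echoes from one fish), and its depth is the
depth of that maximum-TS member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import pandas as pd

from .detection import SingleTarget


@dataclass(frozen=True)
class TrackParams:
    min_single_targets: int = 1
    min_pings: int = 1
    max_ping_gap: int = 2
    range_gate_m: float = 0.4

    def __post_init__(self):
        if self.min_single_targets < 1 or self.min_pings < 1:
            raise ValueError("minimum counts must be >= 1")
        if self.max_ping_gap < 0 or self.range_gate_m <= 0:
            raise ValueError("need max_ping_gap >= 0 and range_gate_m > 0")


@dataclass
class FishTrack:
    """Sequential single targets attributed to one fish."""

    survey_id: str
    track_id: int
    members: List[SingleTarget] = field(default_factory=list)

    @property
    def n_targets(self) -> int:
        return len(self.members)

    @property
    def ts_db(self) -> float:
        return track_ts(self)

    @property
    def _max_member(self) -> SingleTarget:
        return max(self.members, key=lambda t: t.ts_comp_db)

    @property
    def depth_m(self) -> float:
        return self._max_member.depth_m

    @property
    def time(self):
        return self.members[0].time

    @property
    def lat(self):
        return self._max_member.lat

    @property
    def lon(self):
        return self._max_member.lon


def track_ts(track: FishTrack) -> float:
    """Track TS: the maximum compensated TS over member targets."""
    if not track.members:
        raise ValueError("empty track")
    return max(t.ts_comp_db for t in track.members)


def build_tracks(targets: Sequence[SingleTarget], params: TrackParams = TrackParams()) -> List[FishTrack]:
    """Partition targets into tracks by greedy gated association.

    Targets are processed in (survey, transect, ping, range) order. Every
    target ends up in exactly one track; tracks failing the minimum
    target/ping counts are dropped from the output (with default minima of
    1 nothing is dropped).
    """
    ordered = sorted(
        targets, key=lambda t: (t.survey_id, t.transect_id, t.ping_index, t.range_m)
    )
    open_tracks: List[FishTrack] = []  # within the current survey+transect
    done: List[FishTrack] = []
    cur_key = None
    next_id = 0

    for tgt in ordered:
        key = (tgt.survey_id, tgt.transect_id)
        if key != cur_key:
            done.extend(open_tracks)
            open_tracks = []
            cur_key = key
        # close tracks that can no longer be extended
        still = []
        for tr in open_tracks:
            if tgt.ping_index - tr.members[-1].ping_index > params.max_ping_gap:
                done.append(tr)
            else:
                still.append(tr)
        open_tracks = still

        best, best_d = None, None
        for tr in open_tracks:
            last = tr.members[-1]
            if last.ping_index == tgt.ping_index:
                continue  # one target per ping per track
            d = abs(tgt.range_m - last.range_m)
            if d <= params.range_gate_m and (best is None or d < best_d):
                best, best_d = tr, d
        if best is None:
            best = FishTrack(survey_id=tgt.survey_id, track_id=next_id)
            next_id += 1
            open_tracks.append(best)
        best.members.append(tgt)

    done.extend(open_tracks)
    out = []
    for tr in done:
        pings = {t.ping_index for t in tr.members}
        if tr.n_targets >= params.min_single_targets and len(pings) >= params.min_pings:
            out.append(tr)
    out.sort(key=lambda tr: (tr.survey_id, tr.members[0].transect_id, tr.members[0].ping_index))
    for i, tr in enumerate(out):
        tr.track_id = i
    return out


def tracks_to_frame(tracks: Sequence[FishTrack]) -> pd.DataFrame:
    rows = [
        {
            "survey_id": tr.survey_id,
            "track_id": tr.track_id,
            "n_targets": tr.n_targets,
            "ts_db": tr.ts_db,
            "depth_m": tr.depth_m,
            "time": tr.time,
            "lat": tr.lat,
            "lon": tr.lon,
        }
        for tr in tracks
    ]
    return pd.DataFrame(
        rows, columns=["survey_id", "track_id", "n_targets", "ts_db", "depth_m", "time", "lat", "lon"]
    )
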