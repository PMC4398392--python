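"""Echogram line editing: bottom detection and exclusion-zone masking.

Before single-target detection, each ping is cropped to the usable water
column: a surface exclusion layer (default 2 m depth, below the bulk of
surface noise), and everything from the near-bottom dead zone (default
0.55 m above the detected bottom) downward. Depth convention throughout:
depth = range + transducer draft.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_SURFACE_EXCLUSION_M = 2.0
DEFAULT_DEADZONE_M = 0.55
DEFAULT_DRAFT_M = 0.45


@dataclass
class BottomLine:
    """Per-ping bottom range pick (m) and its provenance."""

    ping_index: np.ndarray
    bottom_range_m: np.ndarray
    source: np.ndarray  # "detected" | "interpolated" | "manual"

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ping_index": self.ping_index,
                "bottom_range_m": self.bottom_range_m,
                "source": self.source,
            }
        )


@dataclass
class ExclusionMask:
    """Per-ping excluded range intervals [(start_m, end_m), ...], normalized."""

    intervals: Dict[int, List[Tuple[float, float]]]


def detect_bottom(
    pings: Sequence,
    min_depth_m: float = 3.0,
    smooth_window: int = 5,
    noise_floor_db: float = -75.0,
    overrides: Optional[Dict[int, float]] = None,
) -> BottomLine:
    """Pick the bottom as the strongest sample below ``min_depth_m``, then
    median-smooth the picks over ``smooth_window`` pings.

    A ping with no sample 20 dB above the noise floor below ``min_depth_m``
    gets no pick; such pings are interpolated from neighbouring picks.
    ``overrides`` maps ping_index to a manual bottom range (applied after
    smoothing, marked source="manual"). Raises ValueError when no ping has
    a defined bottom.
    """
    draft = DEFAULT_DRAFT_M
    picks = np.full(len(pings), np.nan)
    idx = np.array([p.ping_index for p in pings])
    for i, p in enumerate(pings):
        rng_min = min_depth_m - draft
        sel = p.range_grid_m >= rng_min
        if not np.any(sel):
            continue
        ts = p.ts_uncomp_db[sel]
        if np.max(ts) < noise_floor_db + 20.0:
            continue
        picks[i] = p.range_grid_m[sel][int(np.argmax(ts))]

    defined = np.isfinite(picks)
    if not np.any(defined):
        raise ValueError("bottom undefined on every ping")
    source = np.where(defined, "detected", "interpolated").astype(object)
    if not np.all(defined):
        picks = np.interp(np.arange(len(picks)), np.nonzero(defined)[0], picks[defined])

    if smooth_window > 1:
        smoothed = (
            pd.Series(picks).rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
        )
    else:
        smoothed = picks

    if overrides:
        for i, pi in enumerate(idx):
            if pi in overrides:
                smoothed[i] = overrides[pi]
                source[i] = "manual"

    return BottomLine(ping_index=idx, bottom_range_m=smoothed, source=source)


def apply_exclusions(
    pings: Sequence,
    bottom: Optional[BottomLine] = None,
    surface_excl_m: float = DEFAULT_SURFACE_EXCLUSION_M,
    deadzone_m: float = DEFAULT_DEADZONE_M,
    draft_m: float = DEFAULT_DRAFT_M,
) -> ExclusionMask:
    """Flag surface-layer and near-bottom samples as excluded, in place.

    A sample is excluded when its depth (range + draft) is shallower than
    ``surface_excl_m`` or its range deeper than ``bottom - deadzone_m``.
    Sets each ping's ``excluded`` boolean mask and returns the interval
    mask. When the whole ping is excluded that is logged, not an error.
    Idempotent: reapplying yields the same mask.
    """
    if surface_excl_m < 0 or deadzone_m < 0:
        raise ValueError("exclusion distances must be >= 0")
    bmap = {}
    if bottom is not None:
        bmap = dict(zip(bottom.ping_index, bottom.bottom_range_m))
    intervals: Dict[int, List[Tuple[float, float]]] = {}
    for p in pings:
        grid = p.range_grid_m
        mask = np.zeros(len(grid), dtype=bool)
        iv = []
        surf_r = surface_excl_m - draft_m
        if surf_r > 0:
            mask |= grid < surf_r
            iv.append((0.0, min(surf_r, grid[-1])))
        if p.ping_index in bmap:
            cut = bmap[p.ping_index] - deadzone_m
            mask |= grid >= cut
            iv.append((max(cut, 0.0), float(grid[-1])))
        p.excluded = mask
        intervals[p.ping_index] = _normalize(iv)
    return ExclusionMask(intervals=intervals)


def _normalize(iv):
    iv = sorted((a, b) for a, b in iv if b > a)
    out = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out
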