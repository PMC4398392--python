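"""Target-strength to fish-length conversion and log2 size classing.

Track target strengths (TS, dB re 1 m^2) are converted to body length with
Love's empirical relation for swim-bladdered fish at 200 kHz,

    L(cm) = 10 ** ((TS + 64.09) / 19.1),

and binned into five half-open log2 length classes (4-8, 8-16, 16-32,
32-64, 64-128 cm), labelled by their lower length bound. TS class
boundaries are always recomputed by inverting the relation at the length
bounds, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

LOVE_INTERCEPT_DB = -64.09
LOVE_SLOPE_DB_PER_DECADE = 19.1

#: lower length bounds (cm) of the standard log2 scheme; upper cap 128 cm
DEFAULT_CLASS_BOUNDS_CM = (4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


def ts_to_length(ts_db):
    """Fish length in cm from target strength in dB (Love, 200 kHz)."""
    ts_db = np.asarray(ts_db, dtype=float)
    out = 10.0 ** ((ts_db + 64.09) / 19.1)
    return float(out) if out.ndim == 0 else out


def length_to_ts(length_cm):
    """Target strength in dB from fish length in cm (inverse Love relation).

    Raises ValueError for non-positive lengths.
    """
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(length_cm <= 0):
        raise ValueError("length must be positive")
    out = 19.1 * np.log10(length_cm) - 64.09
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered, contiguous, half-open (lower-inclusive) size classes.

    ``bounds_cm`` holds n+1 strictly increasing length bounds delimiting n
    classes; ``labels`` default to the integer lower bounds (4, 8, 16, ...).
    TS bounds are derived from the length bounds at construction.
    """

    bounds_cm: tuple = DEFAULT_CLASS_BOUNDS_CM
    labels: tuple = field(default=None)

    def __post_init__(self):
        b = tuple(float(x) for x in self.bounds_cm)
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bounds_cm must be strictly increasing, length >= 2")
        object.__setattr__(self, "bounds_cm", b)
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(int(x) if float(x).is_integer() else x for x in b[:-1])
            )
        elif len(self.labels) != len(b) - 1:
            raise ValueError("need one label per class")

    @property
    def ts_bounds_db(self) -> tuple:
        """TS bounds (dB) obtained by inverting the length relation."""
        return tuple(length_to_ts(x) for x in self.bounds_cm)

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def class_intervals_db(self):
        """List of (label, ts_lo, ts_hi) half-open TS intervals."""
        tb = self.ts_bounds_db
        return [(self.labels[i], tb[i], tb[i + 1]) for i in range(self.n_classes)]


DEFAULT_SCHEME = SizeClassScheme()


def assign_size_class(ts_db: float, scheme: SizeClassScheme = DEFAULT_SCHEME):
    """Label of the class whose half-open TS interval contains ``ts_db``.

    Lower-inclusive: a TS exactly on a boundary belongs to the larger class.
    Returns None below the smallest class or at/above the upper cap.
    """
    tb = scheme.ts_bounds_db
    if not np.isfinite(ts_db) or ts_db < tb[0] or ts_db >= tb[-1]:
        return None
    idx = int(np.searchsorted(tb, ts_db, side="right")) - 1
    return scheme.labels[idx]


def tabulate_counts(
    tracks: Iterable,
    surveys: Sequence,
    scheme: SizeClassScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Per-survey, per-class counts of fish tracks (the unit of trend analysis).

    Parameters
    ----------
    tracks : iterable of objects with ``survey_id`` and ``ts_db`` attributes
        (FishTrack works), or a DataFrame with those columns.
    surveys : sequence of survey metadata. Each element needs ``survey_id``;
        ``date`` and ``year`` are carried through when present (objects,
        dicts, or plain ids all accepted).
    scheme : SizeClassScheme

    Returns a DataFrame with one row per survey and one ``count_<label>``
    column per class; tracks falling outside the scheme are excluded.
    Raises KeyError on a track whose survey_id is not in ``surveys``.
    """

    def _meta(s):
        if isinstance(s, dict):
            return s.get("survey_id"), s.get("date"), s.get("year")
        if hasattr(s, "survey_id"):
            return s.survey_id, getattr(s, "date", None), getattr(s, "year", None)
        return s, None, None

    metas = [_meta(s) for s in surveys]
    order = {m[0]: i for i, m in enumerate(metas)}
    counts = np.zeros((len(metas), scheme.n_classes), dtype=int)
    label_idx = {lab: j for j, lab in enumerate(scheme.labels)}

    if isinstance(tracks, pd.DataFrame):
        it = tracks.itertuples(index=False)
        items = [(row.survey_id, row.ts_db) for row in it]
    else:
        items = [(t.survey_id, t.ts_db) for t in tracks]

    for sid, ts in items:
        if sid not in order:
            raise KeyError(f"track references unknown survey_id {sid!r}")
        lab = assign_size_class(ts, scheme)
        if lab is not None:
            counts[order[sid], label_idx[lab]] += 1

    out = pd.DataFrame(
        {
            "survey_id": [m[0] for m in metas],
            "date": [m[1] for m in metas],
            "year": [m[2] for m in metas],
        }
    )
    for j, lab in enumerate(scheme.labels):
        out[f"count_{lab}"] = counts[:, j]
    return out
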