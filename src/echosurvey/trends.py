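"""Seasonal decline analysis: catch-curve-style loss rates and survival.

The core statistic: for each size class and year, ordinary least squares
of ln(track count) against survey day (days since the year's first
survey), so the intercept is the ln initial count and the slope is the
instantaneous loss (mortality) rate Z in day^-1. Survival over t days is
exp(Z * t). Inter-annual rates compare the last survey of one year to the
first survey of the next, optionally matching each class to the next
larger one (incremented classes) to account for growth over the gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class TrendFit:
    """OLS fit of ln count vs. day for one size class and year."""

    class_label: object
    year: Optional[int]
    ln_initial_count: float  # intercept at the year's first survey day
    slope_per_day: float  # instantaneous loss rate Z
    slope_se: float
    r_squared: float
    p_value: float
    n_surveys: int

    def slope_ci95(self) -> tuple:
        from scipy.stats import t as tdist

        if self.n_surveys < 3:
            return (np.nan, np.nan)
        tc = tdist.ppf(0.975, self.n_surveys - 2)
        return (self.slope_per_day - tc * self.slope_se, self.slope_per_day + tc * self.slope_se)


@dataclass
class SurvivalEstimate:
    rate_per_day: float
    duration_days: float
    survival_fraction: float
    scope: str  # "summer" | "interannual"
    classes: tuple


def fit_loglinear(days, counts, class_label=None, year=None) -> Optional[TrendFit]:
    """OLS of ln(count) on day. Zero counts are dropped with a warning;
    fewer than 3 usable points yields no fit (None)."""
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ok = counts > 0
    if not np.all(ok):
        warnings.warn(
            f"dropping {int((~ok).sum())} zero-count survey(s) from the fit "
            f"(class {class_label}, year {year})",
            stacklevel=2,
        )
    days, counts = days[ok], counts[ok]
    if len(days) < 3 or len(np.unique(days)) < 2:
        return None
    y = np.log(counts)
    if np.allclose(y, y[0]):
        # degenerate flat series: slope 0, no variance explained
        return TrendFit(class_label, year, float(y[0]), 0.0, 0.0, 0.0, 1.0, len(days))
    res = sm.OLS(y, sm.add_constant(days)).fit()
    return TrendFit(
        class_label=class_label,
        year=year,
        ln_initial_count=float(res.params[0]),
        slope_per_day=float(res.params[1]),
        slope_se=float(res.bse[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n_surveys=len(days),
    )


def _survey_days(dates) -> np.ndarray:
    d = pd.to_datetime(list(dates))
    return (d - d.min()).days.to_numpy().astype(float)


def fit_decline(
    counts: pd.DataFrame, class_label, year: Optional[int] = None
) -> Optional[TrendFit]:
    """Fit one class-year decline from a per-survey class-counts table.

    ``counts`` is the tabulated counts frame (columns ``survey_id``,
    ``date`` and/or ``day``, optional ``year``, and ``count_<label>``).
    The day variable is measured from the year's first survey, so the
    intercept is the ln initial count for that year.
    """
    df = counts
    if year is not None and "year" in df.columns and df["year"].notna().any():
        df = df[df["year"] == year]
    col = f"count_{class_label}"
    if col not in df.columns:
        raise KeyError(f"no column {col!r} in counts table")
    if "day" in df.columns:
        days = df["day"].to_numpy(dtype=float)
        days = days - days.min()
    elif "date" in df.columns and df["date"].notna().any():
        days = _survey_days(df["date"])
    else:
        raise KeyError("counts table needs a 'day' or 'date' column")
    return fit_loglinear(days, df[col].to_numpy(dtype=float), class_label, year)


def fit_all_declines(counts: pd.DataFrame, scheme=None) -> List[TrendFit]:
    """fit_decline over every (class, year) present in the counts table."""
    labels = [c[len("count_") :] for c in counts.columns if c.startswith("count_")]
    labels = [int(l) if l.isdigit() else l for l in labels]
    years = (
        sorted(y for y in counts["year"].dropna().unique())
        if "year" in counts.columns and counts["year"].notna().any()
        else [None]
    )
    fits = []
    for y in years:
        for lab in labels:
            f = fit_decline(counts, lab, y)
            if f is not None:
                fits.append(f)
    return fits


def mean_loss_rate(fits: Iterable[TrendFit], class_subset: Optional[Sequence] = None) -> float:
    """Arithmetic mean of fitted slopes, optionally over a class subset."""
    sel = [f.slope_per_day for f in fits if class_subset is None or f.class_label in class_subset]
    if not sel:
        raise ValueError("empty class subset")
    return float(np.mean(sel))


def survival(rate_per_day: float, duration_days: float) -> float:
    """Survival fraction over the interval: exp(rate * duration)."""
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    return float(np.exp(rate_per_day * duration_days))


def interannual_rates(
    last_counts_y1: Mapping,
    first_counts_y2: Mapping,
    delta_days: float,
    incremented: bool = True,
    min_class: Optional[float] = 16,
) -> Dict:
    """Per-class loss rates across the unsampled gap between seasons.

    rate_k = [ln N_y2(class k') - ln N_y1(class k)] / delta_days, where
    k' is the next larger class when ``incremented`` (growth over the gap
    promotes fish a class), and the largest class compares to itself.
    Classes below ``min_class`` are skipped by default (their dynamics are
    dominated by recruitment, not survival). A zero count on either side
    leaves that class's rate undefined (NaN).
    """
    if delta_days <= 0:
        raise ValueError("delta_days must be positive")
    labels = sorted(last_counts_y1.keys(), key=float)
    out: Dict = {}
    for i, k in enumerate(labels):
        if min_class is not None and float(k) < float(min_class):
            continue
        k2 = labels[i + 1] if (incremented and i + 1 < len(labels)) else k
        n1 = last_counts_y1.get(k, 0)
        n2 = first_counts_y2.get(k2, 0)
        out[k] = (
            float((np.log(n2) - np.log(n1)) / delta_days) if n1 > 0 and n2 > 0 else float("nan")
        )
    return out


def abundance_ratio_per_halving(fits_by_year: Iterable[TrendFit]) -> float:
    """Mean factor by which abundance rises per halving of body length.

    exp of the mean adjacent-class difference in ln initial count,
    averaged within each year (largest class to smallest) and then across
    years. Pairs with a missing intercept are skipped.
    """
    by_year: Dict = {}
    for f in fits_by_year:
        by_year.setdefault(f.year, []).append(f)
    year_means = []
    for year, fits in by_year.items():
        fits = sorted(fits, key=lambda f: float(f.class_label))
        diffs = [
            fits[i].ln_initial_count - fits[i + 1].ln_initial_count
            for i in range(len(fits) - 1)
            if np.isfinite(fits[i].ln_initial_count) and np.isfinite(fits[i + 1].ln_initial_count)
        ]
        if diffs:
            year_means.append(np.mean(diffs))
    if not year_means:
        raise ValueError("need at least two classes with intercepts")
    return float(np.exp(np.mean(year_means)))


def fits_to_frame(fits: Sequence[TrendFit], scheme=None) -> pd.DataFrame:
    """Trend table with one row per class-year, mirroring the standard
    loss-rate report (class upper TS bound, year, ln initial count, slope,
    p, R^2)."""
    from .sizeclass import DEFAULT_SCHEME, length_to_ts

    scheme = scheme or DEFAULT_SCHEME
    upper = {
        lab: length_to_ts(scheme.bounds_cm[i + 1]) for i, lab in enumerate(scheme.labels)
    }
    rows = [
        {
            "class_label": f.class_label,
            "max_ts_db": round(upper.get(f.class_label, np.nan), 2)
            if f.class_label in upper
            else np.nan,
            "year": f.year,
            "ln_initial_count": f.ln_initial_count,
            "slope_per_day": f.slope_per_day,
            "slope_se": f.slope_se,
            "p_value": f.p_value,
            "r_squared": f.r_squared,
            "n_surveys": f.n_surveys,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
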