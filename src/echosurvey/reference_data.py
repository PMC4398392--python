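"""Published summary tables from the Lac du Bonnet reservoir survey program
(Manitoba; eleven daytime 200 kHz surveys, summers 2011-2012).

These printed constants are inputs to the worked examples and consistency
checks: the raw ping recordings are proprietary and undeposited, but the
survey metadata and per-class regression summaries are public numbers.
"""

from __future__ import annotations

import pandas as pd

#: basin areas (km^2); the reservoir total is their sum (84 km^2)
BASIN_AREAS_KM2 = (38.5, 27.0, 18.5)
RESERVOIR_AREA_KM2 = float(sum(BASIN_AREAS_KM2))

#: survey_id, date, total transect length (km)
SURVEYS = [
    (1, "2011-07-26", 37.39),
    (2, "2011-08-02", 40.68),
    (3, "2011-08-03", 38.41),
    (4, "2011-08-15", 35.23),
    (5, "2011-08-18", 40.91),
    (6, "2011-08-27", 35.15),
    (7, "2012-07-28", 36.39),
    (8, "2012-08-02", 40.23),
    (9, "2012-08-08", 35.74),
    (10, "2012-08-11", 39.66),
    (11, "2012-08-24", 41.39),
]


def survey_table() -> pd.DataFrame:
    df = pd.DataFrame(SURVEYS, columns=["survey_id", "date", "total_length_km"])
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["day"] = df.groupby("year")["date"].transform(lambda s: (s - s.min()).dt.days)
    return df


def survey_day_offsets(year: int) -> list:
    """Day offsets of each survey from the year's first survey."""
    df = survey_table()
    return df.loc[df["year"] == year, "day"].astype(int).tolist()


#: published class-year log-linear decline fits:
#: (class label = lower length bound cm, year, ln initial count, slope day^-1,
#:  p value, R^2). Class labels map to the printed upper-TS bounds
#: (-46.85, -41.05, -35.35, -29.6, -23.85 dB for classes 4..64).
PUBLISHED_DECLINE_FITS = [
    (4, 2011, 7.423, -0.067, 0.001, 0.96),
    (4, 2012, 6.624, -0.026, 0.059, 0.75),
    (8, 2011, 6.131, -0.055, 0.008, 0.86),
    (8, 2012, 5.659, -0.033, 0.007, 0.93),
    (16, 2011, 5.088, -0.029, 0.002, 0.94),
    (16, 2012, 4.304, -0.055, 0.002, 0.97),
    (32, 2011, 3.951, -0.050, 0.034, 0.72),
    (32, 2012, 3.135, -0.039, 0.044, 0.79),
    (64, 2011, 2.639, -0.036, 0.005, 0.89),
    (64, 2012, 1.609, -0.017, 0.398, 0.24),
]


def published_fits_table() -> pd.DataFrame:
    return pd.DataFrame(
        PUBLISHED_DECLINE_FITS,
        columns=["class_label", "year", "ln_initial_count", "slope_per_day", "p_value", "r_squared"],
    )


#: mean within-year first-to-last survey span (days): (32 + 27) / 2
MEAN_SUMMER_SPAN_DAYS = 29.5

#: last 2011 survey (Aug 27) to first 2012 survey (Jul 28)
INTERANNUAL_GAP_DAYS = 336
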