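"""Bundled reference measurements: bi-exponential T2 decompositions of
apple tissue dried at 45/60/70 degC, sampled every 30 min.

Each row is the mean +/- sd (3 replicates) of the long (ICW) and short
(FW) component T2 and percentage share, plus the fit R^2.  "Fresh" (pre-
drying) is stored as drying time 0.  The printed percentages are reported
as-is; rows do not always sum to exactly 100, so series views normalise
via fw = 100 - icw.
"""

from __future__ import annotations

import pandas as pd

from .compartments import CompartmentSeries

__all__ = ["drying_t2_table", "icw_series", "FRESH_ROW"]

# temperature_c, time_min, t2_long, t2_long_sd, long_pct, long_pct_sd,
# t2_short, t2_short_sd, short_pct, short_pct_sd, r_squared
_ROWS = [
    (45, 0, 90.67, 11.3, 88.10, 7.9, 32.76, 4.8, 11.97, 3.8, 0.9998),
    (45, 30, 92.43, 7.5, 87.96, 6.4, 35.55, 6.9, 12.04, 4.9, 0.9788),
    (45, 60, 96.52, 13.7, 82.52, 7.6, 34.86, 5.6, 13.88, 5.3, 0.9887),
    (45, 90, 89.25, 14.4, 78.14, 6.3, 48.21, 12.5, 17.48, 4.9, 0.9985),
    (45, 120, 88.74, 11.9, 78.81, 10.5, 29.24, 5.8, 21.86, 6.2, 0.9956),
    (45, 150, 90.12, 9.8, 79.22, 7.3, 26.27, 4.9, 21.19, 3.8, 0.9785),
    (45, 180, 100.19, 13.8, 82.13, 5.8, 25.88, 5.2, 20.78, 6.5, 0.9878),
    (45, 210, 125.00, 15.9, 81.06, 8.9, 18.98, 8.9, 17.87, 4.7, 0.9988),
    (45, 240, 100.12, 10.5, 79.80, 7.6, 16.97, 3.8, 18.94, 6.3, 0.9948),
    (45, 270, 108.72, 13.7, 82.01, 9.4, 28.27, 7.8, 20.20, 7.1, 0.9995),
    (45, 300, 106.92, 10.2, 82.71, 6.7, 19.28, 9.4, 17.99, 6.2, 0.9758),
    (45, 360, 98.86, 16.9, 84.23, 8.4, 20.52, 7.5, 15.77, 7.1, 0.9855),
    (45, 420, 182.56, 11.7, 84.51, 9.3, 13.58, 8.5, 15.49, 6.4, 0.9769),
    (60, 30, 90.38, 10.4, 87.32, 9.5, 36.85, 6.2, 12.68, 4.2, 0.9989),
    (60, 60, 99.44, 8.5, 78.30, 8.4, 32.56, 4.3, 21.70, 4.9, 0.9997),
    (60, 90, 116.83, 11.7, 45.10, 7.6, 68.51, 8.7, 54.90, 3.8, 0.9999),
    (60, 120, 102.93, 11.3, 69.41, 6.8, 28.14, 6.4, 30.59, 4.9, 0.9998),
    (60, 150, 109.54, 13.7, 78.45, 8.8, 25.13, 5.3, 21.55, 4.8, 0.9996),
    (60, 180, 76.74, 13.4, 53.46, 9.6, 12.10, 4.7, 46.54, 7.1, 0.9979),
    (60, 210, 98.42, 11.7, 65.03, 6.4, 43.18, 6.8, 34.97, 4.8, 0.9984),
    (60, 240, 123.51, 14.4, 74.45, 6.9, 8.95, 4.4, 25.55, 5.7, 0.9980),
    (60, 270, 125.18, 12.5, 51.72, 5.7, 31.02, 8.9, 48.28, 6.9, 0.9987),
    (60, 300, 141.48, 14.3, 76.93, 6.9, 50.12, 10.6, 23.07, 4.5, 0.9998),
    (60, 360, 121.05, 11.4, 20.02, 4.5, 47.61, 9.7, 79.98, 11.2, 0.9988),
    (60, 420, 284.98, 17.8, 5.12, 3.7, 99.89, 11.7, 94.88, 13.4, 0.9896),
    (70, 30, 109.34, 10.2, 81.59, 10.9, 61.89, 5.6, 18.41, 6.4, 0.9970),
    (70, 40, 133.12, 9.3, 58.02, 8.9, 27.45, 7.2, 41.98, 6.2, 0.9986),
    (70, 60, 120.42, 6.5, 42.86, 7.5, 20.58, 6.3, 57.14, 9.1, 0.9978),
    (70, 90, 148.08, 12.8, 70.59, 6.4, 34.35, 7.5, 29.41, 5.7, 0.9988),
    (70, 120, 137.30, 10.7, 46.12, 6.5, 32.50, 4.9, 53.88, 9.8, 0.9986),
    (70, 150, 120.82, 12.2, 60.03, 7.8, 28.12, 6.1, 39.97, 3.9, 0.9975),
    (70, 180, 98.58, 12.9, 78.26, 9.7, 21.11, 5.7, 21.74, 5.7, 0.9987),
    (70, 210, 95.26, 10.8, 60.07, 8.5, 33.28, 7.2, 39.93, 8.1, 0.9998),
    (70, 240, 128.21, 15.3, 81.50, 7.5, 18.25, 6.2, 18.50, 3.7, 0.9992),
    (70, 270, 139.12, 11.8, 30.10, 7.9, 35.13, 7.9, 69.90, 6.9, 0.9988),
    (70, 300, 137.38, 13.7, 10.11, 4.6, 56.22, 9.9, 89.89, 11.3, 0.9998),
    (70, 360, 119.55, 12.5, 4.20, 3.1, 49.21, 8.6, 95.80, 11.9, 0.9895),
    (70, 420, 284.87, 22.2, 3.50, 2.5, 95.79, 12.6, 96.50, 13.2, 0.9885),
]

_COLUMNS = [
    "temperature_c",
    "time_min",
    "t2_long_ms",
    "t2_long_sd",
    "long_pct",
    "long_pct_sd",
    "t2_short_ms",
    "t2_short_sd",
    "short_pct",
    "short_pct_sd",
    "r_squared",
]

#: the fresh (undried) reference decomposition, used widely in tests
FRESH_ROW = dict(zip(_COLUMNS, _ROWS[0]))


def drying_t2_table() -> pd.DataFrame:
    """The full reference table as a DataFrame (one row per temperature and
    drying time; time 0 = fresh sample)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def icw_series(temperature_c: float, include_fresh: bool = False) -> CompartmentSeries:
    """ICW% drying series at one temperature, built from the reference
    table's long-component percentages (fw = 100 - icw).

    The fresh (time-0) row exists only for 45 degC and is excluded by
    default so the three temperatures share a common 30-min-onward grid.
    """
    df = drying_t2_table()
    df = df[df["temperature_c"] == temperature_c]
    if not include_fresh:
        df = df[df["time_min"] > 0]
    if df.empty:
        raise ValueError(f"no reference rows at {temperature_c} degC")
    icw = df["long_pct"].to_numpy(dtype=float)
    return CompartmentSeries(
        times=df["time_min"].to_numpy(dtype=float),
        icw_pct=icw,
        fw_pct=100.0 - icw,
        temperature_c=float(temperature_c),
    )
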