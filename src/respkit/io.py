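"""CSV dialects for traces, MO2 series and activity records.

All files are UTF-8 CSV with a header row and "." as the decimal separator.

* Trace: time_s, chamber_id, o2_mg_per_l, o2_sat_pct, temp_c,
  phase (flush|wait|measure), cycle_index.  Time must be strictly
  increasing within each chamber.
* MO2: fish_id, time_min, mo2, qc_pass, r2, end_sat_pct.
* Activity: day, bin_start_hhmm, counts (10-min bins by default).

Extra columns are preserved as opaque payload; missing mandatory columns
and non-monotonic time are reported with the offending names/rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .respirometry import MO2Series, PHASES, TRACE_COLUMNS
from .synthetic_data import ActivitySeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_mo2",
    "write_mo2",
    "read_activity",
    "write_activity",
]

MO2_COLUMNS = ("fish_id", "time_min", "mo2", "qc_pass", "r2", "end_sat_pct")
ACTIVITY_COLUMNS = ("day", "bin_start_hhmm", "counts")


def _require(df: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing column(s): {', '.join(missing)}")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRACE_COLUMNS, "trace")
    bad_phase = set(df["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise ValueError(f"trace contains unknown phase value(s): {sorted(bad_phase)}")
    for ch, grp in df.groupby("chamber_id"):
        t = grp["time_s"].to_numpy(dtype=float)
        dec = np.nonzero(np.diff(t) <= 0)[0]
        if len(dec):
            row = grp.index[dec[0] + 1]
            raise ValueError(
                f"non-monotonic time in chamber {ch} at file row {row + 2}"
            )
    return df


def write_trace(trace: pd.DataFrame, path) -> None:
    _require(trace, TRACE_COLUMNS, "trace")
    trace.to_csv(path, index=False)


def read_mo2(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("fish_id", "time_min", "mo2"), "MO2")
    if "qc_pass" in df.columns:
        df["qc_pass"] = df["qc_pass"].astype(bool)
    for fish, grp in df.groupby("fish_id"):
        t = grp["time_min"].to_numpy(dtype=float)
        dec = np.nonzero(np.diff(t) <= 0)[0]
        if len(dec):
            row = grp.index[dec[0] + 1]
            raise ValueError(
                f"non-monotonic time for fish {fish} at file row {row + 2}"
            )
    return df


def write_mo2(series, path) -> None:
    """Write an MO2Series, a list of them, or an equivalent DataFrame."""
    if isinstance(series, MO2Series):
        series = [series]
    if isinstance(series, pd.DataFrame):
        df = series
    else:
        frames = []
        for s in series:
            d = s.data.copy()
            d.insert(0, "fish_id", s.fish_id)
            frames.append(d)
        df = pd.concat(frames, ignore_index=True)
        df = df[[c for c in MO2_COLUMNS if c in df.columns]]
    df.to_csv(path, index=False)


def read_activity(path) -> ActivitySeries:
    df = pd.read_csv(path)
    _require(df, ACTIVITY_COLUMNS, "activity")
    hh = df["bin_start_hhmm"].astype(str).str.split(":", expand=True)
    minutes = hh[0].astype(int) * 60 + hh[1].astype(int)
    df = df.assign(_min=minutes).sort_values(["day", "_min"])
    steps = np.unique(np.diff(df["_min"].to_numpy()) % (24 * 60))
    bin_min = int(steps[steps > 0].min()) if len(steps[steps > 0]) else 10
    counts = df["counts"].to_numpy(dtype=float)
    n_days = int(df["day"].nunique())
    start_clock_h = float(df["_min"].iloc[0]) / 60.0
    return ActivitySeries(
        counts=counts, n_days=n_days, bin_min=bin_min, start_clock_h=start_clock_h
    )


def write_activity(activity: ActivitySeries, path) -> None:
    n = len(activity.counts)
    start_min = int(round(activity.start_clock_h * 60))
    abs_min = start_min + np.arange(n) * activity.bin_min
    day = abs_min // (24 * 60)
    tod = abs_min % (24 * 60)
    hhmm = [f"{m // 60:02d}:{m % 60:02d}" for m in tod]
    pd.DataFrame(
        {"day": day, "bin_start_hhmm": hhmm, "counts": activity.counts}
    ).to_csv(path, index=False)
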