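"""Experiment-specific summaries: SDA, thermal sensitivity and Q10,
anesthetic recovery profiles.

* Specific dynamic action (SDA): the postprandial rise in MO2 of fed fish
  over the same fish fasted, expressed as a per-10-min-bin percent change
  with a paired t-test per bin; the peak percentage, its time, the window of
  significant elevation and the return to baseline summarize the response.
* Thermal sensitivity: the least-squares slope of MO2 on temperature over a
  warming ramp (mg O2 kg-1 h-1 per degC) and the thermal coefficient
  Q10 = (r2/r1)**(10/(t2-t1)), computed per fish and then averaged.
* Anesthetic recovery: each fish's post-recovery MO2 profile rises to a
  maximum and falls back to a plateau; segmented fits give the increase
  rate, time to maximum, maximum, decrease rate, stabilization time and
  post-stabilization base, aggregated as group mean +/- SEM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .respirometry import MO2Series
from .trend import (
    STABLE_SLOPE_TOL,
    fit_segmented,
    pairwise_contrasts,
    stabilization_time,
)

__all__ = [
    "SDAResult",
    "Q10Result",
    "TempSensitivity",
    "AnestheticProfile",
    "sda_metrics",
    "q10",
    "q10_per_fish",
    "temperature_sensitivity",
    "anesthetic_profile",
    "group_metric_tests",
    "mo2_long",
]

ANESTHETIC_METRICS = (
    "maximum",
    "increase_rate",
    "time_to_maximum",
    "decrease_rate",
    "stabilization_time",
    "base",
)


def mo2_long(series_list, qc_only: bool = True, group: str | None = None) -> pd.DataFrame:
    """Stack MO2Series into a long table (fish_id, time_min, mo2[, group])."""
    frames = []
    for s in series_list:
        df = (s.passing if qc_only else s.data)[["time_min", "mo2"]].copy()
        df.insert(0, "fish_id", s.fish_id)
        if group is not None:
            df["group"] = group
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _to_long(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, MO2Series):
        return mo2_long([obj])
    return mo2_long(list(obj))


# ---------------------------------------------------------------------------
# specific dynamic action


@dataclass(frozen=True)
class SDAResult:
    table: pd.DataFrame
    peak_pct: float
    peak_time_min: float
    significant_window_min: tuple | None
    return_to_baseline_min: float | None


def _paired_bin_test(diffs: np.ndarray):
    """Paired t-test of per-fish differences in one bin; degenerate
    zero-variance bins resolve by the mean (all-zero -> p=1, shifted -> p=0)."""
    n = len(diffs)
    if n < 2:
        return float("nan"), float("nan")
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        if np.allclose(diffs, 0):
            return 0.0, 1.0
        return float("inf"), 0.0
    t = diffs.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return float(t), p


def sda_metrics(fed, fasted, bin_min: float = 10.0, alpha: float = 0.05) -> SDAResult:
    """Postprandial metrics from paired fed / fasted MO2 series.

    Both inputs are long tables (fish_id, time_min, mo2) or MO2Series
    collections over the same fish; times are minutes post-feeding.  Values
    are averaged per fish within 10-min bins, the percent change
    100*(fed - fasted)/fasted is computed per fish and averaged, and a
    paired t-test per bin defines the significant window.  The return to
    baseline is the first bin after the peak from which the difference stays
    non-significant to the end of the record.
    """
    fed = _to_long(fed)
    fasted = _to_long(fasted)
    if set(fed["fish_id"]) != set(fasted["fish_id"]):
        raise ValueError("fed and fasted series must cover the same fish")

    def binned(df):
        out = df.copy()
        out["bin"] = (out["time_min"] // bin_min) * bin_min
        return out.groupby(["fish_id", "bin"])["mo2"].mean()

    merged = pd.concat(
        {"fed": binned(fed), "fasted": binned(fasted)}, axis=1
    ).dropna()
    merged["pct"] = 100.0 * (merged["fed"] - merged["fasted"]) / merged["fasted"]
    merged["diff"] = merged["fed"] - merged["fasted"]

    rows = []
    for b, grp in merged.groupby(level="bin"):
        t, p = _paired_bin_test(grp["diff"].to_numpy())
        rows.append(
            {
                "bin_start_min": float(b),
                "pct_change": float(grp["pct"].mean()),
                "mean_diff": float(grp["diff"].mean()),
                "t": t,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    table = pd.DataFrame(rows).sort_values("bin_start_min", ignore_index=True)

    i_peak = int(table["pct_change"].idxmax())
    peak_pct = float(table.loc[i_peak, "pct_change"])
    peak_time = float(table.loc[i_peak, "bin_start_min"])
    sig = table[table["significant"]]
    window = (
        (float(sig["bin_start_min"].min()), float(sig["bin_start_min"].max()))
        if len(sig)
        else None
    )
    ret = None
    after = table[table["bin_start_min"] > peak_time].reset_index(drop=True)
    for i in range(len(after)):
        if not after["significant"].iloc[i:].any():
            ret = float(after["bin_start_min"].iloc[i])
            break
    return SDAResult(table, peak_pct, peak_time, window, ret)


# ---------------------------------------------------------------------------
# thermal coefficient and sensitivity


@dataclass(frozen=True)
class Q10Result:
    per_fish_q10: np.ndarray
    mean: float
    sem: float
    r1: float
    r2: float
    t1_c: float
    t2_c: float


def q10(r1: float, r2: float, t1_c: float, t2_c: float) -> float:
    """Thermal coefficient Q10 = (r2/r1)**(10/(t2-t1))."""
    if t1_c == t2_c:
        raise ValueError("t1 and t2 must differ")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    return float((r2 / r1) ** (10.0 / (t2_c - t1_c)))


def q10_per_fish(table: pd.DataFrame, t1_c: float, t2_c: float) -> Q10Result:
    """Per-fish Q10 from a table with columns fish_id, r1, r2, then the
    group mean +/- SEM (per-animal-then-average)."""
    vals = np.array(
        [q10(r.r1, r.r2, t1_c, t2_c) for r in table.itertuples()], dtype=float
    )
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return Q10Result(
        per_fish_q10=vals,
        mean=float(vals.mean()),
        sem=sem,
        r1=float(table["r1"].mean()),
        r2=float(table["r2"].mean()),
        t1_c=t1_c,
        t2_c=t2_c,
    )


@dataclass(frozen=True)
class TempSensitivity:
    slope_per_degc: float
    se: float
    n: int


def temperature_sensitivity(data: pd.DataFrame, window_min=None) -> TempSensitivity:
    """OLS slope of MO2 on temperature (mg O2 kg-1 h-1 per degC).

    ``data`` needs columns mo2 and temp_c (plus time_min when ``window_min``
    = (start, end) restricts the fit to the warming window).
    """
    df = data
    if window_min is not None:
        lo, hi = window_min
        df = df[(df["time_min"] >= lo) & (df["time_min"] <= hi)]
    temp = df["temp_c"].to_numpy(dtype=float)
    mo2 = df["mo2"].to_numpy(dtype=float)
    if len(df) < 3 or np.ptp(temp) == 0:
        raise ValueError("temperature must vary within the window")
    res = stats.linregress(temp, mo2)
    return TempSensitivity(float(res.slope), float(res.stderr), len(df))


# ---------------------------------------------------------------------------
# anesthetic recovery profiles


@dataclass(frozen=True)
class AnestheticProfile:
    """Group recovery-profile metrics, each as (mean, SEM) across fish."""

    maximum: tuple
    increase_rate: tuple
    time_to_maximum: tuple
    decrease_rate: tuple
    stabilization_time: tuple
    base: tuple
    n_fish: int


def _fish_profile(t, y, slope_tol, min_segment_points):
    fit1 = fit_segmented(t, y, 1, min_segment_points)
    t_max = float(fit1.breakpoints_min[0])
    metrics = {
        "increase_rate": float(fit1.segment_slopes[0]),
        "time_to_maximum": t_max,
        "maximum": float(fit1.predict(t_max)),
        "decrease_rate": float(abs(fit1.segment_slopes[1])),
        "raw_maximum": float(np.max(y)),
    }
    fit2 = fit_segmented(t, y, 2, min_segment_points)
    if slope_tol == "auto":
        # the plateau must be flat relative to the fitted falling phase
        fall = abs(fit2.segment_slopes[1])
        tol = min(STABLE_SLOPE_TOL, fall / 2.0) if fall > 0 else STABLE_SLOPE_TOL
    else:
        tol = float(slope_tol)
    stab = stabilization_time(fit2, tol)
    metrics["stabilization_time"] = stab
    if stab is not None:
        tt = np.asarray(t, dtype=float)
        post = tt[tt >= stab]
        metrics["base"] = float(np.mean(fit2.predict(post))) if len(post) else np.nan
    else:
        metrics["base"] = np.nan
    return metrics


def anesthetic_profile(
    series_by_fish,
    slope_tol="auto",
    min_segment_points: int = 5,
):
    """Recovery-profile metrics per fish, aggregated as group mean +/- SEM.

    ``series_by_fish`` is a long table (fish_id, time_min, mo2) or an
    iterable of MO2Series.  Per fish, a one-breakpoint segmented fit yields
    the increase rate, time to maximum and fitted maximum plus the decrease
    rate; a two-breakpoint fit with the stabilization rule yields the
    stabilization time and the mean fitted value of the post-stabilization
    segment (the base).  Fish whose fits fail are excluded and logged.
    Returns (AnestheticProfile, per_fish_table, log).
    """
    long = _to_long(series_by_fish)
    rows, log = [], []
    for fish, grp in long.groupby("fish_id"):
        t = grp["time_min"].to_numpy(dtype=float)
        y = grp["mo2"].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _fish_profile(t, y, slope_tol, min_segment_points)
        except ValueError as exc:
            log.append(f"{fish}: excluded ({exc})")
            continue
        m["fish_id"] = fish
        rows.append(m)
    if not rows:
        raise ValueError("no fish produced a usable profile")
    per_fish = pd.DataFrame(rows)

    def agg(col):
        v = per_fish[col].dropna().to_numpy(dtype=float)
        if len(v) == 0:
            return (float("nan"), float("nan"))
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return (float(v.mean()), sem)

    prof = AnestheticProfile(
        maximum=agg("maximum"),
        increase_rate=agg("increase_rate"),
        time_to_maximum=agg("time_to_maximum"),
        decrease_rate=agg("decrease_rate"),
        stabilization_time=agg("stabilization_time"),
        base=agg("base"),
        n_fish=len(per_fish),
    )
    if not np.isnan(prof.base[0]) and prof.maximum[0] < prof.base[0]:
        warnings.warn("fitted maximum below the post-stabilization base")
    return prof, per_fish, log


def group_metric_tests(
    per_fish_metrics: pd.DataFrame,
    metrics=None,
    adjust: str = "BH",
) -> dict:
    """Pairwise group contrasts per recovery metric, adjusted within metric.

    ``per_fish_metrics`` holds one row per fish with a ``group`` column and
    one column per metric.  Each group enters as mean +/- SEM and the
    contrasts reuse the Wald machinery.  Returns {metric: contrast table}.
    """
    if metrics is None:
        metrics = [m for m in ANESTHETIC_METRICS if m in per_fish_metrics.columns]
    groups = per_fish_metrics.groupby("group")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (groups.size() < 2).any():
        raise ValueError("need at least 2 fish per group")
    out = {}
    for metric in metrics:
        stats_by_group = {}
        for g, grp in groups:
            v = grp[metric].dropna().to_numpy(dtype=float)
            if len(v) < 2:
                raise ValueError(f"group {g} has fewer than 2 values for {metric}")
            stats_by_group[str(g)] = (
                float(v.mean()),
                float(np.std(v, ddof=1) / np.sqrt(len(v))),
            )
        out[metric] = pairwise_contrasts(stats_by_group, adjust=adjust)
    return out
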