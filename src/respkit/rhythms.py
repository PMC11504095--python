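"""Daily-rhythm inference: cosinor, chi-square periodogram, daily waveform.

The cosinor model for a 24 h rhythm is

    Y(t) = M + A * cos(pi/12 * t - phi)

with mesor M (rhythm mean), amplitude A (mesor-to-peak distance) and
acrophase phi (phase of the fitted maximum); with t in hours since midnight
the acrophase in clock hours is phi / (pi/12).  The fit is linear least
squares on {1, cos(wt), sin(wt)}, and rhythm significance is the
zero-amplitude F-test of the cosinor against a constant mean.

Periodicity of locomotor activity is assessed with the Sokolove-Bushell
chi-square periodogram: the series is folded at each candidate period P
(K = P / bin columns, M_h the column means) and

    Q_P = N * Var_h(M_h) / Var_i(x_i)

is referred to a chi-square distribution with K - 1 degrees of freedom;
under an uncorrelated null E[Q_P] is about K - 1, while a periodic signal
at P inflates Q_P towards N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ActivitySeries

__all__ = [
    "CosinorFit",
    "Periodogram",
    "fit_cosinor",
    "zero_amplitude_test",
    "chi_square_periodogram",
    "daily_waveform",
    "actogram_matrix",
    "group_hourly",
]


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_rad: float
    acrophase_h: float
    period_h: float
    p_zero_amplitude: float
    n: int
    residual_ss: float


@dataclass(frozen=True)
class Periodogram:
    periods_min: np.ndarray
    qp: np.ndarray
    threshold: np.ndarray
    alpha: float
    peak_period_min: float | None


def group_hourly(t_h, y):
    """Collapse samples to hourly means (mean time, mean value per clock hour).

    Mirrors rhythm software that fits grouped hourly means rather than raw
    points; note hourly averaging slightly attenuates the fitted amplitude.
    """
    t = np.asarray(t_h, dtype=float)
    v = np.asarray(y, dtype=float)
    hour = np.floor(t).astype(int)
    df = pd.DataFrame({"hour": hour, "t": t, "y": v})
    g = df.groupby("hour", sort=True).mean()
    return g["t"].to_numpy(), g["y"].to_numpy()


def fit_cosinor(t_h, y, period_h: float = 24.0, grouped_hourly: bool = False) -> CosinorFit:
    """Least-squares cosinor fit of ``y`` sampled at ``t_h`` (hours).

    Exact on noiseless cosinor input.  Raises on a collinear design (all
    samples at one phase of the period); warns when the sampled span is
    shorter than one period.
    """
    t = np.asarray(t_h, dtype=float)
    v = np.asarray(y, dtype=float)
    if grouped_hourly:
        t, v = group_hourly(t, v)
    n = len(t)
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 points")
    if np.ptp(t) < period_h:
        warnings.warn("time span shorter than one period; fit may be unstable")
    omega = 2.0 * math.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear cosinor design (samples cover one phase only)")
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    ss = float(resid @ resid)
    mesor, bc, bs = beta
    amplitude = float(math.hypot(bc, bs))
    phi = float(math.atan2(bs, bc) % (2.0 * math.pi))
    fit = CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_rad=phi,
        acrophase_h=phi / omega % period_h,
        period_h=period_h,
        p_zero_amplitude=float("nan"),
        n=n,
        residual_ss=ss,
    )
    _, p = zero_amplitude_test(fit, t, v)
    return replace(fit, p_zero_amplitude=p)


def zero_amplitude_test(fit: CosinorFit, t_h, y):
    """F-test of the cosinor against a constant mean.

    F = ((SS_null - SS_model)/2) / (SS_model/(n-3)), referred to F(2, n-3).
    A numerically perfect fit gives p = 0.
    """
    t = np.asarray(t_h, dtype=float)
    v = np.asarray(y, dtype=float)
    n = len(v)
    if n <= 3:
        raise ValueError("zero-amplitude test needs n > 3")
    ss_null = float(np.sum((v - v.mean()) ** 2))
    ss_model = fit.residual_ss
    df2 = n - 3
    if ss_model <= 0:
        return float("inf"), 0.0
    F = ((ss_null - ss_model) / 2.0) / (ss_model / df2)
    p = float(stats.f.sf(F, 2, df2))
    return float(F), p


def _fold_column_means(x: np.ndarray, k: int) -> np.ndarray:
    idx = np.arange(len(x)) % k
    sums = np.bincount(idx, weights=x, minlength=k)
    counts = np.bincount(idx, minlength=k)
    return sums / counts


def chi_square_periodogram(
    activity,
    period_grid_min=None,
    alpha: float = 0.05,
    bin_min: int | None = None,
) -> Periodogram:
    """Sokolove-Bushell chi-square periodogram of binned activity counts.

    ``activity`` is an :class:`ActivitySeries` or a plain array of counts
    (then ``bin_min`` is required).  The default candidate grid covers the
    circadian range, 1000-1700 min in bin-width steps; candidate periods
    that are not whole multiples of the bin width are skipped with a warning.
    ``peak_period_min`` is the statistic's argmax among significant periods,
    or None when nothing crosses the threshold.
    """
    if isinstance(activity, ActivitySeries):
        x = np.asarray(activity.counts, dtype=float)
        bin_min = activity.bin_min
    else:
        x = np.asarray(activity, dtype=float)
        if bin_min is None:
            raise ValueError("bin_min required for plain count arrays")
    if period_grid_min is None:
        period_grid_min = np.arange(1000, 1700 + bin_min, bin_min)
    periods, qps, thresholds = [], [], []
    n = len(x)
    xbar = x.mean()
    denom = float(np.sum((x - xbar) ** 2))
    for p_min in np.asarray(period_grid_min, dtype=float):
        k = p_min / bin_min
        if abs(k - round(k)) > 1e-9:
            warnings.warn(
                f"period {p_min} min is not a multiple of the {bin_min} min bin; skipped"
            )
            continue
        k = int(round(k))
        if n < 2 * k:
            warnings.warn(
                f"series shorter than two cycles of {p_min} min; skipped"
            )
            continue
        col_means = _fold_column_means(x, k)
        if denom == 0:
            qp = 0.0
        else:
            # N * variance of column means / variance of the data
            qp = (n * n / k) * float(np.sum((col_means - xbar) ** 2)) / denom
        periods.append(p_min)
        qps.append(qp)
        thresholds.append(float(stats.chi2.ppf(1.0 - alpha, k - 1)))
    periods = np.asarray(periods)
    qps = np.asarray(qps)
    thresholds = np.asarray(thresholds)
    sig = qps > thresholds
    peak = float(periods[sig][np.argmax(qps[sig])]) if np.any(sig) else None
    return Periodogram(periods, qps, thresholds, alpha, peak)


def _activity_to_bins(activity, bin_min):
    if isinstance(activity, ActivitySeries):
        return np.asarray(activity.counts, dtype=float), activity.bin_min, activity.start_clock_h
    return np.asarray(activity, dtype=float), bin_min, 0.0


def daily_waveform(activity, bin_min: int = 10) -> pd.DataFrame:
    """Mean and SD per time-of-day bin across days.

    Returns a DataFrame with columns clock_bin_h (bin start, hours since
    midnight), mean, sd and n_days; bins tile 24 h exactly.  A trailing
    partial day contributes to the bins it covers.
    """
    x, bin_min, start_clock = _activity_to_bins(activity, bin_min)
    per_day = int(round(24 * 60 / bin_min))
    if len(x) < per_day:
        raise ValueError("daily waveform needs at least one full day")
    n_days = math.ceil(len(x) / per_day)
    padded = np.full(n_days * per_day, np.nan)
    padded[: len(x)] = x
    mat = padded.reshape(n_days, per_day)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=0)
    clock = (start_clock + np.arange(per_day) * bin_min / 60.0) % 24.0
    return pd.DataFrame(
        {"clock_bin_h": clock, "mean": mean, "sd": sd, "n_days": len(x) // per_day}
    )


def actogram_matrix(activity, double_plot: bool = False, bin_min: int = 10) -> np.ndarray:
    """Day x bin matrix of activity; incomplete tail bins become NaN.

    With ``double_plot`` each row concatenates day i with day i+1 (the usual
    48 h actogram layout), giving (n_days - 1) rows for n_days >= 2.
    """
    x, bin_min, _ = _activity_to_bins(activity, bin_min)
    per_day = int(round(24 * 60 / bin_min))
    n_days = max(1, math.ceil(len(x) / per_day))
    padded = np.full(n_days * per_day, np.nan)
    padded[: len(x)] = x
    mat = padded.reshape(n_days, per_day)
    if not double_plot:
        return mat
    if n_days == 1:
        return np.concatenate([mat, np.full((1, per_day), np.nan)], axis=1)
    return np.concatenate([mat[:-1], mat[1:]], axis=1)
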