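"""Raw intermittent-flow traces to QC-filtered mass-specific oxygen uptake.

An intermittent-flow respirometer alternates an open flush phase (chamber
water replaced by aerated water) with a closed phase (a short wait followed by
a measurement window).  During the closed measurement window the dissolved-O2
concentration declines linearly; the mass-specific oxygen uptake rate follows
from the fitted slope,

    MO2 = V_eff * M**-1 * |d[O2]/dt|        (mg O2 kg-1 h-1)

where ``V_eff`` is the respirometer volume minus the body volume of the fish
(L), ``M`` the fish mass (kg) and ``d[O2]/dt`` the slope of the linear O2
decline (mg O2 L-1 h-1) while the chamber is closed.

Quality control keeps a measurement only when the regression is tight
(R^2 > 0.95 by default) and the fish never experienced hypoxia (final
saturation in the window above 80% by default).  Microbial background
respiration, estimated from an empty-chamber recording before and after the
experiment, can be subtracted on the slope scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChamberSpec",
    "CycleConfig",
    "SlopeFit",
    "MO2Series",
    "BackgroundEstimate",
    "o2_solubility_mg_l",
    "sat_to_concentration",
    "concentration_to_sat",
    "extract_cycles",
    "fit_slope",
    "compute_mo2",
    "estimate_background",
    "mean_gross_slope",
    "qc_filter",
    "trace_to_mo2",
]

#: default QC thresholds
R2_MIN_DEFAULT = 0.95
SAT_MIN_PCT_DEFAULT = 80.0
#: background above this fraction of gross metabolism is flagged as
#: non-negligible
BACKGROUND_FLAG_FRACTION = 0.01

#: mandatory columns of the trace dialect
TRACE_COLUMNS = (
    "time_s",
    "chamber_id",
    "o2_mg_per_l",
    "o2_sat_pct",
    "temp_c",
    "phase",
    "cycle_index",
)

PHASES = ("flush", "wait", "measure")


# ---------------------------------------------------------------------------
# oxygen solubility


def o2_solubility_mg_l(temp_c):
    """Freshwater O2 solubility at 100% air saturation (mg O2 L-1).

    Benson–Krause polynomial in absolute temperature at zero salinity and
    standard barometric pressure; valid 0-40 degC.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any((t < 0.0) | (t > 40.0)):
        raise ValueError("temperature outside the 0-40 degC solubility range")
    T = t + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / T
        - 6.642308e7 / T**2
        + 1.2438e10 / T**3
        - 8.621949e11 / T**4
    )
    out = np.exp(ln_c)
    return float(out) if out.ndim == 0 else out


def sat_to_concentration(sat_pct, temp_c):
    """Convert % air saturation to mg O2 L-1 at the given temperature."""
    sat = np.asarray(sat_pct, dtype=float)
    out = sat / 100.0 * o2_solubility_mg_l(temp_c)
    return float(out) if out.ndim == 0 else out


def concentration_to_sat(o2_mg_per_l, temp_c):
    """Convert mg O2 L-1 to % air saturation (inverse of sat_to_concentration)."""
    conc = np.asarray(o2_mg_per_l, dtype=float)
    out = conc / o2_solubility_mg_l(temp_c) * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChamberSpec:
    """Respirometer geometry and occupant.

    ``fish_volume_l`` defaults to body mass at a density of 1 kg L-1, so the
    effective water volume is chamber volume minus fish volume.
    """

    fish_mass_kg: float
    volume_l: float = 0.36229
    fish_volume_l: float | None = None

    def __post_init__(self):
        if self.fish_mass_kg <= 0:
            raise ValueError("fish_mass_kg must be positive")
        if self.fish_volume_l is None:
            object.__setattr__(self, "fish_volume_l", self.fish_mass_kg / 1.0)
        if self.fish_volume_l < 0:
            raise ValueError("fish_volume_l must be nonnegative")
        if self.volume_l <= self.fish_volume_l:
            raise ValueError("chamber volume must exceed fish volume")

    @property
    def effective_volume_l(self) -> float:
        return self.volume_l - self.fish_volume_l


@dataclass(frozen=True)
class CycleConfig:
    """Durations (s) of the flush / wait / measure phases of one cycle."""

    flush_s: int = 77
    wait_s: int = 3
    measure_s: int = 80

    def __post_init__(self):
        for name in ("flush_s", "wait_s", "measure_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_s(self) -> int:
        return int(self.flush_s + self.wait_s + self.measure_s)


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of the O2 decline within one closed measurement window."""

    slope_mg_l_h: float
    intercept_mg_l: float
    r2: float
    n_points: int
    end_sat_pct: float
    t_mid_min: float


@dataclass
class MO2Series:
    """Per-fish MO2 time series with QC flags.

    ``data`` columns: time_min (minutes from the experiment's reference
    event, strictly increasing), mo2 (mg O2 kg-1 h-1), r2, end_sat_pct,
    qc_pass.  ``start_clock_h`` anchors time_min = 0 to a clock time so that
    rhythm analyses can work in hours since midnight.
    """

    fish_id: str
    data: pd.DataFrame
    background_corrected: bool = False
    start_clock_h: float | None = None

    @property
    def passing(self) -> pd.DataFrame:
        return self.data[self.data["qc_pass"]]

    @property
    def clock_h(self) -> np.ndarray:
        if self.start_clock_h is None:
            raise ValueError("series has no clock anchor (start_clock_h)")
        return self.start_clock_h + self.data["time_min"].to_numpy() / 60.0


@dataclass(frozen=True)
class BackgroundEstimate:
    """Microbial background respiration from empty-chamber recordings."""

    rate_mg_l_h: float
    rate_before: float | None
    rate_after: float | None
    fraction: float | None
    flagged: bool


# ---------------------------------------------------------------------------
# operations


def extract_cycles(trace: pd.DataFrame, config: CycleConfig | None = None):
    """Split a trace into its closed measurement windows, one per cycle.

    Returns a list of DataFrames (measure-phase rows only), ordered by cycle
    index.  Cycles without any measure-phase sample are skipped with a
    warning.  ``config`` is accepted for interface symmetry; the phase flags
    in the trace are authoritative.
    """
    required = ("time_s", "o2_mg_per_l", "phase", "cycle_index")
    missing = [c for c in required if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing column(s): {', '.join(missing)}")
    windows = []
    for ci, grp in trace.groupby("cycle_index", sort=True):
        meas = grp[grp["phase"] == "measure"]
        if len(meas) == 0:
            warnings.warn(f"cycle {ci} has no measure phase; skipped")
            continue
        windows.append(meas)
    return windows


def fit_slope(window: pd.DataFrame) -> SlopeFit:
    """Ordinary least-squares line through o2_mg_per_l versus time (hours).

    R^2 is the squared Pearson correlation; a zero-variance (constant O2)
    window gets slope 0 and R^2 defined as 0, which QC then rejects.
    """
    if len(window) < 3:
        raise ValueError("measurement window needs at least 3 samples")
    t_s = window["time_s"].to_numpy(dtype=float)
    y = window["o2_mg_per_l"].to_numpy(dtype=float)
    t_h = (t_s - t_s[0]) / 3600.0
    if np.ptp(t_h) == 0:
        raise ValueError("zero time variance in measurement window")
    slope, intercept = np.polyfit(t_h, y, 1)
    if np.std(y) == 0:
        r2 = 0.0
    else:
        r = np.corrcoef(t_h, y)[0, 1]
        r2 = float(r * r)
    if "o2_sat_pct" in window.columns:
        end_sat = float(window["o2_sat_pct"].iloc[-1])
    else:
        end_sat = float("nan")
    t_mid_min = float((t_s[0] + t_s[-1]) / 2.0 / 60.0)
    return SlopeFit(
        slope_mg_l_h=float(slope),
        intercept_mg_l=float(intercept),
        r2=r2,
        n_points=len(window),
        end_sat_pct=end_sat,
        t_mid_min=t_mid_min,
    )


def compute_mo2(fit: SlopeFit, chamber: ChamberSpec) -> float:
    """MO2 = V_eff * |slope| / M, positive for declining O2.

    A rising O2 slope (apparent production) is returned as a negative MO2
    with a warning so that the QC report stays complete.
    """
    if fit.slope_mg_l_h > 0:
        warnings.warn("rising O2 in measurement window; MO2 reported negative")
    return chamber.effective_volume_l * (-fit.slope_mg_l_h) / chamber.fish_mass_kg


def mean_gross_slope(trace: pd.DataFrame, config: CycleConfig | None = None) -> float:
    """Mean O2 decline rate (mg L-1 h-1, positive) over all measure windows."""
    windows = extract_cycles(trace, config)
    if not windows:
        raise ValueError("trace contains no measurement windows")
    return float(np.mean([-fit_slope(w).slope_mg_l_h for w in windows]))


def estimate_background(
    before: pd.DataFrame | None = None,
    after: pd.DataFrame | None = None,
    experiment_mean_slope_mg_l_h: float | None = None,
    config: CycleConfig | None = None,
) -> BackgroundEstimate:
    """Microbial background respiration rate from empty-chamber traces.

    The rate is the mean O2 decline (mg L-1 h-1) over the measure windows of
    the before/after recordings (mean of the two when both are given).  When
    the experiment's mean gross slope is supplied the background fraction is
    computed and flagged if it reaches 1% of total metabolism, the level
    above which it is no longer negligible.
    """
    if before is None and after is None:
        raise ValueError("need at least one empty-chamber trace")
    rate_before = rate_after = None
    if before is not None:
        rate_before = mean_gross_slope(before, config)
    else:
        warnings.warn("no before-experiment background segment; using after only")
    if after is not None:
        rate_after = mean_gross_slope(after, config)
    else:
        warnings.warn("no after-experiment background segment; using before only")
    rates = [r for r in (rate_before, rate_after) if r is not None]
    rate = float(np.mean(rates))
    fraction = None
    flagged = False
    if experiment_mean_slope_mg_l_h is not None:
        fraction = rate / abs(experiment_mean_slope_mg_l_h)
        flagged = fraction >= BACKGROUND_FLAG_FRACTION
    return BackgroundEstimate(rate, rate_before, rate_after, fraction, flagged)


def qc_filter(
    series: MO2Series,
    r2_min: float = R2_MIN_DEFAULT,
    sat_min_pct: float = SAT_MIN_PCT_DEFAULT,
) -> MO2Series:
    """Re-evaluate QC flags: keep points with R^2 >= r2_min and final window
    saturation >= sat_min_pct."""
    if not (0 < r2_min <= 1):
        raise ValueError("r2_min must be in (0, 1]")
    if not (0 < sat_min_pct <= 100):
        raise ValueError("sat_min_pct must be in (0, 100]")
    data = series.data.copy()
    sat_ok = data["end_sat_pct"].isna() | (data["end_sat_pct"] >= sat_min_pct)
    data["qc_pass"] = (data["r2"] >= r2_min) & sat_ok
    return replace(series, data=data)


def _background_rate_at(background, t_min, t_span):
    """Background slope (mg L-1 h-1) at time t; scalar or linear before/after
    interpolation over the experiment duration."""
    if background is None:
        return 0.0
    if isinstance(background, BackgroundEstimate):
        b, a = background.rate_before, background.rate_after
        if b is None or a is None:
            return background.rate_mg_l_h
        lo, hi = t_span
        if hi == lo:
            return background.rate_mg_l_h
        w = (t_min - lo) / (hi - lo)
        return b + w * (a - b)
    return float(background)


def trace_to_mo2(
    trace: pd.DataFrame,
    chamber: ChamberSpec,
    config: CycleConfig | None = None,
    *,
    fish_id: str = "fish",
    r2_min: float = R2_MIN_DEFAULT,
    sat_min_pct: float = SAT_MIN_PCT_DEFAULT,
    background: "BackgroundEstimate | float | None" = None,
    start_clock_h: float | None = None,
) -> MO2Series:
    """Full trace-to-MO2 pipeline: extract cycles, fit slopes, subtract
    background on the slope scale, apply the MO2 equation and QC.

    Each cycle's MO2 is timestamped at the midpoint of its measurement
    window.  ``background`` may be a constant rate (mg L-1 h-1) or a
    :class:`BackgroundEstimate`, in which case the before/after rates are
    interpolated linearly over the experiment.
    """
    windows = extract_cycles(trace, config)
    fits = [fit_slope(w) for w in windows]
    if not fits:
        raise ValueError("trace contains no usable measurement windows")
    t_span = (fits[0].t_mid_min, fits[-1].t_mid_min)
    rows = []
    for f in fits:
        bg = _background_rate_at(background, f.t_mid_min, t_span)
        corrected = replace(f, slope_mg_l_h=f.slope_mg_l_h + bg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mo2 = compute_mo2(corrected, chamber)
        rows.append(
            {
                "time_min": f.t_mid_min,
                "mo2": mo2,
                "r2": f.r2,
                "end_sat_pct": f.end_sat_pct,
                "qc_pass": True,
            }
        )
    data = pd.DataFrame(rows)
    series = MO2Series(
        fish_id=fish_id,
        data=data,
        background_corrected=background is not None,
        start_clock_h=start_clock_h,
    )
    return qc_filter(series, r2_min=r2_min, sat_min_pct=sat_min_pct)
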