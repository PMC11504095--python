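"""Synthetic respirometry traces, MO2 trajectories and locomotor activity.

The generator emulates the five study conditions of a goldfish
intermittent-flow respirometry campaign (362.29 mL chambers, 17-25 g fish,
flush/wait/measure cycles, optode noise, a small microbial background):

* ``daily_rhythm``  - 48 h with a 24 h cosinor MO2 rhythm,
* ``feeding``       - postprandial (specific dynamic action) wave over a
  fasted baseline,
* ``acute_stress``  - three-segment piecewise-linear recovery after a 5 min
  chase,
* ``temperature``   - 0.1 degC min-1 ramp from 21 to 30 degC with a linear
  MO2-temperature response, a post-ramp peak and a slow decline,
* ``anesthetic_*``  - rise / fall / plateau recovery profiles for a control
  group and three anesthetics (2-phenoxyethanol, clove oil, MS-222).

Each preset carries the group-level parameter values reported for the
corresponding experiment, so noiseless simulation followed by the analysis
pipeline must return those values exactly: that round trip is the backbone
of the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .respirometry import ChamberSpec, CycleConfig, o2_solubility_mg_l

__all__ = [
    "TrajectorySpec",
    "TempProfile",
    "ScenarioPreset",
    "ActivitySeries",
    "FishRun",
    "make_trajectory",
    "trajectory_value",
    "synthesize_trace",
    "synthesize_activity",
    "simulate_scenario",
    "fasted_counterpart",
    "PRESETS",
]

TRAJECTORY_KINDS = (
    "constant",
    "cosinor",
    "piecewise_linear",
    "sda_wave",
    "temperature_ramp",
    "anesthetic_profile",
)

#: flow through the chamber during the open phase (L h-1)
FLUSH_FLOW_L_H = 300.0


# ---------------------------------------------------------------------------
# trajectory specification and evaluation


@dataclass(frozen=True)
class TrajectorySpec:
    """Noiseless ground-truth MO2 trajectory (mg O2 kg-1 h-1 vs minutes).

    ``params`` by kind:

    constant:           value
    cosinor:            mesor, amplitude, acrophase_h, period_h (24),
                        start_clock_h (clock time at t=0, default 0)
    piecewise_linear:   start, slopes (list, one per segment),
                        breakpoints_min (strictly increasing, interior)
    sda_wave:           baseline, peak_fraction, peak_time_min, end_min,
                        start_min (0) -- baseline*(1+w(t)) with w a tent
                        rising to peak_fraction at peak_time_min and back to
                        0 at end_min
    temperature_ramp:   start, per_degree, temp_rate_c_per_min (0.1),
                        ramp_end_min, peak, peak_min, decline_rate_per_min
    anesthetic_profile: maximum, increase_rate, time_to_maximum,
                        decrease_rate, stabilization_min
    """

    kind: str
    params: dict
    duration_min: float
    dt_min: float = 1.0

    def __post_init__(self):
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind: {self.kind!r}")
        if self.duration_min <= 0 or self.dt_min <= 0:
            raise ValueError("duration_min and dt_min must be positive")
        need = {
            "constant": ("value",),
            "cosinor": ("mesor", "amplitude", "acrophase_h"),
            "piecewise_linear": ("start", "slopes", "breakpoints_min"),
            "sda_wave": ("baseline", "peak_fraction", "peak_time_min", "end_min"),
            "temperature_ramp": (
                "start",
                "per_degree",
                "ramp_end_min",
                "peak",
                "peak_min",
                "decline_rate_per_min",
            ),
            "anesthetic_profile": (
                "maximum",
                "increase_rate",
                "time_to_maximum",
                "decrease_rate",
                "stabilization_min",
            ),
        }[self.kind]
        missing = [k for k in need if k not in self.params]
        if missing:
            raise ValueError(
                f"trajectory kind {self.kind!r} missing params: {missing}"
            )
        if self.kind == "piecewise_linear":
            bks = list(self.params["breakpoints_min"])
            if sorted(bks) != bks or len(set(bks)) != len(bks):
                raise ValueError("breakpoints must be strictly increasing")
            if bks and (bks[0] <= 0 or bks[-1] >= self.duration_min):
                raise ValueError("breakpoints must lie inside (0, duration)")
            if len(self.params["slopes"]) != len(bks) + 1:
                raise ValueError("need one slope per segment")
        if self.kind == "sda_wave" and self.params["peak_fraction"] < 0:
            raise ValueError("sda peak fraction must be >= 0")

    @property
    def time_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + self.dt_min / 2, self.dt_min)


def _eval_constant(t, p):
    return np.full_like(t, float(p["value"]))


def _eval_cosinor(t, p):
    period = p.get("period_h", 24.0)
    start_clock = p.get("start_clock_h", 0.0)
    omega = 2.0 * math.pi / period
    clock_h = start_clock + t / 60.0
    return p["mesor"] + p["amplitude"] * np.cos(
        omega * (clock_h - p["acrophase_h"])
    )


def _eval_piecewise(t, p):
    start = float(p["start"])
    slopes = list(p["slopes"])
    bks = list(p["breakpoints_min"])
    y = np.full_like(t, start)
    prev = 0.0
    for slope, b in zip(slopes, bks + [np.inf]):
        seg = np.clip(t, prev, b) - prev
        y = y + slope * seg
        prev = b
    return y


def _eval_sda(t, p):
    base = float(p["baseline"])
    frac = float(p["peak_fraction"])
    t0 = float(p.get("start_min", 0.0))
    tp = float(p["peak_time_min"])
    te = float(p["end_min"])
    w = np.zeros_like(t)
    rise = (t >= t0) & (t <= tp)
    fall = (t > tp) & (t <= te)
    if tp > t0:
        w[rise] = frac * (t[rise] - t0) / (tp - t0)
    else:
        w[rise] = frac
    if te > tp:
        w[fall] = frac * (te - t[fall]) / (te - tp)
    return base * (1.0 + w)


def _eval_temperature_ramp(t, p):
    start = float(p["start"])
    rate = float(p["per_degree"]) * float(p.get("temp_rate_c_per_min", 0.1))
    t_ramp = float(p["ramp_end_min"])
    peak = float(p["peak"])
    t_peak = float(p["peak_min"])
    decline = float(p["decline_rate_per_min"])
    ramp_top = start + rate * t_ramp
    y = np.empty_like(t)
    m1 = t <= t_ramp
    m2 = (t > t_ramp) & (t <= t_peak)
    m3 = t > t_peak
    y[m1] = start + rate * t[m1]
    post_slope = (peak - ramp_top) / (t_peak - t_ramp)
    y[m2] = ramp_top + post_slope * (t[m2] - t_ramp)
    y[m3] = peak - decline * (t[m3] - t_peak)
    return y


def _eval_anesthetic(t, p):
    mx = float(p["maximum"])
    inc = float(p["increase_rate"])
    t_max = float(p["time_to_maximum"])
    dec = float(p["decrease_rate"])
    t_stab = float(p["stabilization_min"])
    y = np.empty_like(t)
    m1 = t <= t_max
    m2 = (t > t_max) & (t <= t_stab)
    m3 = t > t_stab
    y[m1] = mx - inc * (t_max - t[m1])
    y[m2] = mx - dec * (t[m2] - t_max)
    y[m3] = mx - dec * (t_stab - t_max)
    return y


_EVAL = {
    "constant": _eval_constant,
    "cosinor": _eval_cosinor,
    "piecewise_linear": _eval_piecewise,
    "sda_wave": _eval_sda,
    "temperature_ramp": _eval_temperature_ramp,
    "anesthetic_profile": _eval_anesthetic,
}


def trajectory_value(spec: TrajectorySpec, t_min) -> np.ndarray:
    """Evaluate the trajectory's functional form at arbitrary minutes."""
    t = np.asarray(t_min, dtype=float)
    return _EVAL[spec.kind](t, spec.params)


def make_trajectory(spec: TrajectorySpec) -> pd.Series:
    """Deterministic, noiseless trajectory on the spec's minute grid."""
    t = spec.time_min
    return pd.Series(trajectory_value(spec, t), index=pd.Index(t, name="time_min"))


# ---------------------------------------------------------------------------
# temperature profiles


@dataclass(frozen=True)
class TempProfile:
    """Water temperature over the experiment: constant, or a linear ramp from
    ``start_c`` at ``rate_c_per_min`` capped at ``max_c``."""

    kind: str = "constant"
    start_c: float = 21.5
    rate_c_per_min: float = 0.0
    max_c: float | None = None

    def at(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.start_c)
        temp = self.start_c + self.rate_c_per_min * t
        if self.max_c is not None:
            temp = np.minimum(temp, self.max_c)
        return temp


# ---------------------------------------------------------------------------
# scenario presets


@dataclass(frozen=True)
class ScenarioPreset:
    """Generative parameters for one experiment."""

    name: str
    trajectory: TrajectorySpec
    n_fish: int
    mass_g_mean: float
    mass_g_sd: float
    chamber_volume_l: float = 0.36229
    cycle: CycleConfig = field(default_factory=CycleConfig)
    noise_sd: float = 0.02
    background_fraction: float = 0.005
    start_clock_h: float = 10.0
    temp_profile: TempProfile = field(default_factory=TempProfile)

    def __post_init__(self):
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if not (0 <= self.background_fraction < 0.05):
            raise ValueError("background_fraction must be in [0, 0.05)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def chamber_for(self, mass_g: float) -> ChamberSpec:
        return ChamberSpec(fish_mass_kg=mass_g / 1000.0, volume_l=self.chamber_volume_l)


def _build_presets() -> dict:
    presets = {}
    presets["daily_rhythm"] = ScenarioPreset(
        name="daily_rhythm",
        trajectory=TrajectorySpec(
            kind="cosinor",
            params={
                "mesor": 90.5,
                "amplitude": 16.9,
                "acrophase_h": 13.2,
                "period_h": 24.0,
                "start_clock_h": 10.0,
            },
            duration_min=2880.0,
        ),
        n_fish=8,
        mass_g_mean=17.1,
        mass_g_sd=3.1,
        start_clock_h=10.0,
    )
    presets["feeding"] = ScenarioPreset(
        name="feeding",
        trajectory=TrajectorySpec(
            kind="sda_wave",
            params={
                "baseline": 90.5,
                "peak_fraction": 0.35,
                "peak_time_min": 180.0,
                "end_min": 420.0,
                "start_min": 0.0,
            },
            duration_min=1440.0,
        ),
        n_fish=8,
        mass_g_mean=24.5,
        mass_g_sd=5.4,
        start_clock_h=10.5,
    )
    presets["acute_stress"] = ScenarioPreset(
        name="acute_stress",
        trajectory=TrajectorySpec(
            kind="piecewise_linear",
            params={
                "start": 180.0,
                "slopes": [1.26, -0.72, -0.0184],
                "breakpoints_min": [72.0, 185.0],
            },
            duration_min=360.0,
        ),
        n_fish=8,
        mass_g_mean=25.2,
        mass_g_sd=1.9,
        start_clock_h=10.5,
    )
    presets["temperature"] = ScenarioPreset(
        name="temperature",
        trajectory=TrajectorySpec(
            kind="temperature_ramp",
            params={
                "start": 112.0,
                "per_degree": 19.0,
                "temp_rate_c_per_min": 0.1,
                "ramp_end_min": 90.0,
                "peak": 352.0,
                "peak_min": 154.0,
                "decline_rate_per_min": 0.16,
            },
            duration_min=390.0,
        ),
        n_fish=8,
        mass_g_mean=20.9,
        mass_g_sd=0.9,
        start_clock_h=10.5,
        temp_profile=TempProfile("ramp", 21.0, 0.1, 30.0),
    )
    anesthetic_params = {
        "anesthetic_control": (353.0, 0.87, 37.5, 0.025, 74.3),
        "anesthetic_2pe": (415.0, 8.34, 27.0, 0.004, 139.6),
        "anesthetic_clove": (359.0, 3.06, 38.6, 0.007, 118.5),
        "anesthetic_ms222": (355.0, 0.99, 52.2, 0.042, 93.9),
    }
    for name, (mx, inc, t_max, dec, stab) in anesthetic_params.items():
        presets[name] = ScenarioPreset(
            name=name,
            trajectory=TrajectorySpec(
                kind="anesthetic_profile",
                params={
                    "maximum": mx,
                    "increase_rate": inc,
                    "time_to_maximum": t_max,
                    "decrease_rate": dec,
                    "stabilization_min": stab,
                },
                duration_min=240.0,
            ),
            n_fish=8,
            mass_g_mean=22.2,
            mass_g_sd=6.8,
            start_clock_h=10.5,
        )
    return presets


PRESETS = _build_presets()


def fasted_counterpart(preset: ScenarioPreset) -> ScenarioPreset:
    """Flat fasted baseline matching a feeding preset (same fish, no wave)."""
    if preset.trajectory.kind != "sda_wave":
        raise ValueError("fasted counterpart only defined for sda_wave presets")
    traj = TrajectorySpec(
        kind="constant",
        params={"value": preset.trajectory.params["baseline"]},
        duration_min=preset.trajectory.duration_min,
        dt_min=preset.trajectory.dt_min,
    )
    return replace(preset, trajectory=traj)


# ---------------------------------------------------------------------------
# trace synthesis


def synthesize_trace(
    trajectory: TrajectorySpec,
    chamber: ChamberSpec,
    cycle: CycleConfig | None = None,
    *,
    temp_profile: TempProfile | None = None,
    noise_sd: float = 0.0,
    background_fraction: float = 0.0,
    background_rate_mg_l_h: float | None = None,
    flow_l_h: float = FLUSH_FLOW_L_H,
    seed: int = 0,
    chamber_id: str = "ch1",
) -> pd.DataFrame:
    """Per-second O2 trace for one fish following the given MO2 trajectory.

    During closed phases (wait + measure) the concentration declines at
    MO2(t) * M / V_eff plus the background rate; during the flush it relaxes
    exponentially towards the saturated concentration with time constant
    V / flow.  Optode noise is Gaussian observation noise added to the true
    concentration.  The saturation column is derived from the freshwater
    solubility at the (possibly ramping) water temperature.

    When ``background_rate_mg_l_h`` is None, the background slope is the
    constant f/(1-f) times the mean fish-driven slope, i.e. the fraction f of
    the *total* measured slope, so that subtracting it recovers the fish
    exactly.
    """
    cycle = cycle or CycleConfig()
    temp_profile = temp_profile or TempProfile()
    n = int(round(trajectory.duration_min * 60.0))
    t_s = np.arange(n, dtype=float)
    t_min = t_s / 60.0
    temp = temp_profile.at(t_min)
    csat = o2_solubility_mg_l(temp)
    # rate over the step ending at each sample, taken at the step midpoint:
    # for (piecewise) linear MO2 this makes the window slope match the
    # trajectory at the window's mid-time exactly
    mo2 = trajectory_value(trajectory, t_min - 0.5 / 60.0)
    mo2[0] = trajectory_value(trajectory, 0.0)
    veff = chamber.effective_volume_l
    fish_rate_h = mo2 * chamber.fish_mass_kg / veff  # mg L-1 h-1
    if background_rate_mg_l_h is None:
        f = background_fraction
        background_rate_h = (
            f / (1.0 - f) * float(np.mean(fish_rate_h)) if f > 0 else 0.0
        )
    else:
        background_rate_h = float(background_rate_mg_l_h)
    rate_s = (fish_rate_h + background_rate_h) / 3600.0  # mg L-1 per second

    total = cycle.total_s
    idx_in_cycle = (t_s.astype(int)) % total
    cycle_index = (t_s.astype(int)) // total
    phase = np.where(
        idx_in_cycle < cycle.flush_s,
        "flush",
        np.where(idx_in_cycle < cycle.flush_s + cycle.wait_s, "wait", "measure"),
    )

    tau_s = chamber.volume_l / flow_l_h * 3600.0
    relax = math.exp(-1.0 / tau_s)
    o2 = np.empty(n)
    cur = float(csat[0])
    n_cycles = int(np.ceil(n / total))
    for c in range(n_cycles):
        s0 = c * total
        f_end = min(s0 + cycle.flush_s, n)
        for i in range(s0, f_end):
            cur = csat[i] + (cur - csat[i]) * relax
            o2[i] = cur
        c_end = min(s0 + total, n)
        if f_end < c_end:
            drop = np.cumsum(rate_s[f_end:c_end])
            o2[f_end:c_end] = cur - drop
            cur = float(o2[c_end - 1])
    if np.min(o2) < 0:
        raise ValueError("trajectory drives O2 below 0% saturation")

    rng = np.random.default_rng(seed)
    observed = o2 + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else o2
    return pd.DataFrame(
        {
            "time_s": t_s,
            "chamber_id": chamber_id,
            "o2_mg_per_l": observed,
            "o2_sat_pct": observed / csat * 100.0,
            "temp_c": temp,
            "phase": phase,
            "cycle_index": cycle_index,
        }
    )


# ---------------------------------------------------------------------------
# locomotor activity


@dataclass(frozen=True)
class ActivitySeries:
    """Locomotor activity in fixed 10-min bins over whole days.

    ``counts`` holds one value per bin; bin i starts at clock time
    ``start_clock_h + i * bin_min / 60`` hours (modulo 24 for clock time).
    """

    counts: np.ndarray
    n_days: int
    bin_min: int = 10
    start_clock_h: float = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("activity counts must be nonnegative")

    @property
    def times_h(self) -> np.ndarray:
        """Hours since midnight of day 0, one per bin start."""
        return self.start_clock_h + np.arange(len(self.counts)) * self.bin_min / 60.0

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_min))


def synthesize_activity(
    mesor: float,
    amplitude: float,
    acrophase_h: float,
    n_days: int,
    mode: str = "intensity",
    seed: int | None = None,
    bin_min: int = 10,
) -> ActivitySeries:
    """Sinusoidal 24 h activity intensity on the 10-min grid.

    ``intensity`` mode returns the noiseless rate; ``poisson`` mode draws
    counts with that intensity (requires amplitude <= mesor so the rate never
    goes negative).
    """
    if mode not in ("intensity", "poisson"):
        raise ValueError(f"unknown mode: {mode!r}")
    n_bins = n_days * int(round(24 * 60 / bin_min))
    t_h = np.arange(n_bins) * bin_min / 60.0
    rate = mesor + amplitude * np.cos(2 * math.pi / 24.0 * (t_h - acrophase_h))
    if mode == "intensity":
        return ActivitySeries(rate, n_days, bin_min)
    if amplitude > mesor:
        raise ValueError("poisson mode needs amplitude <= mesor (nonnegative rate)")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate).astype(float)
    return ActivitySeries(counts, n_days, bin_min)


# ---------------------------------------------------------------------------
# whole-scenario simulation


@dataclass(frozen=True)
class FishRun:
    """One simulated fish: identity, mass, chamber and raw trace."""

    fish_id: str
    mass_g: float
    chamber: ChamberSpec
    trace: pd.DataFrame


def simulate_scenario(
    preset: ScenarioPreset,
    seed: int,
    *,
    n_fish: int | None = None,
    noise_sd: float | None = None,
    background_fraction: float | None = None,
) -> list[FishRun]:
    """Simulate every fish of a scenario; fully reproducible from the seed.

    Fish masses are drawn once from N(mass_g_mean, mass_g_sd) truncated at
    5 g; each fish gets an independent optode-noise substream.
    """
    n_fish = preset.n_fish if n_fish is None else n_fish
    noise_sd = preset.noise_sd if noise_sd is None else noise_sd
    bg = (
        preset.background_fraction
        if background_fraction is None
        else background_fraction
    )
    rng = np.random.default_rng(seed)
    masses = rng.normal(preset.mass_g_mean, preset.mass_g_sd, n_fish)
    masses = np.clip(masses, 5.0, None)
    sub_seeds = rng.integers(0, 2**31 - 1, n_fish)
    runs = []
    for i in range(n_fish):
        chamber = preset.chamber_for(float(masses[i]))
        trace = synthesize_trace(
            preset.trajectory,
            chamber,
            preset.cycle,
            temp_profile=preset.temp_profile,
            noise_sd=noise_sd,
            background_fraction=bg,
            seed=int(sub_seeds[i]),
            chamber_id=f"ch{i + 1}",
        )
        runs.append(FishRun(f"fish_{i + 1:02d}", float(masses[i]), chamber, trace))
    return runs
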