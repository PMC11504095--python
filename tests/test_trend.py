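"""Segmented regression, mixed models, backward selection, contrasts,
two-way ANOVA and the paired t-test."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from respkit.synthetic_data import PRESETS, make_trajectory
from respkit.trend import (
    backward_select,
    fit_random_intercept,
    fit_segmented,
    holm_sidak,
    paired_t_test,
    pairwise_contrasts,
    stabilization_time,
    two_way_anova,
)


# ---------------------------------------------------------------------------
# segmented regression


def _brute_force_segmented(t, y, n_breaks, msp=5):
    """Independent exhaustive scan using plain loops and lstsq."""
    n = len(t)
    best = (np.inf, None)
    idx = range(msp - 1, n - msp)
    for combo in itertools.combinations(idx, n_breaks):
        if any(b - a < msp for a, b in zip(combo, combo[1:])):
            continue
        X = np.column_stack(
            [np.ones(n), t] + [np.maximum(t - t[i], 0.0) for i in combo]
        )
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if rss < best[0]:
            best = (rss, tuple(t[i] for i in combo))
    return best


def test_segmented_matches_brute_force_oracle(rng):
    t = np.arange(40.0)
    y = 2.0 + 0.5 * t + np.maximum(t - 22.0, 0) * -1.2 + rng.normal(0, 1.0, 40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_segmented(t, y, 1)
    rss, breaks = _brute_force_segmented(t, y, 1)
    assert fit.breakpoints_min[0] == breaks[0]
    assert fit.rss == pytest.approx(rss, rel=1e-10)


def test_segmented_two_break_matches_brute_force(rng):
    t = np.arange(60.0)
    y = (
        10.0
        + 1.0 * t
        - 1.8 * np.maximum(t - 18.0, 0)
        + 0.9 * np.maximum(t - 40.0, 0)
        + rng.normal(0, 0.8, 60)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_segmented(t, y, 2)
    rss, breaks = _brute_force_segmented(t, y, 2)
    assert tuple(fit.breakpoints_min) == breaks
    assert fit.rss == pytest.approx(rss, rel=1e-10)


def test_segmented_recovers_noiseless_three_segment_preset():
    traj = make_trajectory(PRESETS["acute_stress"].trajectory)
    fit = fit_segmented(traj.index.to_numpy(), traj.to_numpy(), 2)
    assert tuple(fit.breakpoints_min) == (72.0, 185.0)
    assert fit.segment_slopes == pytest.approx([1.26, -0.72, -0.0184], abs=1e-9)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)
    # continuity at the breaks
    for b in fit.breakpoints_min:
        assert fit.predict(b - 1e-9) == pytest.approx(fit.predict(b + 1e-9), abs=1e-6)


def test_segmented_degenerate_straight_line_warns():
    t = np.arange(30.0)
    y = 1.0 + 0.5 * t
    with pytest.warns(UserWarning, match="negligibly"):
        fit = fit_segmented(t, y, 1)
    assert fit.segment_slopes == pytest.approx([0.5, 0.5], abs=1e-8)


def test_segmented_infeasible_inputs():
    t = np.arange(8.0)
    with pytest.raises(ValueError, match="not enough points"):
        fit_segmented(t, t, 1)
    with pytest.raises(ValueError, match="must be 1, 2 or 3"):
        fit_segmented(np.arange(50.0), np.arange(50.0), 5)


def test_stabilization_time_rules():
    traj = make_trajectory(PRESETS["acute_stress"].trajectory)
    fit = fit_segmented(traj.index.to_numpy(), traj.to_numpy(), 2)
    # the third segment (slope -0.0184) is the first flat one
    assert stabilization_time(fit) == 185.0
    # monotone rising series never stabilizes
    t = np.arange(40.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rising = fit_segmented(t, 1.0 * t, 1)
        assert stabilization_time(rising) is None
        flat = fit_segmented(t, np.full_like(t, 3.0), 1)
    assert stabilization_time(flat) == 0.0


# ---------------------------------------------------------------------------
# random-intercept models


def _simulate_fish(rng, n_fish=10, n_per=8, slope=1.26, sd_fish=10.0, sd_eps=5.0):
    rows = []
    t = np.linspace(0, 70, n_per)
    for i in range(n_fish):
        a = rng.normal(0.0, sd_fish)
        for tt in t:
            rows.append(
                {
                    "fish_id": f"f{i}",
                    "time": tt,
                    "mo2": 180.0 + a + slope * tt + rng.normal(0, sd_eps),
                }
            )
    return pd.DataFrame(rows)


def test_random_intercept_reduces_to_ols_when_no_between_variance(rng):
    df = _simulate_fish(rng, sd_fish=0.0)
    fit = fit_random_intercept(df, "mo2", ["time"])
    ols_slope = stats.linregress(df["time"], df["mo2"]).slope
    # balanced design: the GLS fixed slope equals pooled OLS
    assert fit.fixed_coefficients["time"][0] == pytest.approx(ols_slope, abs=1e-8)


def test_random_intercept_parameter_recovery(rng):
    df = _simulate_fish(rng, n_fish=50, n_per=20, sd_fish=10.0, sd_eps=5.0)
    fit = fit_random_intercept(df, "mo2", ["time"])
    est, se, _ = fit.fixed_coefficients["time"]
    assert abs(est - 1.26) < 2 * se
    assert fit.var_between == pytest.approx(100.0, rel=0.40)
    assert fit.n_fish == 50


def test_random_intercept_preconditions(rng):
    df = _simulate_fish(rng, n_fish=2, n_per=2)
    # collinear covariate duplicating the intercept
    df["dup"] = 1.0
    with pytest.raises(ValueError, match="singular"):
        fit_random_intercept(df, "mo2", ["time", "dup"])
    one = df[df["fish_id"] == "f0"]
    with pytest.raises(ValueError, match="2 fish"):
        fit_random_intercept(one, "mo2", ["time"])


def test_backward_select_retains_strong_slope_and_drops_null(rng):
    strong = _simulate_fish(rng, n_fish=12, n_per=10, slope=1.26)
    fit, log = backward_select(strong, "mo2", ["time"])
    assert "time" in fit.fixed_coefficients

    null = _simulate_fish(rng, n_fish=12, n_per=10, slope=0.0)
    null["noise_cov"] = rng.normal(size=len(null))
    fit2, log2 = backward_select(null, "mo2", ["noise_cov"])
    assert "noise_cov" not in fit2.fixed_coefficients
    assert any("noise_cov" in line for line in log2)


def test_backward_select_null_drop_frequency(rng):
    """A truly zero slope is dropped about (1 - alpha) of the time."""
    drops = 0
    n_rep = 40
    for _ in range(n_rep):
        df = _simulate_fish(rng, n_fish=8, n_per=6, slope=0.0)
        fit, _ = backward_select(df, "mo2", ["time"])
        drops += "time" not in fit.fixed_coefficients
    assert drops / n_rep > 0.8


def test_backward_select_intercept_only_unchanged(rng):
    df = _simulate_fish(rng, n_fish=5, n_per=5)
    fit, log = backward_select(df, "mo2", [])
    assert list(fit.fixed_coefficients) == ["const"]


# ---------------------------------------------------------------------------
# contrasts and multiplicity


def test_pairwise_contrasts_two_groups_adjusted_equals_raw():
    df = pairwise_contrasts({"a": (1.0, 0.5), "b": (2.0, 0.5)})
    assert len(df) == 1
    assert df["p_adjusted"].iloc[0] == pytest.approx(df["p_raw"].iloc[0])


def test_pairwise_contrasts_deviant_group_has_smallest_p():
    groups = {"g1": (1.0, 0.2), "g2": (1.05, 0.2), "g3": (0.95, 0.2), "g4": (5.0, 0.2)}
    df = pairwise_contrasts(groups)
    df["has_g4"] = (df["group_a"] == "g4") | (df["group_b"] == "g4")
    worst_g4 = df[df["has_g4"]]["p_adjusted"].max()
    best_other = df[~df["has_g4"]]["p_adjusted"].min()
    assert worst_g4 < best_other


def test_pairwise_contrasts_null_groups_large_p(rng):
    means = rng.normal(10.0, 0.05, 4)
    groups = {f"g{i}": (float(m), 1.0) for i, m in enumerate(means)}
    df = pairwise_contrasts(groups)
    assert (df["p_adjusted"] > 0.5).all()


def test_pairwise_contrasts_needs_two_groups():
    with pytest.raises(ValueError):
        pairwise_contrasts({"a": (1.0, 0.5)})


@given(
    ps=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_adjustment_monotone_and_never_lowers(ps):
    groups = {f"g{i}": (0.0, 1.0) for i in range(3)}
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(np.asarray(ps), method="fdr_bh")[1]
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# ANOVA, Holm-Sidak, paired t


def _two_by_two():
    rows = []
    means = {("d1", "photo"): 100.0, ("d1", "scoto"): 80.0,
             ("d2", "photo"): 90.0, ("d2", "scoto"): 78.0}
    deltas = [-2.0, 1.0, 3.0, -2.0]
    for (day, phase), m in means.items():
        for d in deltas:
            rows.append({"day": day, "phase": phase, "mo2": m + d})
    return pd.DataFrame(rows)


def test_two_way_anova_matches_hand_sums_of_squares():
    df = _two_by_two()
    table, pw = two_way_anova(df, "mo2", "day", "phase")
    # hand computation (balanced 2x2, 4 reps per cell)
    y = df["mo2"].to_numpy()
    grand = y.mean()
    ss_a = sum(
        len(g) * (g["mo2"].mean() - grand) ** 2 for _, g in df.groupby("day")
    )
    ss_b = sum(
        len(g) * (g["mo2"].mean() - grand) ** 2 for _, g in df.groupby("phase")
    )
    cell_means = df.groupby(["day", "phase"])["mo2"].transform("mean")
    ss_resid = float(np.sum((y - cell_means) ** 2))
    assert table.loc["day", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
    assert table.loc["phase", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
    assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_resid, rel=1e-9)
    assert {"day", "phase"} == set(pw["family"])
    assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-12).all()


def test_two_way_anova_identical_cells_f_near_zero(rng):
    rows = []
    for day in ("d1", "d2"):
        for phase in ("photo", "scoto"):
            for r in range(5):
                rows.append({"day": day, "phase": phase, "mo2": [1.0, 2.0, 3.0, 4.0, 5.0][r]})
    df = pd.DataFrame(rows)
    table, _ = two_way_anova(df, "mo2", "day", "phase")
    assert table.loc["day", "F"] == pytest.approx(0.0, abs=1e-9)
    assert table.loc["phase", "F"] == pytest.approx(0.0, abs=1e-9)


def test_two_way_anova_rejects_empty_cell():
    df = _two_by_two()
    df = df[~((df["day"] == "d2") & (df["phase"] == "scoto"))]
    with pytest.raises(ValueError, match="empty cell"):
        two_way_anova(df, "mo2", "day", "phase")


def test_holm_sidak_formula():
    adj = holm_sidak([0.01, 0.04])
    assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 2)
    assert adj[1] == pytest.approx(0.04)


def test_paired_t_identical_samples():
    res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0
    assert res.p == 1.0
    assert res.df == 2


def test_paired_t_hand_value():
    res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-9)
    assert res.df == 2
    assert res.p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), 2), rel=1e-9)


def test_paired_t_is_order_sensitive():
    x = np.array([1.0, 5.0, 9.0, 4.0])
    y = np.array([2.0, 4.0, 8.0, 1.0])
    a = paired_t_test(x, y)
    b = paired_t_test(x, y[::-1])
    assert a.t != b.t


def test_paired_t_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="equal length"):
        paired_t_test([1.0, 2.0], [1.0])
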