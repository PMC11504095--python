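"""Time-course inference: segmented regression, mixed models, contrasts.

Challenge experiments (handling stress, warming, anesthetic recovery) produce
MO2 time courses with distinct phases.  The tools here mirror the standard
analysis chain for such data:

* continuous piecewise-linear (segmented) regression with the breakpoints
  found by exhaustive search over the observed time grid, which makes the
  fit the exact least-squares minimizer on that grid;
* random-intercept linear mixed models (REML) with fish as the grouping
  factor, plus backward stepwise elimination of non-significant fixed terms;
* pairwise Wald contrasts with Benjamini-Hochberg (or Holm-Sidak)
  adjustment, a type-II two-way ANOVA with Holm-Sidak pairwise tests, and
  the paired Student t-test.
"""

from __future__ import annotations

import itertools
import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SegmentedFit",
    "MixedFit",
    "fit_segmented",
    "fit_random_intercept",
    "backward_select",
    "pairwise_contrasts",
    "stabilization_time",
    "two_way_anova",
    "holm_sidak",
    "paired_t_test",
    "PairedTResult",
]

#: a following-segment slope within this tolerance of zero counts as flat
STABLE_SLOPE_TOL = 0.05


# ---------------------------------------------------------------------------
# segmented (breakpoint) regression


@dataclass(frozen=True)
class SegmentedFit:
    """Continuous piecewise-linear least-squares fit.

    ``segment_slopes[j]`` and ``segment_intercepts[j]`` describe segment j as
    y = intercept_j + slope_j * t; continuity at the breakpoints is built
    into the basis.  Slopes are in response units per minute.
    """

    breakpoints_min: np.ndarray
    segment_slopes: np.ndarray
    segment_intercepts: np.ndarray
    slope_se: np.ndarray
    rss: float
    n: int

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints_min)

    def predict(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        y = self.segment_intercepts[0] + self.segment_slopes[0] * t
        scalar = y.ndim == 0
        y = np.atleast_1d(y)
        tt = np.atleast_1d(t)
        for j, b in enumerate(self.breakpoints_min):
            m = tt > b
            y[m] = self.segment_intercepts[j + 1] + self.segment_slopes[j + 1] * tt[m]
        return float(y[0]) if scalar else y


def _hinge_design(t: np.ndarray, breaks) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for b in breaks:
        cols.append(np.maximum(t - b, 0.0))
    return np.column_stack(cols)


def _rss_beta(X: np.ndarray, y: np.ndarray):
    G = X.T @ X
    c = X.T @ y
    try:
        beta = np.linalg.solve(G, c)
    except np.linalg.LinAlgError:
        return np.inf, None
    r = y - X @ beta
    return float(r @ r), beta


def fit_segmented(
    time_min,
    y,
    n_breakpoints: int,
    min_segment_points: int = 5,
) -> SegmentedFit:
    """Exact continuous piecewise-linear least squares with grid breakpoints.

    Candidate breakpoints are the observed time values; every placement
    leaving at least ``min_segment_points`` points per segment is evaluated
    and the RSS minimizer returned (earliest breakpoints win ties).  On
    noiseless piecewise-linear input whose true breaks lie on the grid the
    fit is exact.
    """
    if n_breakpoints not in (1, 2, 3):
        raise ValueError("n_breakpoints must be 1, 2 or 3")
    t = np.asarray(time_min, dtype=float)
    v = np.asarray(y, dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    n = len(t)
    if n < (n_breakpoints + 1) * min_segment_points:
        raise ValueError("not enough points for the requested segments")

    # candidate break indices: break at t[i] puts points 0..i in the left
    # segment
    lo = min_segment_points - 1
    hi = n - 1 - min_segment_points
    candidates = [i for i in range(lo, hi + 1)]
    best = (np.inf, None)
    for combo in itertools.combinations(candidates, n_breakpoints):
        ok = all(
            combo[k + 1] - combo[k] >= min_segment_points
            for k in range(len(combo) - 1)
        )
        if not ok:
            continue
        breaks = t[list(combo)]
        if len(np.unique(breaks)) < n_breakpoints:
            continue
        rss, _ = _rss_beta(_hinge_design(t, breaks), v)
        if rss < best[0]:
            best = (rss, breaks)
    if best[1] is None:
        raise ValueError("no feasible breakpoint placement")
    rss, breaks = best

    X = _hinge_design(t, breaks)
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    rss = float(resid @ resid)
    p = X.shape[1]
    dof = n - p
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.pinv(X.T @ X)

    # cumulative slopes and their SEs
    slopes, slope_se = [], []
    for j in range(n_breakpoints + 1):
        a = np.zeros(p)
        a[1 : 2 + j] = 1.0
        slopes.append(float(a @ beta))
        slope_se.append(float(np.sqrt(max(a @ cov @ a, 0.0))))
    intercepts = [float(beta[0])]
    for j, b in enumerate(breaks):
        intercepts.append(intercepts[-1] + (slopes[j] - slopes[j + 1]) * b)

    rss_line, _ = _rss_beta(np.column_stack([np.ones(n), t]), v)
    if rss_line - rss <= 1e-10 * max(rss_line, 1.0):
        warnings.warn("breakpoints improve the fit negligibly (degenerate)")

    return SegmentedFit(
        breakpoints_min=np.asarray(breaks, dtype=float),
        segment_slopes=np.asarray(slopes),
        segment_intercepts=np.asarray(intercepts),
        slope_se=np.asarray(slope_se),
        rss=rss,
        n=n,
    )


def stabilization_time(fit: SegmentedFit, slope_tol: float = STABLE_SLOPE_TOL):
    """Time (min) at which the fitted profile becomes flat.

    Returns 0 when the first segment is already flat, the first breakpoint
    whose following segment slope is within ``slope_tol`` of zero, or None
    when no segment flattens out.
    """
    if abs(fit.segment_slopes[0]) < slope_tol:
        return 0.0
    for j, b in enumerate(fit.breakpoints_min):
        if abs(fit.segment_slopes[j + 1]) < slope_tol:
            return float(b)
    return None


# ---------------------------------------------------------------------------
# random-intercept mixed models


@dataclass(frozen=True)
class MixedFit:
    """Random-intercept model fit (REML).

    ``fixed_coefficients`` maps term name to (estimate, SE, Wald p).
    ``var_between`` is the between-fish (random intercept) variance and
    ``var_resid`` the residual variance; var_between = 0 means the model
    collapsed to OLS.
    """

    fixed_coefficients: dict
    var_between: float
    var_resid: float
    n_fish: int
    reml_loglik: float
    method: str = "REML"


def _design(data: pd.DataFrame, fixed):
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for term in fixed:
        X[term] = data[term].to_numpy(dtype=float)
    return X


def fit_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed,
    group: str = "fish_id",
) -> MixedFit:
    """REML random-intercept fit with the named fixed covariates.

    Requires at least 2 groups with at least 2 observations each and a
    full-rank fixed design.  The between-group variance is clipped at the
    zero boundary by the optimizer itself.
    """
    fixed = list(fixed)
    counts = data.groupby(group).size()
    if len(counts) < 2:
        raise ValueError("need at least 2 fish")
    if (counts < 2).any():
        raise ValueError("need at least 2 observations per fish")
    X = _design(data, fixed)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design")
    y = data[response].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=data[group])
        res = model.fit(reml=True)
    names = list(X.columns)
    coefs = {
        name: (
            float(res.fe_params.iloc[i]),
            float(res.bse_fe.iloc[i]),
            float(res.pvalues.iloc[i]),
        )
        for i, name in enumerate(names)
    }
    return MixedFit(
        fixed_coefficients=coefs,
        var_between=float(res.cov_re.iloc[0, 0]),
        var_resid=float(res.scale),
        n_fish=int(len(counts)),
        reml_loglik=float(res.llf),
    )


def _ols_as_mixedfit(data, response, fixed, n_fish) -> MixedFit:
    X = _design(data, fixed)
    y = data[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    coefs = {
        name: (
            float(res.params.iloc[i]),
            float(res.bse.iloc[i]),
            float(res.pvalues.iloc[i]),
        )
        for i, name in enumerate(X.columns)
    }
    return MixedFit(
        fixed_coefficients=coefs,
        var_between=0.0,
        var_resid=float(res.mse_resid),
        n_fish=n_fish,
        reml_loglik=float(res.llf),
        method="OLS",
    )


def backward_select(
    data: pd.DataFrame,
    response: str,
    fixed,
    group: str = "fish_id",
    alpha: float = 0.05,
):
    """Backward stepwise reduction of a random-intercept model.

    Repeatedly drops the fixed term with the largest Wald p-value above
    ``alpha`` and refits until every remaining term is significant (the
    intercept is never dropped; an intercept-only model is a legal outcome).
    The random intercept is dropped only when its variance estimate hits the
    zero boundary, after which refits use OLS.  Returns (fit, audit_log).
    """
    fixed = list(fixed)
    n_fish = data[group].nunique()
    log = []
    use_random = True
    while True:
        if use_random:
            fit = fit_random_intercept(data, response, fixed, group)
            if fit.var_between <= 1e-10 * max(fit.var_resid, 1e-12):
                use_random = False
                log.append("dropped random intercept (variance estimate 0)")
                fit = _ols_as_mixedfit(data, response, fixed, n_fish)
        else:
            fit = _ols_as_mixedfit(data, response, fixed, n_fish)
        droppable = {
            k: v[2] for k, v in fit.fixed_coefficients.items() if k != "const"
        }
        if not droppable:
            break
        worst, p = max(droppable.items(), key=lambda kv: kv[1])
        if not np.isnan(p) and p <= alpha:
            break
        fixed.remove(worst)
        log.append(f"dropped fixed term {worst!r} (p={p:.4g})")
    return fit, log


# ---------------------------------------------------------------------------
# contrasts and classical tests


def pairwise_contrasts(group_stats, adjust: str = "BH") -> pd.DataFrame:
    """All pairwise Wald contrasts between group-level estimates.

    ``group_stats`` is a mapping label -> (estimate, se) or a DataFrame with
    columns group, estimate, se.  P-values come from the normal reference
    and are adjusted across the pair set with Benjamini-Hochberg ("BH") or
    "holm-sidak".
    """
    if isinstance(group_stats, pd.DataFrame):
        group_stats = {
            str(r["group"]): (float(r["estimate"]), float(r["se"]))
            for _, r in group_stats.iterrows()
        }
    labels = list(group_stats)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ea, sa = group_stats[a]
        eb, sb = group_stats[b]
        est = ea - eb
        se = float(np.hypot(sa, sb))
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        rows.append({"group_a": a, "group_b": b, "estimate": est, "se": se, "p_raw": p})
    df = pd.DataFrame(rows)
    method = {"BH": "fdr_bh", "holm-sidak": "holm-sidak"}[adjust]
    df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method=method)[1]
    df["method"] = adjust
    return df


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm-sidak")[1]


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str, factor_b: str):
    """Type-II two-way ANOVA with interaction, plus Holm-Sidak pairwise tests.

    Pairwise comparisons use the model's residual mean square; each factor's
    comparisons within every level of the other factor form one adjustment
    family.  Returns (anova_table, pairwise_table).
    """
    cells = data.groupby([factor_a, factor_b]).size().unstack(fill_value=0)
    if (cells.to_numpy() == 0).any():
        raise ValueError("empty cell in the two-factor layout")
    if (cells.to_numpy() < 2).any():
        raise ValueError("need at least 2 replicates per cell")
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"]

    mse = model.mse_resid
    dof = int(model.df_resid)
    rows = []
    for fac, other in ((factor_a, factor_b), (factor_b, factor_a)):
        fam = []
        for lvl in sorted(data[other].unique()):
            sub = data[data[other] == lvl]
            means = sub.groupby(fac)[response].agg(["mean", "size"])
            for la, lb in itertools.combinations(means.index, 2):
                m1, n1 = means.loc[la]
                m2, n2 = means.loc[lb]
                se = np.sqrt(mse * (1 / n1 + 1 / n2))
                tstat = (m1 - m2) / se
                p = float(2 * stats.t.sf(abs(tstat), dof))
                fam.append(
                    {
                        "family": fac,
                        "within": f"{other}={lvl}",
                        "level_a": la,
                        "level_b": lb,
                        "estimate": float(m1 - m2),
                        "t": float(tstat),
                        "p_raw": p,
                    }
                )
        if fam:
            adj = holm_sidak([r["p_raw"] for r in fam])
            for r, pa in zip(fam, adj):
                r["p_adjusted"] = float(pa)
            rows.extend(fam)
    return table, pd.DataFrame(rows)


PairedTResult = namedtuple("PairedTResult", ["t", "df", "p"])


def paired_t_test(x, y) -> PairedTResult:
    """Paired Student t-test on the per-pair differences."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedTResult(0.0, n - 1, 1.0)
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue))
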