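"""Dose-outcome statistics: dose-response, TCP, toxicity, survival.

The dose-response model is a plateaued exponential,

    dV% = floor + (cap - floor) * exp(-rate * AD),

fit by least squares with a profiled linear solve (for a fixed rate the
model is linear in floor and cap), and patient-level cluster-bootstrap
uncertainty.  Tumor control probability is a binary logistic regression of
the controlled flag on total AD, with a Firth (Jeffreys-prior) fallback
under separation.  Toxicity uses Spearman rank correlation between organ
cumulative dose and percent lab change (exact permutation p for small n),
and paired t tests on baseline vs follow-up labs.  Survival compares
groups dichotomized at the cohort median of a dose index with Kaplan-Meier
curves, a Cox proportional-hazards ratio (Efron ties) and a log-rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit


class StatsError(ValueError):
    """Invalid statistical-analysis input."""


# --- plateaued dose-response fit --------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    """Plateaued-exponential fit with cluster-bootstrap uncertainty."""

    floor: float
    cap: float
    rate: float
    residual_ss: float
    n: int
    ci: dict = field(default_factory=dict)       # param -> (lo, hi), 95% percentile
    association_rho: float = float("nan")        # Spearman of AD vs dV%
    association_p: float = float("nan")
    n_boot: int = 0
    seed: int | None = None

    def predict(self, ad):
        ad = np.asarray(ad, dtype=float)
        return self.floor + (self.cap - self.floor) * np.exp(-self.rate * ad)


def _profile_solve(ad: np.ndarray, y: np.ndarray, rate: float):
    """For a fixed rate, closed-form LSQ over (floor, cap). Returns (floor, cap, ss)."""
    x = np.exp(-rate * ad)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx < 1e-14:
        resid = y - ym
        return ym, ym, float(resid @ resid)
    b = float(((x - xm) * (y - ym)).sum()) / sxx  # cap - floor
    a = ym - b * xm                               # floor
    resid = y - (a + b * x)
    return a, a + b, float(resid @ resid)


def fit_plateau(ad, y, rate_bounds=(1e-4, 0.5), n_grid: int = 64):
    """Least-squares plateaued exponential via grid + golden-section refine.

    Returns (floor, cap, rate, residual_ss).
    """
    ad = np.asarray(ad, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(ad) <= 0:
        raise StatsError("degenerate dose spread: all AD values identical")
    lo, hi = rate_bounds
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    # vectorised profile SS over the rate grid
    X = np.exp(-np.outer(grid, ad))              # n_grid x n
    xm = X.mean(axis=1, keepdims=True)
    ym = y.mean()
    dx = X - xm
    sxx = (dx * dx).sum(axis=1)
    sxy = dx @ (y - ym)
    safe = sxx > 1e-14
    b = np.where(safe, sxy / np.where(safe, sxx, 1.0), 0.0)
    ss = ((y - ym) ** 2).sum() - b * sxy
    k = int(np.argmin(ss))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, n_grid - 1)]
    if bhi > blo:
        res = minimize_scalar(
            lambda r: _profile_solve(ad, y, r)[2],
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rate = float(res.x)
    else:
        rate = float(grid[k])
    floor, cap, ssr = _profile_solve(ad, y, rate)
    if ssr > ss[k] + 1e-12:  # refine never worse than the grid optimum
        rate = float(grid[k])
        floor, cap, ssr = _profile_solve(ad, y, rate)
    return float(floor), float(cap), rate, float(ssr)


def fit_dose_response(
    total_ad,
    delta_v_pct,
    patient_ids,
    n_boot: int = 1000,
    seed: int = 0,
    rate_bounds=(1e-4, 0.5),
    fixed_rate: float | None = None,
) -> DoseResponseFit:
    """Fit dV% ~ floor + (cap-floor)*exp(-rate*AD) with cluster bootstrap.

    Standard errors come from resampling whole patients with replacement
    (>= 1000 resamples recommended); the monotone association is summarised
    by the Spearman correlation of AD with dV%.  ``fixed_rate=0`` collapses
    the model to the constant mean.
    """
    ad = np.asarray(total_ad, dtype=float)
    y = np.asarray(delta_v_pct, dtype=float)
    pid = np.asarray(patient_ids)
    mask = ~(np.isnan(ad) | np.isnan(y))
    ad, y, pid = ad[mask], y[mask], pid[mask]
    if ad.size < 10:
        raise StatsError("need >= 10 lesions with dose and response")
    if np.ptp(ad) <= 0:
        raise StatsError("degenerate dose spread: all AD values identical")

    if fixed_rate is not None:
        if fixed_rate == 0:
            m = float(y.mean())
            resid = y - m
            floor, cap, rate, ssr = m, m, 0.0, float(resid @ resid)
        else:
            floor, cap, ssr = _profile_solve(ad, y, fixed_rate)
            rate = float(fixed_rate)
    else:
        floor, cap, rate, ssr = fit_plateau(ad, y, rate_bounds)

    rho, p = stats.spearmanr(ad, y)

    ci: dict = {}
    if n_boot > 0 and fixed_rate is None:
        rng = np.random.default_rng(seed)
        clusters = [np.flatnonzero(pid == u) for u in pd.unique(pid)]
        k = len(clusters)
        boots = np.empty((n_boot, 3))
        kept = 0
        for _ in range(n_boot):
            pick = rng.integers(0, k, size=k)
            idx = np.concatenate([clusters[j] for j in pick])
            if np.ptp(ad[idx]) <= 0:
                continue
            f, c, r, _ = fit_plateau(ad[idx], y[idx], rate_bounds)
            boots[kept] = (f, c, r)
            kept += 1
        boots = boots[:kept]
        for name, col in zip(("floor", "cap", "rate"), boots.T):
            lo_q, hi_q = np.percentile(col, [2.5, 97.5])
            ci[name] = (float(lo_q), float(hi_q))

    return DoseResponseFit(
        floor=floor, cap=cap, rate=rate, residual_ss=ssr, n=int(ad.size),
        ci=ci, association_rho=float(rho), association_p=float(p),
        n_boot=n_boot, seed=seed,
    )


# --- tumor control probability (logistic) -----------------------------------

@dataclass(frozen=True)
class TCPModel:
    intercept: float
    slope: float                 # per Gy
    fitted_probs: np.ndarray
    converged: bool
    separation: bool
    method: str                  # 'mle' or 'firth'
    se: tuple = (float("nan"), float("nan"))
    d50_gy: float | None = None  # dose at 50% control probability
    d90_gy: float | None = None

    def predict(self, ad):
        return expit(self.intercept + self.slope * np.asarray(ad, dtype=float))


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys prior) by Newton iteration."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat-matrix diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if float(np.abs(step).max()) < tol:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, np.sqrt(np.diag(cov))


def fit_tcp(total_ad, controlled, allow_penalized: bool = True) -> TCPModel:
    """Logistic regression of the controlled flag on total AD.

    Separation (including a single outcome class) triggers a Firth-penalized
    refit and sets the separation flag; with ``allow_penalized=False`` it is
    an error instead.  Reports the doses at 50% and 90% control probability
    when the slope is positive.
    """
    ad = np.asarray(total_ad, dtype=float)
    y = np.asarray(controlled, dtype=float)
    mask = ~(np.isnan(ad) | np.isnan(y))
    ad, y = ad[mask], y[mask]
    if ad.size < 10:
        raise StatsError("need >= 10 lesions for the TCP fit")
    X = np.column_stack([np.ones_like(ad), ad])

    one_class = len(np.unique(y)) < 2
    separation = one_class
    beta = se = None
    converged = False
    method = "mle"
    if not one_class:
        import statsmodels.api as sm

        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
            # runaway coefficients signal quasi-separation
            if not converged or np.any(np.abs(beta) > 1e3) or np.any(~np.isfinite(se)):
                separation = True
        except Exception:
            separation = True

    if separation:
        if not allow_penalized:
            raise StatsError("separation detected and penalized mode disabled")
        beta, se = _firth_logistic(X, y)
        converged = True
        method = "firth"

    intercept, slope = float(beta[0]), float(beta[1])
    d50 = d90 = None
    if slope > 0:
        d50 = -intercept / slope
        d90 = (math.log(0.9 / 0.1) - intercept) / slope
    return TCPModel(
        intercept=intercept, slope=slope, fitted_probs=expit(X @ beta),
        converged=converged, separation=separation, method=method,
        se=(float(se[0]), float(se[1])), d50_gy=d50, d90_gy=d90,
    )


# --- Spearman toxicity correlations -----------------------------------------

def spearman(x, y, exact_max_n: int = 9):
    """Spearman rho with exact-permutation p for n <= exact_max_n.

    Larger samples use the usual large-sample approximation
    (scipy.stats.spearmanr).  Constant columns are an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise StatsError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant column: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxs = (rx - rx.mean()) / rx.std()
        rys = (ry - ry.mean()) / ry.std()
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (rys[perms] * rxs).sum(axis=1) / n
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def correlate_toxicity(pairs: pd.DataFrame, exact_max_n: int = 9) -> pd.DataFrame:
    """Spearman correlation per (organ, lab) pair.

    ``pairs`` holds one row per patient-organ-lab with columns organ, lab,
    cum_ad_gy, pct_change.  Returns organ, lab, rho, p, n.
    """
    rows = []
    for (organ, lab), g in pairs.groupby(["organ", "lab"], sort=True):
        g = g.dropna(subset=["cum_ad_gy", "pct_change"])
        if len(g) < 3:
            raise StatsError(f"{organ}/{lab}: need >= 3 paired observations")
        rho, p = spearman(g["cum_ad_gy"], g["pct_change"], exact_max_n)
        rows.append({"organ": organ, "lab": lab, "rho": rho, "p": p, "n": len(g)})
    return pd.DataFrame(rows, columns=["organ", "lab", "rho", "p", "n"])


def loess_trend(x, y, frac: float = 0.6, n_grid: int = 50) -> pd.DataFrame:
    """LOWESS-smoothed trend on an even grid, for dose-toxicity plots."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sm_xy = lowess(y, x, frac=frac, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.interp(grid, sm_xy[:, 0], sm_xy[:, 1])
    return pd.DataFrame({"x": grid, "fitted": fitted})


# --- paired lab test --------------------------------------------------------

def paired_lab_test(baseline, followup) -> dict:
    """Paired two-sided t test on (follow-up - baseline) differences.

    All-zero differences give t = 0, p = 1 (continuity limit); zero variance
    around a nonzero mean difference leaves p undefined and is an error.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.size != f.size:
        raise StatsError("baseline and follow-up must be paired (equal length)")
    if b.size < 2:
        raise StatsError("paired t test needs n >= 2")
    d = f - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            t_stat, p = 0.0, 1.0
        else:
            raise StatsError("zero variance of nonzero differences: p undefined")
    else:
        t_stat, p = stats.ttest_rel(f, b)
    return {
        "n": int(b.size),
        "baseline_mean": float(b.mean()),
        "baseline_sd": float(b.std(ddof=1)),
        "followup_mean": float(f.mean()),
        "followup_sd": float(f.std(ddof=1)),
        "mean_diff": float(d.mean()),
        "t": float(t_stat),
        "p": float(p),
    }


# --- median-dichotomized survival -------------------------------------------

@dataclass(frozen=True)
class SurvivalComparison:
    endpoint: str
    covariate: str
    median_cut: float
    n_high: int
    n_low: int
    km_curves: pd.DataFrame          # group, time, survival, ci_lower, ci_upper
    median_high: float | None        # None = not reached
    median_low: float | None
    hazard_ratio: float | None       # high vs low; None = non-estimable
    hr_ci: tuple | None
    hr_p: float | None
    logrank_p: float
    hr_estimable: bool


def survival_by_median(
    covariate,
    times,
    events,
    endpoint: str = "survival",
    covariate_name: str = "dose_index",
) -> SurvivalComparison:
    """KM / Cox / log-rank comparison of groups split at the covariate median.

    Values >= the median go to the high group.  The Cox model uses lifelines'
    Efron tie handling; a group with no events leaves the hazard ratio
    flagged non-estimable while the KM curves are still returned.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    cov = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (cov.size == t.size == e.size):
        raise StatsError("covariate, times and events must align")
    cut = float(np.median(cov))
    high = cov >= cut
    if high.sum() < 2 or (~high).sum() < 2:
        raise StatsError("need >= 2 patients per group after dichotomization")

    curves = []
    medians = {}
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter(label=label)
        km.fit(t[mask], e[mask])
        sf = km.survival_function_
        ci = km.confidence_interval_
        curves.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": sf.index.to_numpy(),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "ci_lower": ci.iloc[:, 0].to_numpy(),
                    "ci_upper": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
        med = km.median_survival_time_
        medians[label] = None if np.isinf(med) else float(med)
    km_curves = pd.concat(curves, ignore_index=True)

    lr = logrank_test(t[high], t[~high], e[high], e[~high])

    hr = hr_ci = hr_p = None
    estimable = e[high].sum() > 0 and e[~high].sum() > 0
    if estimable:
        df = pd.DataFrame({"time": t, "event": e, "high": high.astype(int)})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["high"]
            hr = float(np.exp(s["coef"]))
            hr_ci = (float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"])))
            hr_p = float(s["p"])
        except Exception:
            estimable = False

    return SurvivalComparison(
        endpoint=endpoint,
        covariate=covariate_name,
        median_cut=cut,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        km_curves=km_curves,
        median_high=medians["high"],
        median_low=medians["low"],
        hazard_ratio=hr,
        hr_ci=hr_ci,
        hr_p=hr_p,
        logrank_p=float(lr.p_value),
        hr_estimable=bool(estimable),
    )
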