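"""Survival statistics: Kaplan–Meier, log-rank, maximally selected
cutpoints, and Cox proportional hazards by partial likelihood.

Everything here is computed from first principles on (time, event) arrays:

* :func:`km_estimate` — product-limit estimator with Greenwood standard
  errors and log-log confidence bands;
* :func:`logrank_test` — k-group observed-minus-expected test with the
  hypergeometric variance;
* :func:`max_selected_cutpoint` — scans all admissible dichotomizations of
  a continuous covariate, standardizes each split's log-rank statistic with
  the permutational (rank-score) variance, and calibrates the maximum by
  permutation;
* :func:`cox_fit` — Newton–Raphson on the Breslow partial likelihood with
  step-halving and Wald confidence intervals.

Times are in months; ``event`` is 1 for death, 0 for censoring.  When an
event and a censoring share a time, the censored subject is counted as
still at risk for the event (the usual convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KaplanMeierResult",
    "LogrankResult",
    "CutpointResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "logrank_scores",
    "max_selected_cutpoint",
    "cox_fit",
]


def _clean(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if t.size == 0:
        raise ValueError("no records")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (deceased)")
    return t, e


@dataclass
class KaplanMeierResult:
    """Product-limit estimate tabulated at distinct event times."""

    table: pd.DataFrame  # columns: time, n_at_risk, n_events, survival, se, lower, upper

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        tab = self.table
        past = tab["time"] <= t
        if not past.any():
            return 1.0
        return float(tab.loc[past, "survival"].iloc[-1])


def km_estimate(times, events, conf_level: float = 0.95) -> KaplanMeierResult:
    """Kaplan–Meier estimator with Greenwood variance and log-log bands."""
    t, e = _clean(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])

    n = t.size
    rows = []
    surv = 1.0
    greenwood = 0.0
    z = stats.norm.ppf(0.5 + conf_level / 2)
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
        se = surv * np.sqrt(greenwood)
        if 0 < surv < 1 and greenwood > 0:
            # log(-log S) scale keeps the band inside (0, 1)
            theta = np.log(-np.log(surv))
            se_theta = np.sqrt(greenwood) / abs(np.log(surv))
            lower = np.exp(-np.exp(theta + z * se_theta))
            upper = np.exp(-np.exp(theta - z * se_theta))
        else:
            lower = upper = surv
        rows.append((et, at_risk, d, surv, se, lower, upper))
    table = pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "survival", "se", "lower", "upper"]
    )
    return KaplanMeierResult(table)


@dataclass
class LogrankResult:
    statistic: float  # chi-square
    p: float
    df: int
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test (chi-square, df = k - 1)."""
    t, e = _clean(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match times in length")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        d = int(np.sum((t == et) & (e == 1)))
        n_j = np.array([np.sum(at_risk & (g == lab)) for lab in labels], dtype=float)
        d_j = np.array([np.sum((t == et) & (e == 1) & (g == lab)) for lab in labels], dtype=float)
        O += d_j
        E += d * n_j / n
        if n > 1:
            frac = n_j / n
            hyper = d * (n - d) / (n - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogrankResult(chi2, p, k - 1, O, E)


def logrank_scores(times, events) -> np.ndarray:
    """Per-subject log-rank (Savage) scores ``delta_i - Lambda(t_i)``.

    ``Lambda`` is the Nelson–Aalen cumulative hazard.  The two-group
    log-rank numerator equals the sum of scores in one group, which turns
    the cutpoint scan below into a cumulative sum over the sorted covariate.
    """
    t, e = _clean(times, events)
    event_times = np.unique(t[e == 1])
    increments = np.array(
        [np.sum((t == et) & (e == 1)) / np.sum(t >= et) for et in event_times]
    )
    cumhaz_at = np.cumsum(increments)

    idx = np.searchsorted(event_times, t, side="right")
    Lambda = np.where(idx > 0, cumhaz_at[np.maximum(idx - 1, 0)], 0.0)
    return e - Lambda


@dataclass
class CutpointResult:
    """Best dichotomization of a continuous covariate by log-rank statistic."""

    threshold: float
    max_stat: float           # standardized statistic |Z| at the threshold
    p: float                  # permutation p-value of the maximum (NaN if not requested)
    n_low: int
    n_high: int
    scan: pd.DataFrame = field(repr=False)  # threshold, z per admissible split
    naive_p: float = float("nan")           # treats the max as a single z-test


def _standardized_scan(scores: np.ndarray, order: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """|Z| for every split 'first m subjects (by covariate) vs rest'.

    Standardization uses the permutational moments of a rank-score sum:
    E[U] = m * mean(s), Var[U] = m (n-m)/(n (n-1)) * sum((s - mean)^2).
    """
    n = scores.size
    s = scores[order]
    css = np.cumsum(s)
    m = np.arange(1, n)
    sbar = scores.mean()
    ssq = np.sum((scores - sbar) ** 2)
    var = m * (n - m) / (n * (n - 1.0)) * ssq
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (css[:-1] - m * sbar) / np.sqrt(var)
    z = np.abs(z)
    z[: lo - 1] = np.nan
    z[hi:] = np.nan
    return z


def max_selected_cutpoint(
    times,
    events,
    covariate,
    minprop: float = 0.1,
    p_method: str = "permutation",
    n_perm: int = 2000,
    seed: int | np.random.Generator | None = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint on a continuous covariate.

    Candidate thresholds are midpoints between consecutive distinct
    covariate values for which both resulting groups hold at least
    ``ceil(minprop * n)`` subjects.  The returned p-value is the permutation
    tail probability of the maximal standardized statistic (``p_method
    "none"`` skips it); ``naive_p`` treats the maximum as a single z-test
    and is anti-conservative.
    """
    t, e = _clean(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate must match times in length")
    if e.sum() == 0:
        raise ValueError("no events: cutpoint search is undefined")
    n = t.size
    min_group = int(np.ceil(minprop * n))

    scores = logrank_scores(t, e)
    order = np.argsort(x, kind="stable")
    xs = x[order]

    # admissible splits: after position m (1-based count in low group)
    distinct_break = xs[:-1] < xs[1:]
    m_candidates = np.where(distinct_break)[0] + 1  # low-group sizes
    m_candidates = m_candidates[
        (m_candidates >= min_group) & (n - m_candidates >= min_group)
    ]
    if m_candidates.size == 0:
        raise ValueError("no admissible threshold satisfies minprop on both sides")

    z_all = _standardized_scan(scores, order, min_group, n - min_group)
    z_cand = z_all[m_candidates - 1]
    best = int(np.nanargmax(z_cand))
    m_best = int(m_candidates[best])
    threshold = float((xs[m_best - 1] + xs[m_best]) / 2)
    max_stat = float(z_cand[best])
    scan = pd.DataFrame(
        {
            "threshold": (xs[m_candidates - 1] + xs[m_candidates]) / 2,
            "z": z_cand,
            "n_low": m_candidates,
        }
    )

    naive_p = float(2 * stats.norm.sf(max_stat))
    p = float("nan")
    if p_method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        perm_order = np.arange(n)
        for _ in range(n_perm):
            rng.shuffle(perm_order)
            zp = _standardized_scan(scores, perm_order, min_group, n - min_group)
            if np.nanmax(zp[m_candidates - 1]) >= max_stat:
                count += 1
        p = (count + 1) / (n_perm + 1)
    elif p_method != "none":
        raise ValueError("p_method must be 'permutation' or 'none'")

    return CutpointResult(
        threshold=threshold,
        max_stat=max_stat,
        p=p,
        n_low=m_best,
        n_high=n - m_best,
        scan=scan,
        naive_p=naive_p,
    )


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    message: str = ""
    names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        names = self.names or [f"x{i}" for i in range(self.coef.size)]
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_lower": self.ci_lower,
                "hr_upper": self.ci_upper,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=names,
        )


def _cox_loglik_grad_hess(beta, X, t, e):
    """Breslow partial likelihood, score, and information.

    Rows must be sorted by descending time so risk sets are prefix sums.
    """
    eta = X @ beta
    eta -= eta.max()  # guard overflow; cancels in ratios
    w = np.exp(eta)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * X, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)

    # ties at the same time share the full risk set: use the last index with
    # that time (arrays sorted by descending time => risk set of t_i is rows 0..j)
    n = t.size
    last_same = np.empty(n, dtype=int)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and t[k + 1] == t[j]:
            k += 1
        last_same[j : k + 1] = k
        j = k + 1

    ll = 0.0
    score = np.zeros(beta.size)
    info = np.zeros((beta.size, beta.size))
    ev = np.where(e == 1)[0]
    for i in ev:
        r = last_same[i]
        W = cum_w[r]
        Wx = cum_wx[r]
        Wxx = cum_wxx[r]
        mean = Wx / W
        ll += eta[i] - np.log(W)
        score += X[i] - mean
        info += Wxx / W - np.outer(mean, mean)
    return ll, score, info


def cox_fit(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_ll: float = 1e-10,
    conf_level: float = 0.95,
) -> CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Newton–Raphson).

    Convergence: max |score| below ``tol_score`` or relative log-likelihood
    change below ``tol_ll``.  Monotone likelihood (perfect separation) is
    reported as non-convergence with a diagnostic message.
    """
    t, e = _clean(times, events)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != t.size:
        raise ValueError("covariates must have one row per subject")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate")
    if e.sum() < X.shape[1]:
        raise ValueError("fewer events than covariates")

    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    # center for numerical stability; coefficients unaffected
    Xs = Xs - Xs.mean(axis=0)

    beta = np.zeros(X.shape[1])
    ll, score, info = _cox_loglik_grad_hess(beta, Xs, ts, es)
    converged = False
    msg = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            msg = "singular information matrix"
            break
        # step-halving until the likelihood improves
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_score, new_info = _cox_loglik_grad_hess(new_beta, Xs, ts, es)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < tol_score or rel_change < tol_ll:
            converged = True
            break
    if np.max(np.abs(beta)) > 15:
        converged = False
        msg = "monotone likelihood suspected (perfect separation): coefficient diverged"

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
        converged = False
        msg = msg or "singular information at optimum"
    z = stats.norm.ppf(0.5 + conf_level / 2)
    with np.errstate(over="ignore", invalid="ignore"):
        hr = np.exp(beta)
        ci_lower = np.exp(beta - z * se)
        ci_upper = np.exp(beta + z * se)
    return CoxFit(
        coef=beta,
        se=se,
        hr=hr,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        log_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        message=msg,
        names=list(names) if names else [],
    )
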