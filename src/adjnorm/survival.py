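"""Core survival statistics built directly on numpy.

Everything here is implemented from the definitions — Cox partial-likelihood
maximization by Newton–Raphson, Harrell's concordance index, the Kaplan–Meier
product-limit estimator, the two-group log-rank test, the Wilcoxon rank-sum
test with tie correction, and the Pearson correlation — because downstream
modules need full control over tie conventions, risk-set definitions and
penalties, and because published survival packages disagree on exactly these
details.  Conventions:

* Cox ties are handled by Breslow by default (Efron available); the risk set
  of an event at time t is ``{j : t_j >= t}``.
* The concordance index is Harrell's: pair (i, j) is comparable iff
  ``event_i = 1`` and ``t_i < t_j``; tied risk scores count 1/2; pairs with
  tied event times are not comparable.
* The ridge penalty is ``lambda * ||beta||^2`` subtracted from the partial
  log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CoxFit",
    "fit_cox",
    "linear_predictor",
    "wald_test",
    "likelihood_ratio_test",
    "concordance_index",
    "kaplan_meier",
    "logrank_test",
    "wilcoxon_ranksum",
    "pearson_correlation",
]


@dataclass
class CoxFit:
    """Result of a proportional-hazards partial-likelihood fit.

    ``coefficients`` are log hazard ratios; ``standard_errors`` come from the
    inverse observed information (including any ridge contribution);
    ``log_likelihood`` and ``null_log_likelihood`` are unpenalized partial
    log-likelihoods at the estimate and at beta = 0.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    n_iterations: int
    ridge_lambda: float = 0.0
    ties: str = "breslow"


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicators must be 0 or 1")
    return time, event


def _breslow_quantities(eta, X, time, event, need_hessian=True):
    """Unpenalized partial log-likelihood, score and information (Breslow).

    Arrays must already be sorted by ascending time.  Tied times share one
    risk set: risk-set sums are evaluated at the first index of each tie
    group.
    """
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)  # stabilized exp(linear predictor)
    # reverse cumulative sums over the risk set
    rs0 = np.cumsum(w[::-1])[::-1]
    rs1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    # first index of each tie group
    first = np.zeros(n, dtype=int)
    same = time[1:] == time[:-1]
    idx = np.arange(1, n)
    first[1:] = np.where(same, 0, idx)
    first = np.maximum.accumulate(first)
    s0 = rs0[first]
    s1 = rs1[first]
    ev = event.astype(bool)
    ll = float(np.sum(eta[ev] - (np.log(s0[ev]) + shift)))
    mean_x = s1[ev] / s0[ev, None]
    score = X[ev].sum(axis=0) - mean_x.sum(axis=0)
    if not need_hessian:
        return ll, score, None
    rs2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
    s2 = rs2[first][ev]
    info = (s2 / s0[ev, None, None]).sum(axis=0) - mean_x.T @ mean_x
    return ll, score, info


def _efron_quantities(eta, X, time, event):
    """Efron tie handling; plain loop over event-time groups (p is small)."""
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    rs0 = np.cumsum(w[::-1])[::-1]
    rs1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    rs2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dead = np.arange(i, j)[event[i:j] == 1]
        d = len(dead)
        if d:
            wd = w[dead]
            xd = X[dead]
            s0d = wd.sum()
            s1d = (wd[:, None] * xd).sum(axis=0)
            s2d = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            ll += float(eta[dead].sum())
            for ell in range(d):
                f = ell / d
                a0 = rs0[i] - f * s0d
                a1 = rs1[i] - f * s1d
                a2 = rs2[i] - f * s2d
                ll -= np.log(a0) + shift
                score -= a1 / a0
                info += a2 / a0 - np.outer(a1, a1) / a0**2
            score += xd.sum(axis=0)
        i = j
    return ll, score, info


def fit_cox(
    X,
    time,
    event,
    ridge_lambda: float = 0.0,
    ties: str = "breslow",
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_ll: float = 1e-10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Maximizes the partial log-likelihood minus ``ridge_lambda * ||beta||^2``.
    Convergence when the max |penalized score| drops below ``tol_score`` or
    the relative log-likelihood change below ``tol_ll``.  A coefficient
    diverging past |beta| = 50 (on whatever scale X is supplied) is treated
    as separation and returned with ``converged=False``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    time, event = _check_surv(time, event)
    n, p = X.shape
    if n != len(time):
        raise ValueError("X row count must match number of samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if event.sum() < 1:
        raise ValueError("at least one event is required to fit a Cox model")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    quant = _breslow_quantities if ties == "breslow" else _efron_quantities
    beta = np.zeros(p)
    ll_null = quant(Xs @ beta, Xs, ts, es)[0]
    ll_old = ll_null - ridge_lambda * float(beta @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        ll, score, info = quant(eta, Xs, ts, es)
        ll_pen = ll - ridge_lambda * float(beta @ beta)
        score_pen = score - 2.0 * ridge_lambda * beta
        info_pen = info + 2.0 * ridge_lambda * np.eye(p)
        if np.max(np.abs(score_pen)) < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info_pen, score_pen)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info_pen, score_pen, rcond=None)[0]
        # step-halving keeps the penalized likelihood nondecreasing
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            ll_c = quant(Xs @ cand, Xs, ts, es)[0] - ridge_lambda * float(cand @ cand)
            if ll_c >= ll_pen - 1e-12:
                break
            frac *= 0.5
        beta = beta + frac * step
        ll_new = quant(Xs @ beta, Xs, ts, es)[0] - ridge_lambda * float(beta @ beta)
        if np.max(np.abs(beta)) > 50.0:
            break  # separation: likelihood unbounded in beta
        if abs(ll_new - ll_old) <= tol_ll * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll_new
    eta = Xs @ beta
    ll, _, info = quant(eta, Xs, ts, es)
    info_pen = info + 2.0 * ridge_lambda * np.eye(p)
    try:
        cov = np.linalg.inv(info_pen)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(ll),
        null_log_likelihood=float(ll_null),
        converged=converged,
        n_iterations=it,
        ridge_lambda=ridge_lambda,
        ties=ties,
    )


def linear_predictor(fit: CoxFit, X) -> np.ndarray:
    """Risk score X @ beta (no centering)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(fit.coefficients):
        raise ValueError(
            f"X has {X.shape[1]} columns but the fit has {len(fit.coefficients)} coefficients"
        )
    return X @ fit.coefficients


def wald_test(fit: CoxFit):
    """Per-coefficient Wald z and two-sided p from the standard normal."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    z = fit.coefficients / fit.standard_errors
    p = 2.0 * _sps.norm.sf(np.abs(z))
    return z, p


def likelihood_ratio_test(fit: CoxFit):
    """Global likelihood-ratio chi-square against the null model."""
    if not fit.converged:
        raise ValueError("likelihood-ratio test requires a converged fit")
    chi2 = 2.0 * (fit.log_likelihood - fit.null_log_likelihood)
    df = len(fit.coefficients)
    return chi2, float(_sps.chi2.sf(max(chi2, 0.0), df))


def concordance_index(time, event, risk) -> float:
    """Harrell's concordance index.

    The earlier member of a comparable pair must be an observed event with a
    strictly smaller time.  Higher risk at the shorter time is concordant;
    tied risk scores count 1/2.
    """
    time, event = _check_surv(time, event)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != time.shape:
        raise ValueError("risk must match time/event in length")
    t_i = time[:, None]
    comparable = (event[:, None] == 1) & (t_i < time[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    diff = risk[:, None] - risk[None, :]
    conc = (diff > 0) & comparable
    tied = (diff == 0) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


def kaplan_meier(time, event):
    """Product-limit survival estimate.

    Returns ``(times, surv)``: the distinct observed event times in
    increasing order and the estimated S(t) just after each.  The estimate is
    a right-continuous step function equal to 1 before the first event.
    """
    time, event = _check_surv(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    surv = []
    s = 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    if len(uniq) == 0:
        return np.array([]), np.array([])
    return uniq, np.asarray(surv)


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank test (hypergeometric variance, 1 df)."""
    ta, ea = _check_surv(time_a, event_a)
    tb, eb = _check_surv(time_b, event_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("at least one event is required")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    uniq = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in uniq:
        at_risk = t >= u
        n_tot = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        dying = (t == u) & (e == 1)
        d = dying.sum()
        d1 = (dying & (g == 0)).sum()
        exp1 = d * n1 / n_tot
        o_minus_e += d1 - exp1
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(_sps.chi2.sf(chi2, 1))


def wilcoxon_ranksum(a, b):
    """Two-sided Wilcoxon rank-sum with normal approximation and tie
    correction (no continuity correction).

    Returns ``(z, p)``.  If every value in both samples is identical the
    variance is zero and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return float(z), float(2.0 * _sps.norm.sf(abs(z)))


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
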