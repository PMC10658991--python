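"""Survival and association statistics.

Kaplan–Meier curves and the log-rank test are delegated to lifelines;
Wilcoxon rank-sum and Fisher's exact 2x2 test to scipy.  The Cox
proportional-hazards fitter is implemented here directly because screening
needs capabilities the standard fitters do not expose together: a choice of
Efron or Breslow tie handling, an explicit score test at beta = 0 (whose
Breslow form reproduces the log-rank statistic on tie-free data), detection
and flagging of monotone partial likelihoods rather than silent huge
coefficients, and a vectorized path that fits thousands of single
binary-covariate models simultaneously.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import CoxFit, KMCurve, SurvTestResult, ValidationError

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "cox_binary_batch",
    "wilcoxon_rank_sum",
    "fisher_exact",
]

_MAX_ABS_COEF = 15.0  # |log HR| beyond this is treated as a monotone likelihood


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValidationError("times and events must be 1-D arrays of equal length")
    if times.size == 0:
        raise ValidationError("empty survival data")
    if not np.isfinite(times).all() or np.any(times <= 0):
        raise ValidationError("survival times must be positive and finite")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank (lifelines-backed)
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate.

    Samples censored exactly at an event time are counted at risk at that
    time (the standard convention).
    """
    times, events = _check_surv(times, events)
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    mask = tbl["observed"].to_numpy() > 0
    # lifelines includes a t=0 anchor row; keep only times with >= 1 event
    event_times = tbl.index.to_numpy(dtype=float)[mask]
    at_risk = tbl["at_risk"].to_numpy(dtype=float)[mask].astype(int)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(times, events, group) -> SurvTestResult:
    """Two-group log-rank test (chi-square, df = 1).

    The statistic is the standard (O - E)^2 / V construction with the
    hypergeometric variance at each event time.
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {levels.size}")
    if events.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    from lifelines.statistics import logrank_test as _ll_logrank

    a = group == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return SurvTestResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value), method="logrank"
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _risk_group_starts(times_sorted: np.ndarray) -> np.ndarray:
    """start index of each sample's time-tie group under ascending sort."""
    new_group = np.empty(times_sorted.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = times_sorted[1:] != times_sorted[:-1]
    starts = np.where(new_group, np.arange(times_sorted.size), 0)
    return np.maximum.accumulate(starts)


def _cox_quantities(X, times, events, beta, ties):
    """(loglik, score, information) of the partial likelihood at beta."""
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in all ratios
    w = np.exp(eta)
    wX = w[:, None] * Xs
    wXX = w[:, None, None] * np.einsum("ni,nj->nij", Xs, Xs)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    gs = _risk_group_starts(ts)

    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    ev_idx = np.flatnonzero(es == 1)
    # iterate over distinct event times
    for g in np.unique(gs[ev_idx]):
        in_grp = ev_idx[gs[ev_idx] == g]
        d = in_grp.size
        xsum = Xs[in_grp].sum(axis=0)
        ll += float(eta[in_grp].sum())
        if ties == "breslow" or d == 1:
            s0, s1, s2 = S0[g], S1[g], S2[g]
            ll -= d * math.log(s0)
            m1 = s1 / s0
            U += xsum - d * m1
            I += d * (s2 / s0 - np.outer(m1, m1))
        else:  # efron
            s0e = w[in_grp].sum()
            s1e = wX[in_grp].sum(axis=0)
            s2e = wXX[in_grp].sum(axis=0)
            for l in range(d):
                f = l / d
                den = S0[g] - f * s0e
                num1 = S1[g] - f * s1e
                num2 = S2[g] - f * s2e
                ll -= math.log(den)
                m1 = num1 / den
                U += xsum / d - m1
                I += num2 / den - np.outer(m1, m1)
    return ll, U, I


def cox_fit(
    X,
    times,
    events,
    ties: str = "efron",
    names: Sequence[str] | None = None,
    max_iter: int = 60,
) -> CoxFit:
    """Maximum partial-likelihood Cox regression (Newton with step-halving).

    Convergence: max |score| < 1e-9 or relative log-likelihood change
    < 1e-10.  A coefficient walking past |log HR| = 15 marks the fit as
    divergent (monotone likelihood) and ``converged`` is set False.

    Raises on constant or collinear covariate columns and on data with no
    events.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    times, events = _check_surv(times, events)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != times.size:
        raise ValidationError("covariate rows must match number of samples")
    if events.sum() < 1:
        raise ValidationError("Cox model needs at least one event")
    if np.any(X.std(axis=0) == 0):
        j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise ValidationError(f"covariate {j} is constant: non-identifiable")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValidationError("collinear covariates")
    names = tuple(names) if names is not None else tuple(f"x{i}" for i in range(p))

    beta = np.zeros(p)
    ll, U, I = _cox_quantities(X, times, events, beta, ties)
    converged = False
    for _ in range(max_iter):
        if np.abs(U).max() < 1e-9:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            break
        # step-halving to ensure the partial likelihood increases
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, U_new, I_new = _cox_quantities(X, times, events, cand, ties)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.abs(beta).max() > _MAX_ABS_COEF:
            break
        if rel < 1e-10 and np.abs(U).max() < 1e-6:
            converged = True
            break
    divergent = tuple(names[j] for j in np.flatnonzero(np.abs(beta) > _MAX_ABS_COEF))
    if divergent:
        converged = False
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(I)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        p=pvals,
        n=n,
        n_events=int(events.sum()),
        ties_method=ties,
        converged=converged,
        loglik=ll,
        divergent=divergent,
    )


def cox_score_test(x, times, events) -> SurvTestResult:
    """Partial-likelihood score test at beta = 0 (Breslow ties), df = 1.

    For a binary covariate on tie-free event times this is algebraically the
    log-rank statistic.
    """
    times, events = _check_surv(times, events)
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise ValidationError("covariate is constant: non-identifiable")
    _, U, I = _cox_quantities(x[:, None], times, events, np.zeros(1), "breslow")
    stat = float(U[0] ** 2 / I[0, 0])
    return SurvTestResult(
        statistic=stat, df=1, p_value=float(sps.chi2.sf(stat, 1)), method="cox_score_breslow"
    )


def cox_binary_batch(indicators, times, events, ties: str = "efron"):
    """Fit many univariate Cox models with binary covariates at once.

    Parameters
    ----------
    indicators : (P, n) array of 0/1
        One row per candidate covariate (here: one row per gene pair's REO
        indicator).
    times, events : (n,) arrays

    Returns
    -------
    dict of (P,) arrays: ``coef``, ``se``, ``p``, ``ok`` (usable fit) and
    ``divergent`` (monotone likelihood).  Rows with a constant indicator are
    not usable (``ok`` False, ``divergent`` False).

    Notes
    -----
    The vectorized Newton solver exploits that for a binary covariate the
    per-sample relative hazard is ``1 + x (e^beta - 1)`` and that second
    moments equal first moments (x^2 = x).  It requires event times to be
    unique (no tied events), in which case Efron and Breslow coincide;
    with tied events each row falls back to the general fitter.
    """
    times, events = _check_surv(times, events)
    ind = np.asarray(indicators)
    if ind.ndim != 2 or ind.shape[1] != times.size:
        raise ValidationError("indicators must be (P, n_samples)")
    P, n = ind.shape
    ev_times = times[events == 1]
    if np.unique(ev_times).size != ev_times.size:
        # tied event times: general per-row fits
        coef = np.full(P, np.nan)
        se = np.full(P, np.nan)
        pv = np.full(P, np.nan)
        ok = np.zeros(P, dtype=bool)
        div = np.zeros(P, dtype=bool)
        for r in range(P):
            x = ind[r].astype(float)
            if x.std() == 0:
                continue
            fit = cox_fit(x, times, events, ties=ties)
            if fit.divergent:
                div[r] = True
                continue
            if fit.converged:
                coef[r], se[r], pv[r] = fit.coef[0], fit.se[0], fit.p[0]
                ok[r] = True
        return {"coef": coef, "se": se, "p": pv, "ok": ok, "divergent": div}

    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    X = ind[:, order].astype(float)
    gs = _risk_group_starts(ts)
    ev_idx = np.flatnonzero(es == 1)
    gse = gs[ev_idx]
    x_ev_sum = X[:, ev_idx].sum(axis=1)

    variable = X.std(axis=1) > 0
    beta = np.zeros(P)
    alive = variable.copy()  # rows still iterating
    U = np.zeros(P)
    info = np.zeros(P)
    for _ in range(50):
        eb = np.exp(beta)
        w = np.where(X == 1.0, eb[:, None], 1.0)
        S0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
        S1 = np.cumsum((w * X)[:, ::-1], axis=1)[:, ::-1]
        m1 = S1[:, gse] / S0[:, gse]
        U = x_ev_sum - m1.sum(axis=1)
        info = (m1 * (1.0 - m1)).sum(axis=1)
        step = np.where(info > 1e-12, U / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        upd = alive & (np.abs(U) >= 1e-9)
        if not upd.any():
            break
        beta = np.where(upd, np.clip(beta + step, -_MAX_ABS_COEF - 1, _MAX_ABS_COEF + 1), beta)
        alive &= np.abs(beta) <= _MAX_ABS_COEF

    divergent = variable & (np.abs(beta) > _MAX_ABS_COEF)
    ok = variable & ~divergent & (np.abs(U) < 1e-6) & (info > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, 1.0 / np.sqrt(info), np.nan)
        z = beta / se
    pv = np.where(ok, 2.0 * sps.norm.sf(np.abs(z)), np.nan)
    coef = np.where(ok, beta, np.nan)
    return {"coef": coef, "se": se, "p": pv, "ok": ok, "divergent": divergent}


# ---------------------------------------------------------------------------
# Rank-sum and exact tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> SurvTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null distribution when both groups have <= 25 observations and the
    pooled sample has no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.isfinite(pooled).all():
        raise ValidationError("non-finite values in rank-sum input")
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both groups; p = 1", RuntimeWarning)
        return SurvTestResult(statistic=float(x.size * y.size / 2), df=0, p_value=1.0,
                              method="wilcoxon_degenerate")
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return SurvTestResult(
        statistic=float(res.statistic), df=0, p_value=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon_{method}",
    )


def _fisher_2xk_exact(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2xK table by full enumeration.

    Tables with probability <= that of the observed table (up to a relative
    guard of 1e-12) contribute to p.  Feasible for K <= 5 and small n.
    """
    col = table.sum(axis=0)
    r1 = int(table[0].sum())
    log_denom = math.lgamma(table.sum() + 1) - math.lgamma(r1 + 1) - math.lgamma(table.sum() - r1 + 1)

    def logp(cells: tuple[int, ...]) -> float:
        s = 0.0
        for a, c in zip(cells, col):
            s += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
        return s - log_denom

    obs = logp(tuple(int(v) for v in table[0]))
    total = 0.0
    K = col.size

    def rec(j: int, remaining: int, prefix: tuple[int, ...]):
        nonlocal total
        if j == K - 1:
            if 0 <= remaining <= col[j]:
                lp = logp(prefix + (remaining,))
                if lp <= obs + 1e-12:
                    total += math.exp(lp)
            return
        tail_cap = int(col[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, prefix + (a,))

    rec(0, r1, ())
    return min(total, 1.0)


def fisher_exact(table, seed: int = 0, n_mc: int = 200_000) -> SurvTestResult:
    """Two-sided Fisher's exact test for a 2x2 or 2xK contingency table.

    2x2 tables use the hypergeometric enumeration (probability-mass
    ordering); 2xK tables with K <= 5 and n <= 500 use full enumeration,
    larger tables a seeded Monte-Carlo permutation of the column labels.
    All margins must be positive.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValidationError("table must be 2xK")
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero margin in contingency table")
    if table.shape == (2, 2):
        res = sps.fisher_exact(table, alternative="two-sided")
        return SurvTestResult(statistic=float(res.statistic), df=1,
                              p_value=float(res.pvalue), method="fisher_2x2")
    K = table.shape[1]
    if K <= 5 and table.sum() <= 500:
        return SurvTestResult(statistic=float("nan"), df=K - 1,
                              p_value=_fisher_2xk_exact(table), method="fisher_2xk_exact")
    # Monte-Carlo: permute row labels against column labels
    rng = np.random.default_rng(seed)
    rows = np.repeat([0, 1], table.sum(axis=1))
    cols = np.repeat(np.arange(K), table.sum(axis=0))
    obs = _table_logp(table)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros((2, K), dtype=int)
        np.add.at(t, (rows, perm), 1)
        if _table_logp(t) <= obs + 1e-12:
            hits += 1
    return SurvTestResult(statistic=float("nan"), df=K - 1,
                          p_value=(hits + 1) / (n_mc + 1), method="fisher_2xk_montecarlo")


def _table_logp(table: np.ndarray) -> float:
    """log multivariate-hypergeometric probability of a 2xK table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    lp = sum(math.lgamma(v + 1) for v in r) + sum(math.lgamma(v + 1) for v in c)
    lp -= math.lgamma(n + 1)
    lp -= sum(math.lgamma(v + 1) for v in table.ravel())
    return lp
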