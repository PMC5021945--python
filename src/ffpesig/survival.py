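"""From-scratch survival statistics for univariate prognostic screening.

The screening model is the univariate Cox proportional-hazards model

    h(t | x) = h0(t) * exp(beta * x),

fitted by Newton-Raphson on the Efron-approximation partial likelihood
(the default tie handling of the reference survival ecosystem).  The
per-gene p-value reported downstream is the score test at beta = 0,
which for a binary covariate coincides exactly with the classical
two-group log-rank chi-square when event times are distinct; Wald and
likelihood-ratio p-values are computed alongside.  Endpoints are
restricted to a five-year window by administrative censoring before any
model is fitted.  Multiplicity over genes is handled with the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, ConfigurationError, as_frame, endpoint_columns, validate_survival_table

__all__ = [
    "apply_horizon",
    "cox_univariate",
    "logrank_two_group",
    "km_estimate",
    "bh_adjust",
    "screen_genes",
    "CoxUnivariateResult",
    "KMCurve",
    "CoxProblem",
]

#: Coefficients beyond this magnitude indicate monotone-likelihood
#: divergence (perfect separation of risk by the covariate); the
#: estimate is clipped and flagged, the score p-value remains valid.
BETA_CLIP = 15.0


# ---------------------------------------------------------------------------
# horizon
# ---------------------------------------------------------------------------

def apply_horizon(table: pd.DataFrame, horizon_months: float = 60.0) -> pd.DataFrame:
    """Administratively censor both endpoints at a follow-up horizon.

    Any record with time > horizon becomes (horizon, censored); records at
    or before the horizon are unchanged.  Idempotent.
    """
    if horizon_months <= 0:
        raise ConfigurationError("horizon_months must be positive")
    validate_survival_table(table)
    out = table.copy()
    for endpoint in ("OS", "DFS"):
        tcol, ecol = endpoint_columns(endpoint)
        over = out[tcol] > horizon_months
        out.loc[over, ecol] = 0
        out.loc[over, tcol] = float(horizon_months)
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood with Efron ties
# ---------------------------------------------------------------------------

class CoxProblem:
    """Pre-sorted survival data shared across many univariate fits.

    Sorting and tie-group bookkeeping depend only on (time, event), so a
    genome-wide screen against one endpoint pays the O(n log n) setup once.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or event.shape != time.shape:
            raise DataError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise DataError("times must be strictly positive and finite")
        if not np.isin(event, (0, 1)).all():
            raise DataError("event flags must be binary 0/1")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        t = time[self.order]
        e = event[self.order].astype(bool)
        self.n_events = int(e.sum())

        # Distinct-time groups; the risk set of an event at time t is the
        # suffix starting at the first index with that time (samples
        # censored at t remain at risk for deaths at t).
        is_new = np.empty(self.n, dtype=bool)
        is_new[0] = True
        is_new[1:] = t[1:] != t[:-1]
        first_idx = np.flatnonzero(is_new)
        grp_of_pos = np.cumsum(is_new) - 1
        d_per_time = np.bincount(grp_of_pos[e], minlength=first_idx.size)
        has_event = d_per_time > 0

        self.g_first = first_idx[has_event]          # risk-set start per event group
        self.g_d = d_per_time[has_event]             # tied event count per group
        n_groups = self.g_first.size
        # event positions (sorted order) and their compacted group ids
        remap = np.full(first_idx.size, -1)
        remap[has_event] = np.arange(n_groups)
        self.ev_pos = np.flatnonzero(e)
        self.ev_grp = remap[grp_of_pos[self.ev_pos]]
        self.n_groups = n_groups
        # Flattened Efron terms: one (group, l) pair per event, with the
        # fractional tie weight l/d.  For untied data this is l = 0 and the
        # likelihood reduces to Breslow's.
        self.term_g = np.repeat(np.arange(n_groups), self.g_d)
        offsets = np.concatenate(([0], np.cumsum(self.g_d)[:-1]))
        l = np.arange(self.g_d.sum()) - np.repeat(offsets, self.g_d)
        self.term_frac = l / np.repeat(self.g_d, self.g_d)

    # -- internal quantities ------------------------------------------------

    def _suffix_at_groups(self, values: np.ndarray) -> np.ndarray:
        s = np.cumsum(values[::-1])[::-1]
        return s[self.g_first]

    def _tied_sums(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.ev_grp, weights=values[self.ev_pos], minlength=self.n_groups)

    def loglik_grad_info(self, x_sorted: np.ndarray, beta: float):
        """Efron partial log-likelihood, score, and information at beta."""
        xb = beta * x_sorted
        shift = xb.max() if xb.size else 0.0
        r = np.exp(xb - shift)
        rx = r * x_sorted
        rx2 = rx * x_sorted
        S0 = self._suffix_at_groups(r)
        S1 = self._suffix_at_groups(rx)
        S2 = self._suffix_at_groups(rx2)
        T0 = self._tied_sums(r)
        T1 = self._tied_sums(rx)
        T2 = self._tied_sums(rx2)
        tg, fr = self.term_g, self.term_frac
        phi = S0[tg] - fr * T0[tg]
        psi = S1[tg] - fr * T1[tg]
        chi = S2[tg] - fr * T2[tg]
        loglik = xb[self.ev_pos].sum() - np.log(phi).sum() - self.n_events * shift
        grad = x_sorted[self.ev_pos].sum() - (psi / phi).sum()
        info = (chi / phi - (psi / phi) ** 2).sum()
        return loglik, grad, info


@dataclass
class CoxUnivariateResult:
    """Univariate Cox fit summary for one covariate and one endpoint."""

    log_hr: float
    se: float
    score_stat: float
    p_value: float        # score (log-rank-type) test at beta = 0
    wald_p: float
    lrt_p: float
    degenerate: bool
    diverged: bool
    n_events: int


def cox_univariate(expr, time, event, *, max_iter: int = 50, tol: float = 1e-9) -> CoxUnivariateResult:
    """Fit a univariate Cox model with Efron tie handling.

    Newton-Raphson from beta = 0 with step-halving on likelihood
    decrease; convergence when the Newton step is below ``tol``.  A
    zero-variance covariate yields a degenerate result (log HR 0, p 1).
    Monotone-likelihood divergence (|beta| > 15) is clipped and flagged;
    the score p-value is unaffected because it is evaluated at beta = 0.
    """
    x = np.asarray(expr, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("expression vector contains non-finite values")
    problem = CoxProblem(time, event)
    if problem.n_events < 2:
        raise DataError("cox_univariate requires at least 2 events")
    if x.shape != (problem.n,):
        raise DataError("expression vector length does not match survival data")
    return _cox_fit(problem, x[problem.order], max_iter=max_iter, tol=tol)


def _cox_fit(problem: CoxProblem, x_sorted: np.ndarray, *, max_iter: int = 50, tol: float = 1e-9) -> CoxUnivariateResult:
    ll0, u0, i0 = problem.loglik_grad_info(x_sorted, 0.0)
    if x_sorted.std() == 0.0 or i0 <= 0.0 or not np.isfinite(i0):
        return CoxUnivariateResult(0.0, np.inf, 0.0, 1.0, 1.0, 1.0, True, False, problem.n_events)
    score_stat = u0 * u0 / i0
    score_p = float(stats.chi2.sf(score_stat, 1))

    beta, ll, grad, info = 0.0, ll0, u0, i0
    diverged = False
    for _ in range(max_iter):
        step = grad / info
        # step-halving: never accept a likelihood decrease
        new_beta = beta + step
        new_ll, new_grad, new_info = problem.loglik_grad_info(x_sorted, new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = problem.loglik_grad_info(x_sorted, new_beta)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > BETA_CLIP:
            diverged = True
            beta = float(np.clip(beta, -BETA_CLIP, BETA_CLIP))
            ll, grad, info = problem.loglik_grad_info(x_sorted, beta)
            break
        if abs(step) < tol:
            break

    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    wald_p = float(stats.chi2.sf((beta / se) ** 2, 1)) if np.isfinite(se) and se > 0 else 1.0
    lrt_p = float(stats.chi2.sf(max(2.0 * (ll - ll0), 0.0), 1))
    return CoxUnivariateResult(
        float(beta), float(se), float(score_stat), score_p, wald_p, lrt_p,
        False, diverged, problem.n_events,
    )


# ---------------------------------------------------------------------------
# two-group log-rank
# ---------------------------------------------------------------------------

def logrank_two_group(groups, time, event) -> tuple[float, float]:
    """Classical two-group log-rank test.

    At each distinct event time the observed events in group 1 are
    compared with their hypergeometric expectation given the risk sets;
    the chi-square (1 df) sums (O - E) and hypergeometric variances over
    event times.  Returns ``(chi_square, p_value)``.
    """
    g = np.asarray(groups)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if not np.isin(g, (0, 1)).all():
        raise DataError("groups must be binary 0/1 labels")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise DataError("both groups must be non-empty")
    if e.sum() < 1:
        raise DataError("log-rank test requires at least one event")

    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        dying = (t == tt) & e
        d = int(dying.sum())
        d1 = int((dying & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi = o_minus_e * o_minus_e / var
    return float(chi), float(stats.chi2.sf(chi, 1))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times (ascending); ``survival`` the
    right-continuous step values S(t) just after each event time;
    ``at_risk`` the risk-set size just before each event time;
    ``n_events`` the deaths at each time; ``censor_times`` the distinct
    censoring times (tick marks).  S starts at 1 and is non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the right-continuous step function at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
        })


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Samples censored at an event time remain at risk for the deaths at
    that time (deaths precede censorings at equal times).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if t.size < 1:
        raise DataError("km_estimate requires at least one sample")
    event_times = np.unique(t[e])
    surv = []
    at_risk = []
    d_at = []
    s = 1.0
    for tt in event_times:
        n = int((t >= tt).sum())
        d = int(((t == tt) & e).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        d_at.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_at, dtype=int),
        censor_times=np.unique(t[~e]),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.  Input p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p_values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# genome-wide screen
# ---------------------------------------------------------------------------

def screen_genes(matrix, table: pd.DataFrame, endpoint: str, *,
                 horizon_months: float = 60.0, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Univariate Cox screen of every gene against one survival endpoint.

    Applies the five-year horizon, fits each gene's univariate Cox model,
    and adjusts the score-test p-values with Benjamini-Hochberg across
    all genes.  Returns a DataFrame indexed by gene with columns
    ``endpoint, log_hr, se, score_stat, p_value, q_value, wald_p, lrt_p,
    degenerate, diverged, significant``.
    """
    df = as_frame(matrix)
    if set(df.columns) != set(table.index):
        missing = sorted(set(df.columns) ^ set(table.index))
        raise DataError(f"matrix samples and survival table disagree; symmetric difference: {missing}")
    table = table.loc[df.columns]
    table = apply_horizon(table, horizon_months)
    tcol, ecol = endpoint_columns(endpoint)
    problem = CoxProblem(table[tcol].to_numpy(), table[ecol].to_numpy())
    if problem.n_events < 2:
        raise DataError(f"endpoint {endpoint}: fewer than 2 events after horizon")

    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("expression matrix contains non-finite values")
    rows = []
    for x in values[:, problem.order]:
        fit = _cox_fit(problem, x)
        rows.append((fit.log_hr, fit.se, fit.score_stat, fit.p_value,
                     fit.wald_p, fit.lrt_p, fit.degenerate, fit.diverged))
    res = pd.DataFrame(
        rows,
        index=df.index,
        columns=["log_hr", "se", "score_stat", "p_value", "wald_p", "lrt_p", "degenerate", "diverged"],
    )
    res.insert(0, "endpoint", endpoint.upper())
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["q_value"] < fdr_threshold
    res.index.name = "gene"
    return res
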