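"""Regression engines: OLS, logistic, and Cox proportional hazards.

Three fitting contracts used throughout the pipeline, implemented directly
on numpy so that the replicate-heavy validation studies stay fast:

* :func:`fit_linear` — ordinary least squares with homoskedastic standard
  errors and a single-term F-statistic (instrument-strength diagnostic).
* :func:`fit_logistic` — Newton–Raphson maximum likelihood with explicit
  separation detection.
* :func:`fit_cox` — Cox partial likelihood with Efron tie correction,
  Newton iterations, and observed-information standard errors; paired with
  :func:`ph_test`, a Grambsch–Therneau score test of the proportional-hazards
  assumption on scaled Schoenfeld residuals against Kaplan–Meier-transformed
  time.

All engines reject rank-deficient designs up front (naming the offending
columns) rather than silently dropping terms. Confidence intervals are
normal-approximation 95% intervals, exp(coef +/- 1.96 se) on ratio scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "LogisticFit",
    "CoxFit",
    "PhTestResult",
    "fit_linear",
    "fit_logistic",
    "fit_cox",
    "ph_test",
    "ConvergenceError",
    "SeparationError",
    "RankDeficientError",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (collinear or constant columns)."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge."""


class SeparationError(RuntimeError):
    """A covariate (combination) perfectly separates the response."""


def _as_design(design, terms):
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]
    terms = list(terms)
    if len(terms) != X.shape[1]:
        raise ValueError("terms length does not match design columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values")
    return X, terms


def _check_rank(X, terms, *, allow_constant=True):
    """Raise RankDeficientError naming collinear columns via pivoted QR."""
    n, p = X.shape
    if n <= p:
        raise RankDeficientError(f"n={n} observations for p={p} columns")
    if not allow_constant:
        sd = X.std(axis=0)
        const = [t for t, s in zip(terms, sd) if s == 0.0]
        if const:
            raise RankDeficientError(
                f"constant column(s) not allowed in this design: {const}"
            )
    # pivoted QR for column attribution of rank deficiency
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [terms[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
    if bad:
        raise RankDeficientError(f"collinear column(s): {bad}")


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """Ordinary least-squares fit.

    F-statistic is the single-constraint Wald statistic for ``f_term`` and
    therefore equals the squared t-statistic of that term.
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    resid_var: float
    r_squared: float
    n: int
    f_term: str | None = None
    f_stat: float | None = None
    f_pvalue: float | None = None
    fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def tvalues(self):
        return self.coef / self.se

    @property
    def pvalues(self):
        df = self.n - len(self.terms)
        return 2.0 * stats.t.sf(np.abs(self.tvalues), df)

    def __getitem__(self, term):
        j = self.terms.index(term)
        return self.coef[j], self.se[j]


def fit_linear(response, design, terms=None, f_term=None, add_intercept=True):
    """OLS of ``response`` on ``design`` with homoskedastic standard errors.

    Parameters
    ----------
    response : array-like, shape (n,)
    design : array-like, shape (n, p)
    terms : sequence of str, optional
        Column names; defaults to x0..x{p-1}.
    f_term : str, optional
        Term for which the Wald F-statistic (= t^2) is reported.
    add_intercept : bool
        Prepend a constant column named ``"const"``.
    """
    y = np.asarray(response, dtype=float)
    X, terms = _as_design(design, terms)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["const"] + terms
    _check_rank(X, terms)
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    dof = n - p
    resid_var = rss / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * resid_var)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    fstat = fp = None
    if f_term is not None:
        j = terms.index(f_term)
        t = coef[j] / se[j]
        fstat = float(t * t)
        fp = float(stats.f.sf(fstat, 1, dof))
    return LinearFit(
        terms=terms,
        coef=coef,
        se=se,
        resid_var=resid_var,
        r_squared=r2,
        n=n,
        f_term=f_term,
        f_stat=fstat,
        f_pvalue=fp,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# logistic
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    deviance: float
    n_iter: int
    converged: bool

    @property
    def odds_ratio(self):
        return np.exp(self.coef)

    @property
    def ci_low(self):
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_high(self):
        return np.exp(self.coef + _Z95 * self.se)

    @property
    def pvalues(self):
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def __getitem__(self, term):
        j = self.terms.index(term)
        return self.coef[j], self.se[j]


def fit_logistic(
    response, design, terms=None, add_intercept=True, tol=1e-9, max_iter=100
):
    """Logistic regression by Newton–Raphson.

    Converges when the relative deviance change drops below ``tol``.
    Complete or quasi-complete separation raises :class:`SeparationError`
    instead of returning a silently divergent coefficient.
    """
    y = np.asarray(response, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response has a single class")
    X, terms = _as_design(design, terms)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["const"] + terms
    _check_rank(X, terms)
    beta = np.zeros(X.shape[1])
    dev = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        new_dev = -2.0 * float(
            np.sum(y * np.log(np.clip(mu, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1)))
        )
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular (likely separation)"
            ) from exc
        if np.isfinite(dev) and abs(dev - new_dev) <= tol * (abs(dev) + tol):
            dev = new_dev
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 40:
            raise SeparationError(
                "diverging coefficients: response appears perfectly separated"
            )
        dev = new_dev
    else:
        raise ConvergenceError(f"logistic Newton failed to converge in {max_iter} iterations")
    if dev < 1e-8 or np.max(np.abs(beta)) > 30:
        raise SeparationError(
            "perfect or quasi-complete separation detected (deviance ~ 0 or "
            "diverged coefficient); refusing to report a silent huge estimate"
        )
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        terms=terms, coef=beta, se=se, n=len(y), deviance=dev, n_iter=it, converged=True
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Cox partial-likelihood fit (Efron tie handling, no intercept)."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    loglik: float
    n_iter: int
    converged: bool

    @property
    def hazard_ratio(self):
        return np.exp(self.coef)

    @property
    def ci_low(self):
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_high(self):
        return np.exp(self.coef + _Z95 * self.se)

    @property
    def pvalues(self):
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def __getitem__(self, term):
        j = self.terms.index(term)
        return self.coef[j], self.se[j]


def _cox_prepare(followup, event, design):
    t = np.asarray(followup, dtype=float)
    d = np.asarray(event)
    if d.dtype != bool:
        d = d.astype(float)
        if not np.all((d == 0) | (d == 1)):
            raise ValueError("event must be binary 0/1")
        d = d.astype(bool)
    if np.any(t <= 0):
        raise ValueError("follow-up times must be positive")
    if d.sum() == 0:
        raise ValueError("no events in the data")
    order = np.argsort(t, kind="stable")
    return t[order], d[order], order


def _cox_structures(t, d):
    """Risk-set bookkeeping for sorted times.

    Returns, per unique event time (ascending): the suffix start index of
    its risk set, the indices of the tied deaths, and the tie count.
    """
    ev_times = np.unique(t[d])
    starts = np.searchsorted(t, ev_times, side="left")
    death_idx = []
    for tau in ev_times:
        lo = np.searchsorted(t, tau, side="left")
        hi = np.searchsorted(t, tau, side="right")
        idx = np.arange(lo, hi)[d[lo:hi]]
        death_idx.append(idx)
    return ev_times, starts, death_idx


def _make_ngh(t, d, starts, death_idx):
    """Return a (beta, X, want_hess) -> (ll, grad, hess) closure, using the
    vectorized path when every event time is unique."""
    untied = all(len(di) == 1 for di in death_idx)
    if untied:
        lo_of_event = starts  # one event per unique time

        def ngh(beta, X, want_hess=True):
            return _cox_loglik_grad_hess_fast(beta, X, t, d, lo_of_event, want_hess)

    else:

        def ngh(beta, X, want_hess=True):
            return _cox_loglik_grad_hess(beta, X, t, d, starts, death_idx, want_hess)

    return ngh


def _cox_loglik_grad_hess_fast(beta, X, t, d, lo_of_event, want_hess=True):
    """Vectorized likelihood/score/information for unique event times.

    With no tied event times the Efron and Breslow likelihoods coincide;
    the information sum over events of S2/S0 collapses to X^T diag(w c) X
    with c_j the cumulative sum of 1/S0 over event risk sets containing j.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * X

    S0_suffix = np.cumsum(w[::-1])[::-1]  # S0 at suffix starting i
    ev_pos = np.flatnonzero(d)
    S0_ev = S0_suffix[lo_of_event]
    ll = float(eta[ev_pos].sum() - np.log(S0_ev).sum())

    # c_j = sum over events whose risk set contains j of 1/S0
    a = np.zeros(n)
    np.add.at(a, lo_of_event, 1.0 / S0_ev)
    c = np.cumsum(a)
    grad = X[ev_pos].sum(axis=0) - (w * c) @ X

    hess = None
    if want_hess:
        S1_suffix = np.cumsum(wX[::-1], axis=0)[::-1]
        Z = S1_suffix[lo_of_event] / S0_ev[:, None]
        hess = (X * (w * c)[:, None]).T @ X - Z.T @ Z
    return ll, grad, hess


def _cox_loglik_grad_hess(beta, X, t, d, starts, death_idx, want_hess=True):
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # partial likelihood invariant to shifts
    w = np.exp(eta)
    wX = w[:, None] * X

    m = len(starts)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None

    # running suffix sums, processed from the latest event time backwards
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p)) if want_hess else None
    seg_end = n
    for k in range(m - 1, -1, -1):
        lo = starts[k]
        sl = slice(lo, seg_end)
        S0 += float(w[sl].sum())
        S1 += wX[sl].sum(axis=0)
        if want_hess:
            S2 += X[sl].T @ wX[sl]
        seg_end = lo

        di = death_idx[k]
        dcnt = len(di)
        D0 = float(w[di].sum())
        D1 = wX[di].sum(axis=0)
        D2 = X[di].T @ wX[di] if want_hess else None
        ll += float(eta[di].sum())
        grad += X[di].sum(axis=0)
        for l in range(dcnt):
            frac = l / dcnt
            phi = S0 - frac * D0
            z = (S1 - frac * D1) / phi
            ll -= np.log(phi)
            grad -= z
            if want_hess:
                hess += (S2 - frac * D2) / phi - np.outer(z, z)
    return ll, grad, hess


def fit_cox(
    followup,
    event,
    design,
    terms=None,
    tol=1e-9,
    max_iter=100,
):
    """Cox proportional-hazards fit by Newton–Raphson on the Efron partial
    likelihood.

    The design has no intercept (the partial likelihood absorbs it);
    constant columns are rejected. Convergence: relative log-likelihood
    change below ``tol`` (default 1e-9) or 100 iterations; standard errors
    from the inverse observed information. Monotone likelihood (a covariate
    perfectly ranking events) raises :class:`ConvergenceError`.
    """
    X, terms = _as_design(design, terms)
    _check_rank(X, terms, allow_constant=False)
    t, d, order = _cox_prepare(followup, event, X)
    X = X[order]
    # center columns for conditioning; coef/SE unaffected
    Xc = X - X.mean(axis=0)
    ev_times, starts, death_idx = _cox_structures(t, d)
    ngh = _make_ngh(t, d, starts, death_idx)

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, hess = ngh(beta, Xc)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in Cox fit") from exc
        # step-halving if likelihood would decrease
        new_beta = beta + step
        halves = 0
        while halves < 30:
            ll_new, _, _ = ngh(new_beta, Xc, want_hess=False)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
            new_beta = beta + step
            halves += 1
        beta = new_beta
        if np.max(np.abs(beta)) > 100:
            raise ConvergenceError(
                "diverging Cox coefficients (monotone likelihood / perfect separation)"
            )
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll) + tol):
            break
        ll_old = ll
    else:
        raise ConvergenceError(f"Cox Newton failed to converge in {max_iter} iterations")

    ll, grad, hess = ngh(beta, Xc)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        terms=terms,
        coef=beta,
        se=se,
        n=len(t),
        n_events=int(d.sum()),
        loglik=ll,
        n_iter=it,
        converged=True,
    )


def cox_partial_loglik(beta, followup, event, design):
    """Efron partial log-likelihood at ``beta`` (for oracle grid searches)."""
    X, _ = _as_design(design, None)
    t, d, order = _cox_prepare(followup, event, X)
    X = X[order]
    ev_times, starts, death_idx = _cox_structures(t, d)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _cox_loglik_grad_hess(beta, X, t, d, starts, death_idx, want_hess=False)
    return ll


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------


@dataclass
class PhTestResult:
    terms: list[str]
    pvalues: np.ndarray
    statistics: np.ndarray
    global_pvalue: float
    global_statistic: float

    def __getitem__(self, term):
        j = self.terms.index(term)
        return float(self.pvalues[j])


def ph_test(coxfit, followup, event, design):
    """Grambsch–Therneau score test of proportional hazards.

    Correlates Schoenfeld residuals with Kaplan–Meier-transformed event
    time: for covariate j the statistic is d * u_j^2 / (sum((g-gbar)^2) *
    I_jj) with u = sum_k (g_k - gbar) s_k, g the KM-transformed event times,
    s_k the (Efron-averaged) Schoenfeld residual at event k, and I the
    observed information from the fit; chi-squared with 1 df per covariate,
    p df globally. Requires at least 3 events.
    """
    X, terms = _as_design(design, list(coxfit.terms))
    t, d, order = _cox_prepare(followup, event, X)
    X = X[order]
    Xc = X - X.mean(axis=0)
    n_ev = int(d.sum())
    if n_ev < 3:
        raise ValueError("proportional-hazards test undefined with fewer than 3 events")
    ev_times, starts, death_idx = _cox_structures(t, d)

    beta = coxfit.coef
    eta = Xc @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * Xc

    n, p = Xc.shape
    resid = []  # one Schoenfeld residual per death, in time order
    g_per_death = []
    # KM estimate evaluated just before each event time
    km = 1.0
    at_risk_total = n
    S0 = 0.0
    S1 = np.zeros(p)
    seg_end = n
    # backwards pass accumulates risk sums; store per unique event time
    per_time = []
    for k in range(len(starts) - 1, -1, -1):
        lo = starts[k]
        sl = slice(lo, seg_end)
        S0 += float(w[sl].sum())
        S1 += wX[sl].sum(axis=0)
        seg_end = lo
        per_time.append((k, S0, S1.copy()))
    per_time.reverse()

    info = np.zeros((p, p))
    for (k, S0k, S1k) in per_time:
        di = death_idx[k]
        dcnt = len(di)
        D0 = float(w[di].sum())
        D1 = wX[di].sum(axis=0)
        # Efron-averaged risk-set mean at this event time
        zbar = np.zeros(p)
        for l in range(dcnt):
            frac = l / dcnt
            zbar += (S1k - frac * D1) / (S0k - frac * D0)
        zbar /= dcnt
        for i in di:
            resid.append(Xc[i] - zbar)
        # KM survival just before this time
        lo = starts[k]
        at_risk = n - lo
        g_now = 1.0 - km
        km *= 1.0 - dcnt / at_risk
        g_per_death.extend([g_now] * dcnt)

    S = np.array(resid)  # (n_ev, p)
    g = np.array(g_per_death)
    gc = g - g.mean()
    sg2 = float(gc @ gc)
    if sg2 <= 0:
        raise ValueError("degenerate time transform (all events tied)")

    # observed information at beta (full Efron)
    _, _, info = _cox_loglik_grad_hess(beta, Xc, t, d, starts, death_idx)
    u = gc @ S  # (p,)
    I_inv = np.linalg.inv(info)
    stat = n_ev * (u ** 2) / (sg2 * np.diag(info))
    pvals = stats.chi2.sf(stat, df=1)
    global_stat = float(n_ev * u @ I_inv @ u / sg2)
    global_p = float(stats.chi2.sf(global_stat, df=p))
    return PhTestResult(
        terms=terms,
        pvalues=pvals,
        statistics=stat,
        global_pvalue=global_p,
        global_statistic=global_stat,
    )
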