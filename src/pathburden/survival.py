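"""Kaplan-Meier estimation, the log-rank test, and Cox proportional-hazards
regression fitted by Newton-Raphson on the partial likelihood.

The Cox fitter is written directly from the partial likelihood (Efron tie
correction by default, Breslow switchable) rather than delegated, because
it is the inferential engine of the pathway screen and must behave
identically across tens of thousands of single-covariate fits.

Conventions
-----------
* event = 1 means the event occurred; right censoring only.
* Wald inference throughout: HR = exp(beta), 95% CI = exp(beta +- z*se)
  with the exact normal quantile (not the 1.96 shorthand), two-sided p.
* Kaplan-Meier median = smallest t with S(t) <= 0.5 ("not reached" when S
  never drops that far); its CI comes from the log-log transformed
  pointwise band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

Z95 = float(stats.norm.ppf(0.975))

MAX_ITER = 50
SCORE_TOL = 1e-9
LL_TOL = 1e-10
BETA_CAP = 15.0


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n at risk at each event time
    n_events: np.ndarray       # deaths at each event time
    se: np.ndarray             # Greenwood standard errors of S(t)
    median: float | None       # None = not reached
    median_ci: tuple           # (lower, upper); None entries = not reached
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if len(t) == 0:
        raise ValueError("empty group for Kaplan-Meier fit")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    ev_times = np.unique(t[e == 1])
    surv, ses, atrisk, nev = [], [], [], []
    s = 1.0
    gw = 0.0  # Greenwood sum d / (n (n - d))
    for et in ev_times:
        n_at = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_at
        if n_at > d:
            gw += d / (n_at * (n_at - d))
            ses.append(s * np.sqrt(gw))
        else:
            ses.append(0.0)
        surv.append(s)
        atrisk.append(n_at)
        nev.append(d)
    surv = np.array(surv)
    ses = np.array(ses)
    median = _km_quantile(ev_times, surv, 0.5)
    median_ci = _km_median_ci(ev_times, surv, ses)
    return KMCurve(ev_times, surv, np.array(atrisk), np.array(nev), ses,
                   median, median_ci, label)


def _km_quantile(times: np.ndarray, surv: np.ndarray, q: float) -> float | None:
    hit = np.nonzero(surv <= q)[0]
    return float(times[hit[0]]) if len(hit) else None


def _km_median_ci(times: np.ndarray, surv: np.ndarray, se: np.ndarray) -> tuple:
    """Median CI from the log(-log S) pointwise 95% band."""
    if len(times) == 0:
        return (None, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        # se of log(-log S) by the delta method
        ok = (surv > 0) & (surv < 1) & (se > 0)
        theta = np.log(-np.log(surv[ok]))
        sig = se[ok] / np.abs(surv[ok] * np.log(surv[ok]))
        lo = np.exp(-np.exp(theta + Z95 * sig))  # lower survival band
        hi = np.exp(-np.exp(theta - Z95 * sig))  # upper survival band
    t_ok = times[ok]
    lower = _km_quantile(t_ok, hi, 0.5)   # earliest t where even the upper band <= .5
    upper = _km_quantile(t_ok, lo, 0.5)
    return (lower, upper)


def km_fit_groups(times, events, groups) -> dict[str, KMCurve]:
    """One KM curve per group label."""
    g = pd.Series(np.asarray(groups))
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    out = {}
    for label in sorted(g.unique()):
        mask = (g == label).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        out[str(label)] = km_fit(t[mask], e[mask], label=str(label))
    return out


# ---------------------------------------------------------------------------
# Log-rank test


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, two-sided p on 1 df)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(labels)}")
    in1 = g == labels[0]
    if e.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    obs_minus_exp = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & in1).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Wald inference for one model term."""

    term: str
    beta: float
    se: float
    n: int
    n_events: int
    ties_method: str = "efron"
    converged: bool = True
    flag: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            return (float(np.exp(self.beta - Z95 * self.se)),
                    float(np.exp(self.beta + Z95 * self.se)))

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z))) if np.isfinite(self.z) else 0.0


def _prepare(times, events, X):
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(t):
        X = X.T
    order = np.argsort(t, kind="stable")
    return t[order], e[order], X[order]


def _partial_ll(beta, t, e, X, ties):
    """Log partial likelihood and analytic derivatives at beta.

    Works on time-ascending data; risk sets are suffix sums.
    Returns (ll, grad, minus_hessian).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix sums: S_R at index i = sum over j >= i
    S = np.cumsum(w[::-1])[::-1]
    Sx = np.cumsum(wx[::-1], axis=0)[::-1]
    Sxx = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.nonzero(e[i:j])[0] + i
        d = len(dead)
        if d > 0:
            S_R, Z_R, Q_R = S[i], Sx[i], Sxx[i]
            wD = w[dead]
            S_D = wD.sum()
            Z_D = wx[dead].sum(axis=0)
            Q_D = wxx[dead].sum(axis=0)
            ll += eta[dead].sum()
            grad += X[dead].sum(axis=0)
            if ties == "efron":
                fracs = np.arange(d) / d
            else:  # breslow
                fracs = np.zeros(d)
            for f in fracs:
                phi = S_R - f * S_D
                zbar = (Z_R - f * Z_D) / phi
                ll -= np.log(phi)
                grad -= zbar
                info += (Q_R - f * Q_D) / phi - np.outer(zbar, zbar)
        i = j
    return ll, grad, info


def newton_cox(times, events, X, ties: str = "efron"):
    """Maximise the Cox partial likelihood; returns (beta, se, info, diag).

    Newton-Raphson with step-halving when a step decreases the likelihood;
    convergence when max|score| < 1e-9 or the likelihood change < 1e-10.
    Monotone likelihoods (perfect separation) are capped at |beta| = 15
    and flagged rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    t, e, X = _prepare(times, events, X)
    n, p = X.shape
    if e.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    beta = np.zeros(p)
    ll, grad, info = _partial_ll(beta, t, e, X, ties)
    trace = [(0, ll, float(np.max(np.abs(grad))))]
    flag = ""
    converged = False
    for it in range(1, MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving on likelihood decrease
        new_beta = beta + step
        new_ll, new_grad, new_info = _partial_ll(new_beta, t, e, X, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2
            halvings += 1
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_ll(new_beta, t, e, X, ties)
        dll = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        trace.append((it, ll, float(np.max(np.abs(grad)))))
        if np.any(np.abs(beta) > BETA_CAP):
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            ll, grad, info = _partial_ll(beta, t, e, X, ties)
            flag = "monotone_likelihood"
            converged = False
            break
        if np.max(np.abs(grad)) < SCORE_TOL or abs(dll) < LL_TOL:
            converged = True
            break
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {MAX_ITER} iterations", trace
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, info, {"converged": converged, "flag": flag,
                            "trace": trace, "loglik": ll,
                            "n": n, "n_events": int(e.sum())}


def efron_loglik(beta, times, events, X, ties: str = "efron") -> float:
    """Log partial likelihood at a given beta (used by grid/oracle checks)."""
    t, e, Xs = _prepare(times, events, X)
    b = np.atleast_1d(np.asarray(beta, float))
    ll, _, _ = _partial_ll(b, t, e, Xs, ties)
    return float(ll)


# -- design matrix construction from a ClinicalTable ------------------------


def build_design(clinical: ClinicalTable, terms) -> tuple[np.ndarray, list[str]]:
    """Expand model terms into a numeric design matrix.

    Continuous terms enter as-is; binary terms are coded 0/1 (mut_low is
    always the reference for burden-group labels); categorical terms expand
    into dummies against their declared reference level (first in the
    level order).
    """
    cols, names = [], []
    data = clinical.data
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in clinical table")
        kind = clinical.covariate_kinds.get(term, "continuous")
        v = data[term]
        if kind == "continuous":
            arr = v.to_numpy(float)
            if np.all(arr == arr[0]):
                raise ValueError(f"continuous term {term!r} is constant")
            cols.append(arr)
            names.append(term)
        elif kind == "binary":
            vals = sorted(pd.unique(v.astype(str))) if v.dtype == object else None
            if v.dtype == object:
                if set(vals) == {"mut_high", "mut_low"}:
                    ref = "mut_low"
                else:
                    ref = vals[0]
                arr = (v.astype(str) != ref).astype(float).to_numpy()
                names.append(f"{term}[{[x for x in set(v) if x != ref][0]}]"
                             if len(set(v)) == 2 else term)
            else:
                arr = v.to_numpy(float)
                names.append(term)
            if len(np.unique(arr)) < 2:
                raise ValueError(f"binary term {term!r} has a single level")
            cols.append(arr)
        elif kind == "categorical":
            levels = clinical.levels.get(term) or list(pd.unique(v.dropna()))
            for level in levels[1:]:
                cols.append((v == level).astype(float).to_numpy())
                names.append(f"{term}[{level}]")
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {term!r}")
    X = np.column_stack(cols)
    return X, names


def cox_fit(clinical: ClinicalTable, terms, ties: str = "efron") -> list[CoxResult]:
    """Fit a Cox model for the given terms; one CoxResult per design column."""
    if isinstance(terms, str):
        terms = [terms]
    X, names = build_design(clinical, terms)
    t = clinical.data["time"].to_numpy(float)
    e = clinical.data["event"].to_numpy(int)
    _check_events_per_level(clinical, terms, e)
    beta, se, _, diag = newton_cox(t, e, X, ties=ties)
    return [
        CoxResult(names[k], float(beta[k]), float(se[k]), diag["n"],
                  diag["n_events"], ties, diag["converged"], diag["flag"])
        for k in range(len(names))
    ]


def cox_multivariate(clinical: ClinicalTable, terms, ties: str = "efron") -> list[CoxResult]:
    """Joint Cox fit over several terms, with a full-rank design check."""
    if isinstance(terms, str):
        terms = [terms]
    X, names = build_design(clinical, terms)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        # identify offending columns by incremental rank
        bad = []
        base = np.ones((len(X), 1))
        for k in range(X.shape[1]):
            cand = np.column_stack([base, X[:, k]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(names[k])
            else:
                base = cand
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    return cox_fit(clinical, terms, ties=ties)


def _check_events_per_level(clinical, terms, events):
    for term in terms:
        kind = clinical.covariate_kinds.get(term, "continuous")
        if kind in ("binary", "categorical"):
            v = clinical.data[term]
            with_events = v[events == 1]
            if with_events.nunique() < 1:
                raise ValueError(f"term {term!r}: no events in any level")
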