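"""Left-truncated, right-censored Cox proportional-hazards regression.

The model is h(t, x) = lambda0(t) * exp(b x) on the *age* time scale:
subjects enter the risk set at their enrolment age (left truncation) and
leave at diagnosis, last follow-up or death.  The log partial likelihood
is maximized by Newton's method with Efron's correction for tied event
ages (Breslow available behind a flag); the risk set at an event age t
comprises samples with entry_age < t <= exit_age.  Harrell's concordance
index is computed over the same truncation-respecting comparable pairs.

Only a single covariate (the standardized PRS) is supported: that is the
model under study, and the scalar Newton iteration is exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import CohortTable


@dataclass
class CoxFit:
    b: float                      # log hazard ratio per SD of PRS
    se_b: float
    hr: float
    ci95: tuple[float, float]
    c_index: float | None
    c_se: float | None
    n_events: int
    n: int
    loglik: float
    ties: str

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ci95"] = list(self.ci95)
        return d


def _suffix_sums(key: np.ndarray, vals: np.ndarray, queries: np.ndarray,
                 side: str) -> np.ndarray:
    """Sum of ``vals[i]`` over ``key[i] >= q`` (side='left') for each query."""
    order = np.argsort(key, kind="mergesort")
    k = key[order]
    v = vals[order]
    suf = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])
    idx = np.searchsorted(k, queries, side=side)
    return suf[idx]


def _loglik_terms(b: float, x, entry, exit_, event, efron: bool):
    """Log partial likelihood, score and observed information at b."""
    r = np.exp(b * x)
    te = exit_[event]
    xe = x[event]
    re_ = r[event]
    uniq, inv, counts = np.unique(te, return_inverse=True, return_counts=True)

    sums = {}
    for k in range(3):
        xv = r * x ** k
        # risk set {entry < t <= exit}: exit >= t minus entry >= t
        a = _suffix_sums(exit_, xv, uniq, side="left")
        bsum = _suffix_sums(entry, xv, uniq, side="left")
        sums[k] = a - bsum
    s_tie = {k: np.bincount(inv, weights=re_ * xe ** k, minlength=len(uniq))
             for k in range(3)}

    d = counts.astype(float)
    j_of = np.repeat(np.arange(len(uniq)), counts)
    l = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    frac = (l / d[j_of]) if efron else np.zeros_like(l, dtype=float)

    phi0 = sums[0][j_of] - frac * s_tie[0][j_of]
    phi1 = sums[1][j_of] - frac * s_tie[1][j_of]
    phi2 = sums[2][j_of] - frac * s_tie[2][j_of]
    if np.any(phi0 <= 0) or not np.all(np.isfinite(phi0)):
        raise FloatingPointError("non-finite partial likelihood")

    ll = b * xe.sum() - np.log(phi0).sum()
    ratio = phi1 / phi0
    grad = xe.sum() - ratio.sum()
    info = (phi2 / phi0 - ratio ** 2).sum()
    return ll, grad, info


def _cox_newton(x, entry, exit_, event, ties: str = "efron",
                tol: float = 1e-9, max_iter: int = 50):
    efron = ties == "efron"
    xc = x - x.mean()  # centering stabilizes exp() without changing b
    b = 0.0
    ll, grad, info = _loglik_terms(b, xc, entry, exit_, event, efron)
    for _ in range(max_iter):
        if info <= 0:
            raise ValueError("non-positive information; degenerate design")
        step = grad / info
        for _ in range(30):
            try:
                ll_new, grad_new, info_new = _loglik_terms(
                    b + step, xc, entry, exit_, event, efron)
            except FloatingPointError:
                step /= 2.0
                continue
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ValueError("Cox likelihood could not be increased")
        converged = abs(ll_new - ll) < tol
        b, ll, grad, info = b + step, ll_new, grad_new, info_new
        if converged:
            break
    else:
        raise ValueError("Cox Newton iteration did not converge")
    return b, 1.0 / np.sqrt(info), ll


def harrell_c(entry, exit_, event, score) -> tuple[float, float]:
    """Concordance index over truncation-respecting comparable pairs.

    Pair (i, j) is comparable when i has an event at t_i and j is at risk
    then (entry_j < t_i <= exit_j, j != i); it is concordant when the
    event's score is the higher one, with half-credit for score ties.
    The SE is a Noether-type estimate treating each event's pair set as a
    cluster of the underlying U-statistic.
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    score = np.asarray(score, float)
    ev_idx = np.flatnonzero(event)
    if ev_idx.size == 0:
        raise ValueError("no events: concordance undefined")

    m = np.empty(ev_idx.size)
    ch = np.empty(ev_idx.size)  # concordant + half ties per event
    for k, i in enumerate(ev_idx):
        t = exit_[i]
        at_risk = (entry < t) & (t <= exit_)
        at_risk[i] = False
        mi = int(at_risk.sum())
        m[k] = mi
        if mi == 0:
            ch[k] = 0.0
            continue
        s = score[at_risk]
        ch[k] = (s < score[i]).sum() + 0.5 * (s == score[i]).sum()
    tot = m.sum()
    if tot == 0:
        raise ValueError("zero comparable pairs")
    c = float(ch.sum() / tot)
    keep = m > 0
    ci = ch[keep] / m[keep]
    w = m[keep] / tot
    n_ev = keep.sum()
    var = float((w ** 2 * (ci - c) ** 2).sum()) * n_ev / max(n_ev - 1, 1)
    return c, float(np.sqrt(var))


def fit_cox_lt_rc(cohort: CohortTable, ties: str = "efron",
                  concordance: bool = True) -> CoxFit:
    """Fit age-at-onset on standardized PRS under left truncation.

    The cohort must carry ``prs_z``; ``hr = exp(b)`` is the hazard ratio
    per 1 SD of PRS, with a Wald 95% interval on the log scale.
    """
    df = cohort.df
    z = df["prs_z"].to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("cohort has missing prs_z; run scoring first")
    return _fit_arrays(df["entry_age"].to_numpy(), df["exit_age"].to_numpy(),
                       df["event"].to_numpy(bool), z, ties, concordance)


def _fit_arrays(entry, exit_, event, z, ties="efron",
                concordance=True) -> CoxFit:
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    event = np.asarray(event, bool)
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("at least two events required")
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    z = np.asarray(z, float)
    b, se, ll = _cox_newton(z, entry, exit_, event, ties)
    c = cse = None
    if concordance:
        c, cse = harrell_c(entry, exit_, event, z)
    return CoxFit(b=float(b), se_b=float(se), hr=float(np.exp(b)),
                  ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
                  c_index=c, c_se=cse, n_events=n_events, n=len(z),
                  loglik=float(ll), ties=ties)


class CoxPHLeftTruncated(BaseEstimator):
    """Estimator wrapper around the left-truncated Cox fit.

    ``fit(X, y)`` takes the score as ``X`` (n or n x 1) and a record-like
    ``y`` with fields ``entry``, ``exit`` and ``event`` (a DataFrame, a
    structured array or a dict of arrays).  Fitted attributes: ``b_``,
    ``se_b_``, ``hr_``, ``ci95_``, ``c_index_``, ``c_se_``, ``n_events_``.
    """

    def __init__(self, ties: str = "efron", compute_concordance: bool = True):
        self.ties = ties
        self.compute_concordance = compute_concordance

    def fit(self, X, y) -> "CoxPHLeftTruncated":
        z = np.asarray(X, dtype=float)
        if z.ndim == 2:
            if z.shape[1] != 1:
                raise ValueError("exactly one covariate (the PRS) is supported")
            z = z[:, 0]
        entry = np.asarray(y["entry"], float)
        exit_ = np.asarray(y["exit"], float)
        event = np.asarray(y["event"], bool)
        fit = _fit_arrays(entry, exit_, event, z, self.ties,
                          self.compute_concordance)
        self.result_ = fit
        self.b_ = fit.b
        self.se_b_ = fit.se_b
        self.hr_ = fit.hr
        self.ci95_ = fit.ci95
        self.c_index_ = fit.c_index
        self.c_se_ = fit.c_se
        self.n_events_ = fit.n_events
        return self

    def predict(self, X) -> np.ndarray:
        """Relative hazard exp(b z) of new scores."""
        z = np.asarray(X, dtype=float)
        if z.ndim == 2:
            z = z[:, 0]
        return np.exp(self.b_ * z)

    def score(self, X, y) -> float:
        """Harrell's C of the fitted direction on (X, y)."""
        z = np.asarray(X, dtype=float)
        if z.ndim == 2:
            z = z[:, 0]
        c, _ = harrell_c(np.asarray(y["entry"], float),
                         np.asarray(y["exit"], float),
                         np.asarray(y["event"], bool), np.sign(self.b_) * z)
        return c
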