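"""Case/control discrimination metrics for a standardized risk score.

Two summaries of how well the standardized PRS separates cases from
controls: the area under the ROC curve, computed as the Mann–Whitney
probability P(z_case > z_control) + 0.5 P(tie), and the logistic odds
ratio per one standard deviation of the score, fitted by Newton/IRLS on
the binomial log-likelihood with an intercept and no further covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class DiscriminationResult:
    auc: float
    or_per_sd: float
    or_se_log: float          # SE of the log-odds coefficient
    n_cases: int
    n_controls: int

    @property
    def or_ci95(self) -> tuple[float, float]:
        """Wald 95% interval on the log scale."""
        b = np.log(self.or_per_sd)
        return (float(np.exp(b - 1.96 * self.or_se_log)),
                float(np.exp(b + 1.96 * self.or_se_log)))

    def to_dict(self) -> dict:
        lo, hi = self.or_ci95
        return {**self.__dict__, "or_ci95_lo": lo, "or_ci95_hi": hi}


def _as_labels(status) -> np.ndarray:
    status = np.asarray(status)
    if status.dtype.kind in "OUS":
        return (status == "case").astype(int)
    return status.astype(int)


def roc_auc(z, status) -> float:
    """Mann–Whitney AUC with half-credit for ties.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    z = np.asarray(z, dtype=float)
    y = _as_labels(status)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = rankdata(z)  # average ranks implement the tie half-credit
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def logistic_or_per_sd(z, status, tol: float = 1e-8,
                       max_iter: int = 100) -> tuple[float, float]:
    """Odds ratio per unit of the (standardized) score from logistic
    regression of case status on the score alone.

    Returns ``(exp(beta), se(beta))`` with the SE taken from the observed
    information at the MLE.  Raises on complete separation, where the MLE
    diverges.
    """
    z = np.asarray(z, dtype=float)
    y = _as_labels(status).astype(float)
    if y.min() == y.max():
        raise ValueError("both classes required for logistic regression")
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        if w.max() < 1e-12:
            raise ValueError("complete separation: fitted probabilities degenerate")
        grad = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    else:
        raise ValueError("IRLS did not converge in "
                         f"{max_iter} iterations (separation?)")
    if np.abs(beta[1]) > 30:
        raise ValueError("complete separation: coefficient diverged")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (p * (1 - p))[:, None]).T @ X
    se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    return float(np.exp(beta[1])), se


def discrimination(z, status) -> DiscriminationResult:
    """AUC and OR/SD in one result object."""
    y = _as_labels(status)
    or_, se = logistic_or_per_sd(z, status)
    return DiscriminationResult(auc=roc_auc(z, status), or_per_sd=or_,
                                or_se_log=se, n_cases=int(y.sum()),
                                n_controls=int((1 - y).sum()))
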