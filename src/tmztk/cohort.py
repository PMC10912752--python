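"""Patient-cohort analysis linking RAD18 expression to hypermutation.

Recurrent-GBM cohorts confound RAD18 expression with proliferation
(highly proliferative tumors express more of most replication factors),
so expression is adjusted before modelling:

1. a single-sample proliferation score (mean of within-cohort z-scored
   expression over a cell-cycle gene set — a documented simplification of
   kernel-based single-sample enrichment scores, which the downstream
   analysis only needs as a monotone proliferation proxy);
2. OLS of RAD18 on the proliferation score; the residual is the
   proliferation-adjusted RAD18 expression;
3. tertile stratification of adjusted expression into low/medium/high;
4. logistic regression of the hypermutation flag (> 500 mutations
   attributed to the alkylation signature) on adjusted RAD18 and binary
   MGMT status, fit by iteratively reweighted least squares with Wald
   tests from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "proliferation_score",
    "adjust_expression",
    "tertile_stratify",
    "LogisticFit",
    "logistic_fit",
]


def proliferation_score(expression: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Mean of within-cohort z-scored expression over a gene set.

    ``expression`` is genes x samples.  Genes constant across the cohort
    contribute 0.  The score is invariant to per-gene affine rescaling
    and to gene order.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in expression.index]
    if not present:
        raise KeyError("gene set shares no genes with the expression matrix")
    sub = expression.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0).rename("proliferation_score")


def adjust_expression(rad18: pd.Series, proliferation: pd.Series) -> pd.Series:
    """Proliferation-adjusted expression: residuals of OLS with intercept.

    Residuals sum to zero and are orthogonal to the proliferation score
    (to numerical tolerance).
    """
    y = np.asarray(rad18, float)
    x = np.asarray(proliferation, float)
    if y.size != x.size:
        raise ValueError("rad18 and proliferation differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("proliferation score is constant; cannot adjust")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    index = rad18.index if isinstance(rad18, pd.Series) else None
    return pd.Series(resid, index=index, name="rad18_adjusted")


def tertile_stratify(values: pd.Series) -> pd.Series:
    """Label values low/medium/high by empirical 1/3 and 2/3 quantiles.

    Quantiles use linear interpolation; a value <= the lower cut is
    ``low``, > the upper cut is ``high``, otherwise ``medium``.  Ties
    share a label by construction.  If the two cuts coincide (e.g. all
    values equal) every sample is labelled ``medium`` with a warning.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 values to form tertiles")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate tertile cuts; labelling all samples medium")
        labels = np.full(v.size, "medium", dtype=object)
    else:
        labels = np.where(v <= q1, "low", np.where(v > q2, "high", "medium"))
    index = values.index if isinstance(values, pd.Series) else None
    return pd.Series(labels, index=index, name="tertile")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression summary."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    n_iter: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )


def logistic_fit(
    outcome,
    covariates: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    An intercept is prepended to ``covariates``.  Convergence is declared
    when the relative log-likelihood change falls below ``tol``; the
    log-likelihood is non-decreasing across iterations (step-halving on
    the rare decrease).  Wald standard errors come from the inverse
    observed information at the optimum.

    Raises on a constant outcome and on exact or quasi-complete
    separation (diverging coefficients / fitted probabilities pinned at
    0 or 1), naming the offending covariate.
    """
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    cov = pd.DataFrame(covariates).astype(float)
    names = ["intercept", *cov.columns.astype(str)]
    X = np.column_stack([np.ones(len(y)), cov.to_numpy()])
    if X.shape[0] != y.size:
        raise ValueError("outcome and covariates differ in length")

    def _loglik(beta: np.ndarray) -> float:
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    beta = np.zeros(X.shape[1])
    ll = _loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if np.all(w < 1e-12):
            break
        wx = X * w[:, None]
        info = X.T @ wx
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        # step-halving keeps the log-likelihood non-decreasing
        new_ll = _loglik(beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_ll = _loglik(beta + step)
            halvings += 1
        beta = beta + step
        if abs(new_ll - ll) <= tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = X @ beta
    mu = expit(eta)
    scale = np.abs(X).max(axis=0)
    std_beta = np.abs(beta) * np.where(scale > 0, scale, 1.0)
    if std_beta.max() > 1e2 or (np.minimum(mu, 1 - mu) < 1e-10).all():
        worst = names[int(np.argmax(std_beta))]
        raise ValueError(
            f"exact or quasi-complete separation detected (covariate {worst!r})"
        )
    if not converged:
        raise RuntimeError(f"IRLS failed to converge in {max_iter} iterations")

    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov_beta = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(p, index=names),
        loglik=ll,
        n_iter=it,
        converged=converged,
    )
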