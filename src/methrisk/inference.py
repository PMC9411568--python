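"""Significance framework for cross-validated risk-score predictors.

A predictor yhat built out-of-fold is tested against the true outcome with a
univariate regression (linear for continuous outcomes, logistic for binary),

    y = alpha + yhat * beta + eps,

reporting the Wald p-value for beta.  Whether one predictor adds signal over
another is decided by a likelihood-ratio test of the nested pair

    y = a_i + yhat_i b_i                (reduced)
    y = a_ij + yhat_i b_i + yhat_j b_j  (full),

with one degree of freedom.  Families of tests are controlled by Bonferroni
at alpha = 0.05, and metric confidence intervals come from paired percentile
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc", "r2_metrics", "association_test", "lrt_nested", "bonferroni",
    "bootstrap_ci", "percent_change", "AssociationResult", "NestedComparison",
    "MultipleTestingLedger",
]


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random case outscores a random control, ties counted
    half (the rank / Mann-Whitney formulation)."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def r2_metrics(y: np.ndarray, yhat: np.ndarray, n_predictors: int = 1,
               ) -> tuple[float, float]:
    """(R^2, adjusted R^2) with R^2 the squared Pearson correlation of y and
    yhat; a constant predictor gets R^2 = 0 by convention."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if np.var(y) <= 0:
        raise ValueError("outcome has zero variance")
    if np.var(yhat) <= 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    return r2, float(adj)


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    p_value: float
    metric: float
    metric_name: str
    ci: tuple[float, float] | None
    n: int


def _linear_wald(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """Closed-form Wald test for the slope of y ~ 1 + yhat (equivalent to the
    Pearson correlation t test); returns (beta, p)."""
    n = y.size
    vx = np.var(yhat, ddof=0)
    if vx <= 0:
        return 0.0, 1.0
    beta = float(np.cov(yhat, y, ddof=0)[0, 1] / vx)
    r = np.corrcoef(yhat, y)[0, 1]
    r2 = r * r
    if r2 >= 1.0 - 1e-15:
        return beta, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return beta, p


def _logit_fit(y: np.ndarray, X: np.ndarray):
    """Logistic ML fit with a small-ridge fallback under separation.
    Returns (params, loglik, pvalues-or-None)."""
    import statsmodels.api as sm
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.isfinite(fit.params).all() and np.abs(fit.params).max() < 1e3:
            return np.asarray(fit.params), float(fit.llf), np.asarray(fit.pvalues)
    except Exception:
        pass
    # separation or non-convergence: ridge-stabilized IRLS (penalty 1e-6)
    params = np.zeros(X.shape[1])
    lam = 1e-6
    for _ in range(100):
        eta = np.clip(X @ params, -30, 30)
        pv = 1.0 / (1.0 + np.exp(-eta))
        W = np.clip(pv * (1.0 - pv), 1e-10, None)
        z = eta + (y - pv) / W
        A = X.T @ (X * W[:, None]) + lam * np.eye(X.shape[1])
        new = np.linalg.solve(A, X.T @ (W * z))
        if np.abs(new - params).max() < 1e-10:
            params = new
            break
        params = new
    eta = np.clip(X @ params, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return params, ll, None


def association_test(y: np.ndarray, yhat: np.ndarray, link: str,
                     outcome: str = "", predictor: str = "",
                     ci: bool = False, B: int = 1000, seed: int = 0,
                     ) -> AssociationResult:
    """Wald test of beta in y = alpha + yhat*beta, with the predictive metric
    (AUC for logistic, R^2 for linear) attached."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if link == "linear":
        beta, p = _linear_wald(y, yhat)
        metric, _ = r2_metrics(y, yhat)
        metric_name = "r2"
        metric_fn = lambda a, b: r2_metrics(a, b)[0]
    elif link == "logistic":
        X = np.column_stack([np.ones(n), yhat])
        params, _, pvals = _logit_fit(y, X)
        beta = float(params[1])
        if pvals is not None:
            p = float(pvals[1])
        else:  # Wald from the stabilized fit's numeric Hessian
            p = _logit_wald_p(y, X, params)
        metric = auc(y, yhat)
        metric_name = "auc"
        metric_fn = auc
    else:
        raise ValueError(f"unknown link {link!r}")
    interval = bootstrap_ci(metric_fn, y, yhat, B=B, seed=seed) if ci else None
    return AssociationResult(outcome=outcome, predictor=predictor, beta=beta,
                             p_value=p, metric=metric, metric_name=metric_name,
                             ci=interval, n=n)


def _logit_wald_p(y, X, params) -> float:
    eta = X @ params
    pv = 1.0 / (1.0 + np.exp(-eta))
    W = pv * (1.0 - pv)
    info = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(cov[1, 1])
        return float(2.0 * stats.norm.sf(abs(params[1] / se)))
    except np.linalg.LinAlgError:
        return 1.0


@dataclass
class NestedComparison:
    outcome: str
    reduced: str
    full: str
    statistic: float
    df: int
    p_value: float
    metric_reduced: float
    metric_full: float
    pct_change: float | None
    collinear: bool = False


def _gaussian_ll(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def lrt_nested(y: np.ndarray, yhat_i: np.ndarray, yhat_j: np.ndarray, link: str,
               outcome: str = "", label_i: str = "reduced", label_j: str = "added",
               ) -> NestedComparison:
    """Likelihood-ratio test of whether yhat_j adds signal over yhat_i.

    statistic = 2 (ll_full - ll_reduced), df = 1, chi-square p.  When yhat_j
    is numerically collinear with {1, yhat_i} the comparison is flagged and
    p = 1 (no new information).
    """
    y = np.asarray(y, dtype=float)
    yi = np.asarray(yhat_i, dtype=float)
    yj = np.asarray(yhat_j, dtype=float)
    n = y.size
    if n <= 3:
        raise ValueError("need n > 3")
    Xr = np.column_stack([np.ones(n), yi])
    Xf = np.column_stack([np.ones(n), yi, yj])
    # collinearity of yhat_j with the reduced design
    resid_j = yj - Xr @ np.linalg.lstsq(Xr, yj, rcond=None)[0]
    sd_j = yj.std(ddof=0)
    collinear = resid_j.std(ddof=0) <= 1e-10 * max(sd_j, 1.0)

    if link == "linear":
        metric_r, _ = r2_metrics(y, yi)
        metric_f = _regression_r2(y, Xf)
        if collinear:
            return NestedComparison(outcome, label_i, f"{label_i}+{label_j}", 0.0, 1,
                                    1.0, metric_r, metric_r, 0.0, collinear=True)
        rss_r = _rss(y, Xr)
        rss_f = _rss(y, Xf)
        statistic = max(0.0, n * np.log(rss_r / rss_f)) if rss_f > 0 else np.inf
    elif link == "logistic":
        metric_r = auc(y, yi)
        metric_f = auc(y, _logit_fitted(y, Xf))
        if collinear:
            return NestedComparison(outcome, label_i, f"{label_i}+{label_j}", 0.0, 1,
                                    1.0, metric_r, metric_r, 0.0, collinear=True)
        _, ll_r, _ = _logit_fit(y, Xr)
        _, ll_f, _ = _logit_fit(y, Xf)
        statistic = max(0.0, 2.0 * (ll_f - ll_r))
    else:
        raise ValueError(f"unknown link {link!r}")
    p = float(stats.chi2.sf(statistic, df=1))
    pct = percent_change(metric_r, metric_f) if metric_r > 0 else None
    return NestedComparison(outcome, label_i, f"{label_i}+{label_j}",
                            float(statistic), 1, p, metric_r, metric_f, pct)


def _rss(y, X) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _regression_r2(y, X) -> float:
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - _rss(y, X) / tss if tss > 0 else 0.0


def _logit_fitted(y, X) -> np.ndarray:
    params, _, _ = _logit_fit(y, X)
    return X @ params


@dataclass
class MultipleTestingLedger:
    table: pd.DataFrame  # columns: family, test_id, p, adjusted_alpha, significant

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def bonferroni(p_values: pd.DataFrame, alpha: float = 0.05) -> MultipleTestingLedger:
    """Bonferroni control within each family: significant iff
    p < alpha / family size.  ``p_values`` needs columns family, test_id, p."""
    tab = p_values.copy()
    sizes = tab.groupby("family")["p"].transform("size")
    tab["adjusted_alpha"] = alpha / sizes
    tab["significant"] = tab["p"] < tab["adjusted_alpha"]
    return MultipleTestingLedger(table=tab)


def bootstrap_ci(metric_fn, y: np.ndarray, yhat: np.ndarray,
                 B: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 2.5/97.5 interval over B paired resamples of (y, yhat);
    resamples leaving a binary outcome single-class are redrawn."""
    if B < 100:
        raise ValueError("need B >= 100")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    binary = set(np.unique(y)) <= {0.0, 1.0}
    vals = np.empty(B)
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if not binary or 0 < y[idx].sum() < n:
                break
        vals[b] = metric_fn(y[idx], yhat[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def percent_change(metric_base: float, metric_new: float) -> float:
    """Signed percent change 100*(new - base)/base; undefined for base <= 0."""
    if metric_base <= 0:
        raise ValueError("percent change undefined for a non-positive baseline")
    return 100.0 * (metric_new - metric_base) / metric_base
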