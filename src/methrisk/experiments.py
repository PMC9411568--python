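"""Secondary analyses: learning curves, subgroup transfer, interactions.

The downsampling experiment re-runs the full double cross-validation on
subsamples of increasing size (20 repetitions per size) to trace how risk
scores gain accuracy with cohort growth.  Subgroup evaluation measures a
whole-cohort model's out-of-fold accuracy within each labelled group and
bootstrap-tests pairwise differences; within-group retraining re-runs the
pipeline inside each group and flags replication at association p < 0.01.
The interaction analysis asks whether a methylation score and a polygenic
score carry multiplicative information via a 1-df likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, models

__all__ = [
    "DownsamplingResult", "SubgroupReport", "InteractionResult",
    "downsample_experiment", "subgroup_evaluate", "retrain_within_group",
    "interaction_analysis",
]


@dataclass
class DownsamplingResult:
    outcome: str
    sizes: list[int]
    metrics: pd.DataFrame  # columns: size, rep, family, metric (NaN if failed)
    reps: int
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean and normal-approximation 95% CI of the metric per size."""
        g = self.metrics.groupby("size")["metric"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        half = 1.96 * out["std"] / np.sqrt(out["count"])
        out["ci_lo"] = out["mean"] - half
        out["ci_hi"] = out["mean"] + half
        return out


def downsample_experiment(y, genomic: pd.DataFrame, covariates: pd.DataFrame,
                          sizes, reps: int = 20, seed: int = 0,
                          families=("lasso",), outcome: str = "outcome",
                          link: str | None = None, **cv_kwargs) -> DownsamplingResult:
    """Double-CV metric on stratified subsamples drawn without replacement.

    Per (size, repetition): draw a subsample (class-stratified for binary
    outcomes), run the double cross-validation and keep the best family's
    metric.  A subsample that loses a class is redrawn up to 10 times, then
    that repetition is recorded as NaN.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max(sizes) > n:
        raise ValueError("requested size exceeds the cohort")
    if link is None:
        link = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    master = np.random.SeedSequence(seed)
    rows = []
    for si, size in enumerate(sizes):
        for rep in range(reps):
            rng = np.random.default_rng(master.spawn(1)[0])
            idx = None
            for _ in range(10):
                cand = _stratified_subsample(y, size, rng, link)
                if link != "logistic" or len(np.unique(y[cand])) == 2:
                    idx = cand
                    break
            if idx is None:
                rows.append({"size": size, "rep": rep, "family": None, "metric": np.nan})
                continue
            sub_seed = int(rng.integers(0, 2 ** 31))
            preds = models.double_cv(
                y[idx], genomic.iloc[idx], covariates.iloc[idx],
                families=families, seed=sub_seed, outcome=outcome, link=link,
                **cv_kwargs)
            best = models.select_best_model(preds)
            rows.append({"size": size, "rep": rep, "family": best.family,
                         "metric": best.metric})
    return DownsamplingResult(outcome=outcome, sizes=list(sizes),
                              metrics=pd.DataFrame(rows), reps=reps, seed=seed)


def _stratified_subsample(y, size, rng, link):
    if link != "logistic":
        return rng.choice(len(y), size=size, replace=False)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    k1 = max(1, int(round(size * idx1.size / y.size)))
    k1 = min(k1, size - 1, idx1.size)
    k0 = min(size - k1, idx0.size)
    pick = np.concatenate([rng.choice(idx1, size=k1, replace=False),
                           rng.choice(idx0, size=k0, replace=False)])
    return np.sort(pick)


@dataclass
class SubgroupReport:
    outcome: str
    table: pd.DataFrame      # per group: n, metric, ci, p, replicated
    pairwise: pd.DataFrame | None = None
    excluded: list[str] = field(default_factory=list)


def subgroup_evaluate(cv_pred: models.CrossValidatedPrediction, y,
                      groups: pd.Series, B: int = 1000, seed: int = 0,
                      ) -> SubgroupReport:
    """Accuracy of the whole-cohort out-of-fold predictor within each group.

    Pairwise group differences are tested by paired bootstrap of the metric
    difference (significant when the 95% interval excludes zero).  Binary
    groups need at least two cases and two controls to be evaluated.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=cv_pred.yhat.index)
    groups = groups.reindex(y.index)
    link = cv_pred.link
    metric_fn = inference.auc if link == "logistic" else (
        lambda a, b: inference.r2_metrics(a, b)[0])
    rows, excluded, members = [], [], {}
    for g, idx in y.groupby(groups).groups.items():
        yg = y.loc[idx].to_numpy()
        if len(idx) < 4 or (link == "logistic" and (yg.sum() < 2 or (1 - yg).sum() < 2)) \
                or (link != "logistic" and np.var(yg) <= 0):
            excluded.append(str(g))
            continue
        sg = cv_pred.yhat.loc[idx].to_numpy()
        lo, hi = inference.bootstrap_ci(metric_fn, yg, sg, B=B, seed=seed)
        rows.append({"group": g, "n": len(idx), "metric": metric_fn(yg, sg),
                     "ci_lo": lo, "ci_hi": hi})
        members[g] = (yg, sg)
    table = pd.DataFrame(rows)

    pair_rows = []
    names = list(members)
    rng = np.random.default_rng(seed)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ya, sa = members[names[a]]
            yb, sb = members[names[b]]
            diffs = np.empty(B)
            for i in range(B):
                ia = _resample_valid(ya, rng, link)
                ib = _resample_valid(yb, rng, link)
                diffs[i] = metric_fn(ya[ia], sa[ia]) - metric_fn(yb[ib], sb[ib])
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            pair_rows.append({"group_a": names[a], "group_b": names[b],
                              "diff": float(np.mean(diffs)),
                              "ci_lo": float(lo), "ci_hi": float(hi),
                              "significant": bool(lo > 0 or hi < 0)})
    return SubgroupReport(outcome=cv_pred.outcome, table=table,
                          pairwise=pd.DataFrame(pair_rows), excluded=excluded)


def _resample_valid(yg, rng, link):
    n = yg.size
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if link == "logistic":
            if 0 < yg[idx].sum() < n:
                return idx
        elif np.var(yg[idx]) > 0:
            return idx
    return np.arange(n)


def retrain_within_group(y, genomic: pd.DataFrame, covariates: pd.DataFrame,
                         groups: pd.Series, alpha: float = 0.01,
                         min_group_n: int = 50, seed: int = 0,
                         families=("lasso",), outcome: str = "outcome",
                         link: str | None = None, **cv_kwargs) -> SubgroupReport:
    """Re-run the full double-CV pipeline inside each group.

    A group replicates when the association test of its out-of-fold
    prediction against the truth reaches p < ``alpha``.  Pipeline failures
    within a group are reported, not fatal.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=genomic.index)
    if link is None:
        link = "logistic" if set(y.unique()) <= {0.0, 1.0} else "linear"
    groups = groups.reindex(y.index)
    rows, excluded = [], []
    for g, idx in y.groupby(groups).groups.items():
        if len(idx) < min_group_n:
            excluded.append(str(g))
            continue
        try:
            preds = models.double_cv(
                y.loc[idx].to_numpy(), genomic.loc[idx], covariates.loc[idx],
                families=families, seed=seed, outcome=f"{outcome}|{g}",
                link=link, **cv_kwargs)
            best = models.select_best_model(preds)
            assoc = inference.association_test(
                y.loc[idx].to_numpy(), best.yhat.to_numpy(), link,
                outcome=outcome, predictor=best.family)
            rows.append({"group": g, "n": len(idx), "metric": best.metric,
                         "metric_name": best.metric_name, "p": assoc.p_value,
                         "replicated": assoc.p_value < alpha, "error": None})
        except Exception as exc:  # keep going: per-group failures are data
            rows.append({"group": g, "n": len(idx), "metric": np.nan,
                         "metric_name": None, "p": np.nan,
                         "replicated": False, "error": str(exc)})
    return SubgroupReport(outcome=outcome, table=pd.DataFrame(rows),
                          excluded=excluded)


@dataclass
class InteractionResult:
    outcome: str
    p_interaction: float
    metrics: dict[str, float]   # mrs_only, prs_only, additive, interaction
    collinear: bool = False


def interaction_analysis(y, mrs_scores, prs_scores, link: str,
                         outcome: str = "outcome") -> InteractionResult:
    """1-df LRT of y ~ mrs + prs vs y ~ mrs + prs + mrs*prs.

    The interaction column is tested after projecting out the additive terms;
    a numerically collinear interaction (e.g. a constant score) is flagged
    with p = 1.
    """
    y = np.asarray(y, dtype=float)
    mrs = np.asarray(mrs_scores, dtype=float)
    prs = np.asarray(prs_scores, dtype=float)
    inter = mrs * prs
    n = y.size
    X_add = np.column_stack([np.ones(n), mrs, prs])
    resid = inter - X_add @ np.linalg.lstsq(X_add, inter, rcond=None)[0]
    collinear = resid.std(ddof=0) <= 1e-10 * max(inter.std(ddof=0), 1.0)

    if link == "logistic":
        metric = lambda s: inference.auc(y, s)
        fitted = lambda X: inference._logit_fitted(y, X)
    else:
        metric = lambda s: inference.r2_metrics(y, s)[0]
        fitted = lambda X: X @ np.linalg.lstsq(X, y, rcond=None)[0]
    add_hat = fitted(X_add)
    metrics = {
        "mrs_only": metric(mrs),
        "prs_only": metric(prs),
        "additive": metric(add_hat),
    }
    if collinear:
        metrics["interaction"] = metrics["additive"]
        return InteractionResult(outcome, 1.0, metrics, collinear=True)
    X_int = np.column_stack([X_add, inter])
    if link == "logistic":
        _, ll_r, _ = inference._logit_fit(y, X_add)
        _, ll_f, _ = inference._logit_fit(y, X_int)
        statistic = max(0.0, 2.0 * (ll_f - ll_r))
    else:
        rss_r = inference._rss(y, X_add)
        rss_f = inference._rss(y, X_int)
        statistic = max(0.0, n * np.log(rss_r / rss_f)) if rss_f > 0 else np.inf
    from scipy import stats as _st
    p = float(_st.chi2.sf(statistic, df=1))
    metrics["interaction"] = metric(fitted(X_int))
    return InteractionResult(outcome, p, metrics)
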