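"""Baseline and penalized risk-score models under double cross-validation.

A methylation risk score (MRS) is a linear combination of CpG beta values,
score_i = sum_j w_j c_ij; a polygenic risk score (PRS) is the same construct
over allele dosages.  Weights are trained jointly with a fixed set of
baseline covariates,

    y = a + G b_G + C b_C + eps,

where only the genomic block b_G is penalized (lasso / elastic net / ridge;
penalty factor zero on the covariates).  Evaluation uses 10-fold double
cross-validation: an inner cross-validation inside each outer training fold
selects the regularization strength, the model is refit on the full training
fold, and held-out predictions are concatenated across folds into the single
out-of-fold predictor that all downstream significance testing consumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from . import inference
from ._solver import ElasticNetPath, auto_lambda_path, fit_single

__all__ = [
    "PenaltySpec", "FittedRiskModel", "CrossValidatedPrediction",
    "prepare_covariates", "fit_baseline", "fit_penalized", "double_cv",
    "cv_baseline", "select_best_model", "compute_score", "project_external_score",
    "restrict_to_array", "FAMILY_MIXING", "FAMILY_ORDER",
]

FAMILY_MIXING = {"lasso": 1.0, "elastic_net": 0.5, "ridge": 0.0}
FAMILY_ORDER = ("lasso", "elastic_net", "ridge")  # sparser-first tie-break


@dataclass
class PenaltySpec:
    family: str
    link: str = "linear"
    lambda_grid: np.ndarray | str = "auto"
    n_lambda: int = 100
    decades: float = 4.0

    def __post_init__(self):
        if self.family not in FAMILY_MIXING:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in ("linear", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def mixing(self) -> float:
        return FAMILY_MIXING[self.family]


@dataclass
class FittedRiskModel:
    intercept: float
    covariate_effects: pd.Series
    weights: pd.Series  # nonzero genomic weights, original feature scale
    link: str
    penalty: PenaltySpec | None = None
    lam: float | None = None
    training_samples: list = field(default_factory=list)
    data_type: str | None = None

    @property
    def n_selected(self) -> int:
        return int((self.weights != 0).sum())

    def predict(self, genomic: pd.DataFrame | None = None,
                covariates: pd.DataFrame | None = None) -> pd.Series:
        """Linear predictor (log-odds under the logistic link)."""
        if covariates is not None:
            idx = covariates.index
        elif genomic is not None:
            idx = genomic.index
        else:
            raise ValueError("need genomic features or covariates")
        eta = pd.Series(self.intercept, index=idx)
        if len(self.covariate_effects):
            if covariates is None:
                raise ValueError("model has covariate effects; pass covariates")
            eta = eta + covariates[self.covariate_effects.index] @ self.covariate_effects
        if len(self.weights):
            if genomic is None:
                raise ValueError("model has genomic weights; pass the feature matrix")
            eta = eta + compute_score(self.weights, genomic)
        return eta


@dataclass
class CrossValidatedPrediction:
    outcome: str
    family: str
    link: str
    yhat: pd.Series            # concatenated out-of-fold linear predictors
    fold_assignment: pd.Series
    metric: float
    metric_name: str
    chosen_lambdas: list[float] = field(default_factory=list)
    n_selected: list[int] = field(default_factory=list)


def prepare_covariates(raw: pd.DataFrame,
                       cell_props: pd.DataFrame | None = None,
                       genetic_pcs: pd.DataFrame | None = None,
                       include_bmi: bool = True) -> pd.DataFrame:
    """Design-ready covariate table.

    Categorical columns are one-hot encoded with the reference level dropped;
    cell-type proportions drop their first column (rows sum to one, so the
    full simplex is collinear with the intercept); the result must have full
    column rank or the collinear columns are named in the error.
    """
    parts = []
    raw = raw.copy()
    if not include_bmi and "BMI" in raw:
        raw = raw.drop(columns=["BMI"])
    cat = raw.select_dtypes(include=["object", "category"]).columns
    num = raw.columns.difference(cat, sort=False)
    if len(num):
        parts.append(raw[num].astype(float))
    if len(cat):
        parts.append(pd.get_dummies(raw[cat], drop_first=True, dtype=float))
    if cell_props is not None:
        parts.append(cell_props.iloc[:, 1:].astype(float))  # simplex redundancy
    if genetic_pcs is not None:
        parts.append(genetic_pcs.astype(float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in covariates: {bad}")
    _assert_full_rank(X)
    return X


def _assert_full_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    _, R, piv = sla.qr(A, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(A.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < A.shape[1]:
        names = ["(intercept)"] + list(X.columns)
        culprits = [names[j] for j in piv[rank:]]
        raise ValueError(f"covariate design is rank-deficient; collinear with "
                         f"the rest: {culprits}")


def fit_baseline(y, covariates: pd.DataFrame, link: str) -> FittedRiskModel:
    """Unpenalized maximum-likelihood fit of the covariate-only model."""
    y = np.asarray(y, dtype=float)
    C = covariates.to_numpy(dtype=float)
    if len(y) <= C.shape[1] + 1:
        raise ValueError("need n > number of covariate columns")
    X = np.column_stack([np.ones(len(y)), C])
    if link == "linear":
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif link == "logistic":
        coef, _, _ = inference._logit_fit(y, X)
    else:
        raise ValueError(f"unknown link {link!r}")
    return FittedRiskModel(
        intercept=float(coef[0]),
        covariate_effects=pd.Series(coef[1:], index=covariates.columns),
        weights=pd.Series(dtype=float), link=link,
        training_samples=list(covariates.index),
    )


def _standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = A.mean(axis=0)
    s = A.std(axis=0, ddof=0)
    s_safe = np.where(s > 0, s, 1.0)
    return (A - m) / s_safe, m, s


def fit_penalized(y, genomic: pd.DataFrame, covariates: pd.DataFrame,
                  spec: PenaltySpec, lam: float, tol: float = 1e-7,
                  data_type: str | None = None) -> FittedRiskModel:
    """One penalized fit at a given lambda; covariates carry zero penalty.

    Genomic columns are standardized internally for penalization and the
    weights are reported on the original feature scale.  Constant genomic
    columns get weight zero.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not genomic.index.equals(covariates.index):
        raise ValueError("genomic matrix and covariates must be row-aligned")
    y = np.asarray(y, dtype=float)
    G = genomic.to_numpy(dtype=float)
    C = covariates.to_numpy(dtype=float)
    Gs, gm, gsd = _standardize(G)
    Cs, cm, csd = _standardize(C)
    if (csd <= 0).any():
        bad = list(covariates.columns[csd <= 0])
        raise ValueError(f"constant covariate columns: {bad}")
    X = np.column_stack([Cs, Gs])
    pf = np.r_[np.zeros(C.shape[1]), np.ones(G.shape[1])]
    warm = auto_lambda_path(X, y, pf, spec.mixing, n_lambda=20)
    alpha_s, beta_s = fit_single(X, y, pf, spec.mixing, lam, link=spec.link,
                                 tol=tol, warm_path=warm[warm > lam])
    if not np.isfinite(beta_s).all():
        raise RuntimeError(f"penalized fit did not converge at lambda={lam}")
    nc = C.shape[1]
    cov_eff = beta_s[:nc] / csd
    gen_eff = beta_s[nc:] / np.where(gsd > 0, gsd, 1.0)
    gen_eff[gsd <= 0] = 0.0
    intercept = alpha_s - float(cov_eff @ cm) - float(gen_eff @ gm)
    w = pd.Series(gen_eff, index=genomic.columns)
    return FittedRiskModel(
        intercept=float(intercept),
        covariate_effects=pd.Series(cov_eff, index=covariates.columns),
        weights=w[w != 0], link=spec.link, penalty=spec, lam=float(lam),
        training_samples=list(genomic.index), data_type=data_type,
    )


def _outcome_seed(seed: int, outcome: str) -> int:
    return int(np.random.SeedSequence(
        [int(seed), zlib.crc32(outcome.encode())]).generate_state(1)[0] % (2 ** 31))


def _make_folds(y: np.ndarray, k: int, rs: int, link: str):
    from sklearn.model_selection import KFold, StratifiedKFold
    if link == "logistic":
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        return list(kf.split(np.zeros_like(y), y))
    kf = KFold(n_splits=k, shuffle=True, random_state=rs)
    return list(kf.split(np.zeros_like(y)))


def _cv_metric(y: np.ndarray, yhat: np.ndarray, link: str) -> float:
    if link == "logistic":
        return inference.auc(y, yhat)
    if np.var(yhat) <= 0:
        return 0.0
    return inference.r2_metrics(y, yhat)[0]


def double_cv(y, genomic: pd.DataFrame, covariates: pd.DataFrame,
              families=FAMILY_ORDER, outer_k: int = 10, inner_k: int = 10,
              seed: int = 0, outcome: str = "outcome", link: str | None = None,
              n_lambda: int = 100, patience: int = 10, path_tol: float = 1e-5,
              ) -> dict[str, CrossValidatedPrediction]:
    """Concatenated out-of-fold predictions per penalty family.

    Within each outer training fold the genomic and covariate columns are
    standardized (training-fold statistics only), a lambda path is laid out,
    and an inner k-fold cross-validation scores every lambda by the metric of
    the concatenated inner out-of-fold predictions (AUC for binary, squared
    Pearson R^2 for continuous).  The path walk stops early once the inner
    metric has not improved for ``patience`` consecutive lambdas; the model
    is then refit on the whole training fold at the winning lambda and the
    held-out fold predicted.  Binary outer and inner folds are stratified.
    """
    y = np.asarray(y, dtype=float)
    if link is None:
        link = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    n = len(y)
    rs = _outcome_seed(seed, outcome)
    outer = _make_folds(y, outer_k, rs, link)
    if link == "logistic":
        for tr, _ in outer:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("an outer training fold has a single class")
    G_all = genomic.to_numpy(dtype=float)
    C_all = covariates.to_numpy(dtype=float)
    fold_of = np.empty(n, dtype=int)
    for f, (_, te) in enumerate(outer):
        fold_of[te] = f

    results: dict[str, CrossValidatedPrediction] = {}
    for family in families:
        mix = FAMILY_MIXING[family]
        yhat = np.empty(n)
        lams_chosen, n_sel = [], []
        for f, (tr, te) in enumerate(outer):
            Gs, gm, gsd = _standardize(G_all[tr])
            Cs, cm, csd = _standardize(C_all[tr])
            csd_safe = np.where(csd > 0, csd, 1.0)
            gsd_safe = np.where(gsd > 0, gsd, 1.0)
            Xtr = np.column_stack([Cs, Gs])
            pf = np.r_[np.zeros(Cs.shape[1]), np.ones(Gs.shape[1])]
            ytr = y[tr]
            lams = auto_lambda_path(Xtr, ytr, pf, mix, n_lambda=n_lambda)
            best_li = _inner_select(Xtr, ytr, pf, mix, lams, link, inner_k,
                                    rs + 7 * f + 1, patience, path_tol)
            path = ElasticNetPath(Xtr, ytr, pf, mix, lams[:best_li + 1],
                                  link=link, tol=path_tol)
            alpha_s, beta_s = path.fit_to(best_li)
            Xte = np.column_stack([(C_all[te] - cm) / csd_safe,
                                   (G_all[te] - gm) / gsd_safe])
            yhat[te] = alpha_s + Xte @ beta_s
            lams_chosen.append(float(lams[best_li]))
            n_sel.append(int((beta_s[Cs.shape[1]:] != 0).sum()))
        results[family] = CrossValidatedPrediction(
            outcome=outcome, family=family, link=link,
            yhat=pd.Series(yhat, index=genomic.index),
            fold_assignment=pd.Series(fold_of, index=genomic.index),
            metric=_cv_metric(y, yhat, link),
            metric_name="auc" if link == "logistic" else "r2",
            chosen_lambdas=lams_chosen, n_selected=n_sel,
        )
    return results


def _inner_select(Xtr, ytr, pf, mix, lams, link, inner_k, rs, patience, tol,
                  min_delta: float = 5e-3) -> int:
    """Index of the lambda with the best inner-CV metric (ties -> the larger
    lambda, i.e. the sparser model).

    The path walk stops once the metric has not improved by at least
    ``min_delta`` for ``patience`` consecutive lambdas; without the delta,
    chance upticks on noise outcomes would defeat the early stop and force
    the full path on every fold.
    """
    inner = _make_folds(ytr, inner_k, rs, link)
    states = [ElasticNetPath(Xtr[itr], ytr[itr], pf, mix, lams, link=link,
                             tol=tol, irls_max=10)
              for itr, _ in inner]
    oof = np.empty(len(ytr))
    best_li, best_metric = 0, -np.inf
    mark_li, mark_metric = 0, -np.inf
    for li in range(lams.size):
        for state, (itr, ite) in zip(states, inner):
            state.fit_to(li)
            oof[ite] = state.predict(Xtr[ite])
        m = _cv_metric(ytr, oof, link)
        if m > best_metric:
            best_metric, best_li = m, li
        if m > mark_metric + min_delta:
            mark_metric, mark_li = m, li
        elif li - mark_li >= patience:
            break
    return best_li


def cv_baseline(y, covariates: pd.DataFrame, outer_k: int = 10, seed: int = 0,
                outcome: str = "outcome", link: str | None = None,
                ) -> CrossValidatedPrediction:
    """Out-of-fold predictions of the covariate-only baseline model, under
    the same fold assignment double_cv would use for this outcome/seed."""
    y = np.asarray(y, dtype=float)
    if link is None:
        link = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    rs = _outcome_seed(seed, outcome)
    outer = _make_folds(y, outer_k, rs, link)
    n = len(y)
    yhat = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(outer):
        model = fit_baseline(y[tr], covariates.iloc[tr], link)
        yhat[te] = model.predict(covariates=covariates.iloc[te]).to_numpy()
        fold_of[te] = f
    return CrossValidatedPrediction(
        outcome=outcome, family="baseline", link=link,
        yhat=pd.Series(yhat, index=covariates.index),
        fold_assignment=pd.Series(fold_of, index=covariates.index),
        metric=_cv_metric(y, yhat, link),
        metric_name="auc" if link == "logistic" else "r2",
    )


def select_best_model(per_family: dict[str, CrossValidatedPrediction],
                      ) -> CrossValidatedPrediction:
    """Family with the highest CV metric; exact ties prefer the sparser
    family (lasso > elastic_net > ridge)."""
    if not per_family:
        raise ValueError("no fitted families")
    best = None
    for fam in FAMILY_ORDER:
        if fam not in per_family:
            continue
        cand = per_family[fam]
        if best is None or cand.metric > best.metric:
            best = cand
    if best is None:  # families outside the canonical ordering
        best = max(per_family.values(), key=lambda c: c.metric)
    return best


def compute_score(weights: pd.Series, features: pd.DataFrame,
                  missing_policy: str = "error") -> pd.Series:
    """Per-sample weighted sum over available features.

    With ``missing_policy='drop'`` absent features contribute zero (their
    count is tracked on the result's ``attrs``); more than 50% absent is a
    harmonization failure either way.
    """
    present = weights.index.intersection(features.columns)
    n_missing = len(weights) - len(present)
    if len(weights) and n_missing > 0.5 * len(weights):
        raise ValueError(f"{n_missing}/{len(weights)} weight features absent "
                         "from the matrix (harmonization failure)")
    if n_missing and missing_policy != "drop":
        raise KeyError(f"{n_missing} weight features absent; pass "
                       "missing_policy='drop' to score on the overlap")
    if len(present) == 0:
        score = pd.Series(0.0, index=features.index)
    else:
        score = features[present].astype(float) @ weights[present]
    score.attrs["n_missing_features"] = int(n_missing)
    return score


def project_external_score(dosages: pd.DataFrame, weight_table: pd.DataFrame,
                           matrix_alleles: pd.DataFrame,
                           ) -> tuple[pd.Series, dict]:
    """Project an externally trained variant score onto a dosage matrix.

    ``weight_table`` columns: variant id (index or 'rsid'), effect_allele,
    other_allele, effect_weight.  ``matrix_alleles``: per matrix variant, its
    effect_allele / other_allele labels.  Dosages counted on the opposite
    allele are flipped (x -> 2 - x); allele-set mismatches are dropped with a
    report; missing dosages take the per-variant mean.
    """
    wt = weight_table.copy()
    if "rsid" in wt.columns:
        wt = wt.set_index("rsid")
    overlap = wt.index.intersection(dosages.columns).intersection(matrix_alleles.index)
    report = {"n_weights": len(wt), "n_overlap": int(len(overlap)),
              "n_flipped": 0, "n_mismatch": 0}
    if len(overlap) == 0:
        raise ValueError("no overlapping variants between weights and matrix")
    score = pd.Series(0.0, index=dosages.index)
    for v in overlap:
        ea, oa = wt.loc[v, "effect_allele"], wt.loc[v, "other_allele"]
        mea, moa = matrix_alleles.loc[v, "effect_allele"], matrix_alleles.loc[v, "other_allele"]
        x = dosages[v].astype(float)
        x = x.fillna(x.mean())
        if (ea, oa) == (mea, moa):
            aligned = x
        elif (ea, oa) == (moa, mea):
            aligned = 2.0 - x
            report["n_flipped"] += 1
        else:
            report["n_mismatch"] += 1
            continue
        score = score + float(wt.loc[v, "effect_weight"]) * aligned
    return score, report


def restrict_to_array(obj, site_list, mode: str = "apply"):
    """Restrict a model or training matrix to an external array's site list.

    mode='apply' zeroes a fitted model's weights outside the list; the
    retraining path passes a feature matrix and gets back its column subset.
    """
    sites = pd.Index(site_list)
    if len(sites) == 0:
        raise ValueError("site list is empty")
    if isinstance(obj, FittedRiskModel):
        if mode != "apply":
            raise ValueError("models only support mode='apply'")
        kept = obj.weights[obj.weights.index.isin(sites)]
        return FittedRiskModel(
            intercept=obj.intercept, covariate_effects=obj.covariate_effects,
            weights=kept, link=obj.link, penalty=obj.penalty, lam=obj.lam,
            training_samples=obj.training_samples, data_type=obj.data_type)
    if isinstance(obj, pd.DataFrame):
        kept_cols = obj.columns.intersection(sites)
        if len(kept_cols) == 0:
            raise ValueError("no overlap between matrix columns and site list")
        return obj[kept_cols]
    raise TypeError(f"cannot restrict object of type {type(obj)!r}")
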