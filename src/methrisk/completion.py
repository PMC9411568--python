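"""Low-rank completion of mixed EHR matrices and the MRS-augmentation test.

SoftImpute alternates observed-entry substitution with soft-thresholded SVD,
minimizing  1/2 ||P_Omega(X - Z)||_F^2 + lambda ||Z||_*  over low-rank Z.
Completion operates on per-column standardized values (labs z-scored from
their observed entries, binary columns centered only) so no column dominates
the SVD, and observed entries are restored exactly in the output.

Evaluation mimics clinical ordering behaviour: labs arrive in panels, so
when a target lab's entries are masked for evaluation, every lab sharing a
panel with it is masked for the same samples.  Risk-score columns appended
with :func:`augment_with_scores` are tagged and never masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import lrt_nested, percent_change, r2_metrics

__all__ = [
    "ObservedLabMatrix", "CompletionParams", "MaskingPlan", "ImputationComparison",
    "svd_soft_threshold", "softimpute", "build_panel_mask_folds",
    "evaluate_lab_imputation", "augment_with_scores", "compare_base_vs_augmented",
    "select_lambda",
]


@dataclass
class ObservedLabMatrix:
    values: pd.DataFrame          # samples x features, NaN allowed anywhere
    observed: pd.DataFrame        # boolean mask, True => values finite
    feature_types: pd.Series      # per column: lab | binary | demographic | score
    panels: dict[str, list[str]] = field(default_factory=dict)  # panel -> member labs

    def __post_init__(self):
        vals = self.values.to_numpy(dtype=float)
        obs = self.observed.to_numpy(dtype=bool)
        if not np.isfinite(vals[obs]).all():
            raise ValueError("observed mask marks non-finite entries")
        if (self.feature_types == "score").any():
            score_cols = self.feature_types.index[self.feature_types == "score"]
            if not self.observed[score_cols].all().all():
                raise ValueError("score columns must be fully observed")

    def panel_partners(self, lab: str) -> list[str]:
        """Labs sharing at least one panel with ``lab`` (including itself)."""
        partners = {lab}
        for members in self.panels.values():
            if lab in members:
                partners.update(members)
        return sorted(partners & set(self.values.columns))


@dataclass
class CompletionParams:
    lam: float | None = None      # None -> validation-split selection
    max_rank: int | None = 50
    tol: float = 1e-5
    max_iter: int = 200

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class MaskingPlan:
    target_lab: str
    folds: list[np.ndarray]                 # sample positions of target entries
    induced: list[list[tuple[int, int]]]    # per fold, (row, col) pairs masked
    seed: int


@dataclass
class ImputationComparison:
    lab: str
    r2_base: float
    r2_augmented: float
    pct_change: float | None
    p_value: float
    n_masked: int


def svd_soft_threshold(matrix: np.ndarray, lam: float,
                       max_rank: int | None = None) -> np.ndarray:
    """U diag(max(s - lam, 0)) V^T, optionally capped at ``max_rank``."""
    U, s, Vt = np.linalg.svd(np.asarray(matrix, dtype=float), full_matrices=False)
    s = np.maximum(s - lam, 0.0)
    if max_rank is not None and max_rank < s.size:
        s[max_rank:] = 0.0
    return (U * s) @ Vt


def _standardize_columns(vals: np.ndarray, obs: np.ndarray, types: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center every column on its observed mean; scale non-binary columns by
    their observed SD.  Returns (standardized values, centers, scales)."""
    p = vals.shape[1]
    centers = np.zeros(p)
    scales = np.ones(p)
    out = vals.copy()
    for j in range(p):
        col = vals[obs[:, j], j]
        if col.size == 0:
            raise ValueError(f"column {j} has no observed entries")
        centers[j] = col.mean()
        if types[j] != "binary":
            sd = col.std(ddof=0)
            scales[j] = sd if sd > 0 else 1.0
        out[:, j] = (vals[:, j] - centers[j]) / scales[j]
    return out, centers, scales


def softimpute(obs: ObservedLabMatrix, params: CompletionParams | None = None,
               extra_mask: np.ndarray | None = None,
               ) -> tuple[pd.DataFrame, dict]:
    """Complete the matrix; observed entries are restored exactly.

    ``extra_mask`` (boolean, True = hide) lets evaluation drivers mask
    held-out entries without mutating the input.  The info dict carries the
    objective trajectory and a convergence flag.
    """
    params = params or CompletionParams()
    vals = obs.values.to_numpy(dtype=float)
    mask = obs.observed.to_numpy(dtype=bool).copy()
    if extra_mask is not None:
        mask &= ~extra_mask
    types = obs.feature_types.reindex(obs.values.columns).to_numpy()
    work = np.where(mask, vals, np.nan)
    std, centers, scales = _standardize_columns(work, mask, types)
    X = np.where(mask, std, 0.0)

    lam = params.lam
    if lam is None:
        lam = select_lambda(X, mask, params)

    # warm start down a geometric path: cold-started iterations at a small
    # lambda converge to an arbitrary interpolant rather than the low-rank
    # solution, so the path walk is what makes exact recovery possible
    Z = np.zeros_like(X)
    s1 = float(np.linalg.svd(X, compute_uv=False)[0])
    if 0 < lam < 0.5 * s1:
        for wlam in np.geomspace(0.5 * s1, lam, 10)[:-1]:
            for _ in range(params.max_iter):
                Z_new = svd_soft_threshold(np.where(mask, X, Z), wlam, params.max_rank)
                denom = max(float(np.linalg.norm(Z)), 1e-12)
                delta = float(np.linalg.norm(Z_new - Z)) / denom
                Z = Z_new
                if delta < params.tol:
                    break

    objective = []
    converged = False
    for _ in range(params.max_iter):
        filled = np.where(mask, X, Z)
        Z_new = svd_soft_threshold(filled, lam, params.max_rank)
        obj = 0.5 * float(((X - Z_new)[mask] ** 2).sum()) + lam * _nuclear(Z_new)
        objective.append(obj)
        denom = max(float(np.linalg.norm(Z)), 1e-12)
        delta = float(np.linalg.norm(Z_new - Z)) / denom
        Z = Z_new
        if delta < params.tol:
            converged = True
            break
    completed = np.where(mask, std, Z)
    completed = completed * scales + centers
    out = pd.DataFrame(completed, index=obs.values.index, columns=obs.values.columns)
    return out, {"lam": float(lam), "objective": objective, "converged": converged}


def _nuclear(Z: np.ndarray) -> float:
    return float(np.linalg.svd(Z, compute_uv=False).sum())


def select_lambda(X: np.ndarray, mask: np.ndarray, params: CompletionParams,
                  n_lambda: int = 10, holdout: float = 0.1, seed: int = 0) -> float:
    """Pick lambda on a warm-started path over ``n_lambda`` log-spaced values,
    scored on a 10% validation split of the observed entries."""
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    n_obs = rows.size
    val = rng.random(n_obs) < holdout
    fit_mask = mask.copy()
    fit_mask[rows[val], cols[val]] = False
    lam_max = np.linalg.svd(np.where(fit_mask, X, 0.0), compute_uv=False)[0]
    lams = np.geomspace(lam_max * 0.5, lam_max * 5e-3, n_lambda)
    Z = np.zeros_like(X)
    best_lam, best_err = lams[0], np.inf
    for lam in lams:  # warm start down the path
        for _ in range(params.max_iter):
            Z_new = svd_soft_threshold(np.where(fit_mask, X, Z), lam, params.max_rank)
            denom = max(float(np.linalg.norm(Z)), 1e-12)
            delta = float(np.linalg.norm(Z_new - Z)) / denom
            Z = Z_new
            if delta < params.tol:
                break
        err = float(((X - Z)[mask & ~fit_mask] ** 2).mean())
        if err < best_err:
            best_err, best_lam = err, lam
    return float(best_lam)


def build_panel_mask_folds(obs: ObservedLabMatrix, target_lab: str,
                           k: int = 10, seed: int = 0) -> MaskingPlan:
    """Partition the target lab's observed entries into k folds; each fold's
    induced mask adds, per selected sample, every lab sharing a panel with
    the target."""
    if target_lab not in obs.values.columns:
        raise KeyError(target_lab)
    col = obs.values.columns.get_loc(target_lab)
    rows = np.flatnonzero(obs.observed.to_numpy()[:, col])
    if rows.size < k:
        raise ValueError(f"target lab has {rows.size} observed entries, need >= {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(rows)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    partners = obs.panel_partners(target_lab)
    partner_cols = [obs.values.columns.get_loc(p) for p in partners]
    obs_np = obs.observed.to_numpy()
    induced = []
    for fold in folds:
        pairs = []
        for i in fold:
            for c in partner_cols:
                if obs_np[i, c]:
                    pairs.append((int(i), int(c)))
        induced.append(pairs)
    return MaskingPlan(target_lab=target_lab, folds=folds, induced=induced, seed=seed)


def _fold_extra_mask(obs: ObservedLabMatrix, pairs) -> np.ndarray:
    m = np.zeros(obs.values.shape, dtype=bool)
    for i, c in pairs:
        m[i, c] = True
    return m


def evaluate_lab_imputation(obs: ObservedLabMatrix, plan: MaskingPlan,
                            params: CompletionParams | None = None,
                            ) -> tuple[float, pd.DataFrame]:
    """Pooled R^2 between held-out target values and their imputations.

    Per fold: hide the induced entries, complete, and collect the imputed
    target values; R^2 (squared Pearson) pools the held-out truths and
    imputations across all folds.
    """
    params = params or CompletionParams()
    col = obs.values.columns.get_loc(plan.target_lab)
    truths, imputed, fold_ids = [], [], []
    for f, (fold, pairs) in enumerate(zip(plan.folds, plan.induced)):
        extra = _fold_extra_mask(obs, pairs)
        completed, _ = softimpute(obs, params, extra_mask=extra)
        truths.append(obs.values.to_numpy()[fold, col])
        imputed.append(completed.to_numpy()[fold, col])
        fold_ids.append(np.full(fold.size, f))
    truth = np.concatenate(truths)
    imp = np.concatenate(imputed)
    detail = pd.DataFrame({"fold": np.concatenate(fold_ids),
                           "truth": truth, "imputed": imp})
    if np.var(truth) <= 0:
        raise ValueError("held-out target values are constant; R^2 undefined")
    r2, _ = r2_metrics(truth, imp)
    return r2, detail


def augment_with_scores(obs: ObservedLabMatrix, scores: pd.DataFrame,
                        ) -> ObservedLabMatrix:
    """Append fully observed risk-score columns (tagged 'score', z-scored at
    completion time like any continuous column, never masked by plans)."""
    if scores.shape[1] == 0:
        return obs
    if not scores.index.equals(obs.values.index):
        raise ValueError("score rows must align with the matrix samples")
    if scores.isna().any().any():
        raise ValueError("score columns must be fully observed")
    values = pd.concat([obs.values, scores], axis=1)
    observed = pd.concat(
        [obs.observed, pd.DataFrame(True, index=scores.index, columns=scores.columns)],
        axis=1)
    ftypes = pd.concat([obs.feature_types,
                        pd.Series("score", index=scores.columns)])
    return ObservedLabMatrix(values=values, observed=observed,
                             feature_types=ftypes, panels=obs.panels)


def compare_base_vs_augmented(obs: ObservedLabMatrix,
                              plans: list[MaskingPlan],
                              params: CompletionParams | None = None,
                              scores: pd.DataFrame | None = None,
                              ) -> list[ImputationComparison]:
    """Paired-mask comparison of SoftImpute vs SoftImpute + risk scores.

    Both arms see identical induced masks.  Whether the augmented arm adds
    explanatory signal is the nested likelihood-ratio test with the base
    imputations as the reduced predictor and the augmented imputations as
    the added one, against the held-out truth.
    """
    params = params or CompletionParams()
    if scores is None or scores.shape[1] == 0:
        raise ValueError("pass at least one score column to compare")
    aug = augment_with_scores(obs, scores)
    out = []
    for plan in plans:
        r2_b, det_b = evaluate_lab_imputation(obs, plan, params)
        aug_plan = MaskingPlan(plan.target_lab, plan.folds, plan.induced, plan.seed)
        r2_a, det_a = evaluate_lab_imputation(aug, aug_plan, params)
        truth = det_b["truth"].to_numpy()
        cmp_ = lrt_nested(truth, det_b["imputed"].to_numpy(),
                          det_a["imputed"].to_numpy(), "linear",
                          outcome=plan.target_lab, label_i="softimpute",
                          label_j="softimpute+scores")
        pct = percent_change(r2_b, r2_a) if r2_b > 0 else None
        out.append(ImputationComparison(lab=plan.target_lab, r2_base=r2_b,
                                        r2_augmented=r2_a, pct_change=pct,
                                        p_value=cmp_.p_value, n_masked=truth.size))
    return out
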