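"""SoftImpute, panel-aware masking evaluation, and score augmentation."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from methrisk.completion import (
    CompletionParams, MaskingPlan, ObservedLabMatrix, augment_with_scores,
    build_panel_mask_folds, compare_base_vs_augmented, evaluate_lab_imputation,
    softimpute, svd_soft_threshold,
)

SEED = 12345


def _make_obs(values: np.ndarray, observed: np.ndarray | None = None,
              types=None, panels=None, prefix="lab"):
    n, p = values.shape
    cols = [f"{prefix}_{j}" for j in range(p)]
    idx = [f"s{i}" for i in range(n)]
    vals = pd.DataFrame(values, index=idx, columns=cols)
    if observed is None:
        observed = np.ones_like(values, dtype=bool)
    obs = pd.DataFrame(observed, index=idx, columns=cols)
    ftypes = pd.Series(types if types is not None else "lab", index=cols)
    return ObservedLabMatrix(values=vals.where(obs), observed=obs,
                             feature_types=ftypes, panels=panels or {})


class TestSvt:
    def test_zero_threshold_identity(self, rng):
        M = rng.normal(size=(15, 8))
        np.testing.assert_allclose(svd_soft_threshold(M, 0.0), M, atol=1e-10)

    def test_diagonal_case(self):
        M = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svd_soft_threshold(M, 2.0), np.diag([1.0, 0.0]),
                                   atol=1e-12)

    def test_matches_svd_shrink_oracle(self, rng):
        M = rng.normal(size=(20, 10))
        lam = 1.5
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        oracle = (U * np.maximum(s - lam, 0)) @ Vt
        np.testing.assert_allclose(svd_soft_threshold(M, lam), oracle, atol=1e-8)

    def test_nuclear_norm_shrinks(self, rng):
        M = rng.normal(size=(12, 9))
        out = svd_soft_threshold(M, 0.7)
        assert np.linalg.svd(out, compute_uv=False).sum() <= \
            np.linalg.svd(M, compute_uv=False).sum() + 1e-10


class TestSoftImpute:
    def test_fully_observed_unchanged(self, rng):
        vals = rng.normal(size=(30, 6))
        obs = _make_obs(vals)
        completed, info = softimpute(obs, CompletionParams(lam=1.0))
        np.testing.assert_allclose(completed.to_numpy(), vals, atol=1e-10)

    def test_rank2_exact_recovery(self, rng):
        n, p, r = 200, 30, 2
        vals = rng.normal(size=(n, r)) @ rng.normal(size=(r, p))
        mask = rng.random((n, p)) >= 0.2  # 20% masked
        obs = _make_obs(vals, mask)
        params = CompletionParams(lam=1e-3, tol=1e-8, max_iter=1000, max_rank=None)
        completed, info = softimpute(obs, params)
        miss = ~mask
        err = np.linalg.norm((completed.to_numpy() - vals)[miss]) / \
            np.linalg.norm(vals[miss])
        assert err < 1e-3

    def test_objective_monotone(self, rng):
        n, p = 60, 12
        vals = rng.normal(size=(n, 2)) @ rng.normal(size=(2, p)) + \
            0.1 * rng.normal(size=(n, p))
        mask = rng.random((n, p)) >= 0.3
        obs = _make_obs(vals, mask)
        _, info = softimpute(obs, CompletionParams(lam=2.0, tol=1e-9, max_iter=150))
        objective = np.array(info["objective"])
        assert (np.diff(objective) <= 1e-8).all()

    def test_all_missing_column_rejected(self, rng):
        vals = rng.normal(size=(10, 3))
        mask = np.ones_like(vals, dtype=bool)
        mask[:, 1] = False
        with pytest.raises(ValueError, match="no observed"):
            softimpute(_make_obs(vals, mask), CompletionParams(lam=0.1))


class TestMaskFolds:
    def _panel_obs(self, rng, n=100):
        vals = rng.normal(size=(n, 4))
        mask = rng.random((n, 4)) >= 0.2
        panels = {"panel_1": ["lab_0", "lab_1"], "panel_2": ["lab_2"],
                  "panel_3": ["lab_3"]}
        return _make_obs(vals, mask, panels=panels)

    def test_singleton_panel_masks_target_only(self, rng):
        obs = self._panel_obs(rng)
        plan = build_panel_mask_folds(obs, "lab_2", k=5, seed=SEED)
        col = obs.values.columns.get_loc("lab_2")
        for pairs in plan.induced:
            assert all(c == col for _, c in pairs)

    def test_co_paneled_lab_masked_together(self, rng):
        obs = self._panel_obs(rng)
        plan = build_panel_mask_folds(obs, "lab_0", k=5, seed=SEED)
        col0 = obs.values.columns.get_loc("lab_0")
        col1 = obs.values.columns.get_loc("lab_1")
        obs_np = obs.observed.to_numpy()
        for fold, pairs in zip(plan.folds, plan.induced):
            cols_by_row = {}
            for i, c in pairs:
                cols_by_row.setdefault(i, set()).add(c)
            for i in fold:
                assert col0 in cols_by_row[i]
                if obs_np[i, col1]:
                    assert col1 in cols_by_row[i]

    def test_partition_arithmetic(self, rng):
        vals = rng.normal(size=(100, 1))
        obs = _make_obs(vals, panels={"p": ["lab_0"]})
        plan = build_panel_mask_folds(obs, "lab_0", k=10, seed=SEED)
        sizes = [len(f) for f in plan.folds]
        assert sizes == [10] * 10
        all_rows = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(all_rows, np.arange(100))

    def test_too_few_observations(self, rng):
        vals = rng.normal(size=(5, 1))
        obs = _make_obs(vals, panels={"p": ["lab_0"]})
        with pytest.raises(ValueError, match="observed entries"):
            build_panel_mask_folds(obs, "lab_0", k=10)


class TestEvaluate:
    def test_perfect_proxy_high_r2(self, rng):
        # target equals another lab that never shares a panel with it
        n = 150
        base = rng.normal(size=n)
        vals = np.column_stack([base, base, rng.normal(size=n)])
        panels = {"p1": ["lab_0"], "p2": ["lab_1"], "p3": ["lab_2"]}
        obs = _make_obs(vals, panels=panels)
        plan = build_panel_mask_folds(obs, "lab_0", k=5, seed=SEED)
        r2, detail = evaluate_lab_imputation(obs, plan, CompletionParams(lam=0.05, tol=1e-7))
        assert r2 > 0.99

    def test_independent_target_low_r2(self, rng):
        n = 300
        vals = rng.normal(size=(n, 5))  # everything independent
        panels = {f"p{j}": [f"lab_{j}"] for j in range(5)}
        obs = _make_obs(vals, panels=panels)
        plan = build_panel_mask_folds(obs, "lab_0", k=5, seed=SEED)
        r2, _ = evaluate_lab_imputation(obs, plan, CompletionParams(lam=1.0))
        assert r2 < 0.05

    def test_seed_determinism(self, rng):
        n = 80
        vals = rng.normal(size=(n, 3))
        panels = {f"p{j}": [f"lab_{j}"] for j in range(3)}
        obs = _make_obs(vals, panels=panels)
        p1 = build_panel_mask_folds(obs, "lab_1", k=4, seed=9)
        p2 = build_panel_mask_folds(obs, "lab_1", k=4, seed=9)
        r2a, da = evaluate_lab_imputation(obs, p1, CompletionParams(lam=0.5))
        r2b, db = evaluate_lab_imputation(obs, p2, CompletionParams(lam=0.5))
        assert r2a == r2b
        pd.testing.assert_frame_equal(da, db)


class TestAugment:
    def test_empty_append_identity(self, rng):
        obs = _make_obs(rng.normal(size=(20, 3)))
        out = augment_with_scores(obs, pd.DataFrame(index=obs.values.index))
        assert out is obs

    def test_bookkeeping(self, rng):
        obs = _make_obs(rng.normal(size=(20, 3)))
        scores = pd.DataFrame(rng.normal(size=(20, 2)),
                              index=obs.values.index, columns=["mrs_a", "mrs_b"])
        out = augment_with_scores(obs, scores)
        assert (out.feature_types == "score").sum() == 2
        assert out.observed[["mrs_a", "mrs_b"]].all().all()

    def test_score_columns_never_masked(self, rng):
        vals = rng.normal(size=(60, 3))
        panels = {f"p{j}": [f"lab_{j}"] for j in range(3)}
        obs = _make_obs(vals, panels=panels)
        scores = pd.DataFrame(rng.normal(size=(60, 1)),
                              index=obs.values.index, columns=["mrs"])
        aug = augment_with_scores(obs, scores)
        plan = build_panel_mask_folds(aug, "lab_0", k=5, seed=SEED)
        score_col = aug.values.columns.get_loc("mrs")
        for pairs in plan.induced:
            assert all(c != score_col for _, c in pairs)

    def test_row_mismatch_errors(self, rng):
        obs = _make_obs(rng.normal(size=(10, 2)))
        scores = pd.DataFrame(rng.normal(size=(9, 1)), columns=["mrs"])
        with pytest.raises(ValueError):
            augment_with_scores(obs, scores)


class TestCompare:
    def test_zero_weight_scores_change_nothing(self, rng):
        n = 80
        vals = np.column_stack([rng.normal(size=(n, 2)) @ rng.normal(size=(2, 4))])
        panels = {f"p{j}": [f"lab_{j}"] for j in range(4)}
        mask = rng.random(vals.shape) >= 0.2
        obs = _make_obs(vals, mask, panels=panels)
        plan = build_panel_mask_folds(obs, "lab_0", k=4, seed=SEED)
        zero_scores = pd.DataFrame(np.zeros((n, 1)), index=obs.values.index,
                                   columns=["mrs"])
        cmps = compare_base_vs_augmented(obs, [plan], CompletionParams(lam=0.5),
                                         zero_scores)
        assert cmps[0].pct_change == pytest.approx(0.0, abs=1e-9)

    def test_paired_masks_identical(self, rng):
        # both arms must see byte-identical induced masks
        n = 50
        vals = rng.normal(size=(n, 3))
        panels = {f"p{j}": [f"lab_{j}"] for j in range(3)}
        obs = _make_obs(vals, panels=panels)
        scores = pd.DataFrame(rng.normal(size=(n, 1)), index=obs.values.index,
                              columns=["mrs"])
        aug = augment_with_scores(obs, scores)
        plan = build_panel_mask_folds(obs, "lab_0", k=5, seed=SEED)
        plan_aug = build_panel_mask_folds(aug, "lab_0", k=5, seed=SEED)
        h = lambda p: hashlib.sha256(repr(p.induced).encode()).hexdigest()
        assert h(plan) == h(plan_aug)

    def test_informative_score_improves(self, rng):
        n = 120
        signal = rng.normal(size=n)
        target = signal + 0.3 * rng.normal(size=n)
        others = rng.normal(size=(n, 3))
        vals = np.column_stack([target, others])
        panels = {f"p{j}": [f"lab_{j}"] for j in range(4)}
        mask = rng.random(vals.shape) >= 0.2
        mask[:, 0] = rng.random(n) >= 0.2
        obs = _make_obs(vals, mask, panels=panels)
        plan = build_panel_mask_folds(obs, "lab_0", k=5, seed=SEED)
        scores = pd.DataFrame({"mrs": signal}, index=obs.values.index)
        cmps = compare_base_vs_augmented(obs, [plan], CompletionParams(lam=0.3),
                                         scores)
        assert cmps[0].r2_augmented > cmps[0].r2_base
        assert cmps[0].p_value < 0.01
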