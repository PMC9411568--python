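"""Quality control and derived features for genotype and methylation matrices.

Genotype QC applies, in a fixed and reported order, per-variant missingness,
per-sample missingness, minor-allele-frequency, Hardy-Weinberg and chromosome
filters, then mean-imputes any residual missing dosages.  Methylation QC
drops SNP-overlapping and sex-chromosome probes and low-variability sites.
PCA supports genotype-style (standardized) and methylation-style (centered
only) conventions, and outlying samples are flagged on the leading PCs.
Cell-type proportions are estimated per sample by simplex-constrained least
squares against a reference of mean beta profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "maf", "hwe_test", "qc_genotypes", "qc_methylation",
    "pca", "PCResult", "remove_pc_outliers", "estimate_cell_props",
    "GenotypeQCParams", "MethylationQCParams",
]


def maf(dosage_column) -> float:
    """Minor allele frequency min(f, 1-f) with f = mean(dosage)/2 over the
    observed entries."""
    x = np.asarray(dosage_column, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("all-missing dosage column")
    f = x.mean() / 2.0
    return float(min(f, 1.0 - f))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg proportions.

    Expected counts are n*(p^2, 2pq, q^2) at the observed allele frequency.
    Monomorphic variants return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class GenotypeQCParams:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    max_missing: float = 0.01
    autosomes_only: bool = True


@dataclass
class MethylationQCParams:
    sd_min: float = 0.02
    drop_snp_overlap: bool = True
    drop_sex_chr: bool = True


def _hwe_counts(col: np.ndarray) -> tuple[int, int, int]:
    # dosages may be fractional after upstream imputation; use hard calls
    calls = np.rint(col[~np.isnan(col)]).astype(int)
    return int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())


def qc_genotypes(dosages: pd.DataFrame, params: GenotypeQCParams | None = None,
                 variant_annotation: pd.DataFrame | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Filter variants and samples, then mean-impute residual missing dosages.

    Filters run in a fixed order -- variant missingness, sample missingness,
    MAF, HWE, chromosome -- and the report counts removals at each step so
    order-dependent discrepancies stay diagnosable.  Thresholds follow the
    usual conventions: a variant or sample is removed when its missing
    fraction exceeds ``max_missing`` (strictly), a variant when MAF <
    ``maf_min`` or HWE p < ``hwe_p_min``.
    """
    params = params or GenotypeQCParams()
    X = dosages.copy()
    report: dict = {"steps": []}

    miss_var = X.isna().mean(axis=0)
    drop = miss_var.index[miss_var > params.max_missing]
    X = X.drop(columns=drop)
    report["steps"].append({"step": "variant_missingness", "removed": int(len(drop))})

    miss_smp = X.isna().mean(axis=1)
    drop_s = miss_smp.index[miss_smp > params.max_missing]
    X = X.drop(index=drop_s)
    report["steps"].append({"step": "sample_missingness", "removed": int(len(drop_s))})

    mafs = X.apply(maf, axis=0)
    drop = mafs.index[mafs < params.maf_min]
    X = X.drop(columns=drop)
    report["steps"].append({"step": "maf", "removed": int(len(drop))})

    hwe_p = X.apply(lambda c: hwe_test(*_hwe_counts(c.to_numpy(dtype=float))), axis=0)
    drop = hwe_p.index[hwe_p < params.hwe_p_min]
    X = X.drop(columns=drop)
    report["steps"].append({"step": "hwe", "removed": int(len(drop))})

    if params.autosomes_only and variant_annotation is not None and "chromosome" in variant_annotation:
        chrom = variant_annotation.loc[variant_annotation.index.intersection(X.columns), "chromosome"]
        sex = chrom.index[chrom.astype(str).isin(["X", "Y", "23", "24", "chrX", "chrY"])]
        X = X.drop(columns=sex)
        report["steps"].append({"step": "autosomes", "removed": int(len(sex))})

    if X.shape[1] == 0 or X.shape[0] == 0:
        raise RuntimeError("genotype QC removed every variant or sample")
    if X.isna().any().any():
        X = X.fillna(X.mean(axis=0))
        report["mean_imputed"] = True
    report["n_samples"], report["n_variants"] = X.shape
    return X, report


def qc_methylation(betas: pd.DataFrame, params: MethylationQCParams | None = None,
                   site_annotation: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Drop SNP-overlapping probes, sex-chromosome probes, and sites with
    standard deviation below ``sd_min`` (strict <, so sd == sd_min is kept)."""
    params = params or MethylationQCParams()
    X = betas.copy()
    report: dict = {"steps": []}
    if (params.drop_snp_overlap or params.drop_sex_chr) and site_annotation is not None:
        ann = site_annotation.reindex(X.columns)
        if params.drop_snp_overlap and "snp_overlap" in ann:
            drop = ann.index[ann["snp_overlap"].fillna(False).astype(bool)]
            X = X.drop(columns=drop)
            report["steps"].append({"step": "snp_overlap", "removed": int(len(drop))})
        if params.drop_sex_chr and "chromosome" in ann:
            chrom = ann.loc[ann.index.intersection(X.columns), "chromosome"].astype(str)
            drop = chrom.index[chrom.isin(["X", "Y", "chrX", "chrY"])]
            X = X.drop(columns=drop)
            report["steps"].append({"step": "sex_chromosomes", "removed": int(len(drop))})
    sds = X.std(axis=0, ddof=0)
    drop = sds.index[sds < params.sd_min]
    X = X.drop(columns=drop)
    report["steps"].append({"step": "low_variability", "removed": int(len(drop))})
    report["n_samples"], report["n_sites"] = X.shape
    return X, report


@dataclass
class PCResult:
    scores: pd.DataFrame                 # samples x k
    explained_variance_ratio: np.ndarray


def pca(matrix: pd.DataFrame, k: int, standardize: bool = False) -> PCResult:
    """Principal-component scores of the column-centered (optionally
    column-standardized) matrix via SVD.

    Sign convention: within each component, the loading with the largest
    magnitude is made positive, so scores are reproducible across runs.
    """
    X = matrix.to_numpy(dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(matrix dims)={min(X.shape)}")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = (U * s) * flip[None, :]
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    return PCResult(
        scores=pd.DataFrame(scores[:, :k], index=matrix.index,
                            columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance_ratio=evr[:k],
    )


def remove_pc_outliers(pc: PCResult, n_sd: float = 4.0, n_pcs: int = 2) -> pd.Index:
    """Samples whose |score - mean| <= n_sd * sd on each of the first
    ``n_pcs`` components (single pass, strict > flags an outlier)."""
    if n_pcs > pc.scores.shape[1]:
        raise ValueError("n_pcs exceeds available components")
    S = pc.scores.iloc[:, :n_pcs].to_numpy()
    z = np.abs(S - S.mean(axis=0)) / S.std(axis=0, ddof=0)
    # a sample at exactly n_sd is kept; the relative guard absorbs round-off
    keep = (z <= n_sd * (1.0 + 1e-12)).all(axis=1)
    return pc.scores.index[keep]


def estimate_cell_props(betas: pd.DataFrame, cell_reference: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Reference-based cell-type deconvolution.

    Per sample, minimize || beta_ref_sites - R p ||^2 subject to p >= 0 and
    sum(p) = 1 (SLSQP with the simplex constraints).  Rows of the result sum
    to one within 1e-6.
    """
    missing = cell_reference.index.difference(betas.columns)
    if len(missing):
        raise ValueError(f"{len(missing)} reference CpGs absent from the matrix")
    R = cell_reference.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        import warnings
        warnings.warn("cell-type reference is rank-deficient; proportions may "
                      "not be uniquely identified", RuntimeWarning, stacklevel=2)
    B = betas[cell_reference.index].to_numpy(dtype=float)
    k = R.shape[1]
    RtR = R.T @ R
    x0 = np.full(k, 1.0 / k)
    cons = ({"type": "eq", "fun": lambda p: p.sum() - 1.0, "jac": lambda p: np.ones(k)},)
    bounds = [(0.0, 1.0)] * k
    out = np.empty((B.shape[0], k))
    for i in range(B.shape[0]):
        b = B[i]
        Rtb = R.T @ b
        res = optimize.minimize(
            lambda p: 0.5 * p @ RtR @ p - Rtb @ p,
            x0, jac=lambda p: RtR @ p - Rtb,
            bounds=bounds, constraints=cons, method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        p = np.clip(res.x, 0.0, None)
        out[i] = p / p.sum()
    return pd.DataFrame(out, index=betas.index, columns=cell_reference.columns)
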