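"""Seeded synthetic biobank cohorts for methylation risk-score analyses.

The generator emulates the statistical structure the downstream models
assume: CpG beta values arise as mixtures of cell-type reference profiles
plus sparse phenotype-linked effects and measurement noise; genotype dosages
are independent binomial draws in Hardy-Weinberg proportions; binary
outcomes follow a logistic model and continuous outcomes a linear model on a
sparse genomic linear predictor plus covariates; lab missingness is
panel-structured (a missing panel blanks every member lab for that sample).

Each sub-generator draws from its own RNG stream, split deterministically
from the master seed, so e.g. changing the number of variants does not
perturb the methylation draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig", "SyntheticCohort", "TruthRecord", "SimulationError",
    "simulate_cell_reference", "simulate_cell_props", "simulate_methylation",
    "simulate_genotypes", "simulate_covariates", "simulate_outcomes",
    "simulate_lab_missingness", "simulate_cohort",
]

SMOKING_LEVELS = ("never", "former", "current")
GROUP_LEVELS = ("group_a", "group_b", "group_c", "group_d")


class SimulationError(RuntimeError):
    """Raised when a requested cohort property cannot be realized."""


@dataclass
class SimulationConfig:
    """Conditions under which a synthetic cohort is generated.

    ``effect_size_sd`` is the spread of raw causal effects before the global
    rescaling that pins the oracle signal fraction at ``target_oracle_r2``
    (when set).  ``noise_sd`` is the residual SD of continuous outcomes;
    ``meth_noise_sd`` is the measurement noise on beta values, kept <= 0.05 so
    clipping to [0, 1] stays negligible.
    """

    n_samples: int = 800
    n_cpgs: int = 2000
    n_variants: int = 1000
    n_cell_types: int = 5
    causal_cpgs_per_outcome: int = 20
    causal_variants_per_outcome: int = 10
    effect_size_sd: float = 1.0
    noise_sd: float = 1.0
    meth_noise_sd: float = 0.02
    binary_prevalence: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.45)
    panel_spec: list[tuple[str, list[str]]] = field(default_factory=list)
    missing_rate: float = 0.3
    seed: int = 0
    n_binary_outcomes: int = 1
    n_continuous_outcomes: int = 1
    target_oracle_r2: float | None = 0.5

    def __post_init__(self):
        for name in ("n_samples", "n_cpgs", "n_variants", "n_cell_types",
                     "causal_cpgs_per_outcome", "causal_variants_per_outcome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.binary_prevalence < 1.0):
            raise ValueError("binary_prevalence must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated outcome."""

    outcome: str
    kind: str  # "binary" or "continuous"
    causal_cpgs: list[str]
    cpg_effects: np.ndarray
    causal_variants: list[str]
    variant_effects: np.ndarray
    covariate_effects: dict[str, float]
    intercept: float
    linear_predictor: np.ndarray  # noiseless, per sample
    oracle_r2: float | None  # continuous: var(lp) / (var(lp) + noise_sd^2)


@dataclass
class SyntheticCohort:
    methylation: pd.DataFrame       # samples x CpGs, betas in [0, 1]
    genotypes: pd.DataFrame         # samples x variants, dosages in {0,1,2}
    covariates: pd.DataFrame        # raw (un-encoded) covariate table
    outcomes: pd.DataFrame          # samples x outcomes
    outcome_types: dict[str, str]   # outcome id -> binary|continuous
    truth: dict[str, TruthRecord]
    cell_reference: pd.DataFrame    # CpGs x cell types
    true_cell_props: pd.DataFrame   # samples x cell types, rows sum to 1
    config: SimulationConfig


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_cell_reference(n_cpgs: int, n_cell_types: int, seed=0) -> pd.DataFrame:
    """Mean beta per (CpG, cell type).

    Each CpG has a shared baseline methylation level; cell types deviate from
    it independently, which makes the reference columns distinguishable (the
    deconvolution problem is then identifiable).
    """
    if n_cpgs <= 0 or n_cell_types < 2:
        raise ValueError("need n_cpgs >= 1 and n_cell_types >= 2")
    rng = _rng(seed)
    base = rng.uniform(0.05, 0.95, size=n_cpgs)
    ref = np.clip(base[:, None] + rng.normal(0.0, 0.15, size=(n_cpgs, n_cell_types)), 0.0, 1.0)
    ref = pd.DataFrame(ref,
                       index=[f"cg{j:06d}" for j in range(n_cpgs)],
                       columns=[f"cell_{k}" for k in range(n_cell_types)])
    _check_reference(ref)
    return ref


def _check_reference(ref: pd.DataFrame) -> None:
    vals = ref.to_numpy()
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("reference betas must lie in [0, 1]")
    k = vals.shape[1]
    for a in range(k):
        for b in range(a + 1, k):
            if np.abs(vals[:, a] - vals[:, b]).mean() <= 0.0:
                raise ValueError(f"reference columns {a} and {b} are identical")


def simulate_cell_props(n_samples: int, n_cell_types: int, seed=0,
                        concentration: float = 5.0) -> pd.DataFrame:
    """Dirichlet cell-type proportions, rows summing to one."""
    rng = _rng(seed)
    props = rng.dirichlet(np.full(n_cell_types, concentration), size=n_samples)
    return pd.DataFrame(props,
                        index=[f"s{i:05d}" for i in range(n_samples)],
                        columns=[f"cell_{k}" for k in range(n_cell_types)])


def simulate_methylation(cell_reference: pd.DataFrame, true_props: pd.DataFrame,
                         noise_sd: float, seed=0) -> pd.DataFrame:
    """beta_ij = clip( sum_k props_ik * ref_jk + eps, 0, 1 ).

    Additive Gaussian noise with clipping; adequate for noise_sd <= 0.05,
    where clipping artifacts are negligible because mixture means rarely sit
    within one noise SD of the boundary.
    """
    if list(true_props.columns) != list(cell_reference.columns):
        raise ValueError("cell-type columns of props and reference must match")
    rng = _rng(seed)
    mix = true_props.to_numpy() @ cell_reference.to_numpy().T
    betas = np.clip(mix + rng.normal(0.0, noise_sd, size=mix.shape), 0.0, 1.0)
    return pd.DataFrame(betas, index=true_props.index, columns=cell_reference.index)


def simulate_genotypes(n_samples: int, n_variants: int,
                       maf_range=(0.05, 0.45), seed=0) -> pd.DataFrame:
    """Independent dosages ~ Binomial(2, p), p uniform on maf_range (HWE)."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, p, size=(n_samples, n_variants)).astype(float)
    return pd.DataFrame(dosages,
                        index=[f"s{i:05d}" for i in range(n_samples)],
                        columns=[f"rs{j:06d}" for j in range(n_variants)])


def simulate_covariates(n_samples: int, seed=0) -> pd.DataFrame:
    """Baseline covariates: age ~ U(18, 90), sex ~ Bernoulli(1/2), 3-level
    smoking status and a 4-level self-reported group."""
    rng = _rng(seed)
    return pd.DataFrame({
        "age": rng.uniform(18.0, 90.0, size=n_samples),
        "sex": rng.integers(0, 2, size=n_samples).astype(float),
        "smoking": rng.choice(SMOKING_LEVELS, size=n_samples, p=(0.55, 0.3, 0.15)),
        "group": rng.choice(GROUP_LEVELS, size=n_samples, p=(0.55, 0.2, 0.15, 0.1)),
    }, index=[f"s{i:05d}" for i in range(n_samples)])


def _covariate_numeric(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding used inside the generative linear predictor."""
    out = pd.DataFrame(index=covariates.index)
    out["age"] = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std(ddof=0)
    out["sex"] = covariates["sex"].astype(float)
    for lev in SMOKING_LEVELS[1:]:
        out[f"smoking_{lev}"] = (covariates["smoking"] == lev).astype(float)
    for lev in GROUP_LEVELS[1:]:
        out[f"group_{lev}"] = (covariates["group"] == lev).astype(float)
    return out


def _tune_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection on expected prevalence mean(sigmoid(a + lp)) = prevalence."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + lp)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_outcomes(methylation: pd.DataFrame, genotypes: pd.DataFrame,
                      covariates: pd.DataFrame, config: SimulationConfig,
                      seed=0) -> tuple[pd.DataFrame, dict[str, str], dict[str, TruthRecord]]:
    """Sparse-effect outcomes on the cohort's features.

    Continuous:  y = a + M_c b_M + G_c b_G + C b_C + eps,  eps ~ N(0, noise_sd^2)
    Binary:      y ~ Bernoulli(sigmoid(a + lp)), with the intercept tuned by
                 bisection so the empirical prevalence lands within +-0.02 of
                 ``config.binary_prevalence``.

    When ``config.target_oracle_r2`` is set, the noiseless linear predictor is
    rescaled so the continuous signal fraction var(lp)/(var(lp)+noise_sd^2)
    equals it; binary predictors are rescaled against the logistic latent
    variance pi^2/3 by the same rule.
    """
    if not (methylation.index.equals(genotypes.index) and methylation.index.equals(covariates.index)):
        raise ValueError("methylation, genotypes and covariates must be row-aligned")
    rng = _rng(seed)
    n = len(methylation)
    cnum = _covariate_numeric(covariates)
    outcomes = {}
    types: dict[str, str] = {}
    truth: dict[str, TruthRecord] = {}

    specs = [("lab", "continuous")] * config.n_continuous_outcomes + \
            [("phecode", "binary")] * config.n_binary_outcomes
    counters = {"lab": 0, "phecode": 0}
    for prefix, kind in specs:
        counters[prefix] += 1
        name = f"{prefix}_{counters[prefix]}"
        cpg_idx = rng.choice(methylation.shape[1], size=config.causal_cpgs_per_outcome, replace=False)
        var_idx = rng.choice(genotypes.shape[1], size=config.causal_variants_per_outcome, replace=False)
        b_m = rng.normal(0.0, config.effect_size_sd, size=cpg_idx.size)
        b_g = rng.normal(0.0, 0.25 * config.effect_size_sd, size=var_idx.size)
        b_c = rng.normal(0.0, 0.2 * config.effect_size_sd, size=cnum.shape[1])

        M = methylation.iloc[:, cpg_idx].to_numpy()
        G = genotypes.iloc[:, var_idx].to_numpy()
        # effects act on standardized features so effect_size_sd has one scale
        Ms = (M - M.mean(0)) / np.where(M.std(0) > 0, M.std(0), 1.0)
        Gs = (G - G.mean(0)) / np.where(G.std(0) > 0, G.std(0), 1.0)
        lp = Ms @ b_m + Gs @ b_g + cnum.to_numpy() @ b_c

        if config.target_oracle_r2 is not None:
            latent = config.noise_sd ** 2 if kind == "continuous" else np.pi ** 2 / 3.0
            want = latent * config.target_oracle_r2 / (1.0 - config.target_oracle_r2)
            sd = lp.std(ddof=0)
            if sd <= 0:
                raise SimulationError(f"degenerate linear predictor for {name}")
            scale = np.sqrt(want) / sd
            lp, b_m, b_g, b_c = lp * scale, b_m * scale, b_g * scale, b_c * scale

        if kind == "continuous":
            intercept = 0.0
            y = intercept + lp + rng.normal(0.0, config.noise_sd, size=n)
            oracle = float(np.var(lp) / (np.var(lp) + config.noise_sd ** 2)) \
                if config.noise_sd > 0 else 1.0
        else:
            intercept = _tune_intercept(lp, config.binary_prevalence)
            y = None
            for _ in range(20):
                draw = (rng.random(n) < 1.0 / (1.0 + np.exp(-(intercept + lp)))).astype(float)
                emp = draw.mean()
                if abs(emp - config.binary_prevalence) <= 0.02:
                    y = draw
                    break
                # nudge on the logit scale toward the target and redraw
                emp_c = min(max(emp, 1e-6), 1 - 1e-6)
                tgt = config.binary_prevalence
                intercept += np.log(tgt / (1 - tgt)) - np.log(emp_c / (1 - emp_c))
            if y is None:
                raise SimulationError(
                    f"could not reach prevalence {config.binary_prevalence} for {name}")
            oracle = None

        outcomes[name] = y
        types[name] = kind
        truth[name] = TruthRecord(
            outcome=name, kind=kind,
            causal_cpgs=list(methylation.columns[cpg_idx]), cpg_effects=b_m,
            causal_variants=list(genotypes.columns[var_idx]), variant_effects=b_g,
            covariate_effects=dict(zip(cnum.columns, b_c)),
            intercept=float(intercept),
            linear_predictor=intercept + lp, oracle_r2=oracle,
        )
    return pd.DataFrame(outcomes, index=methylation.index), types, truth


def simulate_lab_missingness(lab_matrix: pd.DataFrame,
                             panel_spec: list[tuple[str, list[str]]],
                             missing_rate: float, seed=0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel-structured missingness: each (sample, panel) pair goes missing
    with probability ``missing_rate``; a missing panel blanks all member labs.

    Returns (values with NaN at missing cells, boolean observed mask).
    """
    members: dict[str, list[str]] = {}
    for panel_id, labs in panel_spec:
        for lab in labs:
            members.setdefault(lab, []).append(panel_id)
    for lab in lab_matrix.columns:
        if lab not in members:
            raise ValueError(f"lab {lab!r} belongs to no panel in panel_spec")
    rng = _rng(seed)
    n = len(lab_matrix)
    observed = pd.DataFrame(True, index=lab_matrix.index, columns=lab_matrix.columns)
    panel_missing = {panel_id: rng.random(n) < missing_rate for panel_id, _ in panel_spec}
    for panel_id, labs in panel_spec:
        miss = panel_missing[panel_id]
        for lab in labs:
            if lab in observed.columns:
                observed.loc[miss, lab] = False
    values = lab_matrix.where(observed)
    return values, observed


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort under one master seed; one RNG stream per sub-generator."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    ref = simulate_cell_reference(config.n_cpgs, config.n_cell_types,
                                  np.random.default_rng(streams[0]))
    props = simulate_cell_props(config.n_samples, config.n_cell_types,
                                np.random.default_rng(streams[1]))
    meth = simulate_methylation(ref, props, config.meth_noise_sd,
                                np.random.default_rng(streams[2]))
    geno = simulate_genotypes(config.n_samples, config.n_variants, config.maf_range,
                              np.random.default_rng(streams[3]))
    cov = simulate_covariates(config.n_samples, np.random.default_rng(streams[4]))
    outcomes, types, truth = simulate_outcomes(meth, geno, cov, config,
                                               np.random.default_rng(streams[5]))
    return SyntheticCohort(methylation=meth, genotypes=geno, covariates=cov,
                           outcomes=outcomes, outcome_types=types, truth=truth,
                           cell_reference=ref, true_cell_props=props, config=config)
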