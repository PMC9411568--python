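"""Plain-text interchange formats.

Cohort matrices travel as TSV (sample_id index column, one column per
feature, floats at 10 significant digits); ground truth as JSON.  Trained
weight vectors use a two-column TSV (feature_id, weight) with ``#key=value``
header lines and a JSON sidecar carrying the intercept and covariate
effects, so a score can be recomputed bit-for-bit from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import FittedRiskModel, PenaltySpec
from .synthetic import SyntheticCohort

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv", "write_cohort", "read_cohort_matrices",
    "save_weights", "load_weights",
]

_FLOAT_FMT = "%.10g"


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """betas.tsv, dosages.tsv, covariates.tsv, outcomes.tsv, panels.tsv,
    truth.json under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(cohort.methylation, out / "betas.tsv")
    write_matrix_tsv(cohort.genotypes, out / "dosages.tsv")
    write_matrix_tsv(cohort.covariates, out / "covariates.tsv")
    write_matrix_tsv(cohort.outcomes, out / "outcomes.tsv")
    panels = pd.DataFrame(
        [(pid, lab) for pid, labs in cohort.config.panel_spec for lab in labs],
        columns=["panel_id", "lab_id"])
    panels.to_csv(out / "panels.tsv", sep="\t", index=False)
    truth = {
        name: {
            "kind": t.kind,
            "causal_cpgs": t.causal_cpgs,
            "cpg_effects": [float(v) for v in t.cpg_effects],
            "causal_variants": t.causal_variants,
            "variant_effects": [float(v) for v in t.variant_effects],
            "covariate_effects": {k: float(v) for k, v in t.covariate_effects.items()},
            "intercept": t.intercept,
            "oracle_r2": t.oracle_r2,
            "linear_predictor": [float(v) for v in t.linear_predictor],
        }
        for name, t in cohort.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort_matrices(indir) -> dict[str, pd.DataFrame]:
    ind = Path(indir)
    return {name: read_matrix_tsv(ind / f"{name}.tsv")
            for name in ("betas", "dosages", "covariates", "outcomes")}


def save_weights(model: FittedRiskModel, path, outcome: str = "",
                 data_type: str | None = None) -> None:
    """Weight TSV with header metadata plus a .json sidecar for the intercept
    and covariate effects."""
    path = Path(path)
    family = model.penalty.family if model.penalty else "unpenalized"
    lines = [
        f"#outcome={outcome}",
        f"#family={family}",
        f"#n_train={len(model.training_samples)}",
        f"#data_type={data_type or model.data_type or ''}",
        f"#link={model.link}",
        "feature_id\tweight",
    ]
    for fid, w in model.weights.items():
        lines.append(f"{fid}\t{w!r}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "intercept": model.intercept,
        "covariate_effects": {k: float(v) for k, v in model.covariate_effects.items()},
        "lam": model.lam,
        "link": model.link,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_weights(path) -> tuple[FittedRiskModel, dict]:
    """Inverse of :func:`save_weights`: (model, header metadata)."""
    path = Path(path)
    meta: dict = {}
    ids, ws = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif line and not line.startswith("feature_id"):
                fid, w = line.split("\t")
                ids.append(fid)
                ws.append(float(w))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    link = sidecar.get("link", "linear")
    penalty = None
    if meta.get("family") in ("lasso", "elastic_net", "ridge"):
        penalty = PenaltySpec(family=meta["family"], link=link)
    model = FittedRiskModel(
        intercept=float(sidecar["intercept"]),
        covariate_effects=pd.Series(sidecar.get("covariate_effects", {}), dtype=float),
        weights=pd.Series(np.asarray(ws, dtype=float), index=ids),
        link=link, penalty=penalty, lam=sidecar.get("lam"),
        data_type=meta.get("data_type") or None,
    )
    return model, meta
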