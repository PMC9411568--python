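"""Aggregation of raw EHR event tables into outcome matrices.

Diagnosis records map to binary Phecode indicators, medication orders to
binary pharmaceutical-subclass indicators (via GPI prefixes), and lab events
to the most recent value inside a recency window.  Every aggregation is
temporally safe: only events dated strictly before a patient's sample
collection date contribute, at date resolution, so an event on the
collection date itself never leaks into an outcome.

Expected input frames (one row per event):
  diagnoses:    patient_id, icd_code, icd_version (9 or 10), event_date
  medications:  patient_id, gpi_code, order_date
  labs:         patient_id, lab_id, value, result_date
  sample_dates: a Series indexed by patient_id
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_phecodes", "filter_rare_binary", "aggregate_medications",
    "extract_recent_labs",
]

logger = logging.getLogger(__name__)


def _check_sample_dates(records: pd.DataFrame, sample_dates: pd.Series) -> None:
    missing = set(records["patient_id"]) - set(sample_dates.index)
    if missing:
        raise ValueError(f"patients without a sample date: {sorted(missing)[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")


def aggregate_phecodes(records: pd.DataFrame, phecode_map: pd.DataFrame,
                       sample_dates: pd.Series) -> pd.DataFrame:
    """Binary patient x Phecode matrix.

    An entry is 1 iff the patient carries at least one mapped diagnosis dated
    strictly before their sample collection date.  When a record carries both
    ICD versions (duplicated rows for the same patient/date with version 9
    and 10), only the ICD-10 row of that (patient, date) pair is consulted.
    Unmapped codes are dropped with a logged count.
    """
    _check_sample_dates(records, sample_dates)
    rec = records.copy()
    rec["event_date"] = pd.to_datetime(rec["event_date"]).dt.normalize()
    cutoff = pd.to_datetime(sample_dates).dt.normalize()
    rec = rec[rec["event_date"] < rec["patient_id"].map(cutoff)]

    # a dual-coded record: same patient and date carrying both versions
    has10 = rec[rec["icd_version"] == 10].groupby(["patient_id", "event_date"]).size()
    dual = rec.set_index(["patient_id", "event_date"]).index.isin(has10.index)
    rec = rec[~(dual & (rec["icd_version"] == 9).to_numpy())]

    pm = phecode_map.set_index(["icd_code", "icd_version"])["phecode"]
    keys = pd.MultiIndex.from_frame(rec[["icd_code", "icd_version"]])
    mapped = pm.reindex(keys)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.info("aggregate_phecodes: dropped %d unmapped diagnosis records", n_unmapped)
    rec = rec.assign(phecode=mapped.to_numpy())
    rec = rec.dropna(subset=["phecode"])

    patients = sample_dates.index
    phecodes = sorted(phecode_map["phecode"].astype(str).unique())
    mat = pd.DataFrame(0, index=patients, columns=phecodes, dtype=int)
    if len(rec):
        hits = rec.groupby(["patient_id", "phecode"]).size()
        for (pid, code), _ in hits.items():
            mat.loc[pid, str(code)] = 1
    return mat


def filter_rare_binary(matrix: pd.DataFrame, min_prevalence: float = 0.05,
                       ) -> tuple[pd.DataFrame, pd.Index]:
    """Keep binary columns with prevalence >= min_prevalence (a column at
    exactly 5% is kept: the exclusion rule is occurrence in < 5%)."""
    prev = matrix.mean(axis=0)
    kept = prev.index[prev >= min_prevalence]
    return matrix[kept], kept


def aggregate_medications(orders: pd.DataFrame, gpi_prefix_len: int = 6,
                          sample_dates: pd.Series | None = None,
                          subclass_map: pd.Series | None = None) -> pd.DataFrame:
    """Binary patient x pharmaceutical-subclass matrix.

    Orders are grouped at the subclass level of the GPI hierarchy -- by
    default the first 6 characters of the GPI code, or through an explicit
    ``subclass_map`` (GPI prefix -> subclass label).  An entry is 1 iff at
    least one order in that subclass predates the sample date strictly; an
    order on the collection date contributes nothing.  Unmapped GPI codes
    are dropped with a logged count.
    """
    if sample_dates is None:
        raise ValueError("sample_dates is required")
    _check_sample_dates(orders, sample_dates)
    ord_ = orders.copy()
    ord_["order_date"] = pd.to_datetime(ord_["order_date"]).dt.normalize()
    cutoff = pd.to_datetime(sample_dates).dt.normalize()
    ord_ = ord_[ord_["order_date"] < ord_["patient_id"].map(cutoff)]

    prefix = ord_["gpi_code"].astype(str).str[:gpi_prefix_len]
    if subclass_map is not None:
        subclass = prefix.map(subclass_map)
        n_unmapped = int(subclass.isna().sum())
        if n_unmapped:
            logger.info("aggregate_medications: dropped %d orders with unmapped GPI", n_unmapped)
        ord_ = ord_.assign(subclass=subclass).dropna(subset=["subclass"])
    else:
        ord_ = ord_.assign(subclass=prefix)

    patients = sample_dates.index
    subclasses = sorted(ord_["subclass"].unique())
    mat = pd.DataFrame(0, index=patients, columns=subclasses, dtype=int)
    for (pid, sub), _ in ord_.groupby(["patient_id", "subclass"]).size().items():
        mat.loc[pid, sub] = 1
    return mat


def extract_recent_labs(events: pd.DataFrame, sample_dates: pd.Series,
                        window_days: int = 365, min_patients: int = 50,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Most recent lab value per patient within the recency window.

    A value qualifies when sample_date - window_days <= result_date <
    sample_date; ties on the most recent qualifying date are averaged.  Labs
    with fewer than ``min_patients`` valid entries are dropped.  Returns
    (values with NaN where unobserved, boolean observed mask).
    """
    _check_sample_dates(events, sample_dates)
    ev = events.copy()
    ev["result_date"] = pd.to_datetime(ev["result_date"]).dt.normalize()
    cutoff = pd.to_datetime(sample_dates).dt.normalize()
    ev_cut = ev["patient_id"].map(cutoff)
    keep = (ev["result_date"] < ev_cut) & \
           (ev["result_date"] >= ev_cut - pd.to_timedelta(window_days, unit="D"))
    ev = ev[keep]
    if not np.isfinite(ev["value"]).all():
        raise ValueError("lab values must be finite")

    patients = sample_dates.index
    if len(ev):
        latest = ev.groupby(["patient_id", "lab_id"])["result_date"].transform("max")
        recent = ev[ev["result_date"] == latest]
        values = recent.groupby(["patient_id", "lab_id"])["value"].mean().unstack()
    else:
        values = pd.DataFrame(index=patients)
    values = values.reindex(index=patients)
    n_valid = values.notna().sum(axis=0)
    values = values[n_valid.index[n_valid >= min_patients]]
    return values, values.notna()
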