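"""Aggregate raw EHR event tables into analysis-ready outcomes.

Diagnosis codes map to binary Phecodes (ICD-10 preferred on dual-coded
records), medication orders collapse to pharmaceutical subclasses via GPI
prefixes, and labs keep the most recent value within a 365-day window --
all strictly before each patient's sample collection date, so nothing
post-dating the methylation draw can leak into an outcome.
"""

import pandas as pd

from methrisk import ehr

D = pd.Timestamp("2017-06-01")
sample_dates = pd.Series([D, D, D], index=["p1", "p2", "p3"])

diagnoses = pd.DataFrame({
    "patient_id": ["p1", "p1", "p2", "p3"],
    "icd_code": ["250.00", "E11.9", "401.1", "250.00"],
    "icd_version": [9, 10, 10, 9],
    "event_date": [D - pd.Timedelta(days=400), D - pd.Timedelta(days=30),
                   D - pd.Timedelta(days=10), D + pd.Timedelta(days=5)],
})
phecode_map = pd.DataFrame({
    "icd_code": ["250.00", "E11.9", "401.1"],
    "icd_version": [9, 10, 10],
    "phecode": ["250.2", "250.2", "401"],
})
phe = ehr.aggregate_phecodes(diagnoses, phecode_map, sample_dates)
print("Phecode matrix (1 = any mapped diagnosis before sampling):")
print(phe)
# p3's record post-dates the sample draw, so their row stays zero

orders = pd.DataFrame({
    "patient_id": ["p1", "p2", "p2"],
    "gpi_code": ["58200010100110", "58200020100110", "36150010100105"],
    "order_date": [D - pd.Timedelta(days=20)] * 3,
})
meds = ehr.aggregate_medications(orders, sample_dates=sample_dates)
print("\nMedication subclasses (GPI 6-character prefix):")
print(meds)

labs = pd.DataFrame({
    "patient_id": ["p1", "p1", "p2"],
    "lab_id": ["creatinine"] * 3,
    "value": [0.9, 1.1, 2.4],
    "result_date": [D - pd.Timedelta(days=200), D - pd.Timedelta(days=10),
                    D - pd.Timedelta(days=400)],
})
vals, mask = ehr.extract_recent_labs(labs, sample_dates, min_patients=1)
print("\nMost recent creatinine inside the 365-day window:")
print(vals)
# p1 keeps the day-10 value (most recent); p2's day-400 result is too old
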