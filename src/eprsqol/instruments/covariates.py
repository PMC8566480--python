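"""Derived covariates: HOMA-IR, LTPA volume, comorbidity class, glucose status.

- HOMA-IR = fasting glucose (mmol/l) x fasting insulin (mU/l) / 22.5.
- Leisure-time physical activity volume = sum over reported activities of
  MET x duration (hours) x weekly frequency, in MET-hours/week.
- Comorbidity class caps the chronic-condition count at "2+".
- Glucose regulation status follows the WHO 2006 cut-offs on the 75 g OGTT:
  diabetes when fasting >= 7.0 mmol/l or 2-h >= 11.1 mmol/l (or a known
  diabetes flag from self-report/medication/registry); prediabetes (impaired
  fasting glucose or impaired glucose tolerance pooled) when fasting is
  6.1-6.9 mmol/l or 2-h is 7.8-11.0 mmol/l; otherwise normoglycaemia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

HOMA_DENOMINATOR = 22.5

GLUCOSE_CATEGORIES = ["normoglycaemia", "prediabetes", "diabetes"]
COMORBIDITY_CLASSES = ["0", "1", "2+"]


def homa_ir(fasting_glucose, fasting_insulin):
    """HOMA insulin-resistance index (inputs mmol/l and mU/l)."""
    fg = np.asarray(fasting_glucose, dtype=float)
    fi = np.asarray(fasting_insulin, dtype=float)
    if (fg <= 0).any() or (fi <= 0).any():
        raise ValueError("fasting glucose and insulin must be positive")
    out = fg * fi / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def ltpa_met_hours(activities: Iterable[tuple[float, float, float]]) -> float:
    """MET-hours/week from (MET, hours per session, sessions per week) tuples."""
    total = 0.0
    for met, hours, freq in activities:
        if met < 0 or hours < 0 or freq < 0:
            raise ValueError("activity components must be non-negative")
        total += met * hours * freq
    return total


def comorbidity_class(count) -> str | np.ndarray:
    """Cap the chronic-condition count at two-or-more."""
    arr = np.asarray(count)
    if (arr < 0).any():
        raise ValueError("comorbidity count must be non-negative")
    out = np.where(arr >= 2, "2+", arr.astype(int).astype(str))
    return str(out) if out.ndim == 0 else out


def glucose_status(fasting, two_hour, known_diabetes=False):
    """WHO 2006 OGTT classification; vectorized over array inputs."""
    fg = np.asarray(fasting, dtype=float)
    g2 = np.asarray(two_hour, dtype=float)
    flag = np.asarray(known_diabetes, dtype=bool)
    if (fg < 0).any() or (g2 < 0).any():
        raise ValueError("glucose values must be non-negative")
    diabetes = (fg >= 7.0) | (g2 >= 11.1) | flag
    pre = (~diabetes) & (((fg >= 6.1) & (fg <= 6.9)) | ((g2 >= 7.8) & (g2 <= 11.0)))
    out = np.where(diabetes, "diabetes", np.where(pre, "prediabetes", "normoglycaemia"))
    return str(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CovariateRecord:
    age: float
    sex: str
    smoking: str
    alcohol: str
    ses: str
    comorbidity_class: str
    bmi: float
    ltpa_met_h_wk: float
    homa_ir: float
    glucose_status: str


def derive_covariates(raw: dict) -> CovariateRecord:
    """Build one sample's covariate record from raw phenotype fields.

    Expects keys ``age, sex, smoking, alcohol, ses, n_chronic, bmi,
    glucose_0, glucose_120, insulin_0`` and activity triples
    ``ltpa_met_i, ltpa_hours_i, ltpa_freq_i`` (i = 1..k, absent or zero for
    unused slots); optional ``known_diabetes``.
    """
    if raw["bmi"] <= 0:
        raise ValueError("BMI must be positive")
    acts = []
    i = 1
    while f"ltpa_met_{i}" in raw:
        acts.append((raw[f"ltpa_met_{i}"], raw[f"ltpa_hours_{i}"], raw[f"ltpa_freq_{i}"]))
        i += 1
    return CovariateRecord(
        age=float(raw["age"]),
        sex=str(raw["sex"]),
        smoking=str(raw["smoking"]),
        alcohol=str(raw["alcohol"]),
        ses=str(raw["ses"]),
        comorbidity_class=comorbidity_class(raw["n_chronic"]),
        bmi=float(raw["bmi"]),
        ltpa_met_h_wk=ltpa_met_hours(acts),
        homa_ir=homa_ir(raw["glucose_0"], raw["insulin_0"]),
        glucose_status=glucose_status(
            raw["glucose_0"], raw["glucose_120"], raw.get("known_diabetes", False)
        ),
    )


def derive_covariates_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized covariate derivation for a cohort table."""
    met_cols = sorted(c for c in df.columns if c.startswith("ltpa_met_"))
    ltpa = np.zeros(len(df))
    for mc in met_cols:
        i = mc.rsplit("_", 1)[1]
        ltpa += (
            df[mc].to_numpy(dtype=float)
            * df[f"ltpa_hours_{i}"].to_numpy(dtype=float)
            * df[f"ltpa_freq_{i}"].to_numpy(dtype=float)
        )
    flag = df["known_diabetes"].to_numpy(dtype=bool) if "known_diabetes" in df else False
    out = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "sex": df["sex"].astype(str),
            "smoking": df["smoking"].astype(str),
            "alcohol": df["alcohol"].astype(str),
            "ses": df["ses"].astype(str),
            "comorbidity_class": pd.Categorical(
                comorbidity_class(df["n_chronic"].to_numpy()),
                categories=COMORBIDITY_CLASSES,
            ),
            "bmi": df["bmi"].astype(float),
            "ltpa_met_h_wk": ltpa,
            "homa_ir": homa_ir(df["glucose_0"].to_numpy(), df["insulin_0"].to_numpy()),
            "glucose_status": pd.Categorical(
                glucose_status(
                    df["glucose_0"].to_numpy(), df["glucose_120"].to_numpy(), flag
                ),
                categories=GLUCOSE_CATEGORIES,
            ),
        },
        index=df.index,
    )
    return out
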