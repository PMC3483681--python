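"""Spirometric normalization: raw FVC to percent-of-predicted, and
cross-sectional averaging of a patient cohort into an age trajectory.

Predicted (normal) FVC comes from sex/age/height polynomial reference
equations; a patient's measurement divided by their predicted value, times
100, is the percent-predicted FVC that the disease model's percent
functional volume is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "ReferenceCoefficients",
    "load_default_coefficients",
    "predicted_fvc",
    "percent_predicted",
    "average_by_age",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["patient_id", "sex", "age_years", "height_cm", "fvc_L"]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age_years: float
    height_cm: float
    fvc_L: float

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age_years <= 0 or self.height_cm <= 0:
            raise ValueError("age and height must be positive")
        if self.fvc_L < 0:
            raise ValueError("fvc_L must be non-negative")


class ReferenceCoefficients:
    """Per-sex polynomial coefficients for predicted FVC.

    The prediction is ``b0 + b_age*age + b_age2*age**2 + b_height2*height**2``
    (litres), valid over a declared age/height support.
    """

    def __init__(self, spec: dict):
        self.support = spec["support"]
        self.by_sex = {s: spec[s] for s in _SEXES}

    def check_support(self, age_years: float, height_cm: float) -> None:
        s = self.support
        if not (s["age_min"] <= age_years <= s["age_max"]):
            raise ValueError(
                f"age {age_years} y outside supported range "
                f"[{s['age_min']}, {s['age_max']}]"
            )
        if not (s["height_min"] <= height_cm <= s["height_max"]):
            raise ValueError(
                f"height {height_cm} cm outside supported range "
                f"[{s['height_min']}, {s['height_max']}]"
            )


def load_default_coefficients() -> ReferenceCoefficients:
    """The vendored NHANES III adult Caucasian FVC coefficients."""
    path = resources.files("cflung.data").joinpath("fvc_reference_coefficients.json")
    return ReferenceCoefficients(json.loads(path.read_text()))


def predicted_fvc(sex: str, age_years: float, height_cm: float,
                  coeffs: ReferenceCoefficients | None = None) -> float:
    """Predicted normal FVC in litres for a given sex, age and height."""
    coeffs = coeffs if coeffs is not None else load_default_coefficients()
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
    coeffs.check_support(age_years, height_cm)
    b = coeffs.by_sex[sex]
    value = (b["b0"] + b["b_age"] * age_years + b["b_age2"] * age_years ** 2
             + b["b_height2"] * height_cm ** 2)
    if value <= 0:
        raise ValueError(
            f"predicted FVC non-positive for sex={sex}, age={age_years}, "
            f"height={height_cm}; outside the fixture's sensible range"
        )
    return value


def percent_predicted(record: PatientRecord,
                      coeffs: ReferenceCoefficients | None = None) -> float:
    """A patient's FVC as a percent of their predicted normal FVC."""
    pred = predicted_fvc(record.sex, record.age_years, record.height_cm, coeffs)
    return 100.0 * record.fvc_L / pred


def average_by_age(cohort: pd.DataFrame | Iterable[PatientRecord],
                   coeffs: ReferenceCoefficients | None = None,
                   age_range: Sequence[int] = (18, 50)) -> pd.DataFrame:
    """Cross-sectional mean percent-predicted FVC per completed year of age.

    Ages are binned by completed year (floor).  Ages inside ``age_range``
    with no observations are reported with ``n = 0`` and a missing mean --
    never imputed.

    Returns a frame with columns ``age_years``, ``mean_fvc_pct``, ``n``.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame([r.__dict__ for r in cohort])
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks columns: {sorted(missing)}")
    coeffs = coeffs if coeffs is not None else load_default_coefficients()
    pct = np.array([
        percent_predicted(
            PatientRecord(str(r.patient_id), r.sex, float(r.age_years),
                          float(r.height_cm), float(r.fvc_L)),
            coeffs,
        )
        for r in cohort.itertuples()
    ])
    age_bin = np.floor(cohort["age_years"].to_numpy()).astype(int)
    lo, hi = int(age_range[0]), int(age_range[-1])
    ages = np.arange(lo, hi + 1)
    means = np.full(ages.shape, np.nan)
    counts = np.zeros(ages.shape, dtype=int)
    for i, a in enumerate(ages):
        sel = age_bin == a
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = pct[sel].mean()
    return pd.DataFrame({"age_years": ages, "mean_fvc_pct": means, "n": counts})
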