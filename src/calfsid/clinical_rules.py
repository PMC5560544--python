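"""Rule-based clinical classifiers: SIRS and septicemia.

SIRS (systemic inflammatory response syndrome) is diagnosed when at least
two of four criteria are met, using established calf reference intervals:

* abnormal leukocyte count (outside 5–12 G/L; leukopenia or leukocytosis)
* abnormal rectal temperature (outside 38.5–39.5 °C)
* tachycardia (> 120 beats/min)
* tachypnea (> 36 breaths/min)

A calf is classified as clinically septicemic when it is SIRS-positive AND
shows at least one suggestive sign (marked hyperemia of mucous membranes,
injected episcleral vessels, mucosal/subscleral bleeding, or hypopyon).
Septicemia may additionally be *predicted* by an externally published
logistic model (age, recumbency, absent suckling reflex, focal infection);
this package does not re-derive that model's coefficients — they are loaded
from a model-JSON file and thresholded at probability >= 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ModelSpecificationError
from .regression import LogisticModel

__all__ = [
    "ClinicalExam",
    "SirsResult",
    "SepticemiaAssessment",
    "classify_sirs",
    "classify_clinical_septicemia",
    "predict_septicemia",
    "LEUKOCYTE_INTERVAL",
    "TEMPERATURE_INTERVAL",
    "TACHYCARDIA_THRESHOLD",
    "TACHYPNEA_THRESHOLD",
    "SEPTICEMIA_PROBABILITY_THRESHOLD",
]

LEUKOCYTE_INTERVAL = (5.0, 12.0)  # G/L, inclusive reference interval
TEMPERATURE_INTERVAL = (38.5, 39.5)  # °C, inclusive reference interval
TACHYCARDIA_THRESHOLD = 120.0  # beats/min, strict >
TACHYPNEA_THRESHOLD = 36.0  # breaths/min, strict >
SEPTICEMIA_PROBABILITY_THRESHOLD = 0.3

#: Signs that raise clinical suspicion of septicemia in a SIRS-positive calf.
SEPTICEMIA_SUSPICION_SIGNS = (
    "hyperemia_mucosae",
    "injected_scleral_vessels",
    "mucosal_bleeding",
    "hypopyon",
)


@dataclass
class ClinicalExam:
    """Admission clinical examination of one calf.

    3-point ordinal scores run 1 (normal) to 3 (most severe): suckling
    reflex (strong/weak/absent), behavior (alert/depressed/comatose),
    posture (stands/impaired/recumbent), enophthalmos, body condition
    (good-moderate/bad/cachectic).  Navel infection is 0/1/2
    (none/uncomplicated/complicated); the remaining flags are 0/1.
    Any field may be None (missing in the record).
    """

    suckling_reflex: Optional[int] = None
    behavior: Optional[int] = None
    posture: Optional[int] = None
    enophthalmos: Optional[int] = None
    body_condition: Optional[int] = None
    rectal_temp: Optional[float] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    leukocytes: Optional[float] = None
    age: Optional[float] = None
    abdominal_emergency: Optional[int] = None
    cns_involvement: Optional[int] = None
    orthopedic_problems: Optional[int] = None
    bronchopneumonia: Optional[int] = None
    navel_infection: Optional[int] = None
    hyperemia_mucosae: Optional[int] = None
    injected_scleral_vessels: Optional[int] = None
    mucosal_bleeding: Optional[int] = None
    hypopyon: Optional[int] = None
    focal_infection: Optional[int] = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SirsResult:
    criteria_met: frozenset
    positive: bool
    indeterminate: bool = False

    def __post_init__(self):
        if not self.indeterminate:
            assert self.positive == (len(self.criteria_met) >= 2)


@dataclass(frozen=True)
class SepticemiaAssessment:
    clinical_septicemia: bool
    predicted_probability: Optional[float] = None
    predicted_septicemia: Optional[bool] = None


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def classify_sirs(exam: ClinicalExam) -> SirsResult:
    """Evaluate the four SIRS criteria; positive iff at least two are met.

    If any of the four inputs is missing the result is flagged
    indeterminate rather than silently negative — downstream models treat
    SIRS as a covariate and must be able to distinguish "unknown" from
    "no".  Criteria that can be evaluated are still reported.
    """
    inputs = (exam.leukocytes, exam.rectal_temp, exam.heart_rate, exam.resp_rate)
    indeterminate = any(_is_missing(v) for v in inputs)
    met = set()
    if not _is_missing(exam.leukocytes) and not (
        LEUKOCYTE_INTERVAL[0] <= exam.leukocytes <= LEUKOCYTE_INTERVAL[1]
    ):
        met.add("leukocyte_abnormal")
    if not _is_missing(exam.rectal_temp) and not (
        TEMPERATURE_INTERVAL[0] <= exam.rectal_temp <= TEMPERATURE_INTERVAL[1]
    ):
        met.add("temp_abnormal")
    if not _is_missing(exam.heart_rate) and exam.heart_rate > TACHYCARDIA_THRESHOLD:
        met.add("tachycardia")
    if not _is_missing(exam.resp_rate) and exam.resp_rate > TACHYPNEA_THRESHOLD:
        met.add("tachypnea")
    if indeterminate and len(met) < 2:
        # could still become positive if the missing criteria were known
        return SirsResult(frozenset(met), positive=False, indeterminate=True)
    return SirsResult(frozenset(met), positive=len(met) >= 2)


def classify_clinical_septicemia(exam: ClinicalExam, sirs: SirsResult) -> bool:
    """Clinical septicemia: SIRS-positive plus any suspicion sign."""
    if not sirs.positive:
        return False
    return any(bool(getattr(exam, s)) for s in SEPTICEMIA_SUSPICION_SIGNS if not _is_missing(getattr(exam, s)))


def predict_septicemia(
    exam: ClinicalExam,
    model: LogisticModel,
    threshold: float = SEPTICEMIA_PROBABILITY_THRESHOLD,
) -> SepticemiaAssessment:
    """Score a calf with an externally supplied septicemia logistic model.

    The model must provide coefficients for the four published predictors
    (age, recumbency, absent suckling reflex, focal infection); the calf is
    predicted septicemic when the probability is >= threshold (default 0.3).
    """
    record = {
        "age": exam.age,
        "recumbency": None if _is_missing(exam.posture) else int(exam.posture == 3),
        "suckling_absent": None
        if _is_missing(exam.suckling_reflex)
        else int(exam.suckling_reflex == 3),
        "focal_infection": exam.focal_infection,
    }
    missing_terms = [
        t.name for t in model.terms if t.variable not in record
    ]
    if missing_terms:
        raise ModelSpecificationError(
            "septicemia model refers to unsupported predictors: "
            + ", ".join(missing_terms)
        )
    p = model.predict_record(record)
    sirs = classify_sirs(exam)
    return SepticemiaAssessment(
        clinical_septicemia=classify_clinical_septicemia(exam, sirs),
        predicted_probability=p,
        predicted_septicemia=bool(p >= threshold),
    )
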