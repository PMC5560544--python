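"""Published prognostic models for neonatal calf diarrhea, as scoring
functions.

The registry embeds the four printed multivariable logistic models for
mortality (observed and expert-review-predicted outcome, each in a
clinical+laboratory and a laboratory-only variant) with their
coefficients, standard errors and Youden-optimal probability cutpoints,
plus the standalone profound-acidemia rule (jugular venous pH < 6.85).

Published performance figures (AUCs, the pH rule's 10.9%/97.1%
sensitivity/specificity, Hosmer-Lemeshow statistics) travel as *metadata*
flagged ``emulation_target``: they are properties of the original
1,400-calf dataset and cannot be recomputed from synthetic cohorts, so
the package records them for benchmarking context but never reports them
as its own results.

The registry is for reproduction and benchmarking, not veterinary
decision support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType

from .errors import ModelSpecificationError
from .regression import LogisticModel, Term

__all__ = [
    "PublishedModel",
    "PUBLISHED_MODELS",
    "PH_RULE_CUTPOINT",
    "score_calf",
    "apply_ph_rule",
]

PH_RULE_CUTPOINT = 6.85  # strict: flagged iff pH < 6.85


@dataclass(frozen=True)
class PublishedModel:
    """A printed logistic model plus its classification cutpoint."""

    model: LogisticModel
    cutpoint: float  # classify high-risk when probability >= cutpoint

    def score(self, record: dict) -> tuple[float, bool]:
        p = self.model.predict_record(record)
        return p, p >= self.cutpoint


def _published(intercept, intercept_se, terms, cutpoint, metadata):
    metadata = dict(metadata)
    metadata["emulation_target"] = True
    metadata["source"] = "published 1,400-calf study; not recomputable from synthetic data"
    return PublishedModel(
        model=LogisticModel(
            intercept=intercept,
            intercept_se=intercept_se,
            terms=terms,
            metadata=metadata,
        ),
        cutpoint=cutpoint,
    )


PUBLISHED_MODELS = MappingProxyType(
    {
        "observed_clinical_laboratory": _published(
            -2.082,
            0.098,
            [
                Term("ileus_abdominal_emergency", "abdominal_emergency", 3.761, 0.550),
                Term("cns_involvement", "cns_involvement", 2.978, 0.347),
                Term("orthopedic_problems", "orthopedic_problems", 2.037, 0.271),
                Term("cachectic_body_condition", "body_condition", 1.640, 0.181, op="ge", threshold=3),
                Term("ph_below_6_85", "ph", 1.594, 0.292, op="lt", threshold=6.85),
            ],
            cutpoint=0.25,
            metadata={
                "outcome": "observed mortality",
                "n": 1385,
                "published_or": {
                    "ileus_abdominal_emergency": 42.98,
                    "cns_involvement": 19.65,
                    "orthopedic_problems": 7.67,
                    "cachectic_body_condition": 5.16,
                    "ph_below_6_85": 4.93,
                },
                "published_auc": 0.77,
                "published_auc_ci": (0.73, 0.80),
                "published_sensitivity": 0.66,
                "published_specificity": 0.85,
                "published_hosmer_lemeshow": {"chi_square": 2.89, "df": 1, "p": 0.089},
            },
        ),
        "observed_laboratory": _published(
            -1.958,
            0.096,
            [
                Term("sodium_ge_151", "na", 1.462, 0.195, op="ge", threshold=151.0),
                Term("glucose_below_3_2", "glucose", 1.282, 0.178, op="lt", threshold=3.2),
                Term("ggt_below_31", "ggt", 1.075, 0.198, op="lt", threshold=31.0),
                Term("thrombocytes_below_535", "thrombocytes", 0.846, 0.180, op="lt", threshold=535.0),
            ],
            cutpoint=0.27,
            metadata={
                "outcome": "observed mortality",
                "n": 1380,
                "published_or": {
                    "sodium_ge_151": 4.32,
                    "glucose_below_3_2": 3.60,
                    "ggt_below_31": 2.93,
                    "thrombocytes_below_535": 2.33,
                },
                "published_auc": 0.71,
                "published_auc_ci": (0.67, 0.75),
                "published_sensitivity": 0.59,
                "published_specificity": 0.79,
                "published_hosmer_lemeshow": {"chi_square": 6.98, "df": 3, "p": 0.073},
            },
        ),
        "predicted_clinical_laboratory": _published(
            -3.151,
            0.158,
            [
                Term("ileus_abdominal_emergency", "abdominal_emergency", 4.200, 0.570),
                Term("cns_involvement", "cns_involvement", 3.147, 0.377),
                Term("rectal_temp_below_35_2", "rectal_temp", 1.736, 0.399, op="lt", threshold=35.2),
                Term("total_protein_below_43_8", "total_protein", 1.271, 0.260, op="lt", threshold=43.8),
                Term("pneumonia", "bronchopneumonia", 1.234, 0.206),
                Term("resp_rate_ge_62", "resp_rate", 1.211, 0.315, op="ge", threshold=62.0),
                Term("recumbency", "posture", 1.110, 0.187, op="ge", threshold=3),
                Term("ast_ge_152", "ast", 1.060, 0.243, op="ge", threshold=152.0),
                Term("pco2_ge_65_2", "pco2", 1.012, 0.266, op="ge", threshold=65.2),
            ],
            cutpoint=0.27,
            metadata={
                "outcome": "predicted mortality (expert-review outcome)",
                "n": 1350,
                "published_or": {
                    "ileus_abdominal_emergency": 66.67,
                    "cns_involvement": 23.27,
                    "rectal_temp_below_35_2": 5.67,
                    "total_protein_below_43_8": 3.56,
                    "pneumonia": 3.44,
                    "resp_rate_ge_62": 3.36,
                    "recumbency": 3.04,
                    "ast_ge_152": 2.89,
                    "pco2_ge_65_2": 2.75,
                },
                "published_auc": 0.84,
                "published_auc_ci": (0.81, 0.88),
                "published_sensitivity": 0.69,
                "published_specificity": 0.88,
                "published_hosmer_lemeshow": {"chi_square": 5.55, "df": 4, "p": 0.24},
            },
        ),
        "predicted_laboratory": _published(
            -2.161,
            0.104,
            [
                Term("glucose_below_2_9", "glucose", 1.371, 0.198, op="lt", threshold=2.9),
                Term("ast_above_79", "ast", 1.227, 0.148, op="gt", threshold=79.0),
            ],
            cutpoint=0.19,
            metadata={
                "outcome": "predicted mortality (expert-review outcome)",
                "n": 1398,
                "published_or": {"glucose_below_2_9": 3.94, "ast_above_79": 3.41},
                "published_auc": 0.69,
                "published_auc_ci": (0.65, 0.73),
                "published_sensitivity": 0.62,
                "published_specificity": 0.72,
                "published_hosmer_lemeshow": {"chi_square": 0.11, "df": 1, "p": 0.74},
            },
        ),
    }
)

#: Published operating characteristics of the standalone pH < 6.85 rule on
#: the original cohort — an emulation target, never recomputed here.
PH_RULE_PUBLISHED = MappingProxyType(
    {
        "sensitivity": 0.109,
        "specificity": 0.971,
        "emulation_target": True,
    }
)

#: Published septicemia-prediction context: the external model's printed
#: operating point (its coefficients are not published in this study).
SEPTICEMIA_MODEL_PUBLISHED = MappingProxyType(
    {
        "threshold": 0.3,
        "sensitivity": 0.69,
        "specificity": 0.75,
        "emulation_target": True,
    }
)


def score_calf(record: dict, model_id: str, registry=PUBLISHED_MODELS):
    """Probability of death and high-risk classification for one calf.

    Binary terms are computed from the raw values and the model's printed
    thresholds.  A missing input raises, listing the field — there is no
    silent zero-imputation.
    """
    if model_id not in registry:
        raise ModelSpecificationError(
            f"unknown model {model_id!r}; available: {sorted(registry)}"
        )
    return registry[model_id].score(record)


def apply_ph_rule(record: dict):
    """Profound-acidemia flag: True iff venous pH < 6.85 (strict).

    Returns None (indeterminate) when pH is missing.
    """
    ph = record.get("ph")
    if ph is None or (isinstance(ph, float) and math.isnan(ph)):
        return None
    return bool(ph < PH_RULE_CUTPOINT)
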