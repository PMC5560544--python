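"""Synthetic calf-cohort generator.

Generates cohorts that emulate the *structure* of an admission dataset of
critically ill neonatal diarrheic calves: marginal laboratory-analyte
distributions matched to published median/quartile summaries, clinical
category prevalences, per-column missingness, physicochemically coherent
derived acid-base columns (always computed, never sampled), and a binary
outcome drawn from a logistic model on features computed from the
generated values.

Quantile matching: each analyte's 25th/50th/75th percentiles are matched
exactly by a two-parameter normal (symmetric analytes: electrolytes, pH,
proteins, hematology indices) or a three-parameter shifted log-normal
(right-skewed analytes: lactates, urea, creatinine, enzyme activities,
counts).  Samples are truncated to physiologic bounds that bracket the
quartiles, so the matched quartiles are preserved.

Dependence between analytes is deliberately minimal: a Gaussian copula
links only a configurable set of pairs (default: weak pH–pCO2 and
L-lactate–creatinine links, rho = 0.3); true inter-analyte correlations
are not identifiable from published marginal summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import acid_base
from .clinical_rules import (
    LEUKOCYTE_INTERVAL,
    SEPTICEMIA_SUSPICION_SIGNS,
    TACHYCARDIA_THRESHOLD,
    TACHYPNEA_THRESHOLD,
    TEMPERATURE_INTERVAL,
)
from .errors import ValidationError
from .regression import LogisticModel

__all__ = [
    "AnalyteSpec",
    "CohortSpec",
    "fit_quantile_family",
    "generate_cohort",
    "inject_missingness",
    "default_cohort_spec",
    "DERIVED_COLUMNS",
    "PROTECTED_COLUMNS",
]

_Z25 = 0.674489750196082  # standard normal 75th percentile


@dataclass(frozen=True)
class AnalyteSpec:
    """Marginal target for one analyte: quartiles, bounds and family."""

    name: str
    median: float
    q25: float
    q75: float
    lower: float
    upper: float
    family: str = "lognormal"  # "lognormal" (shifted) or "normal"
    unit: str = ""

    def __post_init__(self):
        if not (self.q25 < self.median < self.q75):
            raise ValidationError(self.name, "need q25 < median < q75")
        if not (self.lower <= self.q25 and self.q75 <= self.upper):
            raise ValidationError(self.name, "bounds must bracket the quartiles")
        if self.family not in ("lognormal", "normal"):
            raise ValidationError(self.name, f"unknown family {self.family!r}")


@dataclass(frozen=True)
class FittedFamily:
    """Quantile function of a fitted marginal family."""

    family: str
    params: tuple  # normal: (mean, sd); lognormal: (shift, mu, sigma)
    lower: float
    upper: float

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        z = stats.norm.ppf(u)
        if self.family == "normal":
            mean, sd = self.params
            x = mean + sd * z
        else:
            shift, mu, sigma = self.params
            x = shift + np.exp(mu + sigma * z)
        return np.clip(x, self.lower, self.upper)


def fit_quantile_family(spec: AnalyteSpec) -> FittedFamily:
    """Fit the declared family so its quartiles hit the targets exactly.

    Shifted log-normal: three parameters solve the three quantile
    equations in closed form; requires right skew (upper quartile gap
    strictly larger than the lower).  Normal: mean = median, sd from the
    average quartile distance, with a warning when the targets are
    noticeably skewed.
    """
    a = spec.median - spec.q25
    b = spec.q75 - spec.median
    if spec.family == "normal":
        if abs(b - a) > 0.2 * (a + b):
            warnings.warn(
                f"{spec.name}: quartile targets are skewed "
                f"(gaps {a:g}/{b:g}) but the normal family is symmetric"
            )
        sd = (a + b) / 2.0 / _Z25
        return FittedFamily("normal", (spec.median, sd), spec.lower, spec.upper)
    if b <= a:
        raise ValidationError(
            spec.name,
            f"shifted log-normal requires right-skewed targets (gaps {a:g}/{b:g})",
        )
    sigma = math.log(b / a) / _Z25
    scale = a * b / (b - a)  # exp(mu)
    shift = spec.median - scale
    return FittedFamily("lognormal", (shift, math.log(scale), sigma), spec.lower, spec.upper)


# ---------------------------------------------------------------------------
# default study-conditions specification
# ---------------------------------------------------------------------------

# Marginal targets: survivor-column medians (Q25/Q75) of the admission
# laboratory panel; survivors are 77.6% of the cohort, so this column is
# the closest available proxy for the full-cohort margin.
_A = AnalyteSpec
DEFAULT_ANALYTES = {
    s.name: s
    for s in [
        _A("ph", 7.181, 7.030, 7.314, 6.40, 7.80, "normal", "pH"),
        _A("pco2", 47.4, 37.8, 55.7, 12.0, 130.0, "normal", "mm Hg"),
        _A("po2", 35.7, 29.9, 42.6, 5.0, 100.0, "normal", "mm Hg"),
        _A("na", 134.7, 129.9, 140.4, 100.0, 200.0, "normal", "mmol/L"),
        _A("k", 4.8, 4.3, 6.0, 2.0, 10.0, "lognormal", "mmol/L"),
        _A("cl", 101.0, 96.0, 107.0, 60.0, 145.0, "normal", "mmol/L"),
        _A("d_lactate", 3.9, 0.7, 9.9, 0.0, 25.0, "lognormal", "mmol/L"),
        _A("l_lactate", 1.6, 0.9, 3.0, 0.1, 20.0, "lognormal", "mmol/L"),
        _A("glucose", 4.4, 3.8, 5.2, 0.3, 15.0, "lognormal", "mmol/L"),
        _A("total_protein", 57.7, 50.9, 65.4, 25.0, 100.0, "normal", "g/L"),
        _A("albumin", 29.2, 26.7, 32.1, 12.0, 45.0, "normal", "g/L"),
        _A("phosphorus", 2.9, 2.4, 3.9, 0.5, 8.0, "lognormal", "mmol/L"),
        _A("urea", 12.1, 7.2, 21.0, 1.0, 60.0, "lognormal", "mmol/L"),
        _A("creatinine", 140.0, 99.0, 262.0, 40.0, 1200.0, "lognormal", "umol/L"),
        _A("ck", 340.0, 173.0, 831.0, 20.0, 20000.0, "lognormal", "U/L"),
        _A("ast", 54.8, 41.4, 77.5, 10.0, 1000.0, "lognormal", "U/L"),
        _A("ggt", 110.0, 57.5, 224.5, 5.0, 2000.0, "lognormal", "U/L"),
        _A("gldh", 7.1, 4.3, 13.2, 0.5, 300.0, "lognormal", "U/L"),
        _A("hemoglobin", 12.8, 11.0, 14.6, 4.0, 22.0, "normal", "g/dL"),
        _A("pcv", 40.9, 34.9, 46.7, 15.0, 65.0, "normal", "%"),
        _A("mcv", 39.8, 37.6, 41.8, 28.0, 55.0, "normal", "fL"),
        _A("leukocytes", 13.4, 9.6, 18.6, 0.5, 60.0, "lognormal", "G/L"),
        _A("thrombocytes", 920.0, 701.0, 1171.0, 50.0, 3000.0, "lognormal", "G/L"),
        _A("age", 9.0, 7.0, 12.0, 1.0, 21.0, "lognormal", "days"),
        # Vital signs other than temperature have no published quartile
        # summary; clinically realistic admission distributions are used.
        _A("heart_rate", 112.0, 96.0, 128.0, 40.0, 220.0, "normal", "beats/min"),
        _A("resp_rate", 36.0, 28.0, 44.0, 10.0, 120.0, "normal", "breaths/min"),
    ]
}

#: 3-point ordinal score prevalences (category 1/2/3), from the admission
#: category counts of the study cohort.
DEFAULT_ORDINALS = {
    "suckling_reflex": (187, 629, 512),
    "behavior": (517, 450, 425),
    "posture": (592, 383, 412),
    "enophthalmos": (436, 664, 294),
    "body_condition": (685, 503, 198),
    "navel_infection": (1192, 108, 95),  # none / uncomplicated / complicated (0/1/2)
}

#: binary concurrent-problem flag prevalences
DEFAULT_FLAGS = {
    "abdominal_emergency": 32 / 1398,
    "cns_involvement": 61 / 1398,
    "orthopedic_problems": 70 / 1398,
    "bronchopneumonia": 208 / 1392,
    "focal_infection": 0.25,
    # septicemia-suspicion signs, set so that SIRS-positive calves carry a
    # suspicion sign at roughly the observed clinical-septicemia prevalence
    "hyperemia_mucosae": 0.15,
    "injected_scleral_vessels": 0.12,
    "mucosal_bleeding": 0.02,
    "hypopyon": 0.015,
}

#: per-column missingness (study-footnote magnitudes)
DEFAULT_MISSINGNESS = {
    "suckling_reflex": 72 / 1400,
    "behavior": 8 / 1400,
    "posture": 13 / 1400,
    "enophthalmos": 6 / 1400,
    "body_condition": 14 / 1400,
    "navel_infection": 5 / 1400,
    "bronchopneumonia": 8 / 1400,
    "abdominal_emergency": 2 / 1400,
    "cns_involvement": 2 / 1400,
    "orthopedic_problems": 2 / 1400,
    "po2": 5 / 1400,
    "ast": 2 / 1400,
    "gldh": 2 / 1400,
    "pcv": 20 / 1400,
    "hemoglobin": 20 / 1400,
    "mcv": 20 / 1400,
    "leukocytes": 20 / 1400,
    "thrombocytes": 20 / 1400,
}

DEFAULT_COPULA = {("ph", "pco2"): 0.3, ("l_lactate", "creatinine"): 0.3}

DERIVED_COLUMNS = [
    "hco3",
    "base_excess",
    "anion_gap",
    "atot",
    "a_minus",
    "sid_m",
    "sig",
    "usi",
    "sirs",
    "clinical_septicemia",
]

PROTECTED_COLUMNS = ("id", "died_observed", "died_predicted")


@dataclass
class CohortSpec:
    """Everything needed to generate one reproducible synthetic cohort."""

    n: int = 1400
    analyte_specs: dict = field(default_factory=lambda: dict(DEFAULT_ANALYTES))
    ordinal_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_ORDINALS))
    flag_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_FLAGS))
    hypothermia_prevalence: float = 572 / 1400
    rectal_temp_sd: float = 0.8
    outcome_model: Optional[LogisticModel] = None  # default: published clinical+lab model
    euthanasia_review_flip: float = 57 / 313  # non-survivors re-labelled survivors
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    copula_correlations: dict = field(default_factory=lambda: dict(DEFAULT_COPULA))
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n", "cohort size must be >= 1")
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(name, f"missingness rate {rate} outside [0, 1]")
        if not 0.0 <= self.hypothermia_prevalence <= 1.0:
            raise ValidationError("hypothermia_prevalence", "must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "hypothermia_prevalence": self.hypothermia_prevalence,
            "rectal_temp_sd": self.rectal_temp_sd,
            "euthanasia_review_flip": self.euthanasia_review_flip,
            "analytes": {k: vars(v) for k, v in self.analyte_specs.items()},
            "ordinal_prevalences": {k: list(v) for k, v in self.ordinal_prevalences.items()},
            "flag_prevalences": self.flag_prevalences,
            "missingness_rates": self.missingness_rates,
            "copula_correlations": {f"{a}:{b}": r for (a, b), r in self.copula_correlations.items()},
            "outcome_model": self.outcome_model.to_dict() if self.outcome_model else None,
        }


def default_cohort_spec(n: int = 1400, seed: int = 0) -> CohortSpec:
    """The default study conditions (published outcome model included)."""
    from .prognosis import PUBLISHED_MODELS

    return CohortSpec(
        n=n, seed=seed, outcome_model=PUBLISHED_MODELS["observed_clinical_laboratory"].model
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample one cohort dataframe (one row per calf) from the spec.

    Sampling order: analyte margins (copula-linked where configured) →
    rectal temperature (normal, mean solved from the hypothermia
    prevalence) → ordinal scores and flags → derived acid-base columns
    (computed from the sampled analytes) → SIRS/septicemia classification
    → outcome by Bernoulli(inverse-logit of the outcome model) → the
    expert-review alternative outcome label → missingness.  Fully
    reproducible from ``spec.seed``.
    """
    if spec.outcome_model is None:
        spec = replace(spec, outcome_model=default_cohort_spec().outcome_model)
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    names = list(spec.analyte_specs)

    z = rng.standard_normal((n, len(names)))
    col = {name: i for i, name in enumerate(names)}
    for (a, b), rho in spec.copula_correlations.items():
        if a in col and b in col:
            z[:, col[b]] = rho * z[:, col[a]] + math.sqrt(1 - rho * rho) * z[:, col[b]]

    data = {}
    for name in names:
        fam = fit_quantile_family(spec.analyte_specs[name])
        data[name] = fam.ppf(stats.norm.cdf(z[:, col[name]]))

    # rectal temperature: sd fixed, mean solved so that
    # P(T < 38.5) equals the configured hypothermia prevalence
    t_mean = TEMPERATURE_INTERVAL[0] - spec.rectal_temp_sd * stats.norm.ppf(
        spec.hypothermia_prevalence
    )
    data["rectal_temp"] = np.clip(
        t_mean + spec.rectal_temp_sd * rng.standard_normal(n), 33.0, 42.0
    )

    for name, counts in spec.ordinal_prevalences.items():
        p = np.asarray(counts, dtype=float)
        p = p / p.sum()
        first = 0 if name == "navel_infection" else 1
        data[name] = rng.choice(np.arange(first, first + len(p)), size=n, p=p)
    for name, prev in spec.flag_prevalences.items():
        data[name] = (rng.random(n) < prev).astype(int)

    df = pd.DataFrame(data)
    df.insert(0, "id", np.arange(1, n + 1))

    # derived acid-base columns are always computed, never sampled
    df["hco3"] = acid_base.bicarbonate(df["ph"], df["pco2"])
    df["base_excess"] = acid_base.base_excess(df["ph"], df["hco3"], df["hemoglobin"])
    df["anion_gap"] = acid_base.anion_gap(df["na"], df["k"], df["cl"], df["hco3"])
    df["atot"] = acid_base.atot(df["total_protein"])
    df["a_minus"] = acid_base.a_minus(df["atot"], df["ph"])
    df["sid_m"] = acid_base.sid_measured(
        df["na"], df["k"], df["cl"], df["d_lactate"], df["l_lactate"]
    )
    df["sig"] = df["a_minus"] - df["anion_gap"]
    df["usi"] = acid_base.unidentified_strong_ions(
        df["sig"], df["d_lactate"], df["l_lactate"]
    )

    # rule-based classifications (vectorized mirror of clinical_rules)
    criteria = (
        (
            (df["leukocytes"] < LEUKOCYTE_INTERVAL[0])
            | (df["leukocytes"] > LEUKOCYTE_INTERVAL[1])
        ).astype(int)
        + (
            (df["rectal_temp"] < TEMPERATURE_INTERVAL[0])
            | (df["rectal_temp"] > TEMPERATURE_INTERVAL[1])
        ).astype(int)
        + (df["heart_rate"] > TACHYCARDIA_THRESHOLD).astype(int)
        + (df["resp_rate"] > TACHYPNEA_THRESHOLD).astype(int)
    )
    df["sirs"] = (criteria >= 2).astype(int)
    suspicion = np.zeros(n, dtype=bool)
    for s in SEPTICEMIA_SUSPICION_SIGNS:
        suspicion |= df[s].to_numpy(dtype=bool)
    df["clinical_septicemia"] = (df["sirs"].astype(bool) & suspicion).astype(int)

    p_death = spec.outcome_model.predict(df)
    df["died_observed"] = (rng.random(n) < p_death).astype(int)

    # expert-review alternative label: a fraction of non-survivors are
    # re-allocated to the survivor group
    died_idx = np.flatnonzero(df["died_observed"].to_numpy() == 1)
    flip = died_idx[rng.random(len(died_idx)) < spec.euthanasia_review_flip]
    df["died_predicted"] = df["died_observed"].copy()
    df.loc[flip, "died_predicted"] = 0

    return inject_missingness(df, spec.missingness_rates, rng=rng)


def inject_missingness(
    records: pd.DataFrame,
    rates: dict,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Blank each eligible cell independently with its column's rate.

    Identifier and outcome columns are protected; supplying a rate for
    one of them is an error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = records.copy()
    for name, rate in rates.items():
        if name in PROTECTED_COLUMNS:
            raise ValidationError(name, "cannot inject missingness into a protected column")
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(name, f"missingness rate {rate} outside [0, 1]")
        if name not in out.columns or rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if mask.any():
            out[name] = out[name].astype(float)
            out.loc[mask, name] = np.nan
    return out
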