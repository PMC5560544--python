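"""Physicochemical acid-base derivations for neonatal calf blood.

Two complementary frameworks are implemented with calf-specific constants:

* the classical Henderson-Hasselbalch quantities — actual bicarbonate,
  van Slyke in-vitro base excess, and the anion gap (AG);
* the simplified strong ion model — total nonvolatile weak acid
  concentration (A_tot, from total protein), its dissociated charge (A-),
  the measured strong ion difference (SID_m, including D- and L-lactate),
  the strong ion gap (SIG = A- − AG), and the unidentified strong ion
  concentration (USI = SIG + D-lactate + L-lactate, also called the
  unmeasured strong ion difference SID_um).

All scalar functions are ufunc-friendly: they accept floats or numpy
arrays / pandas Series and broadcast elementwise, so the same code serves
single-patient use and whole-cohort batch derivation.

Units are fixed by the constants: total protein in g/L, hemoglobin in
g/dL (the van Slyke buffer coefficients require g/dL), gas partial
pressures in mm Hg, electrolytes and lactates in mmol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .errors import MissingAnalyteError, ValidationError

__all__ = [
    "AcidBaseConstants",
    "TemperatureCorrection",
    "BloodGasPanel",
    "ChemistryPanel",
    "DerivedAcidBase",
    "correct_for_temperature",
    "bicarbonate",
    "base_excess",
    "anion_gap",
    "atot",
    "a_minus",
    "sid_measured",
    "strong_ion_gap",
    "unidentified_strong_ions",
    "derive_panel",
]


@dataclass(frozen=True)
class AcidBaseConstants:
    """Calf-plasma constants of the acid-base equations.

    Defaults are the experimentally determined calf values; override via an
    explicit instance only (e.g. to adapt the model to another species).

    pk1_prime : negative log dissociation constant of carbonic acid
    s_co2     : CO2 solubility, mmol/L per mm Hg
    atot_coeff: A_tot per unit total protein, mmol/L per g/L
    pka       : negative log dissociation constant of nonvolatile weak acids
    be_hb_coeff, be_buffer_slope, be_buffer_intercept : van Slyke buffering
        terms (per g/dL hemoglobin)
    hco3_ref, ph_ref : normal reference point of the titration
    """

    pk1_prime: float = 6.105
    s_co2: float = 0.0307
    atot_coeff: float = 0.343
    pka: float = 7.08
    be_hb_coeff: float = 0.014
    be_buffer_slope: float = 1.43
    be_buffer_intercept: float = 7.7
    hco3_ref: float = 24.8
    ph_ref: float = 7.4


#: Module-wide default constant set.
CALF_CONSTANTS = AcidBaseConstants()


@dataclass(frozen=True)
class TemperatureCorrection:
    """Linear-in-log blood-gas temperature-correction coefficients.

    The widely used CLSI-style forms: pH shifts linearly with temperature,
    pCO2 and pO2 exponentially (base-10).  Overridable for analyzers that
    implement a different algorithm.
    """

    ph_slope: float = -0.0146  # pH units per °C
    pco2_log_slope: float = 0.019  # log10 mm Hg per °C
    po2_log_slope: float = 0.0052  # log10 mm Hg per °C


CLSI_CORRECTION = TemperatureCorrection()


def _check_bounds(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValidationError(name, f"value {value!r} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class BloodGasPanel:
    """Blood-gas values measured at 37 °C plus the calf's rectal temperature."""

    ph_37: float
    pco2_37: float
    po2_37: float
    rectal_temp: float = 37.0

    def __post_init__(self):
        _check_bounds("ph_37", self.ph_37, 6.0, 8.0)
        _check_bounds("pco2_37", self.pco2_37, 5.0, 200.0)
        if not (0.0 < self.po2_37 <= 300.0):
            raise ValidationError("po2_37", f"value {self.po2_37!r} outside (0, 300]")
        _check_bounds("rectal_temp", self.rectal_temp, 25.0, 43.0)


@dataclass(frozen=True)
class ChemistryPanel:
    """Electrolytes, lactates, protein and hemoglobin for one calf.

    Only the analytes the acid-base equations consume are required; any
    further panel results travel in ``extra`` untouched.
    """

    na: float
    k: float
    cl: float
    d_lactate: float
    l_lactate: float
    total_protein: float
    hemoglobin: float
    glucose: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("na", "k", "cl", "d_lactate", "l_lactate", "total_protein", "hemoglobin"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingAnalyteError([name])
            if v < 0:
                raise ValidationError(name, f"concentration {v!r} is negative")
        if self.na <= self.cl:
            import warnings

            warnings.warn(
                "sodium does not exceed chloride; physiologically implausible",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DerivedAcidBase:
    """The eight derived acid-base quantities for one calf (see module docs)."""

    hco3: float
    base_excess: float
    anion_gap: float
    atot: float
    a_minus: float
    sid_m: float
    sig: float
    usi: float


def correct_for_temperature(
    panel: BloodGasPanel,
    coefficients: TemperatureCorrection = CLSI_CORRECTION,
) -> BloodGasPanel:
    """Convert 37 °C analyzer readings to the calf's rectal temperature.

    Identity when rectal_temp == 37.  The returned panel keeps the same
    rectal_temp, with pH/pCO2/pO2 now expressed at that temperature.
    """
    dt = panel.rectal_temp - 37.0
    return BloodGasPanel(
        ph_37=panel.ph_37 + coefficients.ph_slope * dt,
        pco2_37=panel.pco2_37 * 10.0 ** (coefficients.pco2_log_slope * dt),
        po2_37=panel.po2_37 * 10.0 ** (coefficients.po2_log_slope * dt),
        rectal_temp=panel.rectal_temp,
    )


def bicarbonate(ph, pco2, constants: AcidBaseConstants = CALF_CONSTANTS):
    """Actual bicarbonate (mmol/L) by Henderson-Hasselbalch: S·pCO2·10^(pH−pK1')."""
    return constants.s_co2 * np.asarray(pco2, dtype=float) * 10.0 ** (
        np.asarray(ph, dtype=float) - constants.pk1_prime
    )


def base_excess(ph, hco3, hb, constants: AcidBaseConstants = CALF_CONSTANTS):
    """In-vitro base excess (mmol/L) by the van Slyke equation.

    BE = (1 − 0.014·Hb) · [(HCO3 − 24.8) + (1.43·Hb + 7.7)·(pH − 7.4)],
    hemoglobin in g/dL.  Zero at the reference point regardless of Hb.
    """
    ph = np.asarray(ph, dtype=float)
    hco3 = np.asarray(hco3, dtype=float)
    hb = np.asarray(hb, dtype=float)
    return (1.0 - constants.be_hb_coeff * hb) * (
        (hco3 - constants.hco3_ref)
        + (constants.be_buffer_slope * hb + constants.be_buffer_intercept)
        * (ph - constants.ph_ref)
    )


def anion_gap(na, k, cl, hco3):
    """Anion gap (mEq/L): Na + K − Cl − HCO3."""
    return (
        np.asarray(na, dtype=float)
        + np.asarray(k, dtype=float)
        - np.asarray(cl, dtype=float)
        - np.asarray(hco3, dtype=float)
    )


def atot(total_protein, constants: AcidBaseConstants = CALF_CONSTANTS):
    """Total nonvolatile weak acid A_tot (mmol/L) from total protein (g/L)."""
    return constants.atot_coeff * np.asarray(total_protein, dtype=float)


def a_minus(atot_value, ph, constants: AcidBaseConstants = CALF_CONSTANTS):
    """Dissociated weak-acid charge A- (mEq/L): A_tot / (1 + 10^(pKa − pH))."""
    return np.asarray(atot_value, dtype=float) / (
        1.0 + 10.0 ** (constants.pka - np.asarray(ph, dtype=float))
    )


def sid_measured(na, k, cl, d_lactate, l_lactate):
    """Measured strong ion difference SID_m (mEq/L): Na + K − Cl − D-lac − L-lac."""
    return (
        np.asarray(na, dtype=float)
        + np.asarray(k, dtype=float)
        - np.asarray(cl, dtype=float)
        - np.asarray(d_lactate, dtype=float)
        - np.asarray(l_lactate, dtype=float)
    )


def strong_ion_gap(atot_value, ph, ag, constants: AcidBaseConstants = CALF_CONSTANTS):
    """Strong ion gap SIG (mEq/L): A-(A_tot, pH) − AG.

    Negative values indicate an excess of unmeasured strong anions.
    """
    return a_minus(atot_value, ph, constants) - np.asarray(ag, dtype=float)


def unidentified_strong_ions(sig, d_lactate, l_lactate):
    """Unidentified strong ions USI = SID_um (mEq/L): SIG + D-lac + L-lac."""
    return (
        np.asarray(sig, dtype=float)
        + np.asarray(d_lactate, dtype=float)
        + np.asarray(l_lactate, dtype=float)
    )


def derive_panel(
    gas: BloodGasPanel,
    chem: ChemistryPanel,
    use_temp_correction: bool = False,
    constants: AcidBaseConstants = CALF_CONSTANTS,
) -> DerivedAcidBase:
    """Compute all eight derived acid-base quantities for one calf.

    Bicarbonate and base excess use the 37 °C measurements (the analyzer
    convention); when ``use_temp_correction`` is set, pH entering the
    strong-ion quantities is first corrected to rectal temperature.

    Raises MissingAnalyteError listing every absent required analyte.
    """
    missing = [
        f.name
        for f in dc_fields(ChemistryPanel)
        if f.name not in ("glucose", "extra")
        and (getattr(chem, f.name) is None or math.isnan(getattr(chem, f.name)))
    ]
    if missing:
        raise MissingAnalyteError(missing)

    hco3 = float(bicarbonate(gas.ph_37, gas.pco2_37, constants))
    be = float(base_excess(gas.ph_37, hco3, chem.hemoglobin, constants))
    ph = gas.ph_37
    if use_temp_correction:
        ph = correct_for_temperature(gas).ph_37
    ag = float(anion_gap(chem.na, chem.k, chem.cl, hco3))
    at = float(atot(chem.total_protein, constants))
    am = float(a_minus(at, ph, constants))
    sid_m = float(sid_measured(chem.na, chem.k, chem.cl, chem.d_lactate, chem.l_lactate))
    sig = am - ag
    usi = float(unidentified_strong_ions(sig, chem.d_lactate, chem.l_lactate))
    return DerivedAcidBase(
        hco3=hco3,
        base_excess=be,
        anion_gap=ag,
        atot=at,
        a_minus=am,
        sid_m=sid_m,
        sig=sig,
        usi=usi,
    )
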