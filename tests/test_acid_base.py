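"""Acid-base derivations: worked examples and algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calfsid import acid_base as ab
from calfsid.errors import MissingAnalyteError, ValidationError

valid_ph = st.floats(6.0, 8.0)
valid_pco2 = st.floats(5.0, 200.0)
valid_hb = st.floats(0.0, 25.0)


class TestTemperatureCorrection:
    def test_identity_at_37(self):
        p = ab.BloodGasPanel(7.20, 50.0, 40.0, 37.0)
        c = ab.correct_for_temperature(p)
        assert (c.ph_37, c.pco2_37, c.po2_37) == (7.20, 50.0, 40.0)

    @pytest.mark.parametrize(
        "ph,pco2,temp,exp_ph,exp_pco2",
        [
            # direct evaluation of the linear-in-log correction forms
            (7.40, 40.0, 38.5, 7.3781, 42.71),
            (7.00, 60.0, 35.0, 7.0292, 54.95),
        ],
    )
    def test_correction_values(self, ph, pco2, temp, exp_ph, exp_pco2):
        c = ab.correct_for_temperature(ab.BloodGasPanel(ph, pco2, 40.0, temp))
        assert c.ph_37 == pytest.approx(exp_ph, abs=1e-3)
        assert c.pco2_37 == pytest.approx(exp_pco2, abs=0.05)

    @given(st.floats(6.5, 7.8), st.floats(20, 100), st.floats(30, 43))
    def test_round_trip(self, ph, pco2, temp):
        """Correcting to T and analytically back recovers the input."""
        c = ab.correct_for_temperature(ab.BloodGasPanel(ph, pco2, 50.0, temp))
        dt = temp - 37.0
        back_ph = c.ph_37 - ab.CLSI_CORRECTION.ph_slope * dt
        back_pco2 = c.pco2_37 / 10.0 ** (ab.CLSI_CORRECTION.pco2_log_slope * dt)
        assert back_ph == pytest.approx(ph, abs=1e-9)
        assert back_pco2 == pytest.approx(pco2, rel=1e-9)

    def test_out_of_bounds_temperature_names_field(self):
        with pytest.raises(ValidationError, match="rectal_temp"):
            ab.BloodGasPanel(7.2, 40, 40, 24.0)


class TestHendersonHasselbalch:
    @pytest.mark.parametrize(
        "ph,pco2,expected",
        [
            (6.105, 100.0, 3.07),  # zero exponent: S x pCO2
            (7.40, 40.0, 24.2),  # hand evaluation
            (7.00, 47.4, 11.4),
        ],
    )
    def test_bicarbonate(self, ph, pco2, expected):
        assert float(ab.bicarbonate(ph, pco2)) == pytest.approx(expected, abs=0.05)

    @given(valid_pco2, st.floats(6.0, 7.9))
    def test_bicarbonate_increasing_in_ph(self, pco2, ph):
        assert ab.bicarbonate(ph + 0.05, pco2) > ab.bicarbonate(ph, pco2)

    @given(valid_ph, valid_pco2, valid_pco2)
    def test_bicarbonate_linear_in_pco2(self, ph, p1, p2):
        lhs = ab.bicarbonate(ph, p1) + ab.bicarbonate(ph, p2)
        rhs = ab.bicarbonate(ph, p1 + p2)
        assert float(lhs) == pytest.approx(float(rhs), rel=1e-12)

    @pytest.mark.parametrize("hb", [0.0, 5.0, 12.8, 25.0])
    def test_base_excess_zero_at_reference(self, hb):
        assert float(ab.base_excess(7.4, 24.8, hb)) == pytest.approx(0.0, abs=1e-12)

    def test_base_excess_acidotic_calf(self):
        assert float(ab.base_excess(7.0, 10.0, 12.0)) == pytest.approx(-20.6, abs=0.05)

    @pytest.mark.parametrize(
        "na,k,cl,hco3,expected",
        [(140, 4, 100, 24, 20.0), (134.7, 4.8, 101, 16.7, 21.8), (0, 0, 0, 0, 0.0)],
    )
    def test_anion_gap(self, na, k, cl, hco3, expected):
        assert float(ab.anion_gap(na, k, cl, hco3)) == pytest.approx(expected, abs=0.05)


class TestStrongIonModel:
    @pytest.mark.parametrize(
        "tp,expected", [(57.7, 19.8), (53.0, 18.2), (0.0, 0.0)]
    )
    def test_atot_from_total_protein(self, tp, expected):
        assert float(ab.atot(tp)) == pytest.approx(expected, abs=0.05)

    def test_a_minus_half_dissociation_at_pka(self):
        assert float(ab.a_minus(19.8, 7.08)) == pytest.approx(9.9, abs=1e-9)

    def test_a_minus_at_normal_ph(self):
        assert float(ab.a_minus(19.8, 7.40)) == pytest.approx(13.39, abs=0.005)

    def test_a_minus_protonation_limit(self):
        assert float(ab.a_minus(19.8, -50.0)) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(1.0, 40.0), valid_ph)
    def test_a_minus_bounded(self, at, ph):
        am = float(ab.a_minus(at, ph))
        assert 0.0 < am < at

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((140, 4, 100, 4, 2), 38.0),
            ((134.7, 4.8, 101, 3.9, 1.6), 33.0),
            ((0, 0, 0, 0, 0), 0.0),
        ],
    )
    def test_sid_measured(self, args, expected):
        assert float(ab.sid_measured(*args)) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "atot_v,ph,ag,expected",
        [(19.8, 7.40, 20.0, -6.61), (0.0, 7.2, 0.0, 0.0), (19.8, 7.08, 9.9, 0.0)],
    )
    def test_strong_ion_gap(self, atot_v, ph, ag, expected):
        assert float(ab.strong_ion_gap(atot_v, ph, ag)) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "sig,dl,ll,expected",
        [(-6.61, 4, 2, -0.61), (0, 0, 0, 0.0), (-15.0, 4.6, 2.1, -8.3)],
    )
    def test_unidentified_strong_ions(self, sig, dl, ll, expected):
        assert float(ab.unidentified_strong_ions(sig, dl, ll)) == pytest.approx(
            expected, abs=0.005
        )


@st.composite
def panels(draw):
    gas = ab.BloodGasPanel(
        draw(st.floats(6.4, 7.8)),
        draw(st.floats(15, 120)),
        draw(st.floats(10, 90)),
        draw(st.floats(33, 42)),
    )
    chem = ab.ChemistryPanel(
        na=draw(st.floats(110, 180)),
        k=draw(st.floats(2.5, 9)),
        cl=draw(st.floats(70, 109)),
        d_lactate=draw(st.floats(0, 20)),
        l_lactate=draw(st.floats(0, 15)),
        total_protein=draw(st.floats(30, 90)),
        hemoglobin=draw(st.floats(5, 20)),
    )
    return gas, chem


class TestDerivePanel:
    def survivor_median_panels(self):
        gas = ab.BloodGasPanel(7.181, 47.4, 35.7)
        chem = ab.ChemistryPanel(
            na=134.7, k=4.8, cl=101.0, d_lactate=3.9, l_lactate=1.6,
            total_protein=57.7, hemoglobin=12.8,
        )
        return gas, chem

    def test_survivor_median_calf(self):
        gas, chem = self.survivor_median_panels()
        d = ab.derive_panel(gas, chem)
        assert d.atot == pytest.approx(19.8, abs=0.05)
        assert d.usi == pytest.approx(d.sig + 3.9 + 1.6, abs=1e-12)

    @given(panels())
    def test_internal_identities(self, gc):
        gas, chem = gc
        d = ab.derive_panel(gas, chem)
        assert d.usi - d.sig - chem.d_lactate - chem.l_lactate == pytest.approx(0, abs=1e-9)
        assert d.usi + d.sid_m - d.a_minus - d.hco3 == pytest.approx(0, abs=1e-9)
        assert d.anion_gap == pytest.approx(chem.na + chem.k - chem.cl - d.hco3, abs=1e-12)

    def test_missing_hemoglobin_named(self):
        with pytest.raises(MissingAnalyteError, match="hemoglobin"):
            ab.ChemistryPanel(
                na=134.7, k=4.8, cl=101.0, d_lactate=3.9, l_lactate=1.6,
                total_protein=57.7, hemoglobin=float("nan"),
            )

    def test_vectorized_matches_scalar(self):
        gas, chem = self.survivor_median_panels()
        d = ab.derive_panel(gas, chem)
        vec = ab.bicarbonate(np.array([gas.ph_37] * 3), np.array([gas.pco2_37] * 3))
        assert np.allclose(vec, d.hco3)
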