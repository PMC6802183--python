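"""Unit tests for the kinetic rate laws (exact algebraic properties)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypoxsim.rate_laws import (
    ATPModel,
    PhosphoLaw,
    VEGFBindingLaw,
    VEGFSynthesisLaw,
    atp_level,
    calibrate_kab,
    phospho_rate,
    phospho_rate_inhibited,
    vegf_binding_rate,
    vegf_synthesis_rate,
)

ATP = ATPModel()


class TestATPLevel:
    def test_half_max_at_3_3_percent_o2(self):
        assert atp_level(0.033, ATP) == pytest.approx(1500.0, rel=1e-15)

    def test_normoxia_value(self):
        # direct substitution: 3000 * 1 / (0.033 + 1)
        assert atp_level(1.0, ATP) == pytest.approx(3000.0 / 1.033, rel=1e-15)

    def test_limit_to_zero(self):
        assert atp_level(1e-12, ATP) < 1e-7

    @given(st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, f):
        v = atp_level(f, ATP)
        assert 0 < v < ATP.atp_normoxia
        assert atp_level(min(1.0, f * 1.01), ATP) >= v

    def test_nonpositive_o2_rejected(self):
        with pytest.raises(ValueError):
            atp_level(0.0, ATP)
        with pytest.raises(ValueError):
            atp_level(-0.1, ATP)


class TestCalibration:
    def test_small_km_limit(self):
        assert calibrate_kab(10.0, 1e-9, 3e6) == pytest.approx(10.0, rel=1e-9)

    def test_printed_example(self):
        # K' = 10 nM, K_M,ATP = 100 nM, ATP = 3,000,000 nM
        expected = 10.0 / (100.0 / 3e6 + 1.0)
        assert calibrate_kab(10.0, 100.0, 3e6) == pytest.approx(
            expected, rel=1e-15
        )
        assert expected == pytest.approx(9.999667, abs=5e-7)

    @given(
        st.floats(min_value=1e-3, max_value=1e4),
        st.floats(min_value=1e-2, max_value=1e6),
        st.floats(min_value=1e3, max_value=1e7),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, k_prime, k_m_atp, atp_norm):
        """Substituting K^AB back reproduces K' to machine precision."""
        k_ab = calibrate_kab(k_prime, k_m_atp, atp_norm)
        assert (k_m_atp / atp_norm + 1.0) * k_ab == pytest.approx(
            k_prime, rel=1e-12
        )

    @given(
        st.floats(min_value=1e-2, max_value=1e4),
        st.floats(min_value=0.0, max_value=1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_eq2_equals_eq3_at_normoxic_atp(self, k_prime, protein):
        """The ATP-explicit law collapses onto the original law at calibration ATP."""
        atp_norm = 2904.0
        law = PhosphoLaw(
            vmax=1.0,
            k_m_atp=100.0,
            k_ab=calibrate_kab(k_prime, 100.0, atp_norm * 1000.0),
            k_prime=k_prime,
        )
        eq2 = phospho_rate(atp_norm * 1000.0, protein, law)
        eq3 = law.vmax * protein / (k_prime + protein)
        assert eq2 == pytest.approx(eq3, rel=1e-12, abs=1e-15)


class TestPhosphoRate:
    law = PhosphoLaw(vmax=1.0, k_m_atp=100.0, k_ab=10.0)

    def test_zero_protein_gives_zero(self):
        assert phospho_rate(3e6, 0.0, self.law) == 0.0

    def test_saturating_atp_reduces_to_substrate_mm(self):
        rate = phospho_rate(1e15, 10.0, self.law)
        assert rate == pytest.approx(1.0 * 10.0 / (10.0 + 10.0), rel=1e-8)

    def test_direct_substitution_value(self):
        # vmax=1, K^AB=10, K_M,ATP=0.1 uM, ATP=3000 uM, P=10 (uM-equivalent)
        law = PhosphoLaw(vmax=1.0, k_m_atp=0.1, k_ab=10.0)
        expected = 1.0 * 10.0 / ((0.1 / 3000.0 + 1.0) * 10.0 + 10.0)
        assert phospho_rate(3000.0, 10.0, law) == pytest.approx(
            expected, rel=1e-15
        )
        assert expected == pytest.approx(0.4999917, abs=5e-7)

    @given(
        st.floats(min_value=1.0, max_value=1e7),
        st.floats(min_value=0.0, max_value=1e5),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, atp, protein):
        r = phospho_rate(atp, protein, self.law)
        assert 0.0 <= r < self.law.vmax
        assert phospho_rate(atp * 1.1, protein, self.law) >= r
        assert phospho_rate(atp, protein + 1.0, self.law) > r

    def test_nonpositive_atp_rejected(self):
        with pytest.raises(ValueError):
            phospho_rate(0.0, 1.0, self.law)


class TestPhosphoRateInhibited:
    law = PhosphoLaw(vmax=1.0, k_m_atp=100.0, k_ab=10.0)

    def test_zero_dose_bit_identical(self):
        for atp, p in [(3e6, 10.0), (88.0, 0.5), (1500.0, 1e4)]:
            assert phospho_rate_inhibited(atp, p, 0.0, self.law) == phospho_rate(
                atp, p, self.law
            )

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_dose(self, dose):
        lo = phospho_rate_inhibited(3000.0, 10.0, dose, self.law)
        hi = phospho_rate_inhibited(3000.0, 10.0, dose * 2, self.law)
        assert hi < lo

    def test_saturating_dose_floor(self):
        """Rate tends to the ATP-competitive floor, then to 0 only via the
        inhibitor-carrying term."""
        atp, p = 3000.0, 10.0
        floor = self.law.vmax * p / (self.law.k_ab + p)
        r = phospho_rate_inhibited(atp, p, 1e12, self.law)
        assert r < 1e-6  # K_M,ATP K^AB (1+D) dominates at huge dose
        # at moderate dose, rate stays between 0 and the no-drug value
        mid = phospho_rate_inhibited(atp, p, 100.0, self.law)
        assert 0 < mid < phospho_rate(atp, p, self.law) <= floor

    def test_direct_substitution_dose_100(self):
        atp, p, dose = 3000.0, 10.0, 100.0
        law = PhosphoLaw(vmax=1.0, k_m_atp=0.1, k_ab=10.0)
        expected = (1.0 * atp * p) / (
            0.1 * 10.0 * (1 + dose) + 10.0 * atp + atp * p
        )
        assert phospho_rate_inhibited(atp, p, dose, law) == pytest.approx(
            expected, rel=1e-15
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            phospho_rate_inhibited(3000.0, 1.0, -1.0, self.law)


class TestVEGFSynthesis:
    def test_baseline_returns_k_syn_exactly(self):
        law = VEGFSynthesisLaw(k_syn_original=0.37, k_alpha=2.0, mrna0=1.7)
        assert vegf_synthesis_rate(1.7, law) == 0.37

    def test_doubling_mrna_quadruples_rate(self):
        law = VEGFSynthesisLaw(k_syn_original=1.0, k_alpha=2.0, mrna0=2.0)
        assert vegf_synthesis_rate(4.0, law) == pytest.approx(4.0, rel=1e-14)

    def test_zero_mrna_gives_zero(self):
        law = VEGFSynthesisLaw(k_syn_original=1.0, k_alpha=2.0, mrna0=1.0)
        assert vegf_synthesis_rate(0.0, law) == 0.0

    def test_unconfigured_mrna0_rejected(self):
        law = VEGFSynthesisLaw(k_syn_original=1.0, k_alpha=2.0, mrna0=None)
        with pytest.raises(ValueError):
            vegf_synthesis_rate(1.0, law)


class TestVEGFBinding:
    law = VEGFBindingLaw(k1f=0.01, k1r=0.1)

    def test_no_drug_plain_mass_action(self):
        assert vegf_binding_rate(2.0, 3.0, 0.5, 0.0, self.law) == pytest.approx(
            0.01 * 6.0 - 0.1 * 0.5, rel=1e-15
        )

    def test_unit_dose_halves_forward_term(self):
        fwd0 = vegf_binding_rate(2.0, 3.0, 0.0, 0.0, self.law)
        fwd1 = vegf_binding_rate(2.0, 3.0, 0.0, 1.0, self.law)
        assert fwd1 == pytest.approx(fwd0 / 2.0, rel=1e-15)

    def test_saturating_dose_leaves_dissociation(self):
        r = vegf_binding_rate(2.0, 3.0, 0.5, 1e15, self.law)
        assert r == pytest.approx(-0.1 * 0.5, rel=1e-9)


@given(st.floats(min_value=1e-2, max_value=1e3))
@settings(max_examples=30, deadline=None)
def test_rate_laws_homogeneous_under_unit_rescaling(scale):
    """Rescaling concentrations and constants together rescales rates linearly."""
    law = PhosphoLaw(vmax=1.0, k_m_atp=100.0, k_ab=10.0)
    law_s = PhosphoLaw(vmax=1.0, k_m_atp=100.0 * scale, k_ab=10.0 * scale)
    r = phospho_rate(3000.0, 10.0, law)
    r_s = phospho_rate(3000.0 * scale, 10.0 * scale, law_s)
    assert r_s == pytest.approx(r, rel=1e-12)
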