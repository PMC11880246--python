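"""Nernst/GHK solvers and permeability-ratio inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from bilayerlab import electrochem as ec
from bilayerlab import solutions
from bilayerlab.exceptions import (
    AmbiguousRootError,
    DomainError,
    NoSolutionError,
    UnsupportedEquationError,
)

RTF = 25.97


class TestNernst:
    @pytest.mark.parametrize(
        "valence, c_out, c_in, expected",
        [
            (+1, 500.0, 50.0, RTF * math.log(10)),  # ~59.80 mV
            (+2, 150.0, 15.0, RTF / 2 * math.log(10)),  # ~29.90 mV
            (-1, 50.0, 500.0, RTF * math.log(10)),  # anion, reversed gradient
            (+1, 150.0, 150.0, 0.0),
        ],
    )
    def test_values(self, valence, c_out, c_in, expected):
        e = ec.nernst_potential(valence, c_out, c_in, rt_over_f=RTF)
        assert e == pytest.approx(expected, abs=1e-12)

    def test_printed_magnitudes(self):
        assert ec.nernst_potential(+1, 500, 50, rt_over_f=RTF) == pytest.approx(
            59.80, abs=0.01
        )
        assert ec.nernst_potential(+2, 150, 15, rt_over_f=RTF) == pytest.approx(
            29.90, abs=0.01
        )

    @given(
        c_out=st.floats(0.1, 1e4),
        c_in=st.floats(0.1, 1e4),
        z=st.sampled_from([-1, 1, 2]),
    )
    def test_antisymmetric_under_side_swap(self, c_out, c_in, z):
        forward = ec.nernst_potential(z, c_out, c_in, rt_over_f=RTF)
        backward = ec.nernst_potential(z, c_in, c_out, rt_over_f=RTF)
        assert forward == pytest.approx(-backward, abs=1e-9)

    @pytest.mark.parametrize("c_out, c_in", [(0.0, 50.0), (500.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_concentration_rejected(self, c_out, c_in):
        with pytest.raises(DomainError):
            ec.nernst_potential(+1, c_out, c_in, rt_over_f=RTF)

    def test_zero_valence_rejected(self):
        with pytest.raises(DomainError):
            ec.nernst_potential(0, 500, 50, rt_over_f=RTF)

    def test_default_temperature_thermal_voltage(self):
        assert ec.rt_over_f_mV(298.15) == pytest.approx(25.693, abs=0.001)
        assert ec.temperature_for_rt_over_f(RTF) == pytest.approx(301.37, abs=0.01)


class TestGHKMonovalent:
    def test_reported_wt_reversal(self):
        bath = solutions.kcl_gradient(
            permeabilities={"K+": 1.0, "Cl-": 0.031482}, rt_over_f=RTF
        )
        assert ec.ghk_reversal_monovalent(bath) == pytest.approx(52.77, abs=0.01)

    def test_single_permeant_equals_nernst(self, kcl_bath):
        e = ec.ghk_reversal_monovalent(kcl_bath)  # only K+ permeant
        assert e == ec.nernst_potential(+1, 500, 50, rt_over_f=RTF)

    def test_symmetric_concentrations_zero(self):
        bath = solutions.kcl_gradient(
            150, 150, permeabilities={"K+": 1.0, "Cl-": 0.5}, rt_over_f=RTF
        )
        assert ec.ghk_reversal_monovalent(bath) == 0.0

    def test_divalent_species_rejected(self, mixture_bath):
        with pytest.raises(UnsupportedEquationError):
            ec.ghk_reversal_monovalent(mixture_bath)

    def test_all_impermeant_rejected(self):
        bath = solutions.kcl_gradient(permeabilities={}, rt_over_f=RTF)
        with pytest.raises(DomainError):
            ec.ghk_reversal_monovalent(bath)

    def test_antisymmetric_under_side_swap(self):
        bath = solutions.kcl_gradient(
            permeabilities={"K+": 1.0, "Cl-": 0.2}, rt_over_f=RTF
        )
        assert ec.ghk_reversal_monovalent(bath.swapped()) == pytest.approx(
            -ec.ghk_reversal_monovalent(bath), abs=1e-12
        )

    @pytest.mark.parametrize("ratio", [10.0, 31.77])
    def test_monotone_in_cation_gradient(self, ratio):
        """E_rev increases strictly with ln(c_cat_out/c_cat_in) at fixed ratio."""
        gradients = [2.0, 5.0, 10.0, 50.0]
        e_revs = []
        for g in gradients:
            bath = solutions.kcl_gradient(
                50.0 * g, 50.0,
                permeabilities={"K+": 1.0, "Cl-": 1.0 / ratio}, rt_over_f=RTF,
            )
            e_revs.append(ec.ghk_reversal_monovalent(bath))
        assert np.all(np.diff(e_revs) > 0)


class TestInvertMonovalent:
    def test_wt_ratio(self, kcl_bath):
        res = ec.invert_monovalent_ratio(52.77, kcl_bath)
        assert res.numerator_species == "K+"
        assert res.ratio == pytest.approx(31.77, rel=0.005)

    def test_mutant_ratio(self, kcl_bath):
        res = ec.invert_monovalent_ratio(46.96, kcl_bath)
        assert res.ratio == pytest.approx(15.38, rel=0.005)

    def test_pure_cation_limit(self, kcl_bath):
        e_k = ec.nernst_potential(+1, 500, 50, rt_over_f=RTF)
        res = ec.invert_monovalent_ratio(e_k, kcl_bath)
        # anion-over-cation permeability vanishes at the cation Nernst potential
        assert 1.0 / res.ratio == 0.0

    @pytest.mark.parametrize("e_rev", [70.0, -70.0])
    def test_unattainable_reversal_rejected(self, kcl_bath, e_rev):
        with pytest.raises(NoSolutionError):
            ec.invert_monovalent_ratio(e_rev, kcl_bath)

    @given(log_ratio=st.floats(-6.0, 6.0))
    def test_forward_inverse_round_trip(self, log_ratio):
        ratio = math.exp(log_ratio)
        bath = solutions.kcl_gradient(
            permeabilities={"K+": 1.0, "Cl-": 1.0 / ratio}, rt_over_f=RTF
        )
        e = ec.ghk_reversal_monovalent(bath)
        res = ec.invert_monovalent_ratio(e, solutions.kcl_gradient(rt_over_f=RTF))
        assert res.ratio == pytest.approx(ratio, rel=1e-9)

    def test_implied_thermal_voltages_agree(self):
        """The two printed (E_rev, ratio) pairs on the same 500:50 KCl bath
        imply the same RT/F (~25.97 mV) within 0.5%."""

        def implied_rtf(e_rev, target_ratio):
            def f(rtf):
                bath = solutions.kcl_gradient(rt_over_f=rtf)
                return ec.invert_monovalent_ratio(e_rev, bath).ratio - target_ratio

            # below ~22.9 mV the measured E_rev exceeds the K+ Nernst
            # potential and no ratio exists, so bracket from 23 mV up
            return brentq(f, 23.0, 30.0, xtol=1e-10)

        rtf_wt = implied_rtf(52.77, 31.77)
        rtf_mut = implied_rtf(46.96, 15.38)
        assert rtf_wt == pytest.approx(25.97, rel=0.005)
        assert rtf_mut == pytest.approx(25.97, rel=0.005)
        assert rtf_wt == pytest.approx(rtf_mut, rel=0.005)


def _independent_forward_erev(k_out, k_in, ca_out, ca_in, p_ca, rtf):
    """Oracle: solve the divalent-capable flux-ratio equation for E_rev by
    root-finding on u (written independently of the library's solver)."""

    def g(u):
        num = k_out * (1 + u) + 4 * p_ca * ca_out
        den = k_in * (1 + u) + 4 * p_ca * ca_in * u
        return u * den - num

    u = brentq(g, 1e-12, 1e12, xtol=1e-300, rtol=1e-15)
    return rtf * math.log(u)


class TestGHKExtended:
    def test_hand_solved_mixture(self, mixture_bath):
        # K 500:50, Ca 10:100, P_K = P_Ca = 1: the flux-ratio equation
        # collapses to 450 u^2 - 450 u - 540 = 0
        u = (450 + math.sqrt(450**2 + 4 * 450 * 540)) / 900
        expected = RTF * math.log(u)
        e = ec.ghk_reversal_extended(mixture_bath)
        assert e == pytest.approx(expected, abs=1e-6)
        assert e == pytest.approx(13.84, abs=0.01)

    def test_zero_divalent_concentration_reduces_to_monovalent(self):
        bath = solutions.k_ca_mixture(
            500, 0.0, 50, 0.0,
            permeabilities={"K+": 1.0, "Ca2+": 1.0}, rt_over_f=RTF,
        )
        mono = solutions.kcl_gradient(rt_over_f=RTF)
        assert ec.ghk_reversal_extended(bath) == ec.ghk_reversal_monovalent(mono)

    def test_symmetric_bath_zero(self):
        bath = solutions.k_ca_mixture(
            100, 20, 100, 20,
            permeabilities={"K+": 1.0, "Ca2+": 0.7}, rt_over_f=RTF,
        )
        assert ec.ghk_reversal_extended(bath) == pytest.approx(0.0, abs=1e-9)

    def test_pure_divalent_equals_nernst(self, ca_bath):
        e = ec.ghk_reversal_extended(ca_bath)
        assert e == pytest.approx(
            ec.nernst_potential(+2, 150, 15, rt_over_f=RTF), abs=1e-6
        )

    def test_antisymmetric_under_side_swap(self, mixture_bath):
        e = ec.ghk_reversal_extended(mixture_bath)
        e_swapped = ec.ghk_reversal_extended(mixture_bath.swapped())
        assert e_swapped == pytest.approx(-e, abs=1e-6)

    def test_matches_independent_root_finder(self, mixture_bath):
        expected = _independent_forward_erev(500, 50, 10, 100, 1.0, RTF)
        assert ec.ghk_reversal_extended(mixture_bath) == pytest.approx(
            expected, abs=1e-6
        )

    def test_no_bracket_raises(self, mixture_bath):
        with pytest.raises(NoSolutionError):
            ec.ghk_reversal_extended(mixture_bath, bracket_mV=(100.0, 200.0))


class TestInvertDivalent:
    def test_round_trip_mixture(self, mixture_bath):
        e = ec.ghk_reversal_extended(mixture_bath)
        res = ec.invert_divalent_ratio(e, mixture_bath)
        assert res.numerator_species == "Ca2+"
        assert res.ratio == pytest.approx(1.0, rel=1e-9)

    def test_monovalent_only_reversal_gives_zero(self):
        bath = solutions.k_ca_mixture(rt_over_f=RTF)
        e_mono = ec.ghk_reversal_monovalent(solutions.kcl_gradient(rt_over_f=RTF))
        res = ec.invert_divalent_ratio(e_mono, bath)
        assert res.ratio == pytest.approx(0.0, abs=1e-12)

    def test_negative_solution_rejected(self, mixture_bath):
        # beyond the monovalent-only limit, P_Ca would have to be negative
        with pytest.raises(NoSolutionError):
            ec.invert_divalent_ratio(70.0, mixture_bath)

    @given(
        log_p=st.floats(-3.0, 3.0),
        k_out=st.floats(50.0, 800.0),
        ca_in=st.floats(5.0, 200.0),
    )
    def test_round_trip_randomized(self, log_p, k_out, ca_in):
        p_ca = math.exp(log_p)
        bath = solutions.k_ca_mixture(
            k_out, 10.0, 50.0, ca_in,
            permeabilities={"K+": 1.0, "Ca2+": p_ca}, rt_over_f=RTF,
        )
        e = ec.ghk_reversal_extended(bath)
        res = ec.invert_divalent_ratio(e, bath)
        assert res.ratio == pytest.approx(p_ca, rel=1e-9)

    @given(
        log_p=st.floats(-2.0, 2.0),
        ca_out=st.floats(5.0, 150.0),
        ca_in=st.floats(5.0, 150.0),
    )
    def test_closed_form_matches_brute_force_scan(self, log_p, ca_out, ca_in):
        """Closed-form inverse vs a log-grid scan refined by bisection on the
        ratio, both against the independent forward oracle."""
        p_true = math.exp(log_p)
        e_rev = _independent_forward_erev(500, 50, ca_out, ca_in, p_true, RTF)
        bath = solutions.k_ca_mixture(
            500, ca_out, 50, ca_in,
            permeabilities={"K+": 1.0, "Ca2+": 1.0}, rt_over_f=RTF,
        )
        closed = ec.invert_divalent_ratio(e_rev, bath).ratio

        def mismatch(log10_p):
            return (
                _independent_forward_erev(500, 50, ca_out, ca_in, 10**log10_p, RTF)
                - e_rev
            )

        grid = np.linspace(-6, 6, 241)
        vals = np.array([mismatch(g) for g in grid])
        idx = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        assert len(idx) >= 1
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
        brute = 10 ** brentq(mismatch, lo, hi, xtol=1e-13)
        assert closed == pytest.approx(brute, rel=1e-6)


class TestBathPair:
    def test_from_salts_expands_stoichiometry(self, mixture_bath):
        cl = mixture_bath.get("Cl-")
        assert cl.conc_out_mM == 500 + 2 * 10
        assert cl.conc_in_mM == 50 + 2 * 100
        mixture_bath.check_electroneutrality()

    def test_unknown_salt_rejected(self):
        with pytest.raises(DomainError):
            ec.BathPair.from_salts(cis={"XyCl": 10}, trans={"XyCl": 10})

    def test_inconsistent_thermal_voltage_rejected(self):
        with pytest.raises(DomainError):
            ec.BathPair(
                species=(ec.IonSpecies("K+", 1, 10, 10, 1.0),),
                temperature_K=298.15,
                rt_over_f_mV=30.0,
            )

    def test_invalid_species_rejected(self):
        with pytest.raises(DomainError):
            ec.IonSpecies("SO4--", -2, 10, 10)
        with pytest.raises(DomainError):
            ec.IonSpecies("K+", 1, -5.0, 10)
        with pytest.raises(DomainError):
            ec.IonSpecies("K+", 1, 5.0, 10, permeability=-1.0)
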