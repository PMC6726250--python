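"""Unit and property tests for the core rate laws and the full RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mamcal import (
    ModelState,
    ParameterSet,
    calcium_fluxes,
    compute_CER,
    ipr_gating,
    ipr_rate_constants,
    mitochondrial_rates,
    plasma_membrane_fluxes,
    rhs,
)
from mamcal.model import FluxSet, rhs_fixed_input
from mamcal.stimulation import StimulusProtocol

from oracle_rhs import oracle_rhs, random_valid_states

P = ParameterSet()


def mk_state(**kw):
    base = dict(C_cyt=0.1, C_MAM=1.0, C_mito=0.2, C_t=5000.0, P=0.3,
                h42=0.9, hn42=0.9, ADP_c=2000.0, ADP_m=10000.0, N=50.0,
                V_m=150.0)
    base.update(kw)
    return ModelState(**base)


class TestParameterSet:
    def test_defaults_spot_check(self):
        # a representative cross-section of the published constant table
        assert P.R_V1 == 2000.0 and P.R_V2 == 10.0 and P.R_V3 == 15.0
        assert P.R_S1 == P.R_S2 == 0.15
        assert P.k_nIPR == pytest.approx(0.5 * P.k_IPR)
        assert P.k_bar == 1e-8 and P.V_MCU == 1e-5
        assert P.q26 == 10500.0 and P.q62 == 4010.0
        assert P.C_p0 == 700.0 and P.C_p_cap == 1.8
        assert P.q9 == 2.0 and P.q10 == -30.0
        assert P.T == 310.16 and P.F == 96480.0 and P.R == 8315.0

    @pytest.mark.parametrize("bad", [
        {"R_S1": 1.5}, {"R_S2": -0.1}, {"f_c": 0.0}, {"f_m": 1.5},
        {"V_SERCA": -1.0}, {"K1": float("nan")},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            P.replace(**bad)

    def test_unknown_override_lists_valid_names(self):
        with pytest.raises(ValueError, match="k_IPR"):
            P.replace(no_such_param=1.0)


class TestComputeCER:
    def test_only_total_calcium(self):
        s = mk_state(C_cyt=0.0, C_MAM=0.0, C_mito=0.0, C_t=7.0)
        assert compute_CER(s, P) == pytest.approx(P.R_V2 * P.f_c * 7.0)

    def test_strictly_decreasing_in_cytosolic_ca(self):
        vals = [compute_CER(mk_state(C_cyt=c), P) for c in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_linear_in_each_compartment(self):
        s0, s1 = mk_state(C_MAM=1.0), mk_state(C_MAM=3.0)
        smid = mk_state(C_MAM=2.0)
        assert compute_CER(smid, P) == pytest.approx(
            0.5 * (compute_CER(s0, P) + compute_CER(s1, P)))


class TestIprRateConstants:
    def test_no_ip3_means_no_park_to_drive(self):
        rc = ipr_rate_constants(0.0)
        assert rc["V42"] == 0.0 and rc["a42"] == 0.0

    def test_saturating_ip3_limits(self):
        rc = ipr_rate_constants(1e6)
        assert rc["V24"] == pytest.approx(62.0, rel=1e-6)
        assert rc["a24"] == pytest.approx(1.0, rel=1e-6)

    def test_printed_value_at_one_micromolar(self):
        assert ipr_rate_constants(1.0)["V24"] == pytest.approx(238.0)


class TestIprGating:
    def test_closed_without_ip3(self):
        g = ipr_gating(mk_state(P=0.0), 540.0, P)
        assert g.q42 == 0.0 and g.qn42 == 0.0
        assert g.D == 0.0 and g.Dn == 0.0
        assert g.O_IPR == 0.0 and g.O_nIPR == 0.0
        assert g.lambda_h42 == pytest.approx(P.L_IPR)

    def test_drive_mode_open_probability(self):
        assert P.q26 / (P.q26 + P.q62) == pytest.approx(0.7236, abs=1e-3)

    def test_pore_concentration_scaling(self):
        g = ipr_gating(mk_state(), 680.0, P)
        assert g.C_p == pytest.approx(P.C_p0)

    @settings(derandomize=True, max_examples=200)
    @given(
        C_cyt=st.floats(0.0, 10.0), C_MAM=st.floats(0.0, 200.0),
        C_ER=st.floats(0.0, 700.0), Pip3=st.floats(0.0, 5.0),
        h42=st.floats(0.0, 1.0), hn42=st.floats(0.0, 1.0),
    )
    def test_gating_bounds(self, C_cyt, C_MAM, C_ER, Pip3, h42, hn42):
        """All probabilities and drive fractions stay in [0,1]; the h-gate
        relaxation rates interpolate between the park and drive rates."""
        s = mk_state(C_cyt=C_cyt, C_MAM=C_MAM, P=Pip3, h42=h42, hn42=hn42)
        g = ipr_gating(s, C_ER, P)
        for name in ("m24_inf", "h24_inf", "m42_inf", "mn42_inf",
                     "h42_inf", "hn42_inf", "D", "Dn", "O_IPR", "O_nIPR"):
            assert 0.0 <= getattr(g, name) <= 1.0, name
        for lam in (g.lambda_h42, g.lambda_hn42):
            assert min(P.L_IPR, P.H_IPR) <= lam <= max(P.L_IPR, P.H_IPR)
        assert g.q24 >= 0 and g.q42 >= 0 and g.qn42 >= 0


class TestCalciumFluxes:
    def test_no_diffusion_without_gradient(self):
        s = mk_state(C_MAM=0.1, C_cyt=0.1)
        g = ipr_gating(s, 540.0, P)
        assert calcium_fluxes(s, 540.0, g, P).J_diff == 0.0

    def test_serca_reversal_point(self):
        C_ER = 540.0
        c = math.sqrt(P.k_bar) * C_ER
        s = mk_state(C_cyt=c)
        g = ipr_gating(s, C_ER, P)
        assert calcium_fluxes(s, C_ER, g, P).J_SERCA == pytest.approx(0.0, abs=1e-12)

    def test_mcu_vanishes_without_cytosolic_ca(self):
        s = mk_state(C_cyt=0.0)
        g = ipr_gating(s, 540.0, P)
        assert calcium_fluxes(s, 540.0, g, P).J_MCU == 0.0

    def test_pump_fluxes_nonnegative(self):
        rng = np.random.default_rng(7)
        for y in random_valid_states(rng, P, 25):
            s = ModelState.from_array(y)
            C_ER = compute_CER(s, P)
            f = calcium_fluxes(s, C_ER, ipr_gating(s, C_ER, P), P)
            for name in ("J_nSERCA", "J_MCU", "J_nMCU", "J_NCX", "J_nNCX"):
                assert getattr(f, name) >= 0.0, name

    def test_ncx_guard_at_zero_source(self):
        s = mk_state(C_cyt=0.0)
        g = ipr_gating(s, 540.0, P)
        f = calcium_fluxes(s, 540.0, g, P)
        assert math.isfinite(f.J_NCX)


class TestPlasmaMembraneFluxes:
    def test_socc_half_maximum(self):
        pm = plasma_membrane_fluxes(mk_state(), P.K_SOCC, P)
        assert pm["J_SOCC"] == pytest.approx(P.V_SOCC / 2.0)

    def test_rocc_linear_in_ip3(self):
        assert plasma_membrane_fluxes(mk_state(P=0.0), 540.0, P)["J_ROCC"] == 0.0
        assert plasma_membrane_fluxes(mk_state(P=0.4), 540.0, P)[
            "J_ROCC"] == pytest.approx(P.V_ROCC * 0.4)

    def test_pmca_half_maximum(self):
        pm = plasma_membrane_fluxes(mk_state(C_cyt=P.K_pm), 540.0, P)
        assert pm["J_pm"] == pytest.approx(P.V_pm / 2.0)


class TestMitochondrialRates:
    def test_proton_leak_is_ohmic(self):
        f = mitochondrial_rates(mk_state(V_m=150.0), FluxSet(), P)
        assert f.I_Hleak == pytest.approx(2.0 * 150.0 - 30.0)  # = 270

    def test_no_oxidation_without_nadh(self):
        f = mitochondrial_rates(mk_state(N=0.0), FluxSet(), P)
        assert f.I_o == 0.0

    def test_agc_inhibited_by_high_mito_ca(self):
        lo = mitochondrial_rates(mk_state(C_mito=0.1), FluxSet(), P).I_agc
        hi = mitochondrial_rates(mk_state(C_mito=1e6), FluxSet(), P).I_agc
        assert hi < 1e-4 * lo

    def test_conservation_bound_violation_flagged(self):
        with pytest.raises(ValueError, match="ADP_c"):
            mitochondrial_rates(mk_state(ADP_c=P.A_tot_cyt * 1.01), FluxSet(), P)


class TestRhs:
    def test_total_calcium_conserved_in_closed_cell(self):
        closed = P.replace(k_leakin=0.0, V_SOCC=0.0, V_ROCC=0.0, V_pm=0.0)
        dy = rhs_fixed_input(0.0, mk_state().to_array(), closed, 0.3, 0.0)
        assert dy[3] == 0.0  # dC_t/dt

    def test_protocol_dispatch_matches_fixed_input(self):
        prot = StimulusProtocol.constant(0.3, t_end=100.0)
        s = mk_state()
        np.testing.assert_allclose(
            rhs(10.0, s, P, prot),
            rhs_fixed_input(10.0, s.to_array(), P, 0.3, 0.0),
        )

    def test_matches_independent_transcription(self):
        """Modular RHS equals a separately coded, literal transcription of
        the model equations at 100 random valid states, to 1e-12 relative."""
        rng = np.random.default_rng(20190822)
        for params in (P, P.replace(R_S1=0.3, R_S2=0.3, k_IPR=0.35,
                                    k_nIPR=0.3, V_MCU=1.3e-5, k_bar=1.25e-8)):
            for y in random_valid_states(rng, params, 50):
                got = rhs_fixed_input(0.0, y, params, 0.4, 2.0)
                want = oracle_rhs(y, params, 0.4, 2.0)
                np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_degenerate_surface_ratios_run(self):
        for rs in (0.0, 1.0):
            params = P.replace(R_S1=rs, R_S2=rs)
            dy = rhs_fixed_input(0.0, mk_state().to_array(), params, 0.3, 0.0)
            assert np.all(np.isfinite(dy))
        dy = rhs_fixed_input(
            0.0, mk_state().to_array(), P.replace(V_nSERCA=0.0), 0.3, 0.0)
        assert np.all(np.isfinite(dy))
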