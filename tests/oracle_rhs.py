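"""Independent, literal transcription of the model equations.

This file is a from-scratch re-coding of the full right-hand side used only
as a cross-check oracle in the tests.  It deliberately shares no helper
code with the package: every rate law is written out inline, in one
function, straight from the model's published algebraic form.
"""

import math

import numpy as np


def oracle_rhs(y, p, Ps, pulse):
    """Time derivative of the 11-vector [C_cyt, C_MAM, C_mito, C_t, P,
    h42, hn42, ADP_c, ADP_m, N, V_m] for parameter object ``p`` (attribute
    access), constant IP3 target ``Ps`` and pulse rate ``pulse``."""
    (C_cyt, C_MAM, C_mito, C_t, P, h42, hn42, ADP_c, ADP_m, N, V_m) = [
        float(v) for v in y
    ]

    # ER concentration from the total-Ca bookkeeping
    C_ER = p.R_V2 * p.f_c * (
        C_t - C_MAM / (p.R_V1 * p.f_c) - C_cyt / p.f_c - C_mito / (p.R_V3 * p.f_m)
    )

    # IP3-dependent gating coefficients
    V24 = 62.0 + 880.0 / (P ** 2 + 4.0)
    a24 = 1.0 + 5.0 / (P ** 2 + 0.25)
    k24 = 0.35
    km24 = 80.0
    V42 = 110.0 * P ** 2 / (P ** 2 + 0.01)
    a42 = 1.8 * P ** 2 / (P ** 2 + 0.34)
    k42 = 0.49 + 0.543 * P ** 3 / (P ** 3 + 64.0)
    km42 = 0.41 + 25.0 * P ** 3 / (P ** 3 + 274.6)

    # pore concentration and quasi-equilibrium gates
    Cp = p.C_p0 * (C_ER / 680.0)
    m24 = Cp ** 3 / (Cp ** 3 + k24 ** 3)
    h24 = km24 ** 2 / (Cp ** 2 + km24 ** 2)
    m42 = C_cyt ** 3 / (C_cyt ** 3 + k42 ** 3)
    mn42 = C_MAM ** 3 / (C_MAM ** 3 + k42 ** 3)
    h42inf = km42 ** 3 / (C_cyt ** 3 + km42 ** 3)
    hn42inf = km42 ** 3 / (C_MAM ** 3 + km42 ** 3)

    q24 = a24 + V24 * (1.0 - m24 * h24)
    q42 = a42 + V42 * m42 * h42
    qn42 = a42 + V42 * mn42 * hn42

    D = q42 * (p.q62 + p.q26) / (q42 * p.q62 + q42 * p.q26 + q24 * p.q62)
    Dn = qn42 * (p.q62 + p.q26) / (qn42 * p.q62 + qn42 * p.q26 + q24 * p.q62)
    O_IPR = p.q26 / (p.q62 + p.q26) * D
    O_nIPR = p.q26 / (p.q62 + p.q26) * Dn
    lam42 = (1.0 - D) * p.L_IPR + D * p.H_IPR
    lamn42 = (1.0 - Dn) * p.L_IPR + Dn * p.H_IPR

    # Ca2+ fluxes
    J_IPR = p.k_IPR * O_IPR * (C_ER - C_cyt)
    J_nIPR = p.k_nIPR * O_nIPR * (C_ER - C_MAM)
    J_diff = p.omega_c * (C_MAM - C_cyt)
    J_SERCA = p.V_SERCA * (C_cyt ** 2 - p.k_bar * C_ER ** 2) / (
        p.K_SERCA ** 2 + C_cyt ** 2)
    J_nSERCA = p.V_nSERCA * (C_MAM ** 2 - p.k_bar * C_ER ** 2) / (
        p.K_SERCA ** 2 + C_MAM ** 2)
    J_SOCC = p.V_SOCC * p.K_SOCC ** 4 / (p.K_SOCC ** 4 + C_ER ** 4)
    J_ROCC = p.V_ROCC * P
    J_in = p.k_leakin + J_SOCC + J_ROCC
    J_pm = p.V_pm * C_cyt ** 2 / (C_cyt ** 2 + p.K_pm ** 2)

    def mcu(C):
        return (
            p.V_MCU * (C / p.K1) * (1.0 + C / p.K1) ** 3 * math.exp(p.p1 * V_m)
            / ((1.0 + C / p.K1) ** 4 + p.L_MCU / (1.0 + C / p.K2) ** 2.8)
        )

    J_MCU = mcu(C_cyt)
    J_nMCU = mcu(C_MAM)
    J_NCX = p.V_NCX * (C_mito / max(C_cyt, 1e-12)) * math.exp(p.p2 * V_m)
    J_nNCX = p.V_NCX * (C_mito / max(C_MAM, 1e-12)) * math.exp(p.p2 * V_m)

    # metabolic rates from the conserved totals
    ATP_c = p.A_tot_cyt - ADP_c
    ATP_m = p.A_tot_mito - ADP_m
    NAD = p.N_tot_mito - N

    I_hyd = ((1.0 - p.R_S1) * J_SERCA + p.R_S1 * J_nSERCA) / 2.0 + (
        p.V_hyd * ATP_c / (ATP_c + p.K_hyd))
    FVRT = p.F * V_m / (p.R * p.T)
    I_ant = p.V_ant * (
        1.0 - (p.alpha_c * ATP_c * ADP_m) / (p.alpha_m * ADP_c * ATP_m)
        * math.exp(-FVRT)
    ) / (
        (1.0 + p.alpha_c * (ATP_c / ADP_c) * math.exp(-0.5 * FVRT))
        * (1.0 + ADP_m / (p.alpha_m * ATP_m))
    )
    I_F1FO = p.V_F1FO * (p.q6 / (p.q6 + ATP_m)) / (
        1.0 + math.exp((p.q7 - V_m) / p.q8))
    I_pdh = (p.k_gly / (p.q1 + N / NAD)) * (C_mito / (p.q2 + C_mito)) if NAD > 1e-12 else 0.0
    I_o = p.k_o * (N / (p.q3 + N)) / (1.0 + math.exp((V_m - p.q4) / p.q5))
    I_agc = p.V_agc * (C_cyt / (p.K_agc + C_cyt)) * (p.q2 / (p.q2 + C_mito)) * (
        math.exp(p.p4 * V_m))
    I_Hleak = p.q9 * V_m + p.q10

    return np.array([
        p.f_c * (
            (1.0 - p.R_S1) * (J_IPR - J_SERCA)
            + (1.0 - p.R_S2) / p.R_V3 * (J_NCX - J_MCU)
            + J_diff + J_in - J_pm
        ),
        p.f_c * (
            p.R_V1 * p.R_S1 * (J_nIPR - J_nSERCA)
            + p.R_V1 * p.R_S2 / p.R_V3 * (J_nNCX - J_nMCU)
            - p.R_V1 * J_diff
        ),
        p.f_m * (p.R_S2 * (J_nMCU - J_nNCX) + (1.0 - p.R_S2) * (J_MCU - J_NCX)),
        J_in - J_pm,
        p.tau_p * (Ps - P) + pulse,
        lam42 * (h42inf - h42),
        lamn42 * (hn42inf - hn42),
        I_hyd - I_ant / p.R_V3,
        I_ant - I_F1FO,
        I_pdh - I_o + I_agc,
        (
            p.a1 * I_o - p.a2 * I_F1FO - I_ant - I_Hleak
            - (1.0 - p.R_S2) * (J_NCX + 2.0 * J_MCU)
            - p.R_S2 * (J_nNCX + 2.0 * J_nMCU)
            - I_agc
        ) / p.C_p_cap,
    ])


def random_valid_states(rng, params, n):
    """Physically plausible random states (concentrations positive, pools
    within their conserved totals, C_ER positive by construction)."""
    states = np.empty((n, 11))
    for i in range(n):
        C_cyt = rng.uniform(0.01, 3.0)
        C_MAM = rng.uniform(0.01, 50.0)
        C_mito = rng.uniform(0.001, 5.0)
        C_ER = rng.uniform(50.0, 650.0)
        C_t = (
            C_ER / (params.R_V2 * params.f_c)
            + C_MAM / (params.R_V1 * params.f_c)
            + C_cyt / params.f_c
            + C_mito / (params.R_V3 * params.f_m)
        )
        states[i] = [
            C_cyt, C_MAM, C_mito, C_t,
            rng.uniform(0.0, 1.5),            # P
            rng.uniform(0.0, 1.0),            # h42
            rng.uniform(0.0, 1.0),            # hn42
            rng.uniform(100.0, 2400.0),       # ADP_c
            rng.uniform(500.0, 14500.0),      # ADP_m
            rng.uniform(5.0, 245.0),          # N
            rng.uniform(100.0, 180.0),        # V_m
        ]
    return states
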