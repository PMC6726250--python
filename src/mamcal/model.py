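"""Core kinetic model of hepatocyte Ca2+ dynamics with an explicit MAM compartment.

The cell is split into four well-mixed Ca2+ pools — the bulk cytosol, the
mitochondria-associated ER membrane microdomain (MAM), the mitochondrial
matrix, and the ER lumen — coupled to a lumped model of mitochondrial
metabolism (ADP/ATP, NADH, inner-membrane potential).  The ER concentration
is not integrated: it follows algebraically from the total intracellular
Ca2+ ``C_t`` and the other pools (:func:`compute_CER`), so the dynamical
system has eleven state variables.

ER Ca2+ release goes through IP3 receptors described by a two-mode
(park/drive) gating scheme: the receptor population switches between a
mostly-closed park mode and a drive mode whose open probability is
``q26/(q26+q62)``.  Four of the six gating variables are fast and are held
at their quasi-equilibria inside the right-hand side; only the two slow
inactivation gates (``h42`` for the bulk-cytosol receptors, ``hn42`` for
the MAM receptors) are integrated.

Units throughout: concentrations in µM, time in s, membrane potential in mV.
All functions here are pure and deterministic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ER_REF_CONC",
    "STATE_VARS",
    "ParameterSet",
    "ModelState",
    "IPRGatingView",
    "FluxSet",
    "compute_CER",
    "ipr_rate_constants",
    "ipr_gating",
    "calcium_fluxes",
    "plasma_membrane_fluxes",
    "mitochondrial_rates",
    "rhs",
    "rhs_fixed_input",
]

#: Reference ER Ca2+ concentration (µM) at which the concentration at the
#: pore of an open IP3 receptor equals C_p0.  A fixed constant of the gating
#: model, not a tunable parameter.
ER_REF_CONC = 680.0

#: Order of the dynamic variables in the state vector.
STATE_VARS = (
    "C_cyt", "C_MAM", "C_mito", "C_t", "P",
    "h42", "hn42", "ADP_c", "ADP_m", "N", "V_m",
)

# Concentration guard for the NCX source-side denominator (µM).
_NCX_EPS = 1e-12

# Parameters that must be >= 0 (q10, the voltage-independent proton-leak
# offset, is legitimately negative and is excluded).
_NONNEGATIVE = (
    "R_V1", "R_V2", "R_V3", "omega_c", "tau_p",
    "k_IPR", "k_nIPR", "V_SERCA", "V_nSERCA", "K_SERCA", "k_bar",
    "V_MCU", "V_NCX", "K1", "K2", "p1", "p2",
    "V_SOCC", "K_SOCC", "V_ROCC", "k_leakin", "V_pm", "K_pm",
    "q26", "q62", "L_IPR", "H_IPR", "C_p0",
    "N_tot_mito", "A_tot_mito", "A_tot_cyt", "C_p_cap", "L_MCU",
    "a1", "a2", "V_hyd", "K_hyd", "V_ant", "alpha_c", "alpha_m",
    "F", "R", "T", "V_F1FO", "k_gly", "k_o", "V_agc", "K_agc", "p4",
    "q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8", "q9",
)


@dataclass(frozen=True, slots=True)
class ParameterSet:
    """All model constants, defaulting to the control (lean, wild-type) cell.

    Volume ratios ``R_V*`` are cytosol:compartment volume quotients; surface
    ratios ``R_S1``/``R_S2`` are the fractions of the ER and mitochondrial
    membranes that face the MAM.  ``k_bar`` is the concentrating power of
    the SERCA ATPase (the reverse-reaction weight); raising it makes the ER
    leakier.  ``C_p_cap`` is the capacitance-like constant converting net
    charge flux into inner-membrane potential change (µM/mV).
    """

    # --- Ca2+ / IP3 compartment equations -------------------------------
    R_V1: float = 2000.0      # cytosol : MAM volume
    R_V2: float = 10.0        # cytosol : ER volume
    R_V3: float = 15.0        # cytosol : mitochondria volume
    R_S1: float = 0.15        # fraction of ER membrane facing the MAM
    R_S2: float = 0.15        # fraction of mito membrane facing the MAM
    omega_c: float = 0.001    # s^-1, MAM<->cytosol Ca2+ diffusion rate
    tau_p: float = 0.1        # s^-1, IP3 relaxation rate to its target
    f_c: float = 0.01         # free-Ca2+ fraction (cytosol, MAM, ER)
    f_m: float = 0.0003       # free-Ca2+ fraction (mitochondria)
    k_IPR: float = 0.3        # s^-1, bulk-cytosol IPR flux coefficient
    k_nIPR: float = 0.15      # s^-1, MAM IPR flux coefficient (= 0.5 k_IPR)
    V_SERCA: float = 30.0     # µM/s, max SERCA flux from the bulk cytosol
    V_nSERCA: float = 10.0    # µM/s, max SERCA flux from the MAM
    K_SERCA: float = 0.35     # µM
    k_bar: float = 1e-8       # concentrating power of the SERCA ATPase
    V_MCU: float = 1e-5       # µM/s, MCU flux coefficient
    V_NCX: float = 0.5        # µM/s, NCX flux coefficient
    K1: float = 19.0          # µM, MCU Ca2+ translocation constant
    K2: float = 0.38          # µM, MCU Ca2+ activation constant
    p1: float = 0.1           # mV^-1, MCU voltage dependence
    p2: float = 0.016         # mV^-1, NCX voltage dependence
    V_SOCC: float = 0.8       # µM/s, max store-operated influx
    K_SOCC: float = 100.0     # µM, half-inhibiting ER Ca2+ for SOCC
    V_ROCC: float = 0.25      # s^-1, receptor-operated influx coefficient
    k_leakin: float = 0.0019  # µM/s, constant plasma-membrane leak in
    V_pm: float = 0.2         # µM/s, max PMCA efflux
    K_pm: float = 0.45        # µM
    # --- IPR park/drive gating ------------------------------------------
    q26: float = 10500.0      # s^-1, drive-mode closed->open rate
    q62: float = 4010.0       # s^-1, drive-mode open->closed rate
    L_IPR: float = 0.02       # s^-1, h-gate relaxation rate in park mode
    H_IPR: float = 0.1        # s^-1, h-gate relaxation rate in drive mode
    C_p0: float = 700.0       # µM, Ca2+ at the pore of an open receptor
    # --- mitochondrial metabolism ---------------------------------------
    N_tot_mito: float = 250.0    # µM, total pyridine nucleotide
    A_tot_mito: float = 15000.0  # µM, total mito adenine nucleotide
    A_tot_cyt: float = 2500.0    # µM, total cytosolic adenine nucleotide
    C_p_cap: float = 1.8         # µM/mV, membrane "capacitance"
    L_MCU: float = 50.0          # MCU allosteric equilibrium constant
    a1: float = 20.0             # NADH oxidation -> voltage scaling
    a2: float = 3.43             # phosphorylation -> voltage scaling
    V_hyd: float = 150.0         # µM/s, max ATP hydrolysis rate
    K_hyd: float = 1000.0        # µM
    V_ant: float = 5000.0        # µM/s, adenine nucleotide translocator
    alpha_c: float = 0.111       # cytosolic ATP4-/ADP3- fraction ratio
    alpha_m: float = 0.139       # mitochondrial ATP4-/ADP3- fraction ratio
    F: float = 96480.0           # C/mol
    R: float = 8315.0            # mJ/(mol K)
    T: float = 310.16            # K
    V_F1FO: float = 35000.0      # µM/s, F1FO-ATPase coefficient
    k_gly: float = 450.0         # µM/s, glycolysis coefficient
    k_o: float = 600.0           # µM/s, NADH oxidation coefficient
    V_agc: float = 100.0         # µM/s, aspartate-glutamate carrier
    K_agc: float = 0.14          # µM
    p4: float = 0.005            # mV^-1, AGC voltage dependence
    q1: float = 1.0              # TCA NAD+ consumption constant
    q2: float = 0.1              # µM, TCA half-activation by mito Ca2+
    q3: float = 100.0            # mV-scaled ETC NADH constant
    q4: float = 177.0            # mV, ETC voltage dependence
    q5: float = 5.0              # mV, ETC voltage dependence
    q6: float = 10000.0          # µM, ATPase inhibition by ATP
    q7: float = 190.0            # mV, ATPase voltage dependence
    q8: float = 8.5              # mV, ATPase voltage dependence
    q9: float = 2.0              # µM/(s mV), ohmic proton leak slope
    q10: float = -30.0           # µM/s, proton leak offset

    def __post_init__(self) -> None:
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v!r}")
        for name in ("R_S1", "R_S2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("f_c", "f_m"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields overridden.

        Raises ``ValueError`` (listing the valid names) for unknown keys.
        """
        valid = {f.name for f in dataclasses.fields(self)}
        unknown = sorted(set(overrides) - valid)
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {unknown}; valid names: {sorted(valid)}"
            )
        return dataclasses.replace(self, **overrides)

    def key(self) -> tuple:
        """Hashable identity of this parameter set (field-value tuple)."""
        return tuple(getattr(self, f.name) for f in dataclasses.fields(self))


@dataclass(slots=True)
class ModelState:
    """The eleven dynamic variables.

    ``C_*`` are free Ca2+ concentrations (µM) in the bulk cytosol, the MAM
    and the mitochondrial matrix; ``C_t`` is the total intracellular Ca2+;
    ``P`` is the IP3 concentration; ``h42``/``hn42`` are the slow IPR
    inactivation gates; ``ADP_c``/``ADP_m`` are adenosine diphosphate pools,
    ``N`` is mitochondrial NADH and ``V_m`` the inner-membrane potential.
    """

    C_cyt: float
    C_MAM: float
    C_mito: float
    C_t: float
    P: float
    h42: float
    hn42: float
    ADP_c: float
    ADP_m: float
    N: float
    V_m: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_VARS),):
            raise ValueError(f"state vector must have shape (11,), got {y.shape}")
        return cls(*(float(v) for v in y))


@dataclass(slots=True)
class IPRGatingView:
    """Snapshot of the IPR park/drive gating quantities at one state.

    ``D``/``Dn`` are the drive-mode fractions of the bulk-cytosol and MAM
    receptor populations; ``O_IPR``/``O_nIPR`` the resulting open
    probabilities; ``lambda_*`` the relaxation rates of the slow gates.
    ``C_p`` is the Ca2+ concentration at the pore, C_p0 * (C_ER / 680).
    """

    m24_inf: float
    h24_inf: float
    m42_inf: float
    mn42_inf: float
    h42_inf: float
    hn42_inf: float
    q24: float
    q42: float
    qn42: float
    D: float
    Dn: float
    O_IPR: float
    O_nIPR: float
    lambda_h42: float
    lambda_hn42: float
    C_p: float


@dataclass(slots=True)
class FluxSet:
    """All Ca2+ fluxes (J_*) and metabolic rates (I_*), in µM/s.

    ``n``-prefixed fluxes are the MAM-side variants of the corresponding
    bulk-cytosol fluxes.  J_* with pump/channel character are non-negative
    for non-negative concentrations; J_IPR, J_nIPR and J_diff are signed.
    """

    J_IPR: float = 0.0
    J_nIPR: float = 0.0
    J_SERCA: float = 0.0
    J_nSERCA: float = 0.0
    J_MCU: float = 0.0
    J_nMCU: float = 0.0
    J_NCX: float = 0.0
    J_nNCX: float = 0.0
    J_diff: float = 0.0
    J_leakin: float = 0.0
    J_SOCC: float = 0.0
    J_ROCC: float = 0.0
    J_in: float = 0.0
    J_pm: float = 0.0
    I_hyd: float = 0.0
    I_ant: float = 0.0
    I_F1FO: float = 0.0
    I_pdh: float = 0.0
    I_o: float = 0.0
    I_agc: float = 0.0
    I_Hleak: float = 0.0


# ---------------------------------------------------------------------------
# Algebraic ER concentration
# ---------------------------------------------------------------------------

def compute_CER(state: ModelState, params: ParameterSet) -> float:
    """Free ER Ca2+ concentration implied by the total-Ca2+ bookkeeping.

    C_ER = R_V2 f_c (C_t - C_MAM/(R_V1 f_c) - C_cyt/f_c - C_mito/(R_V3 f_m)).
    Linear in every compartment concentration; a negative return signals an
    inconsistent state and is flagged by the caller, not here.
    """
    p = params
    return p.R_V2 * p.f_c * (
        state.C_t
        - state.C_MAM / (p.R_V1 * p.f_c)
        - state.C_cyt / p.f_c
        - state.C_mito / (p.R_V3 * p.f_m)
    )


def _cer_from_floats(C_cyt, C_MAM, C_mito, C_t, p: ParameterSet) -> float:
    return p.R_V2 * p.f_c * (
        C_t - C_MAM / (p.R_V1 * p.f_c) - C_cyt / p.f_c - C_mito / (p.R_V3 * p.f_m)
    )


# ---------------------------------------------------------------------------
# IPR gating
# ---------------------------------------------------------------------------

def ipr_rate_constants(P: float) -> dict:
    """IP3-dependent coefficients of the park/drive transition rates.

    Closed-form fits (s^-1 for the V/a terms, µM for the k terms) chosen to
    reproduce the measured mode-switching rate distributions of single IPRs.
    """
    if not math.isfinite(P):
        raise ValueError(f"IP3 concentration must be finite, got {P!r}")
    P2 = P * P
    P3 = P2 * P
    return {
        "V24": 62.0 + 880.0 / (P2 + 4.0),
        "a24": 1.0 + 5.0 / (P2 + 0.25),
        "k24": 0.35,
        "k_m24": 80.0,
        "V42": 110.0 * P2 / (P2 + 0.01),
        "a42": 1.8 * P2 / (P2 + 0.34),
        "k42": 0.49 + 0.543 * P3 / (P3 + 64.0),
        "k_m42": 0.41 + 25.0 * P3 / (P3 + 274.6),
    }


def ipr_gating(state: ModelState, C_ER: float, params: ParameterSet) -> IPRGatingView:
    """Evaluate the park/drive gating scheme at one state.

    The fast gates (m24, h24, m42, mn42) are taken at their quasi-equilibria;
    the slow inactivation gates h42/hn42 enter with their *dynamic* values
    from the state.  Also returns h42_inf/hn42_inf, the targets of the two
    slow-gate ODEs.
    """
    p = params
    rc = ipr_rate_constants(state.P)
    C_p = p.C_p0 * (C_ER / ER_REF_CONC)

    Cp2 = C_p * C_p
    Cp3 = Cp2 * C_p
    k24_3 = rc["k24"] ** 3
    km24_2 = rc["k_m24"] ** 2
    k42_3 = rc["k42"] ** 3
    km42_3 = rc["k_m42"] ** 3
    Ccyt3 = state.C_cyt ** 3
    Cmam3 = state.C_MAM ** 3

    m24_inf = Cp3 / (Cp3 + k24_3)
    h24_inf = km24_2 / (Cp2 + km24_2)
    m42_inf = Ccyt3 / (Ccyt3 + k42_3)
    mn42_inf = Cmam3 / (Cmam3 + k42_3)
    h42_inf = km42_3 / (Ccyt3 + km42_3)
    hn42_inf = km42_3 / (Cmam3 + km42_3)

    q24 = rc["a24"] + rc["V24"] * (1.0 - m24_inf * h24_inf)
    q42 = rc["a42"] + rc["V42"] * m42_inf * state.h42
    qn42 = rc["a42"] + rc["V42"] * mn42_inf * state.hn42

    qsum = p.q62 + p.q26
    denom = q42 * p.q62 + q42 * p.q26 + q24 * p.q62
    D = q42 * qsum / denom if denom > 0 else 0.0
    denom_n = qn42 * p.q62 + qn42 * p.q26 + q24 * p.q62
    Dn = qn42 * qsum / denom_n if denom_n > 0 else 0.0

    drive_open = p.q26 / qsum
    return IPRGatingView(
        m24_inf=m24_inf, h24_inf=h24_inf, m42_inf=m42_inf, mn42_inf=mn42_inf,
        h42_inf=h42_inf, hn42_inf=hn42_inf,
        q24=q24, q42=q42, qn42=qn42,
        D=D, Dn=Dn,
        O_IPR=drive_open * D, O_nIPR=drive_open * Dn,
        lambda_h42=(1.0 - D) * p.L_IPR + D * p.H_IPR,
        lambda_hn42=(1.0 - Dn) * p.L_IPR + Dn * p.H_IPR,
        C_p=C_p,
    )


# ---------------------------------------------------------------------------
# Ca2+ fluxes
# ---------------------------------------------------------------------------

def _mcu_flux(C: float, V_m: float, p: ParameterSet) -> float:
    # Magnus-Keizer uniporter: allosteric activation term L/(1+C/K2)^2.8
    # shrinks as Ca2+ rises (K2 is the activation constant).
    x1 = 1.0 + C / p.K1
    x2 = 1.0 + C / p.K2
    num = p.V_MCU * (C / p.K1) * x1 ** 3 * math.exp(p.p1 * V_m)
    return num / (x1 ** 4 + p.L_MCU / x2 ** 2.8)


def _ncx_flux(C_mito: float, C_source: float, V_m: float, p: ParameterSet) -> float:
    return p.V_NCX * (C_mito / max(C_source, _NCX_EPS)) * math.exp(p.p2 * V_m)


def calcium_fluxes(
    state: ModelState, C_ER: float, gating: IPRGatingView, params: ParameterSet
) -> FluxSet:
    """ER-release, SERCA, diffusion, MCU and NCX fluxes (the J_* Ca2+ part).

    The MAM variants use C_MAM wherever the bulk-cytosol variant uses C_cyt.
    SERCA is a net flux with reverse term k_bar * C_ER^2 in the numerator.
    """
    p = params
    s = state
    f = FluxSet()
    f.J_IPR = p.k_IPR * gating.O_IPR * (C_ER - s.C_cyt)
    f.J_nIPR = p.k_nIPR * gating.O_nIPR * (C_ER - s.C_MAM)
    f.J_diff = p.omega_c * (s.C_MAM - s.C_cyt)
    K2s = p.K_SERCA * p.K_SERCA
    rev = p.k_bar * C_ER * C_ER
    f.J_SERCA = p.V_SERCA * (s.C_cyt * s.C_cyt - rev) / (K2s + s.C_cyt * s.C_cyt)
    f.J_nSERCA = p.V_nSERCA * (s.C_MAM * s.C_MAM - rev) / (K2s + s.C_MAM * s.C_MAM)
    f.J_MCU = _mcu_flux(s.C_cyt, s.V_m, p)
    f.J_nMCU = _mcu_flux(s.C_MAM, s.V_m, p)
    f.J_NCX = _ncx_flux(s.C_mito, s.C_cyt, s.V_m, p)
    f.J_nNCX = _ncx_flux(s.C_mito, s.C_MAM, s.V_m, p)
    return f


def plasma_membrane_fluxes(
    state: ModelState, C_ER: float, params: ParameterSet
) -> dict:
    """Plasma-membrane Ca2+ entry (leak + SOCC + ROCC) and PMCA efflux."""
    p = params
    K4 = p.K_SOCC ** 4
    J_SOCC = p.V_SOCC * K4 / (K4 + C_ER ** 4)
    J_ROCC = p.V_ROCC * state.P
    J_in = p.k_leakin + J_SOCC + J_ROCC
    c2 = state.C_cyt * state.C_cyt
    J_pm = p.V_pm * c2 / (c2 + p.K_pm * p.K_pm)
    return {
        "J_leakin": p.k_leakin,
        "J_SOCC": J_SOCC,
        "J_ROCC": J_ROCC,
        "J_in": J_in,
        "J_pm": J_pm,
    }


# ---------------------------------------------------------------------------
# Mitochondrial metabolic rates
# ---------------------------------------------------------------------------

def mitochondrial_rates(
    state: ModelState,
    flux: FluxSet,
    params: ParameterSet,
    bound_tol: float = 1e-6,
) -> FluxSet:
    """Fill in the metabolic I_* rates on ``flux`` and return it.

    ATP_c, ATP_m and NAD are recovered algebraically from the conserved
    totals; a conservation-bound violation beyond ``bound_tol`` (relative to
    the corresponding total) raises ``ValueError``.
    """
    p = params
    s = state
    for val, tot, name in (
        (s.ADP_c, p.A_tot_cyt, "ADP_c"),
        (s.ADP_m, p.A_tot_mito, "ADP_m"),
        (s.N, p.N_tot_mito, "N"),
    ):
        slack = bound_tol * tot
        if not (-slack <= val <= tot + slack):
            raise ValueError(
                f"{name}={val!r} violates its conservation bound [0, {tot}]"
            )
    ATP_c = p.A_tot_cyt - s.ADP_c
    ATP_m = p.A_tot_mito - s.ADP_m
    NAD = p.N_tot_mito - s.N

    flux.I_hyd = (
        ((1.0 - p.R_S1) * flux.J_SERCA + p.R_S1 * flux.J_nSERCA) / 2.0
        + p.V_hyd * ATP_c / (ATP_c + p.K_hyd)
    )

    # Adenine nucleotide translocator (Magnus-Keizer form); the alpha's are
    # the ATP4-/ADP3- charged-species fraction ratios.
    fvrt = p.F * s.V_m / (p.R * p.T)
    atp_adp_c = p.alpha_c * ATP_c / max(s.ADP_c, _NCX_EPS)
    adp_atp_m = s.ADP_m / (p.alpha_m * max(ATP_m, _NCX_EPS))
    flux.I_ant = (
        p.V_ant
        * (1.0 - atp_adp_c * adp_atp_m * math.exp(-fvrt))
        / ((1.0 + atp_adp_c * math.exp(-0.5 * fvrt)) * (1.0 + adp_atp_m))
    )

    flux.I_F1FO = (
        p.V_F1FO * (p.q6 / (p.q6 + ATP_m)) / (1.0 + math.exp((p.q7 - s.V_m) / p.q8))
    )
    if NAD > _NCX_EPS:
        flux.I_pdh = (
            p.k_gly / (p.q1 + s.N / NAD) * (s.C_mito / (p.q2 + s.C_mito))
        )
    else:
        flux.I_pdh = 0.0
    flux.I_o = p.k_o * (s.N / (p.q3 + s.N)) / (1.0 + math.exp((s.V_m - p.q4) / p.q5))
    flux.I_agc = (
        p.V_agc
        * (s.C_cyt / (p.K_agc + s.C_cyt))
        * (p.q2 / (p.q2 + s.C_mito))
        * math.exp(p.p4 * s.V_m)
    )
    flux.I_Hleak = p.q9 * s.V_m + p.q10
    return flux


# ---------------------------------------------------------------------------
# Full right-hand side
# ---------------------------------------------------------------------------

def rhs_fixed_input(t, y, params: ParameterSet, Ps: float, pulse_rate: float):
    """Time derivative of the 11-vector with a fixed IP3 target and pulse rate.

    This is the form the integrator consumes: between protocol breakpoints
    both the IP3 target ``Ps`` and the square-pulse rate are constant.
    """
    p = params
    state = ModelState(*(float(v) for v in y))
    C_ER = _cer_from_floats(state.C_cyt, state.C_MAM, state.C_mito, state.C_t, p)

    g = ipr_gating(state, C_ER, p)
    f = calcium_fluxes(state, C_ER, g, p)
    pm = plasma_membrane_fluxes(state, C_ER, p)
    f.J_leakin = pm["J_leakin"]
    f.J_SOCC = pm["J_SOCC"]
    f.J_ROCC = pm["J_ROCC"]
    f.J_in = pm["J_in"]
    f.J_pm = pm["J_pm"]
    mitochondrial_rates(state, f, p)

    dC_cyt = p.f_c * (
        (1.0 - p.R_S1) * (f.J_IPR - f.J_SERCA)
        + (1.0 - p.R_S2) / p.R_V3 * (f.J_NCX - f.J_MCU)
        + f.J_diff + f.J_in - f.J_pm
    )
    dC_MAM = p.f_c * (
        p.R_V1 * p.R_S1 * (f.J_nIPR - f.J_nSERCA)
        + p.R_V1 * p.R_S2 / p.R_V3 * (f.J_nNCX - f.J_nMCU)
        - p.R_V1 * f.J_diff
    )
    dC_mito = p.f_m * (
        p.R_S2 * (f.J_nMCU - f.J_nNCX) + (1.0 - p.R_S2) * (f.J_MCU - f.J_NCX)
    )
    dC_t = f.J_in - f.J_pm
    dP = p.tau_p * (Ps - state.P) + pulse_rate
    dh42 = g.lambda_h42 * (g.h42_inf - state.h42)
    dhn42 = g.lambda_hn42 * (g.hn42_inf - state.hn42)
    dADP_c = f.I_hyd - f.I_ant / p.R_V3
    dADP_m = f.I_ant - f.I_F1FO
    dN = f.I_pdh - f.I_o + f.I_agc
    dV_m = (
        p.a1 * f.I_o - p.a2 * f.I_F1FO - f.I_ant - f.I_Hleak
        - (1.0 - p.R_S2) * (f.J_NCX + 2.0 * f.J_MCU)
        - p.R_S2 * (f.J_nNCX + 2.0 * f.J_nMCU)
        - f.I_agc
    ) / p.C_p_cap

    dy = (dC_cyt, dC_MAM, dC_mito, dC_t, dP, dh42, dhn42, dADP_c, dADP_m, dN, dV_m)
    for name, v in zip(STATE_VARS, dy):
        if not math.isfinite(v):
            raise FloatingPointError(
                f"non-finite derivative d{name}/dt = {v!r} at t={t}, state={y!r}"
            )
    return np.array(dy)


def rhs(t, state, params: ParameterSet, stimulus):
    """Full right-hand side with the stimulation protocol evaluated at ``t``.

    ``state`` may be a :class:`ModelState` or an 11-vector; ``stimulus`` is
    any object with ``ps_at(t)`` and ``pulse_at(t)`` methods.
    """
    if isinstance(state, ModelState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    return rhs_fixed_input(t, y, params, stimulus.ps_at(t), stimulus.pulse_at(t))
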