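"""Canonical parameter conditions and figure-style comparison drivers.

Three named conditions are built in: ``control`` (the lean wild-type cell,
all defaults), ``obesity`` (the six-parameter ob/ob override set: more MAM
surface, stronger IPR and MCU expression, leakier SERCA), and ``linker``
(MAM surface ratios mechanically raised to 0.48, emulating synthetic
ER-mitochondria linkers).  ``run_figure`` reruns the simulation underlying
each of the paper-style figure panels and writes trajectories (CSV) plus a
metrics dictionary (JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ModelState, ParameterSet
from .simulate import Trajectory, find_rest_state, integrate
from .stimulation import Pulse, StimulusProtocol, fig13_staircase
from . import analysis

__all__ = [
    "Condition",
    "CONTROL_OVERRIDES",
    "OBESITY_OVERRIDES",
    "LINKER_OVERRIDES",
    "build_parameters",
    "compare_conditions",
    "run_figure",
    "FIGURE_IDS",
]

CONTROL_OVERRIDES: dict = {}
#: ob/ob condition: increased MAM formation (R_S), IPR and MCU expression,
#: and a leakier ER (higher SERCA reverse power k_bar).
OBESITY_OVERRIDES = {
    "R_S1": 0.3,
    "R_S2": 0.3,
    "k_IPR": 0.35,
    "k_nIPR": 0.3,
    "V_MCU": 1.3e-5,
    "k_bar": 1.25e-8,
}
#: synthetic-linker condition: only the MAM surface ratios are raised.
LINKER_OVERRIDES = {"R_S1": 0.48, "R_S2": 0.48}

_NAMED = {
    "control": CONTROL_OVERRIDES,
    "obesity": OBESITY_OVERRIDES,
    "linker": LINKER_OVERRIDES,
}


@dataclass(frozen=True)
class Condition:
    """A named parameter condition with optional extra overrides."""

    name: str = "control"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _NAMED and self.name != "custom":
            raise ValueError(
                f"unknown condition {self.name!r}; choose from "
                f"{sorted(_NAMED) + ['custom']}"
            )


def build_parameters(condition) -> ParameterSet:
    """Parameter set for a condition (name string or :class:`Condition`).

    The named overrides are applied to the control defaults first, then any
    custom overrides on top.  Unknown override keys raise ``ValueError``
    listing the valid parameter names.
    """
    if isinstance(condition, str):
        condition = Condition(name=condition)
    base = ParameterSet()
    named = _NAMED.get(condition.name, {})
    merged = {**named, **condition.overrides}
    return base.replace(**merged) if merged else base


def compare_conditions(
    cond_a="control",
    cond_b="obesity",
    Ps: float = 0.3,
    hours: float = 2.0,
    output_dt: float = 0.1,
) -> dict:
    """Frequency and mitochondrial-level comparison under constant IP3.

    Both conditions are simulated from their own rest states for ``hours``
    of model time at the constant target ``Ps``; cytosolic spike frequency
    and the average mitochondrial Ca2+ level (both the time average and the
    inter-spike baseline average) are compared.
    """
    out = {}
    for tag, cond in (("a", cond_a), ("b", cond_b)):
        params = build_parameters(cond)
        protocol = StimulusProtocol.constant(Ps, t_end=hours * 3600.0)
        traj = integrate(params, protocol, output_dt=output_dt)
        mc = analysis.oscillation_summary(traj, "C_cyt")
        mm = analysis.oscillation_summary(traj, "C_mito")
        out[tag] = {
            "condition": cond if isinstance(cond, str) else cond.name,
            "n_spikes": mc.n_spikes,
            "frequency": mc.mean_frequency,
            "mito_mean_level": mm.mean_level,
            "mito_baseline_level": mm.baseline_level,
        }
    fa, fb = out["a"]["frequency"], out["b"]["frequency"]
    la, lb = out["a"]["mito_mean_level"], out["b"]["mito_mean_level"]
    ba, bb = out["a"]["mito_baseline_level"], out["b"]["mito_baseline_level"]
    out["pct_frequency_increase"] = 100.0 * (fb - fa) / fa
    out["pct_mito_level_increase"] = 100.0 * (lb - la) / la
    out["pct_mito_baseline_increase"] = 100.0 * (bb - ba) / ba
    return out


# ---------------------------------------------------------------------------
# Figure runners
# ---------------------------------------------------------------------------

FIGURE_IDS = tuple(f"fig{i}" for i in range(2, 14))

_PULSE_FIG2 = Pulse(M=10.0, t0=60.0, delta=0.2)
_PULSE_FIG7 = Pulse(M=10.0, t0=100.0, delta=0.2)


def _pulse_protocol(pulse: Pulse, t_end: float) -> StimulusProtocol:
    return StimulusProtocol.constant(0.0, t_end=t_end, pulses=[pulse])


def _write(out_dir, name: str, traj: Trajectory) -> None:
    if out_dir is not None:
        from .io import write_trajectory

        write_trajectory(traj, Path(out_dir) / f"{name}.csv")


def run_figure(figure_id: str, out_dir=None, output_dt: float = None) -> dict:
    """Re-run the simulation behind one figure panel set.

    Writes one CSV per trajectory plus ``<figure_id>_metrics.json`` into
    ``out_dir`` (if given) and returns the metrics dictionary.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; choose from {FIGURE_IDS}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"figure": figure_id}
    runner = globals()[f"_run_{figure_id}"]
    metrics.update(runner(out_dir, output_dt))
    if out_dir is not None:
        with open(out_dir / f"{figure_id}_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
    return metrics


def _norm_peak_metrics(out_dir, output_dt, conditions, pulse, t_end=200.0):
    dt = output_dt or 0.01
    protocol = _pulse_protocol(pulse, t_end)
    trajs = {}
    for name, params in conditions:
        trajs[name] = integrate(params, protocol, output_dt=dt)
        _write(out_dir, name, trajs[name])
    ref = trajs[conditions[0][0]]["C_mito"]
    peaks = {
        name: float(np.max(analysis.normalize_transient(tr["C_mito"], ref)))
        for name, tr in trajs.items()
    }
    return {"normalized_mito_peaks": peaks}


def _run_fig2(out_dir, output_dt):
    """Control vs synthetic-linker mitochondrial transient (pulse M=10 at 60 s)."""
    return _norm_peak_metrics(
        out_dir, output_dt,
        [("control", build_parameters("control")),
         ("linker", build_parameters("linker"))],
        _PULSE_FIG2,
    )


def _run_fig3(out_dir, output_dt):
    """Two-phase stimulation (pulse then a constant-IP3 plateau): mitochondrial
    variables track the cytosolic Ca2+ spikes with slower relaxation."""
    protocol = StimulusProtocol(
        segments=((0.0, 600.0, 0.0), (600.0, 1400.0, 0.3), (1400.0, 2000.0, 0.0)),
        pulses=[Pulse(M=5.0, t0=100.0, delta=0.2)],
    )
    traj = integrate(build_parameters("control"), protocol,
                     output_dt=output_dt or 0.1)
    _write(out_dir, "control_two_phase", traj)
    i0 = int(np.searchsorted(traj.t, 100.0))
    i1 = int(np.searchsorted(traj.t, 400.0))
    seg = slice(i0, i1)
    return {
        "V_m_rise_at_spike": float(np.max(traj["V_m"][seg]) - traj["V_m"][0]),
        "N_rise_at_spike": float(np.max(traj["N"][seg]) - traj["N"][0]),
        "ATP_m_rise_at_spike": float(np.max(traj["ATP_m"][seg]) - traj["ATP_m"][0]),
        "plateau_n_spikes": analysis.oscillation_summary(
            traj, "C_cyt", window=(600.0, 1400.0)).n_spikes,
    }


def _run_fig4(out_dir, output_dt):
    """Constant P_s = 0.3: compartment concentration hierarchy and the
    MAM:cytosol spike-frequency ratio."""
    traj = integrate(build_parameters("control"),
                     StimulusProtocol.constant(0.3, t_end=900.0),
                     output_dt=output_dt or 0.05)
    _write(out_dir, "control_ps0.3", traj)
    window = (300.0, 900.0)
    m = {v: analysis.oscillation_summary(traj, v, window)
         for v in ("C_cyt", "C_MAM", "C_ER")}
    return {
        "mam_spikes_per_cyt_spike": analysis.mam_spikes_per_cytosolic_spike(
            traj, window),
        "mean_peaks": {v: float(np.mean(mm.spike_peaks)) if mm.n_spikes else None
                       for v, mm in m.items()},
        "C_ER_range": [float(traj["C_ER"].min()), float(traj["C_ER"].max())],
    }


def _run_fig5(out_dir, output_dt):
    """MAM oscillations for V_nSERCA = 12, 10, 8 µM/s: less MAM SERCA raises
    the post-spike MAM baseline and the MAM spike frequency."""
    out = {}
    window = (300.0, 900.0)
    for v in (12.0, 10.0, 8.0):
        params = build_parameters(Condition("custom", {"V_nSERCA": v}))
        traj = integrate(params, StimulusProtocol.constant(0.3, t_end=900.0),
                         output_dt=output_dt or 0.05)
        _write(out_dir, f"VnSERCA_{v:g}", traj)
        m = analysis.oscillation_summary(traj, "C_MAM", window)
        out[f"{v:g}"] = {
            "mam_baseline": m.baseline_level,
            "mam_frequency": m.mean_frequency,
        }
    return {"by_VnSERCA": out}


def _run_fig6(out_dir, output_dt):
    """First MAM spike vs the drive-mode inhibition rate H_IPR and the
    initial value of the MAM inactivation gate hn42."""
    dt = output_dt or 0.01
    protocol = StimulusProtocol.constant(0.3, t_end=150.0)
    by_H = {}
    for H in (0.05, 0.1, 0.15):
        params = build_parameters(Condition("custom", {"H_IPR": H}))
        traj = integrate(params, protocol, output_dt=dt)
        _write(out_dir, f"HIPR_{H:g}", traj)
        _, peaks = analysis.detect_spikes(traj.t, traj["C_MAM"])
        by_H[f"{H:g}"] = float(peaks[0])
    params = build_parameters("control")
    rest = find_rest_state(params)
    by_h0 = {}
    for h0 in (0.0, 0.99, 2.0):  # hn42 > 1 is a deliberate manual override
        y = rest.to_array()
        y[5 + 1] = h0  # hn42 slot
        traj = integrate(params, protocol, initial=y, output_dt=dt)
        _write(out_dir, f"hn42_0_{h0:g}", traj)
        _, peaks = analysis.detect_spikes(traj.t, traj["C_MAM"])
        by_h0[f"{h0:g}"] = float(peaks[0])
    return {"first_mam_peak_by_HIPR": by_H, "first_mam_peak_by_hn42_0": by_h0}


def _run_fig7(out_dir, output_dt):
    """Control vs obesity transients under the pulse at t0 = 100 s."""
    return _norm_peak_metrics(
        out_dir, output_dt,
        [("control", build_parameters("control")),
         ("obesity", build_parameters("obesity"))],
        _PULSE_FIG7, t_end=250.0,
    )


def _oscillation_comparison(out_dir, output_dt, overrides, tag, t_end=1800.0):
    protocol = StimulusProtocol.constant(0.3, t_end=t_end)
    out = {}
    for name, params in (
        ("control", build_parameters("control")),
        (tag, build_parameters(Condition("custom", overrides))),
    ):
        traj = integrate(params, protocol, output_dt=output_dt or 0.1)
        _write(out_dir, name, traj)
        mc = analysis.oscillation_summary(traj, "C_cyt")
        mm = analysis.oscillation_summary(traj, "C_mito")
        out[name] = {
            "cyt_frequency": mc.mean_frequency,
            "cyt_mean_peak": float(np.mean(mc.spike_peaks)) if mc.n_spikes else None,
            "mito_mean_level": mm.mean_level,
            "mito_mean_peak": float(np.mean(mm.spike_peaks)) if mm.n_spikes else None,
        }
    return out


def _run_fig8(out_dir, output_dt):
    """Control vs full obesity condition, constant P_s = 0.3."""
    return _oscillation_comparison(out_dir, output_dt, OBESITY_OVERRIDES, "obesity")


def _run_fig9(out_dir, output_dt):
    """MAM surface increase alone (R_S1 = R_S2 = 0.3)."""
    return _oscillation_comparison(
        out_dir, output_dt, {"R_S1": 0.3, "R_S2": 0.3}, "more_MAM")


def _run_fig10(out_dir, output_dt):
    """IPR activity increase alone (k_IPR = 0.35, k_nIPR = 0.3)."""
    return _oscillation_comparison(
        out_dir, output_dt, {"k_IPR": 0.35, "k_nIPR": 0.3}, "more_IPR")


def _run_fig11(out_dir, output_dt):
    """MCU activity increase alone (V_MCU = 1.3e-5 µM/s)."""
    return _oscillation_comparison(
        out_dir, output_dt, {"V_MCU": 1.3e-5}, "more_MCU")


def _run_fig12(out_dir, output_dt):
    """Leakier SERCA alone (k_bar = 1.25e-8): rest-state shifts and
    lower-amplitude oscillations."""
    from .model import compute_CER

    out = {"rest_states": {}}
    for name, params in (
        ("control", build_parameters("control")),
        ("high_kbar", build_parameters(Condition("custom", {"k_bar": 1.25e-8}))),
    ):
        rest = find_rest_state(params)
        out["rest_states"][name] = {
            "C_cyt": rest.C_cyt, "C_ER": compute_CER(rest, params)}
    out.update(_oscillation_comparison(out_dir, output_dt, {"k_bar": 1.25e-8},
                                       "high_kbar"))
    return out


def _run_fig13(out_dir, output_dt):
    """Staircase stimulation: the obesity model stops oscillating at a lower
    IP3 target than the control model."""
    stair = fig13_staircase()
    out = {}
    for name in ("control", "obesity"):
        params = build_parameters(name)
        traj = integrate(params, stair, output_dt=output_dt or 0.1)
        _write(out_dir, f"{name}_staircase", traj)
        reports, cessation = analysis.cessation_scan(params, stair, traj=traj)
        out[name] = {"segments": reports, "cessation_Ps": cessation}
    return out
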