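"""Derived quantities: spike detection, oscillation metrics, transient
normalization, finite-difference peak sensitivities, and the
oscillation-cessation staircase scan.

Spike detection is prominence-based; the defaults (prominence 20% of the
window's dynamic range, 2 s minimum separation) are chosen so that the
narrow MAM Ca2+ spikes are resolved while solver-level ripple is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model import ModelState, ParameterSet
from .simulate import Trajectory, find_rest_state, integrate
from .stimulation import StimulusProtocol

__all__ = [
    "OscillationMetrics",
    "SensitivityEntry",
    "detect_spikes",
    "oscillation_summary",
    "normalize_transient",
    "transient_peak",
    "peak_sensitivity",
    "cessation_scan",
    "mam_spikes_per_cytosolic_spike",
]

DEFAULT_PROMINENCE_FRAC = 0.2
DEFAULT_MIN_SEPARATION = 2.0  # s; MAM spikes are narrow but not closer than this

#: Table-of-sensitivities parameter list, in report order.
SENSITIVITY_PARAMS = ("R_S1", "R_S2", "k_IPR", "k_nIPR", "V_MCU", "k_bar")


@dataclass
class OscillationMetrics:
    """Spike-train summary of one variable over an analysis window.

    ``mean_frequency`` is (spike count - 1)/(last - first spike time) when
    at least two spikes are present, else 0 (``oscillating`` False).
    ``mean_level`` is the time average over the window; ``baseline_level``
    averages the local minima between consecutive spikes (the level the
    trace returns to after each spike), an alternative notion of the
    oscillations' "average level".
    """

    spike_times: np.ndarray
    spike_peaks: np.ndarray
    mean_frequency: float
    mean_level: float
    baseline_level: float
    min_after_spike: float
    oscillating: bool

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class SensitivityEntry:
    """Relative sensitivity of the transient peaks to one parameter:
    percent change of peak per percent change of parameter."""

    parameter: str
    d_pct_Ccyt_peak: float
    d_pct_Cmito_peak: float


def detect_spikes(
    t: np.ndarray,
    x: np.ndarray,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
):
    """Spike times and peak values of a uniformly sampled series.

    A spike is a local maximum with prominence at least ``prominence_frac``
    times the series' dynamic range within the window, separated from its
    neighbours by at least ``min_separation`` seconds.  A constant (or
    empty) series yields zero spikes.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 3:
        return np.array([]), np.array([])
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        return np.array([]), np.array([])
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(x, prominence=prominence_frac * rng, distance=distance)
    return t[idx], x[idx]


def _window_slice(t: np.ndarray, window) -> slice:
    a, b = window
    i0 = int(np.searchsorted(t, a, side="left"))
    i1 = int(np.searchsorted(t, b, side="right"))
    if i1 - i0 < 2:
        raise ValueError(f"window {window!r} contains fewer than two samples")
    return slice(i0, i1)


def oscillation_summary(
    traj: Trajectory,
    variable: str,
    window=None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> OscillationMetrics:
    """Spike statistics and average level of ``variable`` over ``window``."""
    if window is None:
        window = (traj.t[0], traj.t[-1])
    sl = _window_slice(traj.t, window)
    t = traj.t[sl]
    x = traj[variable][sl]
    times, peaks = detect_spikes(t, x, prominence_frac, min_separation)
    if times.size >= 2:
        freq = (times.size - 1) / (times[-1] - times[0])
        oscillating = True
    else:
        freq = 0.0
        oscillating = False
    mean_level = float(np.trapezoid(x, t) / (t[-1] - t[0]))
    if times.size >= 2:
        minima = []
        bounds = np.searchsorted(t, times)
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            minima.append(float(np.min(x[i0:i1 + 1])))
        baseline = float(np.mean(minima))
        min_after = float(np.min(x[bounds[0]:]))
    else:
        baseline = float("nan")
        min_after = float("nan")
    return OscillationMetrics(
        spike_times=times,
        spike_peaks=peaks,
        mean_frequency=float(freq),
        mean_level=mean_level,
        baseline_level=baseline,
        min_after_spike=min_after,
        oscillating=oscillating,
    )


def normalize_transient(test: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Min-max normalize ``test`` by the control transient's range.

    Mirrors the FRET-trace normalization used for transient comparisons:
    the control maps onto [0, 1] and the test is scaled by the control's
    min and range, so a test peak of 1.2 is 20% above the control peak.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    lo = float(np.min(control))
    rng = float(np.max(control) - lo)
    if rng == 0.0:
        raise ValueError("control transient is constant; normalization undefined")
    return (test - lo) / rng


def transient_peak(t: np.ndarray, x: np.ndarray, t_after: float) -> float:
    """Height of the first (largest) transient maximum after ``t_after``,
    refined by quadratic interpolation through the three samples around the
    grid argmax."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    sel = t > t_after
    if not np.any(sel):
        raise ValueError(f"no samples after t={t_after!r}")
    off = int(np.argmax(sel))
    i = off + int(np.argmax(x[sel]))
    if i == 0 or i == t.size - 1:
        return float(x[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a proper local max at grid resolution
        return float(y1)
    delta = 0.5 * (y0 - y2) / denom
    return float(y1 - 0.25 * (y0 - y2) * delta)


def peak_sensitivity(
    params: ParameterSet,
    protocol: StimulusProtocol,
    param_names=SENSITIVITY_PARAMS,
    perturbation: float = 0.001,
    t_end: float = None,
    output_dt: float = 0.01,
):
    """One-sided forward-difference sensitivities of the transient peaks.

    Each parameter is increased by ``perturbation`` (default 0.1%), the
    perturbed model is re-equilibrated to its own rest state, the pulse
    protocol is rerun, and the relative change of the first cytosolic and
    mitochondrial Ca2+ peaks after pulse onset is divided by the relative
    parameter change.  The baseline run is shared across parameters.
    """
    if not protocol.pulses:
        raise ValueError("sensitivity protocol must contain an IP3 pulse")
    t0 = min(pl.t0 for pl in protocol.pulses)

    def run(pset: ParameterSet):
        traj = integrate(pset, protocol, t_end=t_end, output_dt=output_dt)
        return (
            transient_peak(traj.t, traj["C_cyt"], t0),
            transient_peak(traj.t, traj["C_mito"], t0),
        )

    base_cyt, base_mito = run(params)
    entries = []
    for name in param_names:
        value = getattr(params, name, None)
        if value is None:
            params.replace(**{name: 0.0})  # raises with the valid-name list
        if value == 0:
            raise ValueError(
                f"cannot apply a relative perturbation to {name} = 0"
            )
        perturbed = params.replace(**{name: value * (1.0 + perturbation)})
        # warm-start the perturbed rest state from the baseline one
        find_rest_state(perturbed, guess=find_rest_state(params))
        cyt, mito = run(perturbed)
        entries.append(SensitivityEntry(
            parameter=name,
            d_pct_Ccyt_peak=((cyt - base_cyt) / base_cyt) / perturbation,
            d_pct_Cmito_peak=((mito - base_mito) / base_mito) / perturbation,
        ))
    return entries


def cessation_scan(
    params: ParameterSet,
    staircase: StimulusProtocol,
    window_margin: float = 100.0,
    min_spikes: int = 3,
    persistence_factor: float = 2.0,
    output_dt: float = 0.1,
    traj: Trajectory = None,
):
    """Classify each staircase segment as sustaining oscillations or not.

    A segment oscillates if, after discarding ``window_margin`` seconds past
    the step, at least ``min_spikes`` cytosolic Ca2+ spikes are detected
    *and* spiking persists to the end of the segment (the last spike lies
    within ``persistence_factor`` median interspike intervals of the
    segment end).  The persistence requirement separates sustained limit
    cycles from the damped transient burst that follows a step into the
    high-IP3, saturated regime.  Returns ``(segment_reports, cessation_Ps)``
    where ``cessation_Ps`` is the lowest nonzero IP3 target at which
    oscillations have ceased (``None`` if they persist throughout).
    """
    if len(staircase.segments) < 2:
        raise ValueError("staircase must have at least two segments")
    if traj is None:
        traj = integrate(params, staircase, output_dt=output_dt)
    reports = []
    for (a, b, ps) in staircase.segments:
        window = (min(a + window_margin, b), b)
        m = oscillation_summary(traj, "C_cyt", window)
        oscillating = m.n_spikes >= min_spikes
        if oscillating:
            isi = float(np.median(np.diff(m.spike_times)))
            oscillating = (b - m.spike_times[-1]) <= persistence_factor * isi
        reports.append({
            "P_s": ps,
            "t_start": a,
            "t_end": b,
            "oscillating": bool(oscillating),
            "n_spikes": m.n_spikes,
            "frequency": m.mean_frequency if oscillating else 0.0,
        })
    cessation = None
    for rep in reports:
        if rep["P_s"] > 0 and not rep["oscillating"]:
            cessation = rep["P_s"]
            break
    return reports, cessation


def mam_spikes_per_cytosolic_spike(
    traj: Trajectory,
    window=None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> float:
    """Median number of MAM Ca2+ spikes per cytosolic interspike interval."""
    if window is None:
        window = (traj.t[0], traj.t[-1])
    sl = _window_slice(traj.t, window)
    t = traj.t[sl]
    cyt_times, _ = detect_spikes(t, traj["C_cyt"][sl], prominence_frac, min_separation)
    mam_times, _ = detect_spikes(t, traj["C_MAM"][sl], prominence_frac, min_separation)
    if cyt_times.size < 2:
        raise ValueError("need at least two cytosolic spikes to form intervals")
    counts = [
        int(np.sum((mam_times > a) & (mam_times <= b)))
        for a, b in zip(cyt_times[:-1], cyt_times[1:])
    ]
    return float(np.median(counts))
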