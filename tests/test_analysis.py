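"""Tests for spike detection, normalization, sensitivities and the scan."""

import numpy as np
import pytest

from mamcal import (
    ParameterSet,
    Pulse,
    StimulusProtocol,
    detect_spikes,
    normalize_transient,
    oscillation_summary,
    peak_sensitivity,
    transient_peak,
)
from mamcal.analysis import cessation_scan
from mamcal.simulate import Trajectory


def synthetic_traj(t, x):
    states = np.zeros((t.size, 11))
    states[:, 0] = x
    return Trajectory(t=t, states=states, params=ParameterSet())


def brute_force_spikes(t, x, prominence_frac=0.2, min_separation=2.0):
    """O(n^2) local-extremum oracle: a point is a spike if it is the strict
    maximum of its neighbourhood and rises at least the prominence threshold
    above the highest valley separating it from larger terrain."""
    rng = x.max() - x.min()
    if rng <= 0:
        return np.array([])
    thresh = prominence_frac * rng
    cand = []
    for i in range(1, len(x) - 1):
        if x[i] >= x[i - 1] and x[i] > x[i + 1]:
            # prominence: drop to the highest saddle on each side
            left = x[:i + 1]
            right = x[i:]
            higher_l = np.where(left > x[i])[0]
            base_l = left[higher_l[-1]:].min() if higher_l.size else left.min()
            higher_r = np.where(right > x[i])[0]
            base_r = right[:higher_r[0] + 1].min() if higher_r.size else right.min()
            if x[i] - max(base_l, base_r) >= thresh:
                cand.append(i)
    # enforce separation, keeping the larger peak
    kept = []
    for i in cand:
        if kept and t[i] - t[kept[-1]] < min_separation:
            if x[i] > x[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return t[np.array(kept, dtype=int)] if kept else np.array([])


class TestDetectSpikes:
    def test_constant_series_has_no_spikes(self):
        t = np.arange(0, 100, 0.1)
        times, peaks = detect_spikes(t, np.full_like(t, 3.0))
        assert times.size == 0 and peaks.size == 0

    def test_recovers_constructed_bump_times(self):
        t = np.arange(0, 40, 0.01)
        x = sum(np.exp(-0.5 * ((t - c) / 0.8) ** 2) for c in (10.0, 20.0, 30.0))
        times, peaks = detect_spikes(t, x)
        np.testing.assert_allclose(times, [10.0, 20.0, 30.0], atol=0.02)

    def test_agrees_with_brute_force_oracle(self):
        """Prominence-based detection matches an O(n^2) local-extremum oracle
        on random synthetic spike trains."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = np.arange(0, 120, 0.05)
            n = rng.integers(2, 8)
            centers = np.sort(rng.uniform(10, 110, n))
            widths = rng.uniform(0.5, 2.0, n)
            amps = rng.uniform(0.5, 5.0, n)
            x = sum(a * np.exp(-0.5 * ((t - c) / w) ** 2)
                    for a, c, w in zip(amps, centers, widths))
            got, _ = detect_spikes(t, x)
            want = brute_force_spikes(t, x)
            np.testing.assert_allclose(got, want, atol=0.05)


class TestOscillationSummary:
    def test_sinusoid_frequency(self):
        t = np.arange(0, 7200, 0.5)
        x = 1.0 + np.sin(2 * np.pi * 0.01 * t)
        m = oscillation_summary(synthetic_traj(t, x), "C_cyt")
        assert m.mean_frequency == pytest.approx(0.01, rel=1e-3)
        assert m.mean_level == pytest.approx(1.0, abs=1e-2)
        assert m.oscillating

    def test_too_few_spikes_reports_zero_frequency(self):
        t = np.arange(0, 100, 0.1)
        x = np.exp(-0.5 * ((t - 50) / 2.0) ** 2)
        m = oscillation_summary(synthetic_traj(t, x), "C_cyt")
        assert m.n_spikes == 1 and m.mean_frequency == 0.0
        assert not m.oscillating

    def test_frequency_stable_under_grid_refinement(self):
        for dt in (0.5, 0.1):
            t = np.arange(0, 3600, dt)
            x = 1.0 + np.sin(2 * np.pi * 0.013 * t)
            m = oscillation_summary(synthetic_traj(t, x), "C_cyt")
            assert m.mean_frequency == pytest.approx(0.013, rel=0.01)


class TestNormalizeTransient:
    def test_control_maps_to_unit_interval(self):
        x = np.array([1.0, 3.0, 2.0])
        n = normalize_transient(x, x)
        assert n.min() == 0.0 and n.max() == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        a, b = 2.5, -1.0
        np.testing.assert_allclose(
            normalize_transient(a * x + b, a * y + b),
            normalize_transient(x, y))

    def test_idempotent_on_normalized_control(self):
        x = np.array([0.2, 0.9, 0.4])
        n = normalize_transient(x, x)
        np.testing.assert_array_equal(normalize_transient(n, n), n)

    def test_constant_control_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_transient(np.ones(5), np.ones(5))


class TestTransientPeak:
    def test_quadratic_refinement_recovers_true_vertex(self):
        t = np.arange(0, 10, 0.1)
        x = -(t - 5.03) ** 2 + 4.0
        assert transient_peak(t, x, 1.0) == pytest.approx(4.0, abs=1e-12)


class TestPeakSensitivity:
    def test_unknown_parameter_is_an_error(self, control_params):
        prot = StimulusProtocol.constant(
            0.0, t_end=150.0, pulses=[Pulse(10.0, 100.0, 0.2)])
        with pytest.raises(ValueError):
            peak_sensitivity(control_params, prot, param_names=["not_a_param"])

    def test_pulse_required(self, control_params):
        with pytest.raises(ValueError, match="pulse"):
            peak_sensitivity(control_params,
                             StimulusProtocol.constant(0.3, t_end=100.0))

    def test_ipr_activity_dominates_cytosolic_peak(self, sensitivity_tables):
        """The cytosolic transient peak is most sensitive to the bulk IPR
        activity level, for both conditions."""
        for cond in ("control", "obesity"):
            table = {e.parameter: e.d_pct_Ccyt_peak
                     for e in sensitivity_tables[cond]}
            assert max(table, key=lambda k: abs(table[k])) == "k_IPR"


class TestCessationScan:
    def test_quiescent_segment_not_oscillating(self, staircase_runs):
        stair, runs = staircase_runs
        reports, _ = cessation_scan(
            ParameterSet(), stair, traj=runs["control"])
        assert reports[0]["P_s"] == 0.0 and not reports[0]["oscillating"]

    def test_single_segment_consistency(self, fig4_run):
        """A one-step staircase reproduces the plain oscillation summary on
        that segment."""
        stair = StimulusProtocol(segments=((0.0, 450.0, 0.3), (450.0, 900.0, 0.3)))
        reports, cess = cessation_scan(ParameterSet(), stair, traj=fig4_run,
                                       min_spikes=2)
        m = oscillation_summary(fig4_run, "C_cyt", (100.0, 450.0))
        assert reports[0]["n_spikes"] == m.n_spikes
        assert cess is None
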