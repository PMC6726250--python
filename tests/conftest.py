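"""Shared fixtures.  The expensive simulations (two-hour condition
comparison, staircase scans, sensitivity tables) are session-scoped so the
acceptance tests and the property tests reuse the same runs."""

import numpy as np
import pytest

from mamcal import (
    ParameterSet,
    Pulse,
    StimulusProtocol,
    fig13_staircase,
    integrate,
    peak_sensitivity,
)
from mamcal.scenarios import build_parameters


@pytest.fixture(scope="session")
def control_params():
    return build_parameters("control")


@pytest.fixture(scope="session")
def obesity_params():
    return build_parameters("obesity")


@pytest.fixture(scope="session")
def linker_params():
    return build_parameters("linker")


@pytest.fixture(scope="session")
def two_hour_runs(control_params, obesity_params):
    """Control and obesity trajectories: 2 h of constant P_s = 0.3 µM."""
    protocol = StimulusProtocol.constant(0.3, t_end=7200.0)
    return {
        "control": integrate(control_params, protocol, output_dt=0.1),
        "obesity": integrate(obesity_params, protocol, output_dt=0.1),
    }


@pytest.fixture(scope="session")
def fig4_run(control_params):
    """Control trajectory, constant P_s = 0.3 µM for 900 s, finely sampled."""
    protocol = StimulusProtocol.constant(0.3, t_end=900.0)
    return integrate(control_params, protocol, output_dt=0.05)


@pytest.fixture(scope="session")
def pulse_fig2_protocol():
    return StimulusProtocol.constant(
        0.0, t_end=200.0, pulses=[Pulse(M=10.0, t0=60.0, delta=0.2)])


@pytest.fixture(scope="session")
def linker_pulse_runs(control_params, linker_params, pulse_fig2_protocol):
    """Control vs synthetic-linker mitochondrial transients (pulse at 60 s)."""
    return {
        "control": integrate(control_params, pulse_fig2_protocol, output_dt=0.01),
        "linker": integrate(linker_params, pulse_fig2_protocol, output_dt=0.01),
    }


@pytest.fixture(scope="session")
def sensitivity_tables(control_params, obesity_params):
    """Transient-peak sensitivity entries for both conditions (0.1% forward
    perturbations, pulse M=10 at t0=100 s)."""
    protocol = StimulusProtocol.constant(
        0.0, t_end=250.0, pulses=[Pulse(M=10.0, t0=100.0, delta=0.2)])
    return {
        "control": peak_sensitivity(control_params, protocol),
        "obesity": peak_sensitivity(obesity_params, protocol),
    }


@pytest.fixture(scope="session")
def staircase_runs(control_params, obesity_params):
    """Control and obesity trajectories under the rising IP3 staircase."""
    stair = fig13_staircase()
    return stair, {
        "control": integrate(control_params, stair, output_dt=0.1),
        "obesity": integrate(obesity_params, stair, output_dt=0.1),
    }
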