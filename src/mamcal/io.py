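"""Run configuration (schema-validated) and trajectory CSV readers/writers.

Trajectories are written as RFC-4180 CSV with a single comment-prefixed
preamble line stating the units (times in s, concentrations in µM, voltage
in mV) and full double precision, so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import STATE_VARS, ParameterSet
from .scenarios import Condition, build_parameters
from .simulate import DEFAULT_RTOL, Trajectory, integrate
from .stimulation import StimulusProtocol

__all__ = [
    "RunConfig",
    "load_config",
    "run_config",
    "write_trajectory",
    "read_trajectory",
]

_PREAMBLE = (
    "# units: t [s]; Ca2+, IP3, adenine/pyridine nucleotide concentrations "
    "[uM]; V_m [mV]"
)
_DERIVED_COLS = ("C_ER", "ATP_c", "ATP_m", "NAD")


class ConditionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "control"
    overrides: dict = Field(default_factory=dict)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    segments: list  # [t_start, t_end, P_s] triples
    pulses: list = Field(default_factory=list)  # [M, t0, delta] triples


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = DEFAULT_RTOL
    atol: Optional[list] = None
    t_end: Optional[float] = None
    output_dt: float = 0.1
    method: str = "LSODA"


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prominence_frac: float = 0.2
    min_separation: float = 2.0
    window: Optional[list] = None  # [t_a, t_b]


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "."
    trajectory_csv: str = "trajectory.csv"
    metrics_json: Optional[str] = "metrics.json"


class RunConfig(BaseModel):
    """A complete, schema-validated simulation run description."""

    model_config = ConfigDict(extra="forbid")
    condition: ConditionConfig = Field(default_factory=ConditionConfig)
    protocol: ProtocolConfig
    solver: SolverConfig = Field(default_factory=SolverConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data)


def run_config(cfg: RunConfig, write: bool = True) -> tuple:
    """Execute a validated run config; returns ``(trajectory, metrics)``."""
    from . import analysis as _analysis

    params = build_parameters(
        Condition(cfg.condition.name, dict(cfg.condition.overrides))
    )
    protocol = StimulusProtocol.from_dict(
        {"segments": cfg.protocol.segments, "pulses": cfg.protocol.pulses}
    )
    traj = integrate(
        params,
        protocol,
        t_end=cfg.solver.t_end,
        output_dt=cfg.solver.output_dt,
        rtol=cfg.solver.rtol,
        atol=np.asarray(cfg.solver.atol) if cfg.solver.atol else None,
        method=cfg.solver.method,
    )
    window = tuple(cfg.analysis.window) if cfg.analysis.window else None
    metrics = {}
    for var in ("C_cyt", "C_MAM", "C_mito"):
        m = _analysis.oscillation_summary(
            traj, var, window,
            prominence_frac=cfg.analysis.prominence_frac,
            min_separation=cfg.analysis.min_separation,
        )
        metrics[var] = {
            "n_spikes": m.n_spikes,
            "mean_frequency": m.mean_frequency,
            "mean_level": m.mean_level,
            "baseline_level": m.baseline_level,
        }
    if write:
        out = Path(cfg.output.directory)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectory(traj, out / cfg.output.trajectory_csv)
        if cfg.output.metrics_json:
            with open(out / cfg.output.metrics_json, "w") as fh:
                json.dump(metrics, fh, indent=2, default=float)
    return traj, metrics


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write ``t``, the 11 state variables and the derived observables as
    RFC-4180 CSV with a unit preamble, at full double precision."""
    df = traj.to_dataframe(derived=traj.params is not None)
    with open(path, "w", newline="") as fh:
        fh.write(_PREAMBLE + "\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_trajectory(path, params: ParameterSet = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    Raises ``ValueError`` naming any missing required column.
    """
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV: surface the parser's message
        raise ValueError(f"could not parse trajectory file {path}: {exc}") from exc
    missing = [c for c in ("t", *STATE_VARS) if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing column(s): {missing}")
    return Trajectory(
        t=df["t"].to_numpy(),
        states=df[list(STATE_VARS)].to_numpy(),
        params=params,
    )
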