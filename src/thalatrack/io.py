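"""Configuration, CSV/JSON round-tripping and canned fixtures.

CSV is the canonical exchange format for time series (full ``%.17g``
precision, lossless for doubles); JSON holds run configurations and reports.
Configuration keys carry their units in the name (``dt_ms``,
``i_sm_pA_per_um2``) and unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import model as tc
from .noise import NoiseSpec
from .ukf import EstimateTrace

__all__ = [
    "RunConfig", "load_config", "save_trajectory", "load_trajectory",
    "save_trace", "load_trace", "make_fixture", "config_hash",
]

TRAJECTORY_COLUMNS = ["time_ms", "V_mV", "h", "w", "I_applied"]
TRACE_COLUMNS = ["time_ms", "Iext_hat", "V_hat", "h_hat", "w_hat", "innovation"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StimulusConfig(_Strict):
    kind: str = "square_wave"
    rho_sm_ms: float = 25.0
    delta_sm_ms: float = 5.0
    i_sm_pA_per_um2: float = 5.0
    rate_hz: float = 30.0
    cv: float = 0.2
    level_pA_per_um2: float = 0.0
    seed: int = 0

    def to_spec(self) -> tc.StimulusSpec:
        return tc.StimulusSpec(kind=self.kind, rho_sm=self.rho_sm_ms,
                               delta_sm=self.delta_sm_ms, i_sm=self.i_sm_pA_per_um2,
                               rate=self.rate_hz, cv=self.cv,
                               level=self.level_pA_per_um2, seed=self.seed)


class GpiConfig(_Strict):
    mode: str = "normal"
    level_pA_per_um2: float = 0.0
    parkinsonian_level_pA_per_um2: float = -0.6
    period_ms: Optional[float] = None
    duty: float = 0.5

    def to_spec(self) -> tc.GpiInputSpec:
        return tc.GpiInputSpec(mode=self.mode, level=self.level_pA_per_um2,
                               parkinsonian_level=self.parkinsonian_level_pA_per_um2,
                               period_ms=self.period_ms, duty=self.duty)


class NoiseConfig(_Strict):
    kind: str = "gaussian"
    strength_mV: float = 1.0
    seed: int = 0
    phase_rad: float = 0.0

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(kind=self.kind, strength=self.strength_mV,
                         seed=self.seed, phase=self.phase_rad)


class UkfConfigSection(_Strict):
    q: float = 5e-5
    r: float = 5.0
    burn_in_ms: float = 100.0
    internal_model: str = "cetc"
    known_stimulus: bool = True


class RunConfig(_Strict):
    """Validated experiment configuration (unknown keys rejected)."""

    duration_ms: float = 2000.0
    dt_ms: float = 0.01
    obs_dt_ms: float = 0.05
    seed: int = 0
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    gpi: GpiConfig = Field(default_factory=GpiConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    ukf: UkfConfigSection = Field(default_factory=UkfConfigSection)
    experiment: str = "run"
    output_dir: Optional[str] = None


def load_config(path) -> RunConfig:
    """Read and validate a JSON run configuration."""
    text = pathlib.Path(path).read_text()
    return RunConfig.model_validate_json(text)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# time-series round-trips
# ---------------------------------------------------------------------------


def save_trajectory(traj: tc.Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_trajectory(path) -> tc.Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed trajectory CSV {path}: missing column(s) {missing}")
    times = df["time_ms"].to_numpy()
    if len(times) > 1:
        steps = np.diff(times)
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise ValueError(f"trajectory CSV {path}: time_ms not uniformly spaced")
        dt = float(steps[0])
    else:
        dt = 1.0
    return tc.Trajectory(times=times, v=df["V_mV"].to_numpy(), h=df["h"].to_numpy(),
                         w=df["w"].to_numpy(),
                         applied_current=df["I_applied"].to_numpy(), dt=dt)


def save_trace(trace: EstimateTrace, path_csv, path_json=None,
               summary: Optional[dict] = None) -> None:
    """Estimate trace as CSV plus an optional JSON sidecar of config/summary."""
    df = pd.DataFrame(trace.means, columns=TRACE_COLUMNS[1:5])
    df.insert(0, "time_ms", trace.times)
    df["innovation"] = trace.innovations if trace.innovations is not None else np.nan
    df.to_csv(path_csv, index=False, float_format="%.17g")
    if path_json is not None:
        payload = {"cf_rmse": {k: float(v) for k, v in (trace.cf_rmse or {}).items()}}
        if trace.config is not None:
            payload["q"] = np.asarray(trace.config.q).tolist()
            payload["r"] = np.asarray(trace.config.r).tolist()
            payload["dt_ms"] = trace.config.dt
            payload["burn_in_ms"] = trace.config.burn_in_ms
        payload.update(summary or {})
        pathlib.Path(path_json).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_trace(path_csv) -> pd.DataFrame:
    df = pd.read_csv(path_csv, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"malformed trace CSV {path_csv}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixture(name: str, seed: int = 0):
    """Small canned inputs for tests and examples; deterministic per seed.

    Available: ``short_normal`` / ``short_parkinsonian`` (200 ms trajectories),
    ``noisy_observation`` (trajectory + contaminated voltage),
    ``spd_matrix`` (a random symmetric positive-definite 4x4),
    ``toy_plf`` (a 3-segment piecewise-linear function).
    """
    rng = np.random.default_rng(seed)
    if name in ("short_normal", "short_parkinsonian"):
        mode = name.split("_", 1)[1]
        params = tc.default_parameters()
        return tc.simulate(params, tc.GpiInputSpec(mode=mode),
                           tc.StimulusSpec(kind="square_wave"), 200.0, dt=0.01)
    if name == "noisy_observation":
        traj = make_fixture("short_normal", seed)
        from .noise import contaminate
        obs = contaminate(traj, NoiseSpec(kind="gaussian", strength=1.0, seed=seed))
        return traj, obs
    if name == "spd_matrix":
        a = rng.standard_normal((4, 4))
        return a @ a.T + 0.5 * np.eye(4)
    if name == "toy_plf":
        from .linearize import PiecewiseLinearFunction
        edges = np.array([-10.0, -2.0, 3.0, 10.0])
        slopes = rng.choice([-0.5, 0.25, 1.0], size=3)
        return PiecewiseLinearFunction.from_slopes(edges, slopes, float(rng.uniform(-1, 1)))
    raise ValueError(f"unknown fixture: {name!r}")
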