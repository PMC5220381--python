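"""Observation-noise processes for the robustness study.

Five kinds contaminate the measured membrane potential: Gaussian white noise,
mains interference at 50 Hz ("industrial"), its odd harmonic at 150 Hz, a
high-frequency 350 Hz component, and the mixture of all four.  "Strength" is a
single scale for all kinds: the sinusoid amplitude, or the Gaussian standard
deviation, in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trajectory

__all__ = ["NoiseSpec", "generate", "contaminate", "NOISE_KINDS"]

NOISE_KINDS = ("gaussian", "industrial_50", "odd_harmonic_150", "high_freq_350", "mixed")

_FREQ_HZ = {"industrial_50": 50.0, "odd_harmonic_150": 150.0, "high_freq_350": 350.0}


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "gaussian"
    strength: float = 1.0  # mV (amplitude for sinusoids, sd for gaussian)
    seed: int = 0
    phase: float = 0.0  # radians, applied to every sinusoidal component

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if self.strength < 0:
            raise ValueError("noise strength must be non-negative")


def generate(spec: NoiseSpec, times: np.ndarray) -> np.ndarray:
    """Noise series (mV) on the sample instants ``times`` (ms).

    Deterministic for a fixed seed (numpy PCG64 generator).  The mixed kind is
    the elementwise sum of the four single kinds, each at ``spec.strength``
    and the Gaussian part drawn with the same seed.
    """
    times = np.asarray(times, dtype=float)
    if spec.kind == "mixed":
        total = np.zeros(times.shape)
        for kind in NOISE_KINDS[:-1]:
            total += generate(NoiseSpec(kind=kind, strength=spec.strength,
                                        seed=spec.seed, phase=spec.phase), times)
        return total
    if spec.kind == "gaussian":
        rng = np.random.default_rng(spec.seed)
        return spec.strength * rng.standard_normal(times.shape)
    f = _FREQ_HZ[spec.kind]
    return spec.strength * np.sin(2.0 * np.pi * f * times / 1000.0 + spec.phase)


def contaminate(traj: Trajectory, spec: NoiseSpec) -> np.ndarray:
    """Observed voltage: the trajectory's V plus generated noise.

    The trajectory itself is untouched, so the clean truth stays available for
    scoring.
    """
    return traj.v + generate(spec, traj.times)
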