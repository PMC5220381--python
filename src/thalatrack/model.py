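"""Reduced three-variable thalamocortical (TC) relay neuron.

The cell is a conductance-based model with membrane potential ``V`` and two
gating variables: ``h``, the sodium inactivation gate, and ``w``, the
de-inactivation gate of the low-threshold T-type calcium current.  Fast sodium
activation is slaved to its steady state ``m_inf(V)`` and potassium activation
is tied to ``1 - h``, which reduces the classical five-dimensional relay cell
to the three-dimensional system

    C_m dV/dt = -I_L - I_Na - I_K - I_T + I_Gi->Th + I_SM
    dh/dt     = a_h(V) (1 - h) - b_h(V) h
    dw/dt     = (w_inf(V) - w) / tau_w(V)

The default closed forms and constants follow the Rubin-Terman (2004) TC relay
cell.  The difference between the *normal* and the *Parkinsonian* regime is the
inhibitory pallidal current ``I_Gi->Th``: sustained hyperpolarization
de-inactivates the T-current (raises ``w``) so that sensorimotor pulses evoke
rebound bursts instead of faithfully relayed single spikes.

All gating maps are plain vectorized callables collected in a
:class:`GatingFunctionSet`, so a piecewise-linear (CETC) variant built by
:mod:`thalatrack.linearize` is a drop-in replacement.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GatingFunctionSet",
    "TCParameters",
    "NeuronState",
    "StimulusSpec",
    "GpiInputSpec",
    "Trajectory",
    "DivergenceError",
    "rubin_terman_gating",
    "default_parameters",
    "ionic_currents",
    "derivatives",
    "euler_step",
    "sm_square_wave",
    "sm_gamma_pulse_train",
    "stimulus_series",
    "gpi_series",
    "rest_state",
    "simulate",
    "steady_state_currents",
    "detect_spikes",
]


class DivergenceError(RuntimeError):
    """Raised when forward integration produces a non-finite state."""


# ---------------------------------------------------------------------------
# gating functions and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingFunctionSet:
    """The eight voltage-dependent maps of the reduced relay cell.

    ``f1``, ``f2`` and ``f3`` are the composite channel nonlinearities that
    enter the ionic currents (sodium activation power, calcium activation
    power, and the potassium term built from ``1 - h``); ``h_inf`` .. ``tau_w``
    are the primitive steady states and rates.  ``inv_tau_w`` is kept as its
    own map because the hardware-friendly variant linearizes ``1/tau_w``
    directly.  All callables must accept numpy arrays.
    """

    m_inf: Callable
    h_inf: Callable
    p_inf: Callable
    w_inf: Callable
    a_h: Callable
    b_h: Callable
    tau_w: Callable
    f1: Callable  # I_Na voltage nonlinearity, default m_inf**3
    f2: Callable  # I_T voltage nonlinearity, default p_inf**2
    f3: Callable  # I_K gate nonlinearity, a function of h, default (0.75(1-h))**4
    inv_tau_w: Callable
    name: str = "original"


def rubin_terman_gating(
    *,
    na_power: int = 3,
    ca_power: int = 2,
    c_k: float = 0.75,
    tau_w_scale: float = 1.0,
    conductance_jitter: Optional[dict] = None,
    half_voltage_shift: Optional[dict] = None,
) -> GatingFunctionSet:
    """Rubin-Terman (2004) TC relay gating functions.

    Parameters
    ----------
    na_power, ca_power
        Exponents of the sodium and calcium activation terms (``f1``, ``f2``).
    c_k
        Coefficient of the potassium gate term ``(c_k (1 - h))**4``.
    tau_w_scale
        Multiplicative scale on the T-current de-inactivation time constant
        (1.0 keeps the published form).
    half_voltage_shift
        Optional mapping gate-name -> multiplicative factor applied to that
        gate's half-activation voltage (used for double-blind perturbation).
    """
    hv = {"m": -37.0, "h": -41.0, "p": -60.0, "w": -84.0, "ah": -46.0, "bh": -23.0, "tw": -25.0}
    if half_voltage_shift:
        for k, fac in half_voltage_shift.items():
            hv[k] = hv[k] * fac

    def m_inf(v):
        return 1.0 / (1.0 + np.exp(-(v - hv["m"]) / 7.0))

    def h_inf(v):
        return 1.0 / (1.0 + np.exp((v - hv["h"]) / 4.0))

    def p_inf(v):
        return 1.0 / (1.0 + np.exp(-(v - hv["p"]) / 6.2))

    def w_inf(v):
        return 1.0 / (1.0 + np.exp((v - hv["w"]) / 4.0))

    def a_h(v):
        return 0.128 * np.exp(-(v - hv["ah"]) / 18.0)

    def b_h(v):
        return 4.0 / (1.0 + np.exp(-(v - hv["bh"]) / 5.0))

    def tau_w(v):
        return tau_w_scale * (28.0 + np.exp(-(v - hv["tw"]) / 10.5))

    def inv_tau_w(v):
        return 1.0 / tau_w(v)

    def f1(v):
        return m_inf(v) ** na_power

    def f2(v):
        return p_inf(v) ** ca_power

    def f3(h):
        return (c_k * (1.0 - h)) ** 4

    return GatingFunctionSet(
        m_inf=m_inf, h_inf=h_inf, p_inf=p_inf, w_inf=w_inf,
        a_h=a_h, b_h=b_h, tau_w=tau_w, f1=f1, f2=f2, f3=f3,
        inv_tau_w=inv_tau_w, name="original",
    )


@dataclass(frozen=True)
class TCParameters:
    """Passive and channel constants of the relay cell.

    Units: capacitance density pF/um^2, conductance densities nS/um^2,
    potentials mV, currents pA/um^2, time ms.
    """

    c_m: float = 1.0
    g_l: float = 0.05
    e_l: float = -70.0
    g_na: float = 3.0
    e_na: float = 50.0
    g_k: float = 5.0
    e_k: float = -90.0
    g_t: float = 5.0
    e_t: float = 0.0
    gating: GatingFunctionSet = field(default_factory=rubin_terman_gating)

    def __post_init__(self):
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be positive")
        for name in ("g_l", "g_na", "g_k", "g_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if not self.e_na > self.e_k:
            raise ValueError("physiological ordering requires E_Na > E_K")

    def with_gating(self, gating: GatingFunctionSet) -> "TCParameters":
        return dataclasses.replace(self, gating=gating)


def default_parameters(**kwargs) -> TCParameters:
    """Rubin-Terman TC relay constants with optional overrides."""
    return TCParameters(**kwargs)


@dataclass
class NeuronState:
    """Instantaneous state (V, h, w); h and w live in [0, 1]."""

    v: float
    h: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.h, self.w], dtype=float)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """Sensorimotor input specification.

    ``square_wave``: periodic pulses of amplitude ``i_sm`` lasting ``delta_sm``
    ms at the start of each ``rho_sm`` ms period (the Heaviside comb of the
    relay-fidelity protocol).  ``gamma_pulse_train``: monophasic pulses whose
    inter-pulse intervals are gamma distributed with mean ``1000/rate`` ms and
    coefficient of variation ``cv`` — the irregular cortical drive used in the
    double-blind protocol.
    """

    kind: str = "square_wave"  # square_wave | gamma_pulse_train | constant | none
    rho_sm: float = 25.0
    delta_sm: float = 5.0
    i_sm: float = 5.0
    rate: float = 30.0
    cv: float = 0.2
    level: float = 0.0  # for kind == constant
    seed: int = 0

    def __post_init__(self):
        if self.kind == "square_wave" and not (0 < self.delta_sm < self.rho_sm):
            raise ValueError("square wave requires 0 < delta_sm < rho_sm")
        if self.kind == "gamma_pulse_train" and not (self.rate > 0 and self.cv > 0):
            raise ValueError("gamma pulse train requires rate > 0 and cv > 0")


def sm_square_wave(t, spec: StimulusSpec):
    """Square-wave sensorimotor current at time(s) ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    out = np.where(np.mod(t, spec.rho_sm) < spec.delta_sm, spec.i_sm, 0.0)
    return out if out.ndim else float(out)


def sm_gamma_pulse_train(spec: StimulusSpec, duration: float, dt: float) -> np.ndarray:
    """Sampled gamma-interval pulse train on ``t = 0, dt, ..., duration``.

    Pulse onsets are separated by gamma-distributed intervals with mean
    ``1000/rate`` ms and coefficient of variation ``cv``; each pulse holds
    ``i_sm`` for ``delta_sm`` ms.  Overlapping pulses merge (the amplitude does
    not stack) with a warning when the pulse duration reaches the mean
    interval.  Reproducible for a fixed ``spec.seed``.
    """
    mean_iv = 1000.0 / spec.rate
    if spec.delta_sm >= mean_iv:
        warnings.warn("pulse duration >= mean inter-pulse interval; overlapping pulses merge")
    shape = 1.0 / spec.cv**2
    scale = mean_iv * spec.cv**2
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    out = np.zeros(n)
    # draw enough intervals to cover the duration, topping up if needed
    t_on = []
    acc = 0.0
    while acc <= duration:
        acc += rng.gamma(shape, scale)
        if acc <= duration:
            t_on.append(acc)
    for on in t_on:
        i0 = int(np.ceil((on - 1e-12) / dt))
        i1 = min(int(np.floor((on + spec.delta_sm) / dt)) + 1, n)
        out[i0:i1] = spec.i_sm
    return out


def stimulus_series(spec: StimulusSpec, times: np.ndarray) -> np.ndarray:
    """Sampled sensorimotor current on a uniform time grid (ms)."""
    times = np.asarray(times, dtype=float)
    if spec.kind == "square_wave":
        return np.asarray(sm_square_wave(times, spec))
    if spec.kind == "gamma_pulse_train":
        dt = times[1] - times[0] if len(times) > 1 else 1.0
        return sm_gamma_pulse_train(spec, float(times[-1] - times[0]), float(dt))
    if spec.kind == "constant":
        return np.full(times.shape, spec.level)
    if spec.kind == "none":
        return np.zeros(times.shape)
    raise ValueError(f"unknown stimulus kind: {spec.kind!r}")


@dataclass(frozen=True)
class GpiInputSpec:
    """Pallidal (GPi -> TC) inhibitory current.

    ``normal`` is zero; ``parkinsonian`` is a sustained hyperpolarizing level
    (default -0.6 pA/um^2, calibrated once so that square-wave relay turns into
    rebound-burst events); ``custom`` takes ``level`` directly.  A phasic
    square-wave option is available through ``period_ms``/``duty`` because
    pathological pallidal output is rhythmic in vivo.
    """

    mode: str = "normal"  # normal | parkinsonian | custom
    level: float = 0.0
    parkinsonian_level: float = -0.6
    period_ms: Optional[float] = None
    duty: float = 0.5

    def baseline(self) -> float:
        if self.mode == "normal":
            return 0.0
        if self.mode == "parkinsonian":
            return self.parkinsonian_level
        return self.level

    def __post_init__(self):
        if self.mode not in ("normal", "parkinsonian", "custom"):
            raise ValueError(f"unknown GPi mode: {self.mode!r}")


def gpi_series(spec: GpiInputSpec, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    level = spec.baseline()
    if spec.period_ms is None:
        return np.full(times.shape, level)
    on = np.mod(times, spec.period_ms) < spec.duty * spec.period_ms
    return np.where(on, level, 0.0)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def ionic_currents(state: NeuronState, params: TCParameters):
    """Return (I_L, I_Na, I_K, I_T) in pA/um^2 for one state."""
    v, h, w = state.v, state.h, state.w
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(h)) and np.all(np.isfinite(w))):
        raise DivergenceError("non-finite state passed to ionic_currents")
    g = params.gating
    i_l = params.g_l * (v - params.e_l)
    i_na = params.g_na * g.f1(v) * h * (v - params.e_na)
    i_k = params.g_k * g.f3(h) * (v - params.e_k)
    i_t = params.g_t * g.f2(v) * w * (v - params.e_t)
    return i_l, i_na, i_k, i_t


def derivatives(state: NeuronState, i_gpi: float, i_sm: float, params: TCParameters):
    """Time derivatives (dV/dt, dh/dt, dw/dt)."""
    i_l, i_na, i_k, i_t = ionic_currents(state, params)
    g = params.gating
    v = state.v
    dv = (-i_l - i_na - i_k - i_t + i_gpi + i_sm) / params.c_m
    dh = g.a_h(v) * (1.0 - state.h) - g.b_h(v) * state.h
    dw = (g.w_inf(v) - state.w) * g.inv_tau_w(v)
    return dv, dh, dw


def euler_step(state: NeuronState, i_gpi: float, i_sm: float, dt: float,
               params: TCParameters) -> NeuronState:
    """One forward-Euler step; gates clamped to [0, 1] afterwards."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dv, dh, dw = derivatives(state, i_gpi, i_sm, params)
    v = state.v + dt * dv
    h = np.clip(state.h + dt * dh, 0.0, 1.0)
    w = np.clip(state.w + dt * dw, 0.0, 1.0)
    if not np.all(np.isfinite(v)):
        raise DivergenceError("integration diverged in variable V")
    return NeuronState(v=v if np.ndim(v) else float(v),
                       h=h if np.ndim(h) else float(h),
                       w=w if np.ndim(w) else float(w))


def rest_state(params: TCParameters, i_const: float = 0.0,
               method: str = "root") -> NeuronState:
    """Resting state under a constant external current.

    By default the membrane equation is solved for the most hyperpolarized
    stable zero of the steady-state current (gates at their steady-state
    values), which the relay cell possesses for physiological inputs.  With
    ``method='relax'`` the model is instead integrated for 5 s.
    """
    g = params.gating

    def h_eq(v):
        # the h-dynamics equilibrium a/(a+b); close to, but not identical
        # with, the steady-state sigmoid h_inf
        a, b = float(g.a_h(v)), float(g.b_h(v))
        return a / (a + b)

    def net(v):
        st = NeuronState(v=v, h=h_eq(v), w=float(g.w_inf(v)))
        i_l, i_na, i_k, i_t = ionic_currents(st, params)
        return -i_l - i_na - i_k - i_t + i_const

    if method == "relax":
        st = NeuronState(v=-65.0, h=0.9, w=0.05)
        for _ in range(int(5000.0 / 0.05)):
            st = euler_step(st, i_const, 0.0, 0.05, params)
        return st

    grid = np.linspace(-110.0, -30.0, 1601)
    vals = np.array([net(v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(net, grid[i], grid[i + 1]))
    stable = [r for r in roots if net(r - 0.05) > 0 > net(r + 0.05)]
    if not stable:
        return rest_state(params, i_const, method="relax")
    v0 = min(stable)
    return NeuronState(v=float(v0), h=h_eq(v0), w=float(g.w_inf(v0)))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Uniformly sampled simulation output."""

    times: np.ndarray
    v: np.ndarray
    h: np.ndarray
    w: np.ndarray
    applied_current: np.ndarray
    dt: float

    def __post_init__(self):
        n = len(self.times)
        for name in ("v", "h", "w", "applied_current"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in trajectory field {name}")

    def __len__(self):
        return len(self.times)

    def state_at(self, i: int) -> NeuronState:
        return NeuronState(v=float(self.v[i]), h=float(self.h[i]), w=float(self.w[i]))

    def decimate(self, step: int) -> "Trajectory":
        return Trajectory(times=self.times[::step], v=self.v[::step],
                          h=self.h[::step], w=self.w[::step],
                          applied_current=self.applied_current[::step],
                          dt=self.dt * step)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.times, "V_mV": self.v, "h": self.h, "w": self.w,
            "I_applied": self.applied_current,
        })


def simulate(params: TCParameters, gpi: GpiInputSpec, sm: StimulusSpec,
             duration: float, dt: float = 0.01,
             initial: Optional[NeuronState] = None) -> Trajectory:
    """Integrate the relay cell with forward Euler.

    The initial state defaults to the resting state under the GPi baseline
    current with no sensorimotor input.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    i_sm = stimulus_series(sm, times)
    i_gpi = gpi_series(gpi, times)
    if initial is None:
        initial = rest_state(params, i_const=float(i_gpi[0]))

    g = params.gating
    c_m, g_l, e_l = params.c_m, params.g_l, params.e_l
    g_na, e_na, g_k, e_k, g_t, e_t = (params.g_na, params.e_na, params.g_k,
                                      params.e_k, params.g_t, params.e_t)
    v, h, w = float(initial.v), float(initial.h), float(initial.w)
    vs = np.empty(n + 1); hs = np.empty(n + 1); ws = np.empty(n + 1)
    vs[0], hs[0], ws[0] = v, h, w
    for k in range(n):
        i_ext = i_gpi[k] + i_sm[k]
        dv = (-(g_l * (v - e_l)) - g_na * g.f1(v) * h * (v - e_na)
              - g_k * g.f3(h) * (v - e_k) - g_t * g.f2(v) * w * (v - e_t)
              + i_ext) / c_m
        dh = g.a_h(v) * (1.0 - h) - g.b_h(v) * h
        dw = (g.w_inf(v) - w) * g.inv_tau_w(v)
        v = v + dt * dv
        h = min(1.0, max(0.0, h + dt * dh))
        w = min(1.0, max(0.0, w + dt * dw))
        if not np.isfinite(v):
            raise DivergenceError(f"integration diverged in variable V at t={times[k + 1]:.3f} ms")
        vs[k + 1], hs[k + 1], ws[k + 1] = v, h, w
    return Trajectory(times=times, v=vs, h=hs, w=ws,
                      applied_current=i_gpi + i_sm, dt=dt)


def steady_state_currents(v_grid, params: TCParameters):
    """Ionic currents with the slow gates at their steady-state values.

    Returns a dict of arrays keyed ``I_L, I_Na, I_K, I_T`` over ``v_grid``.
    """
    v = np.asarray(v_grid, dtype=float)
    g = params.gating
    st = NeuronState(v=v, h=g.h_inf(v), w=g.w_inf(v))
    i_l, i_na, i_k, i_t = ionic_currents(st, params)
    return {"V": v, "I_L": i_l, "I_Na": i_na, "I_K": i_k, "I_T": i_t}


def detect_spikes(traj_or_v, dt: Optional[float] = None, threshold: float = -20.0,
                  merge_window: float = 2.0) -> np.ndarray:
    """Spike times from upward threshold crossings.

    Crossings closer together than ``merge_window`` ms count as one spike.
    """
    if isinstance(traj_or_v, Trajectory):
        v = traj_or_v.v
        dt = traj_or_v.dt
    else:
        v = np.asarray(traj_or_v, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a raw voltage array")
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = idx * dt
    out = []
    for t in times:
        if not out or t - out[-1] >= merge_window:
            out.append(t)
    return np.array(out)
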