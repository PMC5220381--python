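"""Joint state-and-parameter unscented Kalman filtering of the relay cell.

The filter state is the augmented vector ``x = [I_ext, V, h, w]``: one unknown
external-current parameter followed by the three dynamical variables, ordered
so the observation row ``C = [0 1 0 0]`` selects the membrane potential.  The
parameter evolves as a random walk; the dynamical variables advance by one
forward-Euler step of the neuron model driven by each sigma point's own
``I_ext`` (plus an optional known control input, e.g. an experimenter-applied
stimulus).

Sigma points are the symmetric 2N set ``x_bar +/- columns of sqrt(N * P)``
with equal weights ``1/(2N)`` and no central point — eight points for N = 4,
matching a fully parallel hardware realization.  For linear dynamics this set
reproduces the exact Kalman filter.

Everything is vectorized over an optional leading batch axis so that an
ensemble of independent filters (e.g. 20 noise realizations x a grid of Q/R
settings) runs in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np

from .model import TCParameters, DivergenceError

__all__ = [
    "N_STATE",
    "OBSERVED_INDEX",
    "UKFConfig",
    "SigmaPointSet",
    "EstimateTrace",
    "FilterDivergenceError",
    "cholesky_factor",
    "generate_sigma_points",
    "neuron_transition",
    "propagate",
    "predict",
    "update",
    "estimate",
    "cf_rmse",
]

#: augmented state dimension: p = 1 parameter (I_ext) + n = 3 variables (V, h, w)
N_STATE = 4
#: index of the observed component (V) — the C = [0 1 0 0] convention
OBSERVED_INDEX = 1

STATE_NAMES = ("i_ext", "v", "h", "w")


class FilterDivergenceError(RuntimeError):
    """Covariance lost positive definiteness beyond repair."""


# ---------------------------------------------------------------------------
# numerical building blocks
# ---------------------------------------------------------------------------


def cholesky_factor(p: np.ndarray, jitter: float = 1e-10,
                    max_jitter: float = 1e-4) -> np.ndarray:
    """Lower-triangular factor of a (batch of) SPD matrix(es).

    On failure an escalating diagonal jitter (x10 per retry up to
    ``max_jitter``) is added before declaring divergence.
    """
    p = np.asarray(p, dtype=float)
    p = 0.5 * (p + np.swapaxes(p, -1, -2))
    try:
        return np.linalg.cholesky(p)
    except np.linalg.LinAlgError:
        pass
    eye = np.eye(p.shape[-1])
    eps = jitter
    while eps <= max_jitter:
        try:
            return np.linalg.cholesky(p + eps * eye)
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise FilterDivergenceError(
        f"covariance not factorizable after jitter escalation to {max_jitter:g}")


@dataclass
class SigmaPointSet:
    """2N symmetric sigma points with equal weights."""

    points: np.ndarray  # (..., 2N, N)
    weights: np.ndarray  # (2N,)

    @property
    def n(self) -> int:
        return self.points.shape[-1]

    def mean(self) -> np.ndarray:
        return np.einsum("i,...ij->...j", self.weights, self.points)

    def scatter(self) -> np.ndarray:
        d = self.points - self.mean()[..., None, :]
        return np.einsum("i,...ij,...ik->...jk", self.weights, d, d)


def generate_sigma_points(mean: np.ndarray, cov: np.ndarray) -> SigmaPointSet:
    """Symmetric sigma set ``mean +/- columns of sqrt(N) L`` with L L^T = cov.

    The weighted mean and scatter of the returned set reproduce ``mean`` and
    ``cov`` exactly (to round-off).
    """
    mean = np.asarray(mean, dtype=float)
    n = mean.shape[-1]
    ell = cholesky_factor(cov)
    offsets = np.sqrt(n) * np.swapaxes(ell, -1, -2)  # rows are scaled columns of L
    points = np.concatenate([mean[..., None, :] + offsets,
                             mean[..., None, :] - offsets], axis=-2)
    weights = np.full(2 * n, 1.0 / (2 * n))
    return SigmaPointSet(points=points, weights=weights)


# ---------------------------------------------------------------------------
# process models
# ---------------------------------------------------------------------------


def neuron_transition(params: TCParameters, dt: float,
                      control: Optional[np.ndarray] = None,
                      clamp_gates: bool = False) -> Callable:
    """Transition map for the augmented neuron state.

    Returns ``f(x, k)`` advancing ``[I_ext, V, h, w]`` by one Euler step of
    ``dt`` ms with applied current ``I_ext + control[k]``; ``I_ext`` itself is
    the random-walk parameter and passes through unchanged.  ``control`` is a
    known per-step input current (None means fully blind estimation).

    ``clamp_gates`` clips sigma-point gates to [0, 1] before and after the
    step.  Off by default: the gating equations are stable slightly outside
    the unit interval, while clipping before the moment computation biases the
    posterior whenever the true gate sits near a boundary (h ~ 1 at rest).
    """
    g = params.gating
    c_m = params.c_m

    def f(x: np.ndarray, k: int) -> np.ndarray:
        i_ext = x[..., 0]
        v = x[..., 1]
        h = x[..., 2]
        w = x[..., 3]
        if clamp_gates:
            h = np.clip(h, 0.0, 1.0)
            w = np.clip(w, 0.0, 1.0)
        i_tot = i_ext if control is None else i_ext + control[k]
        dv = (-(params.g_l * (v - params.e_l))
              - params.g_na * g.f1(v) * h * (v - params.e_na)
              - params.g_k * g.f3(h) * (v - params.e_k)
              - params.g_t * g.f2(v) * w * (v - params.e_t)
              + i_tot) / c_m
        hn = h + dt * (g.a_h(v) * (1.0 - h) - g.b_h(v) * h)
        wn = w + dt * (g.w_inf(v) - w) * g.inv_tau_w(v)
        if clamp_gates:
            hn = np.clip(hn, 0.0, 1.0)
            wn = np.clip(wn, 0.0, 1.0)
        return np.stack([i_ext, v + dt * dv, hn, wn], axis=-1)

    return f


# ---------------------------------------------------------------------------
# filter cycle
# ---------------------------------------------------------------------------


def propagate(points: SigmaPointSet, transition: Callable, k: int = 0
              ) -> Tuple[SigmaPointSet, np.ndarray]:
    """Push sigma points through the process model.

    Returns the transformed set and the per-point predicted observations
    (the V component).
    """
    newp = transition(points.points, k)
    if not np.all(np.isfinite(newp)):
        raise FilterDivergenceError("sigma point diverged during propagation")
    out = SigmaPointSet(points=newp, weights=points.weights)
    return out, newp[..., OBSERVED_INDEX]


def expand_q(q: Union[float, np.ndarray], n: int = N_STATE,
             batch: Optional[int] = None) -> np.ndarray:
    """Process-noise covariance from a scalar, diagonal or full specification.

    A scalar becomes ``q * I_n``; a length-``n`` vector a diagonal matrix; an
    ``(n, n)`` matrix passes through.  With ``batch`` given, a 1-D array of
    ``batch`` scalars yields per-filter ``q_b * I_n`` matrices.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim == 0:
        return float(q) * np.eye(n)
    if q.ndim == 1 and batch is not None and len(q) == batch and batch != n:
        return q[:, None, None] * np.eye(n)
    if q.ndim == 1 and len(q) == n:
        return np.diag(q)
    if q.ndim == 2 and q.shape == (n, n):
        return q
    if q.ndim == 1 and batch is not None and len(q) == batch:
        # ambiguous batch == n case: treat as per-filter scalars
        return q[:, None, None] * np.eye(n)
    raise ValueError(f"cannot interpret process noise of shape {q.shape}")


def predict(transformed: SigmaPointSet, q: Union[float, np.ndarray]):
    """A priori mean, covariance (scatter + Q) and predicted observation mean.

    ``q`` may be a scalar (expands to ``q * I``), a diagonal vector, a full
    matrix, or an already-expanded batch of matrices.
    """
    xp = transformed.mean()
    d = transformed.points - xp[..., None, :]
    w = transformed.weights
    cov = np.einsum("i,...ij,...ik->...jk", w, d, d)
    q = np.asarray(q, dtype=float)
    if q.ndim < 2:
        q = expand_q(q, transformed.n)
    return xp, cov + q, xp[..., OBSERVED_INDEX]


def update(x_prior: np.ndarray, p_prior: np.ndarray,
           y: Union[float, np.ndarray], r: Union[float, np.ndarray]):
    """Scalar-observation measurement update.

    The observation model is linear (``C = [0 1 0 0]`` selects V), so the
    cross- and observation covariances come directly from the a priori
    covariance: ``P_xy = P C^T`` and ``P_yy = C P C^T``, and the update is the
    exact Kalman correction ``K = P_xy / (P_yy + R)``.  Returns (posterior
    mean, posterior covariance, gain, innovation); the posterior covariance is
    re-symmetrized.
    """
    p_xy = p_prior[..., :, OBSERVED_INDEX]
    p_yy = p_prior[..., OBSERVED_INDEX, OBSERVED_INDEX]
    s = p_yy + np.asarray(r, dtype=float)
    gain = p_xy / s[..., None]
    innovation = np.asarray(y, dtype=float) - x_prior[..., OBSERVED_INDEX]
    x_post = x_prior + gain * innovation[..., None]
    p_post = p_prior - s[..., None, None] * np.einsum("...i,...j->...ij", gain, gain)
    p_post = 0.5 * (p_post + np.swapaxes(p_post, -1, -2))
    return x_post, p_post, gain, innovation


# ---------------------------------------------------------------------------
# the full filter
# ---------------------------------------------------------------------------


@dataclass
class UKFConfig:
    """Filter settings.

    ``q`` and ``r`` are the scalar process/observation noise covariances
    (``q`` expands to ``q * I_4``; per-filter arrays are accepted for batched
    ensembles).  ``transition`` is any ``f(points, step_index)`` map; use
    :func:`neuron_transition` for the relay cell.  ``x0``/``p0`` default to
    ``[0, first observation, 0.5, 0.1]`` and the identity.
    """

    q: Union[float, np.ndarray] = 5e-5
    r: Union[float, np.ndarray] = 5.0
    dt: float = 0.05
    transition: Optional[Callable] = None
    x0: Optional[np.ndarray] = None
    p0: Optional[np.ndarray] = None
    burn_in_ms: float = 100.0


@dataclass
class EstimateTrace:
    """Per-step filter output.

    ``means`` has shape (T, 4) (or (B, T, 4) for a batch); covariances,
    innovations and gains are recorded when the filter ran with
    ``record=True``.  ``cf_rmse`` holds post-burn-in root-mean-square errors
    per state component when a ground-truth series was supplied.
    """

    times: np.ndarray
    means: Optional[np.ndarray] = None
    covariances: Optional[np.ndarray] = None
    innovations: Optional[np.ndarray] = None
    gains: Optional[np.ndarray] = None
    cf_rmse: Optional[Dict[str, np.ndarray]] = None
    config: Optional[UKFConfig] = None


def estimate(observations: np.ndarray, config: UKFConfig,
             truth: Optional[np.ndarray] = None,
             record: bool = True) -> EstimateTrace:
    """Run one predict/update cycle per observation.

    Parameters
    ----------
    observations
        Voltage series of shape (T,) or (B, T) for a batch of independent
        filters (each may carry its own ``q``/``r`` entry).
    truth
        Optional ground-truth array of shape (T, 4) or (B, T, 4) with columns
        ``[I_ext, V, h, w]``; post-burn-in CF_rmse per component is then
        accumulated online.
    record
        Keep full per-step means/covariances/innovations/gains.  Turn off for
        large ensembles where only the error summary is needed.
    """
    obs = np.asarray(observations, dtype=float)
    single = obs.ndim == 1
    if single:
        obs = obs[None, :]
    b, t = obs.shape
    if config.transition is None:
        raise ValueError("UKFConfig.transition is required")

    x = np.zeros((b, N_STATE))
    if config.x0 is not None:
        x[:] = np.asarray(config.x0, dtype=float)
    else:
        x[:, OBSERVED_INDEX] = obs[:, 0]
        x[:, 2] = 0.5
        x[:, 3] = 0.1
    p = np.tile(np.eye(N_STATE), (b, 1, 1))
    if config.p0 is not None:
        p[:] = np.asarray(config.p0, dtype=float)

    qmat = expand_q(config.q, N_STATE, batch=b)
    if qmat.ndim == 2:
        qmat = np.broadcast_to(qmat, (b, N_STATE, N_STATE))
    r = np.broadcast_to(np.asarray(config.r, dtype=float), (b,))
    burn = int(round(config.burn_in_ms / config.dt))
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        if truth.ndim == 2:
            truth = np.broadcast_to(truth, (b,) + truth.shape)
        if t - burn < 1:
            raise ValueError("no samples left after burn-in")

    means = np.empty((b, t, N_STATE)) if record else None
    covs = np.empty((b, t, N_STATE, N_STATE)) if record else None
    innovs = np.empty((b, t)) if record else None
    gains = np.empty((b, t, N_STATE)) if record else None
    if record:
        means[:, 0] = x
        covs[:, 0] = p
        innovs[:, 0] = 0.0
        gains[:, 0] = 0.0
    sse = np.zeros((b, N_STATE))

    for k in range(1, t):
        try:
            sigma = generate_sigma_points(x, p)
        except FilterDivergenceError as exc:
            raise FilterDivergenceError(f"filter diverged at step {k}: {exc}") from exc
        transformed, _ = propagate(sigma, config.transition, k - 1)
        x_prior, p_prior, _ = predict(transformed, qmat)
        x, p, gain, innovation = update(x_prior, p_prior, obs[:, k], r)
        if record:
            means[:, k] = x
            covs[:, k] = p
            innovs[:, k] = innovation
            gains[:, k] = gain
        if truth is not None and k >= burn:
            e = x - truth[:, k]
            sse += e * e

    cf = None
    if truth is not None:
        cf_arr = np.sqrt(sse / max(t - burn, 1))
        cf = {name: (cf_arr[0, i] if single else cf_arr[:, i])
              for i, name in enumerate(STATE_NAMES)}

    def _sq(a):
        return None if a is None else (a[0] if single else a)

    return EstimateTrace(times=np.arange(t) * config.dt, means=_sq(means),
                         covariances=_sq(covs), innovations=_sq(innovs),
                         gains=_sq(gains), cf_rmse=cf, config=config)


def cf_rmse(estimates: np.ndarray, truth: np.ndarray, burn_in: int = 0) -> float:
    """Root-mean-square error between two series after dropping ``burn_in`` samples."""
    a = np.asarray(estimates, dtype=float)[burn_in:]
    b = np.asarray(truth, dtype=float)[burn_in:]
    if len(a) != len(b):
        raise ValueError("series must have equal length after burn-in removal")
    if len(a) == 0:
        raise ValueError("no samples left after burn-in")
    return float(np.sqrt(np.mean((a - b) ** 2)))
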