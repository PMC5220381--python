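"""Piecewise-linear, shift-add-friendly reduction of the gating functions.

Multiplierless digital hardware evaluates ``K_i * V + C_i`` per segment with
the slope ``K_i`` restricted to a short signed sum of powers of two (barrel
shifts and adds).  This module fits such functions to the eight nonlinear maps
of the relay cell (``f1``..``f8``), quantifies the approximation error with
three criteria (root-mean-square ERR_CF, its range-normalized percentage
NERR_CF%, and the mean absolute error MAE, each over ``M`` uniform samples),
and assembles a cost-efficient (CETC) gating set that drops into
:func:`thalatrack.model.simulate`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .model import GatingFunctionSet

__all__ = [
    "PiecewiseLinearFunction",
    "ShiftAddForm",
    "ApproximationReport",
    "quantize_slope",
    "fit_piecewise",
    "err_cf",
    "nerr_cf",
    "mae",
    "build_cetc",
    "InfeasibleBudgetError",
]

#: metric sampling domain for voltage-dependent functions (mV)
DEFAULT_DOMAIN = (-120.0, 20.0)
DEFAULT_M = 1000


class InfeasibleBudgetError(ValueError):
    """No shift-add representation exists within the requested budget."""


# ---------------------------------------------------------------------------
# shift-add slope representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftAddForm:
    """A slope written as a signed sum of powers of two.

    ``terms`` is a tuple of ``(sign, shift)`` pairs so that the value is
    ``sum(sign * 2**shift)``; every term is one barrel shift plus one add in
    hardware.
    """

    terms: Tuple[Tuple[int, int], ...]

    @property
    def value(self) -> float:
        return float(sum(s * 2.0**e for s, e in self.terms))

    def __len__(self):
        return len(self.terms)


@lru_cache(maxsize=8)
def _candidate_table(max_terms: int, lo: int, hi: int):
    """All distinct shift-add values with at most ``max_terms`` terms.

    Returns (sorted values array, list of best forms per value), where "best"
    means fewest terms.  Zero (the empty sum) is included.
    """
    shifts = range(lo, hi + 1)
    best: Dict[float, ShiftAddForm] = {0.0: ShiftAddForm(terms=())}
    for m in range(1, max_terms + 1):
        for combo in itertools.combinations(shifts, m):
            for signs in itertools.product((1, -1), repeat=m):
                val = float(sum(s * 2.0**e for s, e in zip(signs, combo)))
                form = ShiftAddForm(terms=tuple(zip(signs, combo)))
                prev = best.get(val)
                if prev is None or len(form) < len(prev) or (
                    len(form) == len(prev) and abs(val) < abs(prev.value)
                ):
                    best[val] = form
    values = np.array(sorted(best))
    forms = [best[v] for v in values]
    return values, forms


def quantize_slope(k: float, max_terms: int = 3,
                   shift_range: Tuple[int, int] = (-10, 4)) -> ShiftAddForm:
    """Nearest shift-add representable value to ``k``.

    Ties resolve toward fewer terms, then toward smaller magnitude (both are
    cheaper in hardware).
    """
    if max_terms < 1:
        raise InfeasibleBudgetError("shift-add budget must allow at least one term")
    values, forms = _candidate_table(max_terms, shift_range[0], shift_range[1])
    i = int(np.searchsorted(values, k))
    cand = [j for j in (i - 1, i, i + 1) if 0 <= j < len(values)]
    errs = [abs(values[j] - k) for j in cand]
    lo = min(errs)
    tied = [forms[j] for j, e in zip(cand, errs) if e <= lo + 0.0]
    tied.sort(key=lambda f: (len(f), abs(f.value)))
    return tied[0]


# ---------------------------------------------------------------------------
# piecewise-linear functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseLinearFunction:
    """Continuous piecewise-linear map ``V -> K_i V + C_i``.

    ``edges`` has ``n + 1`` strictly increasing entries delimiting ``n``
    segments over the stated domain; a query exactly on an interior breakpoint
    uses the right-hand segment, and queries outside the domain clamp to the
    boundary segment.  ``slope_forms`` keeps the exact shift-add decomposition
    of each slope when the function was built under a hardware budget.
    """

    edges: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    slope_forms: Optional[Tuple[ShiftAddForm, ...]] = None
    name: str = ""

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        slopes = np.asarray(self.slopes, dtype=float)
        intercepts = np.asarray(self.intercepts, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("breakpoints must be strictly increasing with >= 1 segment")
        if not (len(slopes) == len(intercepts) == len(edges) - 1):
            raise ValueError("need one slope and intercept per segment")
        # continuity at interior breakpoints
        left = slopes[:-1] * edges[1:-1] + intercepts[:-1]
        right = slopes[1:] * edges[1:-1] + intercepts[1:]
        if len(left) and np.max(np.abs(left - right)) > 1e-9:
            raise ValueError("piecewise-linear function is discontinuous at a breakpoint")

    @property
    def n_segments(self) -> int:
        return len(self.slopes)

    @property
    def domain(self) -> Tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    @classmethod
    def from_slopes(cls, edges, slopes, value_at_left: float,
                    slope_forms=None, name: str = "") -> "PiecewiseLinearFunction":
        """Build a continuous function from slopes and the value at the left edge."""
        edges = np.asarray(edges, dtype=float)
        slopes = np.asarray(slopes, dtype=float)
        widths = np.diff(edges)
        # value at each segment's left edge
        v_left = value_at_left + np.concatenate(([0.0], np.cumsum(slopes[:-1] * widths[:-1])))
        intercepts = v_left - slopes * edges[:-1]
        return cls(edges=edges, slopes=slopes, intercepts=intercepts,
                   slope_forms=tuple(slope_forms) if slope_forms is not None else None,
                   name=name)

    def segment_index(self, v):
        n = self.n_segments
        return np.clip(np.searchsorted(self.edges, v, side="right") - 1, 0, n - 1)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        i = self.segment_index(v)
        out = self.slopes[i] * v + self.intercepts[i]
        return out if out.ndim else float(out)


def evaluate(plf: PiecewiseLinearFunction, v):
    """Evaluate ``plf`` at voltage(s) ``v`` (clamping outside the domain)."""
    return plf(v)


# ---------------------------------------------------------------------------
# error criteria
# ---------------------------------------------------------------------------


def _sample(f_lin, f_ori, domain, m):
    x = np.linspace(domain[0], domain[1], m)
    a = np.asarray(f_lin(x), dtype=float)
    b = np.asarray(f_ori(x), dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("functions must be finite on the sampling grid")
    return x, a, b


def err_cf(f_lin, f_ori, domain=DEFAULT_DOMAIN, m: int = DEFAULT_M) -> float:
    """Root-mean-square deviation over ``m`` uniform samples."""
    if m < 2:
        raise ValueError("ERR_CF requires at least two sample points")
    _, a, b = _sample(f_lin, f_ori, domain, m)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nerr_cf(f_lin, f_ori, domain=DEFAULT_DOMAIN, m: int = DEFAULT_M) -> float:
    """ERR_CF normalized by the range of the linearized function, in percent."""
    _, a, b = _sample(f_lin, f_ori, domain, m)
    span = float(a.max() - a.min())
    if span <= 0:
        raise ValueError("degenerate range: f_max must exceed f_min")
    return float(100.0 * np.sqrt(np.mean((a - b) ** 2)) / span)


def mae(f_lin, f_ori, domain=DEFAULT_DOMAIN, m: int = DEFAULT_M) -> float:
    """Mean absolute deviation over ``m`` uniform samples."""
    if m < 1:
        raise ValueError("MAE requires at least one sample point")
    _, a, b = _sample(f_lin, f_ori, domain, m)
    return float(np.mean(np.abs(a - b)))


@dataclass
class ApproximationReport:
    """Per-function and mean error criteria of a piecewise-linear model."""

    per_function: Dict[str, Dict[str, float]] = field(default_factory=dict)
    m: int = DEFAULT_M

    def add(self, name, plf, original, domain):
        self.per_function[name] = {
            "err_cf": err_cf(plf, original, domain, self.m),
            "nerr_cf_pct": nerr_cf(plf, original, domain, self.m),
            "mae": mae(plf, original, domain, self.m),
            "n_segments": plf.n_segments,
        }

    def mean(self, key: str) -> float:
        return float(np.mean([d[key] for d in self.per_function.values()]))

    def to_dict(self) -> dict:
        return {
            "per_function": self.per_function,
            "M": self.m,
            "mean_err_cf": self.mean("err_cf"),
            "mean_nerr_cf_pct": self.mean("nerr_cf_pct"),
            "mean_mae": self.mean("mae"),
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _ls_continuous_fit(f, edges, m):
    """Least-squares continuous piecewise-linear fit: offset + per-segment slopes."""
    x = np.linspace(edges[0], edges[-1], m)
    y = np.asarray(f(x), dtype=float)
    widths = np.diff(edges)
    # basis: constant plus one clamped ramp per segment
    ramps = np.clip(x[:, None] - edges[None, :-1], 0.0, widths[None, :])
    design = np.hstack([np.ones((m, 1)), ramps])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[0], coef[1:], x, y, ramps


def fit_piecewise(f: Callable, domain=DEFAULT_DOMAIN, n_segments: int = 8,
                  max_terms: int = 3, shift_range: Tuple[int, int] = (-10, 4),
                  m: int = DEFAULT_M, quantize: bool = True,
                  name: str = "") -> PiecewiseLinearFunction:
    """Fit a continuous piecewise-linear approximation to ``f``.

    Breakpoints are uniform over the domain.  A least-squares continuous fit
    provides ideal slopes; each slope is then quantized to its nearest
    shift-add form and improved by a greedy per-segment search over
    neighbouring representable values (re-optimizing the free offset after
    every change).  With ``quantize=False`` the ideal slopes are kept.
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    edges = np.linspace(domain[0], domain[1], n_segments + 1)
    c0, slopes, x, y, ramps = _ls_continuous_fit(f, edges, m)

    if not quantize:
        v_left = float(c0)
        return PiecewiseLinearFunction.from_slopes(edges, slopes, v_left, name=name)

    values, _forms = _candidate_table(max_terms, shift_range[0], shift_range[1])

    def rms_for(slope_vec):
        pred_wo_offset = ramps @ slope_vec
        offset = float(np.mean(y - pred_wo_offset))  # optimal free offset
        r = y - (pred_wo_offset + offset)
        return float(np.sqrt(np.mean(r * r))), offset

    q = np.array([quantize_slope(k, max_terms, shift_range).value for k in slopes])
    best_rms, _ = rms_for(q)
    # greedy coordinate refinement over nearby representable slopes
    for _ in range(2):
        improved = False
        for i in range(n_segments):
            j = int(np.searchsorted(values, q[i]))
            for cand in values[max(0, j - 3):j + 4]:
                trial = q.copy()
                trial[i] = cand
                r, _ = rms_for(trial)
                if r < best_rms - 1e-15:
                    q = trial
                    best_rms = r
                    improved = True
        if not improved:
            break
    _, offset = rms_for(q)
    forms = [quantize_slope(k, max_terms, shift_range) for k in q]
    # exact reconstruction check (invariant: slope equals its shift-add value)
    assert all(abs(fm.value - k) == 0.0 for fm, k in zip(forms, q))
    return PiecewiseLinearFunction.from_slopes(edges, q, offset,
                                               slope_forms=forms, name=name)


# ---------------------------------------------------------------------------
# the CETC gating set
# ---------------------------------------------------------------------------

#: the eight linearized maps: name -> (attribute on GatingFunctionSet, domain)
CETC_FUNCTIONS = {
    "f1": ("f1", DEFAULT_DOMAIN),
    "f2": ("f2", DEFAULT_DOMAIN),
    "f3": ("f3", (0.0, 1.0)),  # a function of the gate h, not of voltage
    "f4_h_inf": ("h_inf", DEFAULT_DOMAIN),
    "f5_a_h": ("a_h", DEFAULT_DOMAIN),
    "f6_b_h": ("b_h", DEFAULT_DOMAIN),
    "f7_w_inf": ("w_inf", DEFAULT_DOMAIN),
    "f8_inv_tau_w": ("inv_tau_w", DEFAULT_DOMAIN),
}


def build_cetc(gating: GatingFunctionSet, n_segments=8, max_terms: int = 3,
               shift_range: Tuple[int, int] = (-10, 4), m: int = DEFAULT_M,
               tables: Optional[Dict[str, PiecewiseLinearFunction]] = None):
    """Build the cost-efficient (CETC) gating set.

    Each of the eight nonlinear maps is replaced by a shift-add-constrained
    piecewise-linear fit (or by an explicitly supplied coefficient table, e.g.
    transcribed from published segment listings).  ``n_segments`` may be an int
    or a per-function dict.  Returns ``(cetc_gating, report)`` where the report
    carries ERR_CF / NERR_CF% / MAE for every function at ``m`` samples.
    """
    tables = tables or {}
    plfs: Dict[str, PiecewiseLinearFunction] = {}
    report = ApproximationReport(m=m)
    for fname, (attr, domain) in CETC_FUNCTIONS.items():
        original = getattr(gating, attr)
        if fname in tables:
            plf = tables[fname]
        else:
            nseg = n_segments[fname] if isinstance(n_segments, dict) else n_segments
            plf = fit_piecewise(original, domain=domain, n_segments=nseg,
                                max_terms=max_terms, shift_range=shift_range,
                                m=m, name=fname)
        plfs[fname] = plf
        report.add(fname, plf, original, domain)
    missing = set(CETC_FUNCTIONS) - set(plfs)
    if missing:
        raise ValueError(f"CETC build missing functions: {sorted(missing)}")

    inv_tau = plfs["f8_inv_tau_w"]
    cetc = GatingFunctionSet(
        m_inf=gating.m_inf,  # m is slaved to f1 in the reduced dynamics
        h_inf=plfs["f4_h_inf"],
        p_inf=gating.p_inf,
        w_inf=plfs["f7_w_inf"],
        a_h=plfs["f5_a_h"],
        b_h=plfs["f6_b_h"],
        tau_w=lambda v: 1.0 / np.maximum(inv_tau(v), 1e-12),
        f1=plfs["f1"],
        f2=plfs["f2"],
        f3=plfs["f3"],
        inv_tau_w=inv_tau,
        name="cetc",
    )
    return cetc, report
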