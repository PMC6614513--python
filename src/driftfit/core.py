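"""Wiener diffusion process primitives.

A two-choice decision is modelled as a one-dimensional diffusion

    dX_t = v dt + s dW_t,    X_0 = z,

absorbed at 0 (lower boundary) and ``a`` (upper boundary).  The boundary
reached determines the choice; the first-passage time plus the non-decision
time ``Ter`` is the predicted response time.  The noise scale ``s`` is a
pure scaling constant (fixed at 0.1 by convention, so that drift magnitudes
are comparable across the diffusion-modelling literature) and is never
estimated.

This module provides the closed-form hitting probabilities, the
first-passage-time (FPT) densities and defective CDFs via the classical
small-time / large-time series expansions, mean decision times, and a
trial-level Euler-Maruyama simulator with a Brownian-bridge crossing
correction.  Everything downstream (data generation, likelihood fitting,
predictive checks) is built on these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "DDMParams",
    "hit_probability",
    "fpt_density",
    "fpt_cdf",
    "mean_decision_time",
    "simulate_trials",
    "simulate_trial",
]

#: Conventional within-trial noise scale (evidence units per sqrt-second).
DEFAULT_NOISE = 0.1

_SERIES_EPS = 1e-7  # absolute truncation tolerance for the density series
_CDF_EPS = 1e-12  # truncation tolerance for the CDF series


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a single diffusion process.

    Attributes
    ----------
    a : float
        Boundary separation (evidence units), ``a > 0``.
    v : float
        Drift rate (evidence units per second).  Positive drift pushes the
        accumulator toward the upper boundary.
    z : float
        Absolute starting point, ``0 < z < a``.  ``z = a/2`` means no bias.
    ter : float
        Non-decision time in seconds (stimulus encoding + motor output).
    s : float
        Within-trial noise scale; held fixed within any fitted model
        (identifiability scaling constant).
    """

    a: float
    v: float
    z: float
    ter: float
    s: float = DEFAULT_NOISE

    def __post_init__(self) -> None:
        if not np.isfinite([self.a, self.v, self.z, self.ter, self.s]).all():
            raise ParameterError("diffusion parameters must be finite")
        if self.a <= 0:
            raise ParameterError(f"boundary separation must be positive, got a={self.a}")
        if not 0 < self.z < self.a:
            raise ParameterError(f"starting point must satisfy 0 < z < a, got z={self.z}, a={self.a}")
        if self.ter < 0:
            raise ParameterError(f"non-decision time must be non-negative, got ter={self.ter}")
        if self.s <= 0:
            raise ParameterError(f"noise scale must be positive, got s={self.s}")

    @property
    def w(self) -> float:
        """Relative starting point ``z / a``."""
        return self.z / self.a

    def with_(self, **kwargs) -> "DDMParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _check_boundary(boundary: str) -> str:
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary


# ---------------------------------------------------------------------------
# Hitting probabilities and moments (closed forms)
# ---------------------------------------------------------------------------

def _hit_upper(a: float, v: float, z: float, s: float) -> float:
    # P(hit a before 0) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2)),
    # with the v -> 0 limit z / a.  expm1 keeps the ratio stable for small v.
    x = 2.0 * v / (s * s)
    if abs(x * a) < 1e-12:
        return z / a
    return np.expm1(-x * z) / np.expm1(-x * a)


def hit_probability(params: DDMParams, boundary: str = "upper") -> float:
    """Probability that the diffusion is absorbed at the given boundary.

    Uses the closed-form exponential formula; the zero-drift limit is
    handled analytically (``z/a`` for the upper boundary as ``v -> 0``
    under this sign convention, where positive drift points up).
    """
    _check_boundary(boundary)
    p_up = _hit_upper(params.a, params.v, params.z, params.s)
    return float(p_up if boundary == "upper" else 1.0 - p_up)


def _mean_dt(a: float, v: float, z: float, s: float) -> float:
    # Solution of (s^2/2) m'' + v m' = -1 with m(0) = m(a) = 0:
    #   m(z) = (a * P_upper(z) - z) / v,  limit z (a - z) / s^2 as v -> 0.
    if abs(2.0 * v * a / (s * s)) < 1e-9:
        return z * (a - z) / (s * s)
    return (a * _hit_upper(a, v, z, s) - z) / v


def mean_decision_time(params: DDMParams) -> float:
    """Mean first-passage (decision) time in seconds, over both boundaries.

    For an unbiased start (``z = a/2``) this reduces to
    ``(a / 2v) * tanh(v a / 2 s^2)``, with limit ``a^2 / (4 s^2)`` as
    ``v -> 0``.  Non-decision time is *not* included.
    """
    return float(_mean_dt(params.a, params.v, params.z, params.s))


# ---------------------------------------------------------------------------
# First-passage-time density (small-time / large-time series)
# ---------------------------------------------------------------------------

def _f0_lower(tau: np.ndarray, w: float, eps: float = _SERIES_EPS) -> np.ndarray:
    """Zero-drift, unit-boundary FPT density at the lower boundary.

    ``tau`` is decision time rescaled by ``(a/s)^2``.  The small-time and
    large-time expansions are switched per element at the point needing
    fewer terms, with the number of terms bound from the absolute
    tolerance ``eps`` (the standard truncation rule for this pair of
    series).
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]

    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * eps * np.sqrt(2.0 * np.pi * t)
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * eps
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * t)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    vals = np.empty_like(t)
    small = ks < kl

    if small.any():
        ts = t[small]
        kmax = int(np.ceil(ks[small].max()))
        k = np.arange(-kmax, kmax + 1)
        wk = w + 2.0 * k  # image charges
        expo = np.exp(-(wk[:, None] ** 2) / (2.0 * ts[None, :]))
        vals[small] = (wk[:, None] * expo).sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)

    large = ~small
    if large.any():
        tl = t[large]
        kmax = int(np.ceil(kl[large].max()))
        k = np.arange(1, kmax + 1)
        term = k[:, None] * np.exp(-(k[:, None] ** 2) * np.pi**2 * tl[None, :] / 2.0)
        vals[large] = np.pi * (term * np.sin(k[:, None] * np.pi * w)).sum(axis=0)

    out[pos] = np.maximum(vals, 0.0)
    return out


def _fpt_density(t, a: float, v: float, z: float, s: float, boundary: str) -> np.ndarray:
    at = a / s
    vt = v / s
    w = z / a
    if boundary == "upper":
        vt, w = -vt, 1.0 - w
    t = np.asarray(t, dtype=float)
    tau = t / at**2
    scale = np.exp(-vt * at * w - vt**2 * t / 2.0) / at**2
    return scale * _f0_lower(tau, w)


def fpt_density(t, params: DDMParams, boundary: str = "upper"):
    """Defective first-passage-time density at decision time ``t`` (1/s).

    ``t`` is the decision time, i.e. RT minus non-decision time; it must be
    strictly positive.  The density is non-negative and integrates over
    ``(0, inf)`` to ``hit_probability(params, boundary)``.
    """
    _check_boundary(boundary)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("fpt_density requires decision times t > 0")
    out = _fpt_density(t_arr, params.a, params.v, params.z, params.s, boundary)
    return out if np.ndim(t) else float(out)


def _fpt_cdf(t, a: float, v: float, z: float, s: float, boundary: str) -> np.ndarray:
    """Defective FPT CDF: P(absorbed at `boundary` and FPT <= t)."""
    at = a / s
    vt = v / s
    w = z / a
    if boundary == "upper":
        vt, w = -vt, 1.0 - w
    p_bound = _hit_upper(a, v, z, s)
    if boundary == "lower":
        p_bound = 1.0 - p_bound

    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not pos.any():
        return out
    tp = t[pos]

    # Term-by-term integral of the large-time series; eigenvalues
    # lambda_k = (vt^2 + (k pi / at)^2) / 2 grow like k^2, so the series
    # converges for every t > 0; the required K follows from the tail bound
    # exp(-k^2 pi^2 tau / 2) < eps.
    tau_min = tp.min() / at**2
    kmax = int(np.ceil(np.sqrt(max(-2.0 * np.log(_CDF_EPS), 1.0) / (np.pi**2 * tau_min)))) + 1
    kmax = min(max(kmax, 2), 100_000)
    k = np.arange(1, kmax + 1)
    lam = 0.5 * (vt**2 + (k * np.pi / at) ** 2)
    coef = k * np.sin(k * np.pi * w) / lam
    tail = (coef[:, None] * np.exp(-lam[:, None] * tp[None, :])).sum(axis=0)
    vals = p_bound - (np.pi / at**2) * np.exp(-vt * at * w) * tail
    out[pos] = np.clip(vals, 0.0, p_bound)
    return out


def fpt_cdf(t, params: DDMParams, boundary: str = "upper"):
    """Defective FPT CDF ``P(hit boundary, FPT <= t)`` at decision time ``t``.

    Returns 0 for ``t <= 0`` and approaches ``hit_probability`` as
    ``t -> inf``.  Vectorised over ``t``.
    """
    _check_boundary(boundary)
    out = _fpt_cdf(np.asarray(t, dtype=float), params.a, params.v, params.z, params.s, boundary)
    return out if np.ndim(t) else float(out)


# ---------------------------------------------------------------------------
# Trial simulator
# ---------------------------------------------------------------------------

def simulate_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    step: float = 5e-4,
    max_time: float | None = None,
    bridge: bool = True,
    v=None,
):
    """Simulate ``n`` first-passage trials by Euler-Maruyama.

    Parameters
    ----------
    step : float
        Euler time step in seconds (default 0.5 ms).
    max_time : float, optional
        Censor walks still unabsorbed at this decision time (used to apply
        a response deadline); censored trials get ``boundary = 0`` and
        ``dt = nan``.
    bridge : bool
        Apply the Brownian-bridge within-step crossing correction.  Plain
        discrete monitoring misses intra-step excursions and biases hit
        probabilities by O(sqrt(step)); the bridge correction removes that
        leading-order bias.
    v : array, optional (keyword)
        A per-trial drift vector of length ``n`` may be passed to batch
        heterogeneous trials (e.g. one session with cell-specific drifts)
        through a single call; it overrides ``params.v``.

    Returns
    -------
    boundary : int8 array
        +1 upper hit, -1 lower hit, 0 censored.
    dt : float array
        Decision time (seconds, excluding ``ter``); nan where censored.
    """
    a, z, s = params.a, params.z, params.s
    if v is None:
        v = params.v
    v = np.broadcast_to(np.asarray(v, dtype=float), (n,))
    x = np.full(n, z, dtype=float)
    bnd = np.zeros(n, dtype=np.int8)
    dt_out = np.full(n, np.nan)
    active = np.arange(n)
    sdt = s * np.sqrt(step)
    var_step = s * s * step
    t = 0.0
    hard_cap = max_time if max_time is not None else 2000.0 * (a / s) ** 2 + 10.0

    while active.size:
        if t >= hard_cap:
            break  # remaining walks censored
        x0 = x[active]
        x1 = x0 + v[active] * step + sdt * rng.standard_normal(active.size)
        hit_up = x1 >= a
        hit_lo = (~hit_up) & (x1 <= 0.0)
        t_cross = np.full(active.size, t + step)
        if bridge:
            open_ = ~(hit_up | hit_lo)
            if open_.any():
                xo0 = np.clip(x0[open_], 0.0, a)
                xo1 = x1[open_]
                p_up = np.exp(-2.0 * (a - xo0) * (a - xo1) / var_step)
                p_lo = np.exp(-2.0 * xo0 * xo1 / var_step)
                u = rng.random(xo0.size)
                b_up = u < p_up
                b_lo = (~b_up) & (u < p_up + p_lo)
                idx_open = np.flatnonzero(open_)
                hit_up[idx_open[b_up]] = True
                hit_lo[idx_open[b_lo]] = True
                # bridge crossings happen strictly inside the step
                t_cross[idx_open[b_up | b_lo]] = t + 0.5 * step
        done = hit_up | hit_lo
        if done.any():
            gid = active[done]
            bnd[gid] = np.where(hit_up[done], 1, -1).astype(np.int8)
            dt_out[gid] = t_cross[done]
            keep = ~done
            active = active[keep]
            x[active] = x1[keep]
        else:
            x[active] = x1
        t += step

    return bnd, dt_out


def simulate_trial(params: DDMParams, rng: np.random.Generator, step: float = 5e-4):
    """Simulate one trial; returns ``(boundary_label, rt_seconds)``.

    ``rt = ter + first crossing time``; the boundary label matches the
    crossing.  Reproducible given the generator state.
    """
    bnd, dt = simulate_trials(params, 1, rng, step=step)
    label = "upper" if bnd[0] == 1 else "lower"
    return label, float(params.ter + dt[0])
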