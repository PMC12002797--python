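"""Two-boundary constant-drift diffusion engine.

Shared by the social-perception and altruistic-choice models: closed-form
choice probabilities, the Wiener first-passage-time (WFPT) density via the
standard small-time/large-time series expansions, a seeded Euler-Maruyama
simulator (with Brownian-bridge within-step crossing correction), and the
per-trial log-likelihood used as the fitting objective.

Conventions
-----------
The accumulator starts at ``z = w * a`` between a lower boundary at 0 and an
upper boundary at ``a``. The Wiener noise scale ``sigma`` defaults to 1 and is
held fixed within a fit (drift-side parameters are identified relative to it).
Observed response time is first-crossing time plus non-decision time ``ndt``.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
from numba import njit
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DDMSpec",
    "TrialOutcome",
    "choice_probability",
    "wfpt_density",
    "wfpt_loglik",
    "trial_loglik",
    "simulate_trial",
    "simulate_many",
    "first_passage_cdf",
    "LOGLIK_FLOOR",
]

#: default log-likelihood contribution for an impossible trial (rt <= ndt)
LOGLIK_FLOOR = -1e10

#: truncation error target of the WFPT series
_SERIES_EPS = 1e-7


class ParameterDomainError(ValueError):
    """A DDM parameter is outside its admissible domain."""


@dataclasses.dataclass(frozen=True)
class DDMSpec:
    """Parameter set of a two-boundary constant-drift diffusion.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per second).
    a : float
        Boundary separation (> 0); lower boundary at 0, upper at ``a``.
    w : float
        Relative start point in (0, 1); absolute start ``z = w * a``.
    ndt : float
        Non-decision time in seconds (>= 0).
    sigma : float
        Diffusion noise scale (> 0), fixed within a fit.
    """

    v: float
    a: float
    w: float = 0.5
    ndt: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ParameterDomainError(f"drift must be finite, got {self.v}")
        if not (self.a > 0):
            raise ParameterDomainError(f"threshold a must be > 0, got {self.a}")
        if not (0.0 < self.w < 1.0):
            raise ParameterDomainError(f"start fraction w must be in (0,1), got {self.w}")
        if self.ndt < 0:
            raise ParameterDomainError(f"ndt must be >= 0, got {self.ndt}")
        if not (self.sigma > 0):
            raise ParameterDomainError(f"sigma must be > 0, got {self.sigma}")

    @property
    def z(self) -> float:
        """Absolute start point ``w * a``."""
        return self.w * self.a

    def normalized(self) -> tuple[float, float, float]:
        """(v, a, w) rescaled to the sigma=1 convention."""
        return self.v / self.sigma, self.a / self.sigma, self.w

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "DDMSpec":
        return cls(**json.loads(text))


@dataclasses.dataclass(frozen=True)
class TrialOutcome:
    """One simulated or observed trial: absorbing boundary and response time."""

    boundary: str  # "upper" | "lower"
    rt: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.boundary not in ("upper", "lower"):
            raise ValueError(f"boundary must be 'upper' or 'lower', got {self.boundary!r}")


# ---------------------------------------------------------------------------
# closed-form choice probability
# ---------------------------------------------------------------------------

def choice_probability(spec: DDMSpec) -> float:
    """Probability of absorbing at the *upper* boundary.

    Closed form ``P = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2))`` for
    nonzero drift, continuous at v = 0 where it equals ``w``.
    """
    v, a, w = spec.normalized()
    x = 2.0 * v * a  # sigma already folded in
    if abs(x) < 1e-10:
        return w
    # expm1 keeps the ratio stable for small |x|
    p = math.expm1(-x * w) / math.expm1(-x)
    return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# WFPT density (Navarro-Fuss style series switching)
# ---------------------------------------------------------------------------

def _f1(tau: np.ndarray, w: float, eps: float = _SERIES_EPS) -> np.ndarray:
    """Density of first passage through 0 of a zero-drift unit diffusion
    started at ``w`` between boundaries 0 and 1, at normalized times ``tau``.

    Switches between the small-time and large-time series by the standard
    required-number-of-terms criterion with truncation error target ``eps``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]

    with np.errstate(invalid="ignore"):
        ks = np.where(
            2.0 * np.sqrt(2.0 * np.pi * t) * eps < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * t)), 0.0)),
            np.sqrt(t) + 1.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        kl = np.where(
            np.pi * t * eps < 1.0,
            np.maximum(
                np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * eps), 0.0) / (np.pi**2 * t)),
                1.0 / (np.pi * np.sqrt(t)),
            ),
            1.0 / (np.pi * np.sqrt(t)),
        )

    res = np.empty_like(t)
    small = ks < kl
    if small.any():
        ts = t[small]
        K = int(np.ceil((ks[small].max() - 1.0) / 2.0))
        k = np.arange(-K, K + 1)
        wk = w + 2.0 * k[None, :]
        terms = wk * np.exp(-(wk**2) / (2.0 * ts[:, None]))
        res[small] = terms.sum(axis=1) / np.sqrt(2.0 * np.pi * ts**3)
    if (~small).any():
        tl = t[~small]
        K = max(int(np.ceil(kl[~small].max())), 1)
        k = np.arange(1, K + 1, dtype=float)
        terms = k[None, :] * np.exp(-(k[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0) * np.sin(
            k[None, :] * np.pi * w
        )
        res[~small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(res, 0.0)
    return out


def _wfpt_lower(t_dec: np.ndarray, v: np.ndarray, a: float, w: float) -> np.ndarray:
    """Lower-boundary defective density at decision times ``t_dec`` (sigma=1).

    ``v`` may be scalar or per-element (shared a/w), which is the shape the
    multi-attribute models need: drift varies trial by trial, geometry does not.
    """
    t_dec = np.asarray(t_dec, dtype=float)
    v = np.broadcast_to(np.asarray(v, dtype=float), t_dec.shape)
    out = np.zeros_like(t_dec)
    ok = t_dec > 0
    if not ok.any():
        return out
    td = t_dec[ok]
    vv = v[ok]
    tau = td / a**2
    scale = np.exp(-vv * a * w - (vv**2) * td / 2.0) / a**2
    out[ok] = scale * _f1(tau, w)
    return out


def wfpt_density(t, boundary: str, spec: DDMSpec):
    """First-passage-time density (1/s) at observed time(s) ``t``.

    The density of the requested ``boundary`` evaluated at ``t - ndt``;
    zero for ``t <= ndt``. The upper boundary is computed by reflection:
    ``f_upper(t | v, a, w) = f_lower(t | -v, a, 1 - w)``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    v, a, w = spec.normalized()
    scalar = np.isscalar(t)
    t_dec = np.atleast_1d(np.asarray(t, dtype=float)) - spec.ndt
    if boundary == "upper":
        out = _wfpt_lower(t_dec, -v, a, 1.0 - w)
    else:
        out = _wfpt_lower(t_dec, v, a, w)
    return float(out[0]) if scalar else out


def wfpt_loglik(
    rt: np.ndarray,
    upper: np.ndarray,
    v,
    a: float,
    w: float,
    ndt: float,
    sigma: float = 1.0,
    floor: float = LOGLIK_FLOOR,
) -> np.ndarray:
    """Vectorized per-trial log-density with trial-varying drift.

    Parameters
    ----------
    rt, upper : arrays
        Observed response times (s) and boolean upper-boundary indicators.
    v : scalar or array
        Drift per trial.
    floor : float
        Log-likelihood contribution substituted when ``rt <= ndt`` (keeps
        optimizers away from -inf).
    """
    rt = np.asarray(rt, dtype=float)
    upper = np.asarray(upper, dtype=bool)
    v = np.broadcast_to(np.asarray(v, dtype=float) / sigma, rt.shape)
    a_n = a / sigma
    t_dec = rt - ndt
    dens = np.zeros_like(rt)
    if upper.any():
        dens[upper] = _wfpt_lower(t_dec[upper], -v[upper], a_n, 1.0 - w)
    if (~upper).any():
        dens[~upper] = _wfpt_lower(t_dec[~upper], v[~upper], a_n, w)
    out = np.full_like(rt, floor)
    good = dens > 0
    out[good] = np.log(dens[good])
    return out


def trial_loglik(outcome: TrialOutcome, spec: DDMSpec, floor: float = LOGLIK_FLOOR) -> float:
    """Log of the WFPT density at the observed boundary/rt; floored for rt <= ndt."""
    if outcome.rt <= 0:
        raise ValueError("rt must be positive")
    dens = wfpt_density(outcome.rt, outcome.boundary, spec)
    return float(np.log(dens)) if dens > 0 else floor


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _sim_batch(v, a, w, sigma, dt, max_steps, seed, bridge):  # pragma: no cover - numba
    np.random.seed(seed)
    n = v.shape[0]
    boundary = np.empty(n, dtype=np.int8)
    t_dec = np.empty(n, dtype=np.float64)
    sq = sigma * math.sqrt(dt)
    inv = 1.0 / (sigma * sigma * dt)
    # beyond this distance product the bridge-crossing probability is < e^-18
    far = 9.0 * sigma * sigma * dt
    for i in range(n):
        x = w * a
        t = 0.0
        b = np.int8(-1)
        vi = v[i]
        for _ in range(max_steps):
            xn = x + vi * dt + sq * np.random.standard_normal()
            t += dt
            if xn >= a:
                b = np.int8(1)
                break
            if xn <= 0.0:
                b = np.int8(0)
                break
            if bridge:
                # Brownian-bridge probability of an unobserved within-step crossing
                pu = (a - x) * (a - xn)
                if pu < far and np.random.random() < math.exp(-2.0 * pu * inv):
                    b = np.int8(1)
                    break
                pl = x * xn
                if pl < far and np.random.random() < math.exp(-2.0 * pl * inv):
                    b = np.int8(0)
                    break
            x = xn
        boundary[i] = b
        # crossing happened somewhere inside the last step: midpoint assignment
        # removes the first-order O(dt) time bias
        t_dec[i] = t - 0.5 * dt if b >= 0 else t
    return boundary, t_dec


def simulate_many(
    spec: DDMSpec,
    n: int | None = None,
    *,
    v: np.ndarray | None = None,
    seed: int = 0,
    dt: float = 1e-3,
    max_time: float = 20.0,
    bridge: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate first-passage trials by Euler-Maruyama.

    Either ``n`` identical trials from ``spec`` or one trial per element of a
    drift array ``v`` (sharing the spec's geometry). Returns ``(boundary, rt)``
    where ``boundary`` is +1 upper / 0 lower / -1 non-converged (no crossing
    within ``max_time``, never silently dropped) and ``rt`` includes ``ndt``.
    Deterministic given ``seed``.
    """
    if (n is None) == (v is None):
        raise ValueError("provide exactly one of n or v")
    drifts = np.full(n, spec.v, dtype=float) if v is None else np.asarray(v, dtype=float)
    max_steps = int(np.ceil(max_time / dt))
    b, t_dec = _sim_batch(
        drifts, float(spec.a), float(spec.w), float(spec.sigma), float(dt), max_steps,
        int(seed) % (2**32), bool(bridge),
    )
    rt = np.where(b >= 0, t_dec + spec.ndt, np.nan)
    return b, rt


def simulate_trial(
    spec: DDMSpec,
    seed: int = 0,
    *,
    dt: float = 1e-3,
    max_time: float = 20.0,
    bridge: bool = True,
) -> TrialOutcome:
    """Simulate a single trial; see :func:`simulate_many` for the contract."""
    b, rt = simulate_many(spec, 1, seed=seed, dt=dt, max_time=max_time, bridge=bridge)
    if b[0] < 0:
        return TrialOutcome("lower", float(max_time + spec.ndt), converged=False)
    return TrialOutcome("upper" if b[0] == 1 else "lower", float(rt[0]))


def first_passage_cdf(
    spec: DDMSpec, boundary: str, t_max: float = 20.0, n_grid: int = 4000
) -> tuple[np.ndarray, np.ndarray]:
    """Numerical (defective) CDF of the first-passage time at one boundary.

    Quadrature over the series density on a grid log-dense near zero (the
    density can peak within milliseconds of onset when a boundary is close);
    used as the reference distribution for simulation oracles.
    """
    early = np.geomspace(1e-6, 1.0, n_grid // 2)
    late = np.linspace(1.0, t_max, n_grid - n_grid // 2)
    t = spec.ndt + np.unique(np.concatenate([[0.0], early, late]))
    f = wfpt_density(t, boundary, spec)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(f, t)])
    return t, cdf
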