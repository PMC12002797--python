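"""Multi-attribute DDM of altruistic choice with condition-dependent weights.

Each accept/reject decision over a proposed allocation (vs. a $20/$20
default) is modeled as drift

    v = w0 + w_self * Self + w_other * Other + w_fairness * Fairness

where ``Self = (offer_self - 20)/10``, ``Other = (offer_other - 20)/10`` and
``Fairness = -|Other - Self|``; accept maps to the upper boundary. Each of
the four weights carries a baseline (reference condition: unknown merit, low
need) plus three additive change parameters (high merit, low merit, high
need; no merit x need interaction), giving 16 weight parameters; threshold,
non-decision time and start fraction are shared across the six conditions
(19 parameters total).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit
from sklearn.base import BaseEstimator

from .ddm import LOGLIK_FLOOR, wfpt_loglik

__all__ = [
    "MERIT_LEVELS",
    "NEED_LEVELS",
    "WEIGHT_NAMES",
    "DEFAULT_OFFER",
    "AltruismParameters",
    "compute_attributes",
    "condition_weights",
    "build_drift_altruism",
    "AltruismDDM",
    "fit_subject_altruism",
    "fit_cohort_altruism",
    "change_scores",
]

MERIT_LEVELS = ("high", "unknown", "low")
NEED_LEVELS = ("high", "low")
WEIGHT_NAMES = ("w0", "self", "other", "fairness")
DEFAULT_OFFER = 20.0

BOUNDS = {
    "weight": (-5.0, 5.0),
    "delta": (-3.0, 3.0),
    "a": (0.3, 5.0),
    "w": (0.05, 0.95),
    "ndt_lo": 0.05,
}


@dataclasses.dataclass
class AltruismParameters:
    """Subject-level parameters: baseline weights, per-weight change
    parameters for high merit / low merit / high need, shared a/ndt/z."""

    base: dict[str, float]             # one per WEIGHT_NAMES
    delta_merit_high: dict[str, float]
    delta_merit_low: dict[str, float]
    delta_need_high: dict[str, float]
    threshold: float
    ndt: float
    start: float

    def validate(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.start < 1:
            raise ValueError("start fraction must be in (0,1)")
        if self.ndt < 0:
            raise ValueError("ndt must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AltruismParameters":
        return cls(
            base=dict(d["base"]),
            delta_merit_high=dict(d["delta_merit_high"]),
            delta_merit_low=dict(d["delta_merit_low"]),
            delta_need_high=dict(d["delta_need_high"]),
            threshold=float(d["threshold"]),
            ndt=float(d["ndt"]),
            start=float(d["start"]),
        )

    def to_json(self, **meta) -> str:
        return json.dumps({**self.to_dict(), **({"meta": meta} if meta else {})}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AltruismParameters":
        return cls.from_dict(json.loads(text))


def compute_attributes(offer_self, offer_other, default: float = DEFAULT_OFFER):
    """Rescaled attributes (Self, Other, Fairness) of a proposal.

    Vectorized; payoff differences from the default are divided by 10 and
    Fairness is ``-|Other - Self|`` on the rescaled values (<= 0, zero iff
    equal payoffs).
    """
    s = (np.asarray(offer_self, dtype=float) - default) / 10.0
    o = (np.asarray(offer_other, dtype=float) - default) / 10.0
    f = -np.abs(o - s)
    if s.ndim == 0:
        return float(s), float(o), float(f)
    return s, o, f


def condition_weights(params: AltruismParameters, merit: str, need: str) -> np.ndarray:
    """Weight vector (w0, w_self, w_other, w_fairness) in one condition.

    Unknown merit + low need is the reference condition (baselines);
    change parameters add linearly, with no merit x need interaction.
    """
    if merit not in MERIT_LEVELS:
        raise ValueError(f"unknown merit level {merit!r}")
    if need not in NEED_LEVELS:
        raise ValueError(f"unknown need level {need!r}")
    w = np.array([params.base[k] for k in WEIGHT_NAMES], dtype=float)
    if merit == "high":
        w += [params.delta_merit_high[k] for k in WEIGHT_NAMES]
    elif merit == "low":
        w += [params.delta_merit_low[k] for k in WEIGHT_NAMES]
    if need == "high":
        w += [params.delta_need_high[k] for k in WEIGHT_NAMES]
    return w


def build_drift_altruism(weights: np.ndarray, attrs) -> float:
    """Drift ``w0 + w_self*Self + w_other*Other + w_fairness*Fairness``."""
    s, o, f = attrs
    w = np.asarray(weights, dtype=float)
    return float(w[0] + w[1] * s + w[2] * o + w[3] * f)


def change_scores(params: AltruismParameters) -> dict[str, float]:
    """Overall (6-cell mean) weights and merit/need change scores per weight.

    Merit change = delta_merit_high - delta_merit_low (identical to
    differencing the condition-resolved weights); need change =
    delta_need_high.
    """
    out = {}
    for k in WEIGHT_NAMES:
        cells = [
            condition_weights(params, m, n)[WEIGHT_NAMES.index(k)]
            for m in MERIT_LEVELS for n in NEED_LEVELS
        ]
        out[f"overall_{k}"] = float(np.mean(cells))
        out[f"dmerit_{k}"] = params.delta_merit_high[k] - params.delta_merit_low[k]
        out[f"dneed_{k}"] = params.delta_need_high[k]
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_CELLS = [(m, n) for m in MERIT_LEVELS for n in NEED_LEVELS]


def _theta_to_wmat(theta: np.ndarray) -> np.ndarray:
    """(6, 4) condition-by-weight matrix from the 19-vector
    [base(4), d_merit_high(4), d_merit_low(4), d_need_high(4), a, ndt, w]."""
    base, dmh, dml, dnh = theta[0:4], theta[4:8], theta[8:12], theta[12:16]
    wmat = np.empty((6, 4))
    for i, (m, n) in enumerate(_CELLS):
        w = base.copy()
        if m == "high":
            w = w + dmh
        elif m == "low":
            w = w + dml
        if n == "high":
            w = w + dnh
        wmat[i] = w
    return wmat


def _altruism_nll(theta, X, cell_idx, rt, accept, floor, prior=None):
    wmat = _theta_to_wmat(theta)
    a, ndt, w = theta[16], theta[17], theta[18]
    v = np.einsum("ij,ij->i", X, wmat[cell_idx])
    ll = wfpt_loglik(rt, accept, v, a, w, ndt, floor=floor).sum()
    if prior is not None:
        mu, sd = prior
        ll -= 0.5 * np.sum(((theta - mu) / sd) ** 2)
    return -ll


class AltruismDDM(BaseEstimator):
    """Maximum-likelihood fit of the 19-parameter altruistic-choice DDM.

    Same optimizer conventions as :class:`~socialddm.perception.PerceptionDDM`:
    seeded multi-start L-BFGS-B plus a logistic-regression-informed start;
    accept = upper boundary.

    Attributes
    ----------
    params_ : AltruismParameters
    loglik_ : float
    converged_ : bool
    n_used_ : dict
        Usable trial count per merit x need cell.
    """

    def __init__(
        self,
        n_restarts: int = 8,
        random_state: int = 0,
        min_trials_per_cell: int = 25,
        loglik_floor: float = LOGLIK_FLOOR,
        rt_max: float | None = None,
        prior: tuple | None = None,
    ):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.min_trials_per_cell = min_trials_per_cell
        self.loglik_floor = loglik_floor
        self.rt_max = rt_max
        self.prior = prior

    def fit(self, X: pd.DataFrame, y=None):
        """Fit one subject's trials (columns ``partner_merit, need_level,
        offer_self, offer_other, response, rt``)."""
        df = X.copy()
        rt = df["rt"].to_numpy(dtype=float)
        ok = np.isfinite(rt) & (rt > 0)
        if self.rt_max is not None:
            ok &= rt <= self.rt_max
        df = df[ok]
        missing = []
        n_used = {}
        for m, n in _CELLS:
            cnt = int(((df["partner_merit"] == m) & (df["need_level"] == n)).sum())
            n_used[(m, n)] = cnt
            if cnt < self.min_trials_per_cell:
                missing.append((m, n, cnt))
        if missing:
            raise ValueError(
                "under-filled merit x need cells (need >= "
                f"{self.min_trials_per_cell} trials): {missing}"
            )

        rt = df["rt"].to_numpy(dtype=float)
        accept = df["response"].astype(str).str.lower().isin(
            ["accept", "yes", "1", "true"]
        ).to_numpy()
        s, o, f = compute_attributes(
            df["offer_self"].to_numpy(), df["offer_other"].to_numpy()
        )
        Xmat = np.column_stack([np.ones_like(s), s, o, f])
        cell_idx = np.array([
            _CELLS.index((m, n))
            for m, n in zip(df["partner_merit"], df["need_level"])
        ])

        min_rt = rt.min()
        ndt_hi = max(min_rt - 0.01, BOUNDS["ndt_lo"] + 1e-3)
        bounds = (
            [BOUNDS["weight"]] * 4 + [BOUNDS["delta"]] * 12
            + [BOUNDS["a"], (BOUNDS["ndt_lo"], ndt_hi), BOUNDS["w"]]
        )
        rng = np.random.default_rng(self.random_state)
        starts = [self._informed_start(Xmat, accept, min_rt)]
        for _ in range(self.n_restarts):
            starts.append(np.concatenate([
                rng.uniform(-1.0, 1.5, 4),
                rng.uniform(-0.5, 0.5, 12),
                [rng.uniform(1.0, 2.5), rng.uniform(BOUNDS["ndt_lo"], ndt_hi),
                 rng.uniform(0.35, 0.65)],
            ]))
        best, best_ll, conv = None, -np.inf, False
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        for x0 in starts:
            res = minimize(
                _altruism_nll, np.clip(x0, lo, hi),
                args=(Xmat, cell_idx, rt, accept, self.loglik_floor, self.prior),
                method="L-BFGS-B", bounds=bounds,
            )
            if -res.fun > best_ll:
                best, best_ll, conv = res.x, -res.fun, bool(res.success)

        t = best
        self.params_ = AltruismParameters(
            base=dict(zip(WEIGHT_NAMES, map(float, t[0:4]))),
            delta_merit_high=dict(zip(WEIGHT_NAMES, map(float, t[4:8]))),
            delta_merit_low=dict(zip(WEIGHT_NAMES, map(float, t[8:12]))),
            delta_need_high=dict(zip(WEIGHT_NAMES, map(float, t[12:16]))),
            threshold=float(t[16]), ndt=float(t[17]), start=float(t[18]),
        )
        self.loglik_ = float(best_ll)
        self.converged_ = conv
        self.n_used_ = {f"{m}/{n}": c for (m, n), c in n_used.items()}
        return self

    @staticmethod
    def _informed_start(Xmat, accept, min_rt):
        a0 = 1.8
        p = float(np.clip(accept.mean(), 0.05, 0.95))
        w0 = logit(p) / a0
        # least-squares of choice on attributes as a crude weight guess
        try:
            beta, *_ = np.linalg.lstsq(Xmat, accept.astype(float) - 0.5, rcond=None)
            wguess = np.clip(4.0 * beta[1:], -3, 3)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            wguess = np.zeros(3)
        return np.concatenate([
            [np.clip(w0, -2, 2)], wguess, np.zeros(12),
            [a0, max(0.8 * min_rt, 0.06), 0.5],
        ])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Model acceptance probability for each trial row."""
        from .ddm import DDMSpec, choice_probability

        p = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            wvec = condition_weights(self.params_, row["partner_merit"], row["need_level"])
            attrs = compute_attributes(row["offer_self"], row["offer_other"])
            v = build_drift_altruism(wvec, attrs)
            p[i] = choice_probability(DDMSpec(
                v, self.params_.threshold, self.params_.start, self.params_.ndt
            ))
        return p


def fit_subject_altruism(
    trials: pd.DataFrame, config: dict | None = None
) -> tuple[AltruismParameters, dict]:
    """Functional wrapper over :class:`AltruismDDM` for one subject."""
    est = AltruismDDM(**dict(config or {})).fit(trials)
    diag = {
        "loglik": est.loglik_,
        "converged": est.converged_,
        "n_used": est.n_used_,
        "seed": est.random_state,
        "n_restarts": est.n_restarts,
    }
    return est.params_, diag


def fit_cohort_altruism(
    trials: pd.DataFrame,
    config: dict | None = None,
    shrinkage: bool = False,
) -> dict[str, tuple[AltruismParameters, dict]]:
    """Fit every subject; optional two-stage empirical-Bayes shrinkage."""
    cfg = dict(config or {})
    subjects = list(pd.unique(trials["subject_id"]))
    first = {
        s: fit_subject_altruism(trials[trials["subject_id"] == s], cfg)
        for s in subjects
    }
    if not shrinkage or len(subjects) < 3:
        return first
    mat = np.array([_params_to_vec(p) for p, _ in first.values()])
    mu = mat.mean(axis=0)
    sd = np.maximum(mat.std(axis=0, ddof=1), 0.05)
    cfg["prior"] = (mu, sd)
    return {
        s: fit_subject_altruism(trials[trials["subject_id"] == s], cfg)
        for s in subjects
    }


def _params_to_vec(p: AltruismParameters) -> np.ndarray:
    return np.array([
        *[p.base[k] for k in WEIGHT_NAMES],
        *[p.delta_merit_high[k] for k in WEIGHT_NAMES],
        *[p.delta_merit_low[k] for k in WEIGHT_NAMES],
        *[p.delta_need_high[k] for k in WEIGHT_NAMES],
        p.threshold, p.ndt, p.start,
    ])
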