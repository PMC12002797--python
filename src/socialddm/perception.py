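"""Social-perception DDM: evidence bias and sensitivity decomposition.

On each trial of the speeded yes/no judgment task, the decision maker
accumulates noisy evidence whose mean drift is a condition-specific bias plus
a weighted sum of the stimulus's normative evidence on all three judgment
dimensions (merit, need, control)::

    v = Bias_c + S[c][merit] * Merit + S[c][need] * Need + S[c][control] * Control

with mean-centered normative evidence, "yes" mapped to the upper boundary,
and condition-specific threshold / non-decision time / start fraction.
Subjects are fitted by per-condition maximum likelihood with seeded
multi-start (the three conditions share no parameters, so the 18-parameter
subject fit factorizes into three 7-parameter fits), with an optional
empirical-Bayes shrinkage mode at the cohort level.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit
from sklearn.base import BaseEstimator

from .ddm import LOGLIK_FLOOR, wfpt_loglik

__all__ = [
    "CONDITIONS",
    "EVIDENCE_DIMS",
    "PerceptionParameters",
    "center_evidence",
    "build_drift",
    "PerceptionDDM",
    "fit_subject",
    "fit_cohort_perception",
    "extract_bias_sensitivity",
    "task_relevance_check",
]

CONDITIONS = ("merit", "need", "control")
EVIDENCE_DIMS = ("merit", "need", "control")

#: optimizer box constraints (wide margins around plausible estimates)
BOUNDS = {
    "S": (-10.0, 10.0),
    "bias": (-5.0, 5.0),
    "a": (0.3, 5.0),
    "w": (0.05, 0.95),
    "ndt_lo": 0.05,
}


@dataclasses.dataclass
class PerceptionParameters:
    """Subject-level parameter set: 9 sensitivities, 3 biases, 3 thresholds,
    3 non-decision times, 3 start fractions (18 parameters)."""

    sensitivity: dict[str, dict[str, float]]  # [condition][evidence dim]
    bias: dict[str, float]
    threshold: dict[str, float]
    ndt: dict[str, float]
    start: dict[str, float]

    def validate(self) -> None:
        for c in CONDITIONS:
            if not self.threshold[c] > 0:
                raise ValueError(f"threshold[{c}] must be > 0")
            if not 0 < self.start[c] < 1:
                raise ValueError(f"start[{c}] must be in (0,1)")
            if self.ndt[c] < 0:
                raise ValueError(f"ndt[{c}] must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PerceptionParameters":
        return cls(
            sensitivity={c: dict(d["sensitivity"][c]) for c in CONDITIONS},
            bias=dict(d["bias"]),
            threshold=dict(d["threshold"]),
            ndt=dict(d["ndt"]),
            start=dict(d["start"]),
        )

    def to_json(self, **meta) -> str:
        return json.dumps({**self.to_dict(), **({"meta": meta} if meta else {})}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PerceptionParameters":
        return cls.from_dict(json.loads(text))


def center_evidence(stimuli: pd.DataFrame) -> pd.DataFrame:
    """Mean-center the normative evidence columns over the full stimulus set.

    Expects columns ``stimulus_id, merit_prop, need_prop, control_prop`` with
    raw "yes" proportions in [0, 1]; returns a copy with added centered
    columns ``merit, need, control`` (dataset means recorded in ``.attrs``).
    """
    out = stimuli.copy()
    means = {}
    for dim in EVIDENCE_DIMS:
        raw = out[f"{dim}_prop"].to_numpy(dtype=float)
        if ((raw < 0) | (raw > 1)).any():
            raise ValueError(f"{dim}_prop must lie in [0, 1] before centering")
        means[dim] = float(raw.mean())
        out[dim] = raw - means[dim]
    out.attrs["evidence_means"] = means
    return out


def build_drift(
    params: PerceptionParameters, stimulus, condition: str
) -> float:
    """Drift for one (centered) stimulus under one judgment condition.

    ``stimulus`` is anything with centered ``merit/need/control`` entries
    (a Series, dict, or mapping row of :func:`center_evidence` output).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    v = params.bias[condition]
    for dim in EVIDENCE_DIMS:
        v += params.sensitivity[condition][dim] * float(stimulus[dim])
    if not np.isfinite(v):
        raise ValueError("drift is not finite")
    return float(v)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _theta_split(theta: np.ndarray):
    bias, s1, s2, s3, a, ndt, w = theta
    return bias, np.array([s1, s2, s3]), a, ndt, w


def _condition_nll(
    theta: np.ndarray,
    E: np.ndarray,
    rt: np.ndarray,
    yes: np.ndarray,
    floor: float,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    bias, s, a, ndt, w = _theta_split(theta)
    v = bias + E @ s
    ll = wfpt_loglik(rt, yes, v, a, w, ndt, floor=floor).sum()
    if prior is not None:
        mu, sd = prior
        ll -= 0.5 * np.sum(((theta - mu) / sd) ** 2)
    return -ll


class PerceptionDDM(BaseEstimator):
    """Per-subject maximum-likelihood fit of the social-perception DDM.

    Parameters
    ----------
    n_restarts : int
        Random multi-start count per condition, in addition to a
        logistic-regression-informed start.
    random_state : int
        Seed for the restart draws.
    rt_window : float
        Response window (s); trials with RT outside (0, rt_window] are
        treated as missing and excluded from the likelihood.
    min_trials : int
        Minimum usable trials required per condition.
    loglik_floor : float
        Per-trial floor substituted for impossible observations.
    prior : dict or None
        Optional shrinkage prior: ``{condition: (mu, sd)}`` over the
        7-vector (bias, S_merit, S_need, S_control, a, ndt, w); used by the
        cohort-level empirical-Bayes mode.

    Attributes
    ----------
    params_ : PerceptionParameters
    loglik_ : float
        Maximized summed log-likelihood over all conditions.
    converged_ : bool
    n_used_ : dict
        Usable trial count per condition.
    """

    def __init__(
        self,
        n_restarts: int = 8,
        random_state: int = 0,
        rt_window: float = 2.0,
        min_trials: int = 20,
        loglik_floor: float = LOGLIK_FLOOR,
        prior: dict | None = None,
    ):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.rt_window = rt_window
        self.min_trials = min_trials
        self.loglik_floor = loglik_floor
        self.prior = prior

    def fit(self, X: pd.DataFrame, y=None, *, stimuli: pd.DataFrame):
        """Fit one subject's trials.

        ``X`` needs columns ``stimulus_id, condition, response, rt``
        (one subject); ``stimuli`` is the :func:`center_evidence` output.
        """
        if not all(dim in stimuli.columns for dim in EVIDENCE_DIMS):
            stimuli = center_evidence(stimuli)
        ev = stimuli.set_index("stimulus_id")[list(EVIDENCE_DIMS)]

        rng = np.random.default_rng(self.random_state)
        sens: dict[str, dict[str, float]] = {}
        bias: dict[str, float] = {}
        thr: dict[str, float] = {}
        ndt: dict[str, float] = {}
        start: dict[str, float] = {}
        total_ll = 0.0
        converged = True
        n_used = {}

        for cond in CONDITIONS:
            sub = X[X["condition"] == cond]
            rt = sub["rt"].to_numpy(dtype=float)
            yes = sub["response"].astype(str).str.lower().isin(["yes", "1", "true"]).to_numpy()
            ok = np.isfinite(rt) & (rt > 0) & (rt <= self.rt_window)
            sub, rt, yes = sub[ok], rt[ok], yes[ok]
            n_used[cond] = int(ok.sum())
            if n_used[cond] < self.min_trials:
                raise ValueError(
                    f"condition {cond!r}: {n_used[cond]} usable trials "
                    f"< required minimum {self.min_trials}"
                )
            E = ev.loc[sub["stimulus_id"]].to_numpy(dtype=float)
            prior = None if self.prior is None else self.prior.get(cond)
            theta, ll, conv = self._fit_condition(E, rt, yes, rng, prior)
            b, s, a, t0, w = _theta_split(theta)
            bias[cond] = float(b)
            sens[cond] = {dim: float(s[i]) for i, dim in enumerate(EVIDENCE_DIMS)}
            thr[cond] = float(a)
            ndt[cond] = float(t0)
            start[cond] = float(w)
            total_ll += ll
            converged &= conv

        self.params_ = PerceptionParameters(sens, bias, thr, ndt, start)
        self.loglik_ = float(total_ll)
        self.converged_ = bool(converged)
        self.n_used_ = n_used
        return self

    def _fit_condition(self, E, rt, yes, rng, prior):
        min_rt = rt.min()
        ndt_hi = max(min_rt - 0.01, BOUNDS["ndt_lo"] + 1e-3)
        bounds = [
            BOUNDS["bias"], BOUNDS["S"], BOUNDS["S"], BOUNDS["S"],
            BOUNDS["a"], (BOUNDS["ndt_lo"], ndt_hi), BOUNDS["w"],
        ]
        starts = [self._informed_start(E, yes, min_rt)]
        for _ in range(self.n_restarts):
            starts.append(np.array([
                rng.uniform(-1.5, 1.5),
                *rng.uniform(-1.0, 5.0, 3),
                rng.uniform(0.8, 2.5),
                rng.uniform(BOUNDS["ndt_lo"], ndt_hi),
                rng.uniform(0.35, 0.65),
            ]))
        best, best_ll, conv = None, -np.inf, False
        for x0 in starts:
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                _condition_nll, x0, args=(E, rt, yes, self.loglik_floor, prior),
                method="L-BFGS-B", bounds=bounds,
            )
            if -res.fun > best_ll:
                best, best_ll, conv = res.x, -res.fun, bool(res.success)
        return best, best_ll, conv

    @staticmethod
    def _informed_start(E, yes, min_rt):
        """Choice-only start: at w=0.5 the closed form gives
        P(yes) ~ logistic(v*a), so a logistic fit of yes on evidence yields
        drift-scale slopes once divided by the threshold guess."""
        a0 = 1.5
        p = yes.mean()
        b0 = float(np.clip(logit(min(max(p, 0.05), 0.95)), -3, 3)) / a0
        s0 = np.zeros(3)
        var = E.var(axis=0)
        if yes.any() and not yes.all():
            cov = (E[yes].mean(axis=0) - E[~yes].mean(axis=0))
            s0 = np.clip(4.0 * cov / np.maximum(var * 4, 0.05), -8, 8)
        return np.array([b0, *s0, a0, max(0.8 * min_rt, 0.06), 0.5])

    def predict_proba(self, X: pd.DataFrame, *, stimuli: pd.DataFrame) -> np.ndarray:
        """Model probability of a 'yes' for each trial row."""
        from .ddm import DDMSpec, choice_probability

        if not all(dim in stimuli.columns for dim in EVIDENCE_DIMS):
            stimuli = center_evidence(stimuli)
        ev = stimuli.set_index("stimulus_id")
        p = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            c = row["condition"]
            v = build_drift(self.params_, ev.loc[row["stimulus_id"]], c)
            p[i] = choice_probability(DDMSpec(
                v, self.params_.threshold[c], self.params_.start[c], self.params_.ndt[c]
            ))
        return p


def fit_subject(
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
    config: dict | None = None,
) -> tuple[PerceptionParameters, dict]:
    """Functional wrapper over :class:`PerceptionDDM` for one subject.

    Returns the fitted parameters and a diagnostics dict
    (loglik, convergence flag, usable trial counts, seed).
    """
    cfg = dict(config or {})
    est = PerceptionDDM(**cfg).fit(trials, stimuli=stimuli)
    diag = {
        "loglik": est.loglik_,
        "converged": est.converged_,
        "n_used": est.n_used_,
        "seed": est.random_state,
        "n_restarts": est.n_restarts,
    }
    return est.params_, diag


def fit_cohort_perception(
    trials: pd.DataFrame,
    stimuli: pd.DataFrame,
    config: dict | None = None,
    shrinkage: bool = False,
) -> dict[str, tuple[PerceptionParameters, dict]]:
    """Fit every subject in a trial table (column ``subject_id``).

    With ``shrinkage=True`` a two-stage empirical-Bayes MAP is used: normal
    priors whose hyper-mean/SD are the first-stage MLE moments across
    subjects (an explicit stand-in for full hierarchical pooling).
    """
    cfg = dict(config or {})
    stimuli = stimuli if all(d in stimuli.columns for d in EVIDENCE_DIMS) else center_evidence(stimuli)
    subjects = list(pd.unique(trials["subject_id"]))
    first = {
        s: fit_subject(trials[trials["subject_id"] == s], stimuli, cfg) for s in subjects
    }
    if not shrinkage or len(subjects) < 3:
        return first
    # stage 2: normal priors from first-stage moments, per condition
    prior = {}
    for cond in CONDITIONS:
        mat = np.array([
            [p.bias[cond], *[p.sensitivity[cond][d] for d in EVIDENCE_DIMS],
             p.threshold[cond], p.ndt[cond], p.start[cond]]
            for p, _ in first.values()
        ])
        mu = mat.mean(axis=0)
        sd = np.maximum(mat.std(axis=0, ddof=1), [0.1, 0.2, 0.2, 0.2, 0.1, 0.02, 0.02])
        prior[cond] = (mu, sd)
    cfg["prior"] = prior
    return {
        s: fit_subject(trials[trials["subject_id"] == s], stimuli, cfg) for s in subjects
    }


def extract_bias_sensitivity(params: PerceptionParameters) -> dict[str, float]:
    """Task-relevant projections: ``S_c = S[c][c]`` and the three biases."""
    out = {}
    for c in CONDITIONS:
        out[f"S_{c}"] = params.sensitivity[c][c]
    for c in CONDITIONS:
        out[f"Bias_{c}"] = params.bias[c]
    return out


def task_relevance_check(params: PerceptionParameters) -> dict[str, bool]:
    """Per condition: is the task-relevant sensitivity the largest one?"""
    return {
        c: all(
            params.sensitivity[c][c] > params.sensitivity[c][d]
            for d in EVIDENCE_DIMS if d != c
        )
        for c in CONDITIONS
    }
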