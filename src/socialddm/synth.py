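"""Seeded generators for both task designs and synthetic subject cohorts.

The generators emulate the statistical structure the analysis assumes:

* a 64-image normative-evidence table (Beta-distributed "yes" proportions
  with a configurable merit-need evidence correlation),
* the perception task design (64 stimuli x 3 judgment conditions = 192
  trials, 2 s response window),
* the altruism task design (300 trials = 5 runs x 3 partner blocks x 20
  trials; 100 trials per partner, half high-need with cues 80 +/- 4 and half
  low-need with cues 20 +/- 4; proposals $5-$35 plus $0-$4 jitter, mostly
  trade-off quadrants),
* subject-level parameter distributions centered on the reported group
  statistics, with cross-parameter couplings (merit bias/need bias
  correlation, merit sensitivity -> merit change parameters and an
  rTPJ-like neural covariate) that give the linking stage something to find,
* ground truth emitted alongside every dataset.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .altruism import (
    MERIT_LEVELS,
    NEED_LEVELS,
    WEIGHT_NAMES,
    AltruismParameters,
    compute_attributes,
    condition_weights,
)
from .ddm import DDMSpec, simulate_many
from .perception import CONDITIONS, EVIDENCE_DIMS, PerceptionParameters, center_evidence

__all__ = [
    "CohortConfig",
    "generate_normative_stimuli",
    "draw_cohort",
    "generate_perception_dataset",
    "generate_altruism_design",
    "generate_altruism_dataset",
    "generate_neural_covariate",
    "generate_linked_cohort",
]


def _default_perception() -> dict:
    return {
        # task-relevant sensitivities: reported group means +/- SD
        "S_mean": {"merit": 2.84, "need": 3.28, "control": 4.40},
        "S_sd": {"merit": 1.02, "need": 0.75, "control": 0.69},
        # task-irrelevant sensitivities: low but non-zero
        "S_offdiag_mean": 0.3,
        "S_offdiag_sd": 0.3,
        "bias_mean": {"merit": 0.33, "need": -0.17, "control": 0.09},
        "bias_sd": {"merit": 0.47, "need": 0.39, "control": 0.36},
        # reported merit-need bias intercorrelation
        "bias_merit_need_corr": 0.73,
        # nuisance DDM parameters (not reported; field-typical values)
        "a_mean": 1.5, "a_sd": 0.25,
        "ndt_mean": 0.35, "ndt_sd": 0.05,
        "w_mean": 0.5, "w_sd": 0.05,
        "rt_window": 2.0,
    }


def _default_altruism() -> dict:
    # baselines back-computed so the 6-cell mean weights equal the reported
    # overall means (w_self 0.97, w_other 0.22, w_fairness 0.35)
    return {
        "base_mean": {"w0": 0.15, "self": 1.1033, "other": 0.0117, "fairness": 0.4333},
        "base_sd": {"w0": 0.30, "self": 0.70, "other": 0.42, "fairness": 0.32},
        "dmh_mean": {"w0": 0.10, "self": -0.25, "other": 0.30, "fairness": 0.15},
        "dml_mean": {"w0": -0.10, "self": 0.15, "other": -0.20, "fairness": -0.10},
        "dnh_mean": {"w0": 0.05, "self": -0.20, "other": 0.35, "fairness": -0.20},
        "delta_sd": 0.18,
        "a_mean": 1.8, "a_sd": 0.3,
        "ndt_mean": 0.5, "ndt_sd": 0.1,
        "w_mean": 0.5, "w_sd": 0.05,
    }


def _default_coupling() -> dict:
    return {
        # corr between merit sensitivity and merit-induced weight changes
        "s_merit_delta": 0.7,
        # corr between merit bias and baseline other-regard
        "bias_merit_wother": 0.6,
        "rtpj_coupling": 1.0,
        "rtpj_noise_sd": 0.8,
    }


def _default_stimuli() -> dict:
    # Beta means set to the reported mean response rates; concentration 2
    # spans roughly 0.1-0.9 (a stimulus set built to include clear exemplars
    # at both ends of each judgment dimension)
    return {
        "mean": {"merit": 0.567, "need": 0.487, "control": 0.549},
        "concentration": 2.0,
        "merit_need_corr": 0.3,
    }


@dataclasses.dataclass
class CohortConfig:
    """Generator configuration: group means/SDs for every model parameter,
    cross-parameter couplings, stimulus-norm distribution and delay range."""

    n_subjects: int = 25
    perception: dict = dataclasses.field(default_factory=_default_perception)
    altruism: dict = dataclasses.field(default_factory=_default_altruism)
    coupling: dict = dataclasses.field(default_factory=_default_coupling)
    stimuli: dict = dataclasses.field(default_factory=_default_stimuli)
    delay_days: tuple[int, int] = (27, 663)

    def __post_init__(self) -> None:
        for grp in (self.perception, self.altruism):
            for k, v in grp.items():
                if k.endswith("_sd"):
                    vals = v.values() if isinstance(v, dict) else [v]
                    if any(x < 0 for x in vals):
                        raise ValueError(f"negative SD in {k}")
        for key in ("bias_merit_need_corr",):
            if not -1 <= self.perception[key] <= 1:
                raise ValueError(f"{key} must be a correlation in [-1, 1]")
        for key in ("s_merit_delta", "bias_merit_wother"):
            if not 0 <= self.coupling[key] <= 1:
                raise ValueError(f"coupling {key} must be in [0, 1]")
        if not -1 < self.stimuli["merit_need_corr"] < 1:
            raise ValueError("merit_need_corr must be in (-1, 1)")


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def generate_normative_stimuli(
    n_images: int = 64, config: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Normative "yes"-proportion table for ``n_images`` stimuli.

    Beta marginals through a Gaussian copula (the merit-need correlation is
    configurable; control is independent). Returns raw proportion columns
    plus the mean-centered evidence columns of
    :func:`~socialddm.perception.center_evidence`.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    cfg = {**_default_stimuli(), **(config or {})}
    rho = cfg["merit_need_corr"]
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    zs = rng.multivariate_normal(np.zeros(3), cov, size=n_images, method="cholesky")
    u = norm.cdf(zs)
    kappa = cfg["concentration"]
    cols = {}
    for j, dim in enumerate(EVIDENCE_DIMS):
        m = cfg["mean"][dim]
        a, b = m * kappa, (1.0 - m) * kappa
        cols[f"{dim}_prop"] = beta_dist.ppf(u[:, j], a, b)
    df = pd.DataFrame({"stimulus_id": [f"img{i:03d}" for i in range(n_images)], **cols})
    return center_evidence(df)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def draw_cohort(config: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Draw per-subject true parameters for both tasks plus covariates.

    Returns one row per subject with flat columns for all perception and
    altruism parameters, the rTPJ covariate and the inter-task delay.
    Parameter objects can be rebuilt with :func:`truth_to_params`.
    """
    p, alt, cpl = config.perception, config.altruism, config.coupling
    n = config.n_subjects
    rng = np.random.default_rng(seed)

    z_sm = rng.standard_normal(n)  # merit-sensitivity latent
    rho_b = p["bias_merit_need_corr"]
    z_bm = rng.standard_normal(n)  # merit-bias latent
    z_bn = rho_b * z_bm + np.sqrt(1 - rho_b**2) * rng.standard_normal(n)

    rows: dict[str, np.ndarray] = {"subject_id": np.array([f"s{i:03d}" for i in range(n)])}

    # perception parameters
    for c in CONDITIONS:
        lat = z_sm if c == "merit" else rng.standard_normal(n)
        for d in EVIDENCE_DIMS:
            if c == d:
                vals = p["S_mean"][c] + p["S_sd"][c] * lat
            else:
                vals = rng.normal(p["S_offdiag_mean"], p["S_offdiag_sd"], n)
            rows[f"S_{d}|{c}"] = vals
        blat = {"merit": z_bm, "need": z_bn}.get(c, rng.standard_normal(n))
        rows[f"Bias_{c}"] = p["bias_mean"][c] + p["bias_sd"][c] * blat
        rows[f"a_{c}"] = np.clip(rng.normal(p["a_mean"], p["a_sd"], n), 0.6, 4.0)
        rows[f"ndt_{c}"] = np.clip(rng.normal(p["ndt_mean"], p["ndt_sd"], n), 0.1, 0.8)
        rows[f"z_{c}"] = np.clip(rng.normal(p["w_mean"], p["w_sd"], n), 0.2, 0.8)

    # altruism parameters: merit-responsiveness latent coupled to S_merit
    q = cpl["s_merit_delta"]
    z_m = q * z_sm + np.sqrt(1 - q**2) * rng.standard_normal(n)
    qb = cpl["bias_merit_wother"]
    z_bw = qb * z_bm + np.sqrt(1 - qb**2) * rng.standard_normal(n)
    sd = alt["delta_sd"]
    mix = 0.7  # share of delta variance carried by the responsiveness latent

    for k in WEIGHT_NAMES:
        blat = z_bw if k == "other" else rng.standard_normal(n)
        rows[f"base_{k}"] = alt["base_mean"][k] + alt["base_sd"][k] * blat
        # merit deltas load on z_m with the sign of their group-mean effect,
        # in opposite directions for the high vs. low partner
        sgn = np.sign(alt["dmh_mean"][k]) or 1.0
        noise = np.sqrt(1 - mix**2)
        rows[f"dmh_{k}"] = alt["dmh_mean"][k] + sd * (
            mix * sgn * z_m + noise * rng.standard_normal(n)
        )
        rows[f"dml_{k}"] = alt["dml_mean"][k] + sd * (
            -mix * sgn * z_m + noise * rng.standard_normal(n)
        )
        rows[f"dnh_{k}"] = rng.normal(alt["dnh_mean"][k], sd, n)
    rows["alt_a"] = np.clip(rng.normal(alt["a_mean"], alt["a_sd"], n), 0.6, 4.0)
    rows["alt_ndt"] = np.clip(rng.normal(alt["ndt_mean"], alt["ndt_sd"], n), 0.1, 1.0)
    rows["alt_z"] = np.clip(rng.normal(alt["w_mean"], alt["w_sd"], n), 0.2, 0.8)

    rows["rTPJ_beta"] = generate_neural_covariate(
        rows["S_merit|merit"], cpl["rtpj_coupling"], cpl["rtpj_noise_sd"],
        seed=int(rng.integers(2**31)),
    )
    rows["inter_task_delay_days"] = rng.integers(
        config.delay_days[0], config.delay_days[1] + 1, n
    )
    return pd.DataFrame(rows)


def truth_to_params(row: pd.Series) -> tuple[PerceptionParameters, AltruismParameters]:
    """Rebuild parameter objects from one truth-table row."""
    pp = PerceptionParameters(
        sensitivity={c: {d: float(row[f"S_{d}|{c}"]) for d in EVIDENCE_DIMS}
                     for c in CONDITIONS},
        bias={c: float(row[f"Bias_{c}"]) for c in CONDITIONS},
        threshold={c: float(row[f"a_{c}"]) for c in CONDITIONS},
        ndt={c: float(row[f"ndt_{c}"]) for c in CONDITIONS},
        start={c: float(row[f"z_{c}"]) for c in CONDITIONS},
    )
    ap = AltruismParameters(
        base={k: float(row[f"base_{k}"]) for k in WEIGHT_NAMES},
        delta_merit_high={k: float(row[f"dmh_{k}"]) for k in WEIGHT_NAMES},
        delta_merit_low={k: float(row[f"dml_{k}"]) for k in WEIGHT_NAMES},
        delta_need_high={k: float(row[f"dnh_{k}"]) for k in WEIGHT_NAMES},
        threshold=float(row["alt_a"]), ndt=float(row["alt_ndt"]),
        start=float(row["alt_z"]),
    )
    return pp, ap


def generate_neural_covariate(
    s_merit, coupling: float = 1.0, noise_sd: float = 0.8, seed: int = 0
) -> np.ndarray:
    """rTPJ-like covariate: coupling x standardized(S_merit) + noise."""
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    s = np.asarray(s_merit, dtype=float)
    sd = s.std()
    zs = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    rng = np.random.default_rng(seed)
    return coupling * zs + rng.normal(0.0, noise_sd, len(s))


# ---------------------------------------------------------------------------
# perception dataset
# ---------------------------------------------------------------------------

def generate_perception_dataset(
    cohort: pd.DataFrame | Iterable[PerceptionParameters],
    stimuli: pd.DataFrame,
    seed: int = 0,
    rt_window: float = 2.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate the perception task (64 stimuli x 3 conditions per subject).

    ``cohort`` is a truth table from :func:`draw_cohort` (or a list of
    parameter objects). Trials whose simulated RT exceeds the response
    window are marked missing (NaN response/rt, ``timed_out`` True) but
    never dropped.
    """
    if isinstance(cohort, pd.DataFrame):
        subjects = [(r["subject_id"], truth_to_params(r)[0]) for _, r in cohort.iterrows()]
    else:
        subjects = [(f"s{i:03d}", p) for i, p in enumerate(cohort)]
    if not all(d in stimuli.columns for d in EVIDENCE_DIMS):
        stimuli = center_evidence(stimuli)
    E = stimuli[list(EVIDENCE_DIMS)].to_numpy(dtype=float)
    sids = stimuli["stimulus_id"].to_numpy()
    ss = np.random.SeedSequence(seed)
    frames = []
    for (subj, params), child in zip(subjects, ss.spawn(len(subjects))):
        sub_seeds = child.generate_state(len(CONDITIONS))
        for c, cseed in zip(CONDITIONS, sub_seeds):
            s_vec = np.array([params.sensitivity[c][d] for d in EVIDENCE_DIMS])
            v = params.bias[c] + E @ s_vec
            spec = DDMSpec(0.0, params.threshold[c], params.start[c], params.ndt[c])
            b, rt = simulate_many(spec, v=v, seed=int(int(cseed) % (2**32)), dt=dt)
            resp = np.where(b == 1, "yes", "no").astype(object)
            timed_out = ~(rt <= rt_window) | (b < 0)
            resp[timed_out] = None
            rt = np.where(timed_out, np.nan, rt)
            frames.append(pd.DataFrame({
                "subject_id": subj, "stimulus_id": sids, "condition": c,
                "response": resp, "rt": rt, "timed_out": timed_out,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# altruism design + dataset
# ---------------------------------------------------------------------------

_PARTNER_MERIT = {"P1": "high", "P2": "unknown", "P3": "low"}
_BELOW = np.array([5, 8, 11, 14, 17])
_ABOVE = np.array([23, 26, 29, 32, 35])


def generate_altruism_design(
    seed: int = 0,
    order_index: int = 0,
    tradeoff_share: float = 0.75,
    jitter_band: int = 4,
) -> pd.DataFrame:
    """One subject's altruism-task design (no behavior).

    300 trials = 5 runs x 3 partner blocks x 20 trials (100 per partner,
    partner-block order rotated by ``order_index`` for counterbalancing).
    Per partner, 50 high-need and 50 low-need trials in random order; need
    cues are 80 or 20 plus a symmetric integer jitter on [-4, +4]. Base
    proposals come from a $5-$35 grid emphasizing trade-off quadrants and
    receive a $0-$4 jitter.
    """
    rng = np.random.default_rng(seed)
    partners = list(_PARTNER_MERIT)
    # need schedule: per partner, 50 high / 50 low shuffled
    need_by_partner = {}
    for pid in partners:
        lv = np.array(["high"] * 50 + ["low"] * 50, dtype=object)
        rng.shuffle(lv)
        need_by_partner[pid] = iter(lv)

    rows = []
    trial = 0
    for run in range(1, 6):
        order = np.roll(partners, order_index + run - 1)
        for pid in order:
            for _ in range(20):
                need = next(need_by_partner[pid])
                cue = (80 if need == "high" else 20) + int(
                    rng.integers(-jitter_band, jitter_band + 1)
                )
                # quadrant-weighted base proposal, then $0-$4 jitter
                u = rng.random()
                if u < tradeoff_share / 2:
                    s, o = rng.choice(_BELOW), rng.choice(_ABOVE)
                elif u < tradeoff_share:
                    s, o = rng.choice(_ABOVE), rng.choice(_BELOW)
                elif u < tradeoff_share + (1 - tradeoff_share) / 2:
                    s, o = rng.choice(_BELOW), rng.choice(_BELOW)
                else:
                    s, o = rng.choice(_ABOVE), rng.choice(_ABOVE)
                trial += 1
                rows.append({
                    "trial": trial, "run": run, "partner": pid,
                    "partner_merit": _PARTNER_MERIT[pid], "need_level": need,
                    "need_cue_pct": cue,
                    "offer_self": int(s + rng.integers(0, 5)),
                    "offer_other": int(o + rng.integers(0, 5)),
                })
    return pd.DataFrame(rows)


def generate_altruism_dataset(
    cohort: pd.DataFrame | Iterable[AltruismParameters],
    design: pd.DataFrame,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate accept/reject choices and RTs for every subject on a design."""
    if isinstance(cohort, pd.DataFrame):
        subjects = [(r["subject_id"], truth_to_params(r)[1]) for _, r in cohort.iterrows()]
    else:
        subjects = [(f"s{i:03d}", p) for i, p in enumerate(cohort)]
    s_att, o_att, f_att = compute_attributes(
        design["offer_self"].to_numpy(), design["offer_other"].to_numpy()
    )
    X = np.column_stack([np.ones(len(design)), s_att, o_att, f_att])
    cell_keys = list(zip(design["partner_merit"], design["need_level"]))
    ss = np.random.SeedSequence(seed)
    frames = []
    for (subj, params), child in zip(subjects, ss.spawn(len(subjects))):
        wmat = {
            (m, n): condition_weights(params, m, n)
            for m in MERIT_LEVELS for n in NEED_LEVELS
        }
        v = np.array([float(X[i] @ wmat[cell_keys[i]]) for i in range(len(design))])
        spec = DDMSpec(0.0, params.threshold, params.start, params.ndt)
        b, rt = simulate_many(
            spec, v=v, seed=int(int(child.generate_state(1)[0]) % (2**32)), dt=dt
        )
        df = design.copy()
        df.insert(0, "subject_id", subj)
        df["response"] = np.where(b == 1, "accept", "reject")
        df["rt"] = rt
        df["converged"] = b >= 0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_linked_cohort(config: CohortConfig | None = None, seed: int = 0) -> dict:
    """End-to-end synthetic bundle: stimuli, truth table, both trial tables.

    Partner-block order is counterbalanced across subjects (order index =
    subject number mod 3); proposal/cue jitters are redrawn per subject.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    s_stim, s_cohort, s_perc, s_alt, s_design = ss.generate_state(5) % (2**31)
    stimuli = generate_normative_stimuli(seed=int(s_stim))
    truth = draw_cohort(config, seed=int(s_cohort))
    perception = generate_perception_dataset(truth, stimuli, seed=int(s_perc))
    d_ss = np.random.SeedSequence(int(s_design))
    frames = []
    for i, child in enumerate(d_ss.spawn(config.n_subjects)):
        frames.append(generate_altruism_design(
            seed=int(int(child.generate_state(1)[0]) % (2**31)), order_index=i % 3
        ))
    altruism = []
    for (_, row), design in zip(truth.iterrows(), frames):
        altruism.append(generate_altruism_dataset(
            truth[truth["subject_id"] == row["subject_id"]], design,
            seed=int((int(s_alt) + abs(hash(row["subject_id"]))) % (2**31)),
        ))
    return {
        "config": config,
        "stimuli": stimuli,
        "truth": truth,
        "perception_trials": perception,
        "altruism_trials": pd.concat(altruism, ignore_index=True),
    }
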