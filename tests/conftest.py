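import numpy as np
import pandas as pd
import pytest

from socialddm.perception import CONDITIONS, EVIDENCE_DIMS, PerceptionParameters
from socialddm.synth import generate_normative_stimuli


@pytest.fixture(scope="session")
def stimuli():
    return generate_normative_stimuli(seed=1)


@pytest.fixture(scope="session")
def group_mean_perception_params():
    """One subject at the reported group-mean parameter values."""
    s_diag = {"merit": 2.84, "need": 3.28, "control": 4.40}
    return PerceptionParameters(
        sensitivity={
            c: {d: (s_diag[c] if c == d else 0.3) for d in EVIDENCE_DIMS}
            for c in CONDITIONS
        },
        bias={"merit": 0.33, "need": -0.17, "control": 0.09},
        threshold={c: 1.5 for c in CONDITIONS},
        ndt={c: 0.35 for c in CONDITIONS},
        start={c: 0.5 for c in CONDITIONS},
    )


def simulate_glmm_trials(
    n_subjects, n_trials, beta_need=0.0, beta_merit_high=0.0,
    beta_merit_unknown=0.0, intercept=-0.5, re_sd=0.8, seed=0,
):
    """Direct logistic simulation of generous/selfish choices (no DDM):
    the generating model is exactly the random-intercept logistic the
    mixed model assumes, so it serves as a calibration oracle."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subjects):
        u = rng.normal(0.0, re_sd)
        need = rng.choice(["high", "low"], n_trials)
        merit = rng.choice(["high", "unknown", "low"], n_trials)
        eta = (
            intercept + u
            + beta_need * (need == "high")
            + beta_merit_high * (merit == "high")
            + beta_merit_unknown * (merit == "unknown")
        )
        y = rng.random(n_trials) < 1.0 / (1.0 + np.exp(-eta))
        rows.append(pd.DataFrame({
            "subject_id": f"s{j:03d}", "need_level": need,
            "partner_merit": merit, "generous": y.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)
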