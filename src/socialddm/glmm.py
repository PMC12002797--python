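"""Random-intercept logistic regression of generous choice.

The trial-level model is

    GenerousChoice ~ 1 + Need + Merit + Need x Merit + (1 | Participant)

with dummy coding (reference: low need, low merit) and a participant random
intercept. The marginal likelihood is maximized with adaptive Gauss-Hermite
quadrature centered on each participant's posterior mode (one node recovers
the Laplace approximation); likelihood-ratio chi-squares compare the full
model against the intercept-plus-random-effect null and against the
main-effects-only model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["GenerosityGLMM", "fit_generosity_glmm", "glmm_design"]

_FULL_TERMS = [
    "Intercept", "need_high", "merit_unknown", "merit_high",
    "need_high:merit_unknown", "need_high:merit_high",
]


def glmm_design(trials: pd.DataFrame, interaction: bool = True) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded fixed-effects design (reference: low need, low merit)."""
    nh = (trials["need_level"] == "high").to_numpy(dtype=float)
    mu = (trials["partner_merit"] == "unknown").to_numpy(dtype=float)
    mh = (trials["partner_merit"] == "high").to_numpy(dtype=float)
    cols = [np.ones(len(trials)), nh, mu, mh]
    names = _FULL_TERMS[:4]
    if interaction:
        cols += [nh * mu, nh * mh]
        names = list(_FULL_TERMS)
    return np.column_stack(cols), names


class GenerosityGLMM:
    """ML fit of a random-intercept logistic model via adaptive quadrature.

    Parameters
    ----------
    n_quad : int
        Gauss-Hermite nodes (1 = Laplace approximation).
    interaction : bool
        Include the Need x Merit interaction terms.

    Attributes
    ----------
    fe_params_ : pd.Series        fixed effects (log-odds)
    fe_se_, fe_ci_ : Wald SEs and 95% CIs
    re_sd_ : float                random-intercept SD
    loglik_ : float
    r2_marginal_, r2_conditional_ : latent-scale pseudo-R2
    separation_flag_ : bool       |beta| near bounds (quasi-separation)
    """

    def __init__(self, n_quad: int = 15, interaction: bool = True, ridge: float = 0.0):
        self.n_quad = n_quad
        self.interaction = interaction
        self.ridge = ridge

    # -- marginal log-likelihood -------------------------------------------
    def _loglik(self, theta, X, y, groups_idx):
        beta, log_sd = theta[:-1], theta[-1]
        sd = np.exp(log_sd)
        eta = X @ beta
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        ll = 0.0
        for idx in groups_idx:
            e, yy = eta[idx], y[idx]
            # posterior mode of the scaled intercept u ~ N(0,1) by Newton
            u = 0.0
            for _ in range(25):
                p = expit(e + sd * u)
                g = sd * np.sum(yy - p) - u
                h = -(sd**2) * np.sum(p * (1 - p)) - 1.0
                step = g / h
                u -= step
                if abs(step) < 1e-9:
                    break
            p = expit(e + sd * u)
            shat = 1.0 / np.sqrt((sd**2) * np.sum(p * (1 - p)) + 1.0)
            uk = u + np.sqrt(2.0) * shat * nodes
            eta_k = e[:, None] + sd * uk[None, :]
            # log p and log(1-p) via logaddexp: finite for any eta
            logf = np.sum(
                np.where(yy[:, None] > 0,
                         -np.logaddexp(0.0, -eta_k),
                         -np.logaddexp(0.0, eta_k)),
                axis=0,
            ) - 0.5 * uk**2
            ll += (
                logsumexp(logf + nodes**2 + np.log(weights))
                + np.log(np.sqrt(2.0) * shat)
                - 0.5 * np.log(2.0 * np.pi)
            )
        if self.ridge:
            ll -= 0.5 * self.ridge * np.sum(beta**2)
        return ll

    def fit(self, trials: pd.DataFrame, y_col: str = "generous"):
        need = set(trials["need_level"].unique())
        merit = set(trials["partner_merit"].unique())
        if need != {"high", "low"} or merit != {"high", "unknown", "low"}:
            raise ValueError(
                f"all factor levels must be present; got need={sorted(need)}, "
                f"merit={sorted(merit)}"
            )
        if trials["subject_id"].nunique() < 2:
            raise ValueError("at least 2 subjects required")
        X, names = glmm_design(trials, self.interaction)
        y = trials[y_col].to_numpy(dtype=float)
        codes = pd.factorize(trials["subject_id"].to_numpy())[0]
        groups_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]

        k = X.shape[1]
        x0 = np.zeros(k + 1)
        x0[0] = np.log(max(y.mean(), 0.02) / max(1 - y.mean(), 0.02))
        x0[-1] = np.log(0.5)
        res = minimize(
            lambda t: -self._loglik(t, X, y, groups_idx), x0, method="L-BFGS-B",
            bounds=[(-15, 15)] * k + [(np.log(1e-4), np.log(10.0))],
        )
        theta = res.x
        self.separation_flag_ = bool(np.any(np.abs(theta[:-1]) > 10))
        if self.separation_flag_ and self.ridge == 0.0:
            # penalized-likelihood fallback under (quasi-)separation
            self.ridge = 1e-2
            res = minimize(
                lambda t: -self._loglik(t, X, y, groups_idx), x0, method="L-BFGS-B",
                bounds=[(-15, 15)] * k + [(np.log(1e-4), np.log(10.0))],
            )
            theta = res.x
            self.ridge = 0.0
            self.penalized_ = True
        else:
            self.penalized_ = False

        self.theta_ = theta
        self.loglik_ = float(self._loglik(theta, X, y, groups_idx))
        self.fe_params_ = pd.Series(theta[:-1], index=names)
        self.re_sd_ = float(np.exp(theta[-1]))
        H = approx_hess1(theta, lambda t: -self._loglik(t, X, y, groups_idx))
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(k, np.nan)
        self.fe_se_ = pd.Series(se, index=names)
        zc = norm.ppf(0.975)
        self.fe_ci_ = pd.DataFrame(
            {"lo": theta[:-1] - zc * se, "hi": theta[:-1] + zc * se}, index=names
        )
        # latent-scale pseudo-R2 (Nakagawa marginal / conditional)
        var_f = float(np.var(X @ theta[:-1]))
        denom = var_f + self.re_sd_**2 + np.pi**2 / 3.0
        self.r2_marginal_ = var_f / denom
        self.r2_conditional_ = (var_f + self.re_sd_**2) / denom
        self.n_obs_ = len(y)
        self.n_groups_ = len(groups_idx)
        return self


def _lrt(ll_full: float, ll_red: float, df: int) -> dict:
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    return {"chi2": stat, "df": df, "p": float(chi2.sf(stat, df))}


def fit_generosity_glmm(trials: pd.DataFrame, y_col: str = "generous", n_quad: int = 15) -> dict:
    """Fit the full, main-effects and null models and report estimates + LRTs.

    Returns a dict with fixed effects (log-odds), 95% CIs, random-intercept
    SD, marginal/conditional pseudo-R2, and likelihood-ratio tests of the
    full model vs. the random-intercept-only null and of the interaction
    vs. the main-effects model.
    """
    full = GenerosityGLMM(n_quad=n_quad, interaction=True).fit(trials, y_col)
    main = GenerosityGLMM(n_quad=n_quad, interaction=False).fit(trials, y_col)
    null_df = trials.copy()
    Xn = np.ones((len(trials), 1))
    # null = intercept + random effect: reuse the machinery with a 1-column design
    null = GenerosityGLMM(n_quad=n_quad, interaction=False)
    y = trials[y_col].to_numpy(dtype=float)
    codes = pd.factorize(trials["subject_id"].to_numpy())[0]
    groups_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    res = minimize(
        lambda t: -null._loglik(t, Xn, y, groups_idx),
        np.array([0.0, np.log(0.5)]), method="L-BFGS-B",
        bounds=[(-15, 15), (np.log(1e-4), np.log(10.0))],
    )
    ll_null = float(-res.fun)
    return {
        "fixed_effects": full.fe_params_.to_dict(),
        "se": full.fe_se_.to_dict(),
        "ci95": {k: (float(full.fe_ci_.loc[k, "lo"]), float(full.fe_ci_.loc[k, "hi"]))
                 for k in full.fe_params_.index},
        "re_sd": full.re_sd_,
        "r2_marginal": full.r2_marginal_,
        "r2_conditional": full.r2_conditional_,
        "loglik_full": full.loglik_,
        "loglik_main": main.loglik_,
        "loglik_null": ll_null,
        "lrt_full_vs_null": _lrt(full.loglik_, ll_null, full.fe_params_.size - 1),
        "lrt_interaction": _lrt(full.loglik_, main.loglik_, 2),
        "separation_flag": full.separation_flag_ or main.separation_flag_,
        "n_obs": full.n_obs_,
        "n_subjects": full.n_groups_,
    }
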