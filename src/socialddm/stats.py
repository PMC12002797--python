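"""Individual-differences statistics linking perception to altruistic action.

Wilcoxon condition contrasts on attribute weights, Spearman correlation
batteries with Benjamini-Hochberg FDR within declared families, single-pass
3-SD outlier screening, OLS linking regressions (behavioral sensitivity +
neural covariate), and rank-based partial correlations. The mixed logistic
model of generous choice lives in :mod:`socialddm.glmm`.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .glmm import GenerosityGLMM, fit_generosity_glmm  # noqa: F401  (re-export)

__all__ = [
    "remove_outliers_3sd",
    "benjamini_hochberg",
    "spearman",
    "spearman_fdr",
    "partial_spearman",
    "weight_condition_contrasts",
    "linking_regression",
    "fit_generosity_glmm",
    "GenerosityGLMM",
]


def remove_outliers_3sd(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of points more than 3 SD from the mean.

    Mean and SD are computed once on the full vector (no iteration); a
    zero-variance vector is returned unchanged. Returns
    ``(filtered_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    z = np.abs(x - x.mean()) > 3.0 * sd
    return x[~z], np.flatnonzero(z)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (thin wrapper over statsmodels)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Two-tailed p by exact permutation enumeration for n <= 8, otherwise
    the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(rx_c @ ry_c[list(perm)])
            count += stat >= obs - 1e-12
            total += 1
        return r, count / total
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-12))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def spearman_fdr(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    screen: bool = True,
) -> pd.DataFrame:
    """Spearman battery with BH adjustment within the declared family.

    ``pairs`` maps a label to an aligned (x, y) pair; each variable is
    screened by the single-pass 3-SD rule (a subject removed in either
    member of a pair is removed from that pair) unless ``screen=False``.
    """
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if screen:
            _, bad_x = remove_outliers_3sd(x)
            _, bad_y = remove_outliers_3sd(y)
            keep = np.setdiff1d(np.arange(len(x)), np.union1d(bad_x, bad_y))
            x, y = x[keep], y[keep]
        if len(x) < 5:
            raise ValueError(f"{name}: fewer than 5 subjects after screening")
        r, p = spearman(x, y)
        rows.append({"pair": name, "r": r, "p": p, "n": len(x)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def partial_spearman(x, y, control) -> tuple[float, float]:
    """Partial rank correlation of x and y controlling for one covariate.

    Spearman correlation of the residuals of rank(x) and rank(y) after
    linear regression on rank(control); a constant control reduces to the
    plain Spearman correlation (flagged by a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(x)
    if n < 6 or len(y) != n or len(c) != n:
        raise ValueError("need aligned vectors of length >= 6")
    if np.std(c) == 0:
        import warnings

        warnings.warn("constant control variable; returning plain Spearman")
        return spearman(x, y)
    rx, ry, rc = sps.rankdata(x), sps.rankdata(y), sps.rankdata(c)
    C = np.column_stack([np.ones(n), rc])
    res_x = rx - C @ np.linalg.lstsq(C, rx, rcond=None)[0]
    res_y = ry - C @ np.linalg.lstsq(C, ry, rcond=None)[0]
    r = float(np.corrcoef(res_x, res_y)[0, 1])
    t = r * math.sqrt((n - 3) / max(1.0 - r * r, 1e-12))
    p = 2.0 * sps.t.sf(abs(t), n - 3)
    return r, float(min(p, 1.0))


def weight_condition_contrasts(weights: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of paired condition-resolved weights.

    ``weights`` has one row per subject and columns
    ``{attr}_merit_high, {attr}_merit_low, {attr}_need_high, {attr}_need_low``
    for attr in self/other/fairness. Six contrasts (3 attributes x 2
    manipulations), exact distribution for n <= 25 without ties, BH-adjusted
    as one family. All-zero differences are reported as p = 1 and flagged.
    """
    rows = []
    for attr in ("self", "other", "fairness"):
        for manip in ("merit", "need"):
            hi = weights[f"{attr}_{manip}_high"].to_numpy(dtype=float)
            lo = weights[f"{attr}_{manip}_low"].to_numpy(dtype=float)
            d = hi - lo
            if np.allclose(d, 0):
                rows.append({
                    "attribute": attr, "manipulation": manip,
                    "median_diff": 0.0, "stat": np.nan, "p": 1.0,
                    "undefined": True,
                })
                continue
            n = len(d)
            method = "exact" if (n <= 25 and not np.any(d == 0)
                                 and len(np.unique(np.abs(d))) == n) else "approx"
            res = sps.wilcoxon(hi, lo, method=method)
            rows.append({
                "attribute": attr, "manipulation": manip,
                "median_diff": float(np.median(d)),
                "stat": float(res.statistic), "p": float(res.pvalue),
                "undefined": False,
            })
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def linking_regression(y, s_merit, rtpj) -> dict:
    """OLS of a change score on merit sensitivity and the rTPJ covariate.

    ``y ~ 1 + S_merit + rTPJ`` with intercept; reports coefficients, SEs,
    95% CIs, t and two-tailed p per term, R-squared, the F test against the
    intercept-only model, and a collinearity flag when the two predictors
    correlate above |r| = 0.99.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s_merit, dtype=float)
    r = np.asarray(rtpj, dtype=float)
    if np.isnan(y).any() or np.isnan(s).any() or np.isnan(r).any():
        raise ValueError("missing values must be screened before regression")
    X = sm.add_constant(np.column_stack([s, r]))
    collinear = bool(abs(np.corrcoef(s, r)[0, 1]) > 0.99)
    fit = sm.OLS(y, X).fit()
    names = ["Intercept", "S_merit", "rTPJ"]
    ci = fit.conf_int(alpha=0.05)
    return {
        "coef": dict(zip(names, map(float, fit.params))),
        "se": dict(zip(names, map(float, fit.bse))),
        "ci95": {nm: (float(ci[i][0]), float(ci[i][1])) for i, nm in enumerate(names)},
        "t": dict(zip(names, map(float, fit.tvalues))),
        "p": dict(zip(names, map(float, fit.pvalues))),
        "r2": float(fit.rsquared),
        "f_vs_intercept": {"F": float(fit.fvalue), "p": float(fit.f_pvalue),
                           "df": (int(fit.df_model), int(fit.df_resid))},
        "collinearity_flag": collinear,
        "n": len(y),
    }
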