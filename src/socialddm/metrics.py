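"""Model-free behavioral quantities for the altruism task.

Generosity classification and fractions, the cold-pressor (CPT) buy-out
rule, and data-quality exclusions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .altruism import MERIT_LEVELS, NEED_LEVELS

__all__ = [
    "classify_generous",
    "generosity_fractions",
    "GenerosityTable",
    "buyout_probability",
    "qc_exclusions",
]

_ACCEPT = ("accept", "yes", "1", "true")


@dataclasses.dataclass
class GenerosityTable:
    """Per-subject generosity summary: overall fraction, fraction and trial
    count per merit x need cell, and the count of unclassifiable
    (equal-payoff) trials."""

    overall: float
    cells: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], int]
    n_unclassifiable: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": "overall", "fraction": self.overall,
                 "n": sum(self.counts.values())}]
        for (m, n), frac in self.cells.items():
            rows.append({"condition": f"merit_{m}/need_{n}", "fraction": frac,
                         "n": self.counts[(m, n)]})
        return pd.DataFrame(rows)


def classify_generous(response: str, offer_self: float, offer_other: float):
    """Classify one choice as generous (1), selfish (0) or unclassifiable.

    Generous: accepting a proposal with $Self < $Other, or rejecting one
    with $Self > $Other. Equal-payoff proposals involve no trade-off and
    return ``None``.
    """
    accept = str(response).lower() in _ACCEPT
    if offer_self == offer_other:
        return None
    favors_other = offer_self < offer_other
    return int(accept == favors_other)


def _classify_vec(df: pd.DataFrame) -> np.ndarray:
    accept = df["response"].astype(str).str.lower().isin(_ACCEPT).to_numpy()
    s = df["offer_self"].to_numpy(dtype=float)
    o = df["offer_other"].to_numpy(dtype=float)
    out = np.where(accept == (s < o), 1.0, 0.0)
    out[s == o] = np.nan
    return out


def generosity_fractions(trials: pd.DataFrame) -> GenerosityTable:
    """Overall and per merit x need cell fractions of generous choices.

    Equal-payoff trials are excluded from every fraction and counted
    separately; an empty cell yields a NaN fraction with a warning.
    """
    g = _classify_vec(trials)
    n_uncl = int(np.isnan(g).sum())
    overall = float(np.nanmean(g)) if np.isfinite(g).any() else float("nan")
    cells, counts = {}, {}
    for m in MERIT_LEVELS:
        for n in NEED_LEVELS:
            mask = (
                (trials["partner_merit"] == m) & (trials["need_level"] == n)
            ).to_numpy()
            gi = g[mask]
            k = int(np.isfinite(gi).sum())
            counts[(m, n)] = k
            if k == 0:
                import warnings

                warnings.warn(f"no classifiable trials in cell merit={m}, need={n}")
                cells[(m, n)] = float("nan")
            else:
                cells[(m, n)] = float(np.nanmean(gi))
    return GenerosityTable(overall, cells, counts, n_uncl)


def buyout_probability(p0: float, dollars: float) -> float:
    """CPT probability (in %) left after spending ``dollars``.

    Each dollar subtracts 10 percentage points; clamped at 0.
    """
    if dollars < 0:
        raise ValueError("dollars must be >= 0")
    if not 0 <= p0 <= 100:
        raise ValueError("p0 must be a percentage in [0, 100]")
    return max(0.0, p0 - 10.0 * dollars)


def qc_exclusions(
    trials: pd.DataFrame,
    invariant_threshold: float = 0.90,
    min_trials: int = 50,
    response_col: str = "response",
) -> pd.DataFrame:
    """Per-subject keep/drop flags.

    Subjects are dropped for invariant responding (the modal response on
    strictly more than ``invariant_threshold`` of trials — boundary ties are
    kept) or for fewer than ``min_trials`` trials. Deterministic report with
    one row per subject and a ``reason`` column.
    """
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        n = len(sub)
        frac_modal = sub[response_col].value_counts(normalize=True).max() if n else 1.0
        keep, reason = True, ""
        if n < min_trials:
            keep, reason = False, f"too few trials ({n} < {min_trials})"
        elif frac_modal > invariant_threshold:
            keep, reason = False, "invariant responding"
        rows.append({
            "subject_id": sid, "n_trials": n,
            "modal_response_fraction": float(frac_modal),
            "keep": keep, "reason": reason,
        })
    return pd.DataFrame(rows)
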