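"""Config-driven end-to-end runs: generate -> fit -> summarize -> link.

``run_pipeline`` executes the full analysis on either synthetic data (the
default) or user-supplied trial tables, writing per-subject parameter JSONs,
a subject-summary CSV, the generosity table, a statistics JSON and a
human-readable text report. Every artifact records the master seed; the
report embeds a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as lstats
from .altruism import fit_cohort_altruism, change_scores
from .metrics import generosity_fractions, qc_exclusions
from .perception import extract_bias_sensitivity, fit_cohort_perception, center_evidence
from .synth import CohortConfig, generate_linked_cohort

logger = logging.getLogger("socialddm")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "build_subject_summary"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration.

    ``perception_trials``/``altruism_trials``/``stimuli`` are file paths
    (CSV/TSV) or None for synthetic mode. Fitting options are forwarded to
    the estimators; FDR families and alpha parameterize the linking stage.
    """

    out_dir: str = "socialddm_out"
    seed: int = 0
    n_subjects: int = 25
    perception_trials: str | None = None
    altruism_trials: str | None = None
    stimuli: str | None = None
    n_restarts: int = 3
    shrinkage: bool = False
    alpha: float = 0.05
    run_perception: bool = True
    run_altruism: bool = True

    def config_hash(self) -> str:
        # output location does not affect the analysis
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _read_table(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def validate_inputs(tables: dict[str, pd.DataFrame]) -> dict:
    """Schema/range checks for input tables.

    Returns ``{"hard": [...], "soft": [...], "ok": bool}``; hard violations
    (negative RTs, unknown factor levels, missing columns) should abort a
    run, soft ones (need cues outside the jitter bands) only warn.
    """
    hard: list[str] = []
    soft: list[str] = []
    if "stimuli" in tables:
        st = tables["stimuli"]
        for col in ("stimulus_id", "merit_prop", "need_prop", "control_prop"):
            if col not in st.columns:
                hard.append(f"stimuli: missing column {col}")
        for col in ("merit_prop", "need_prop", "control_prop"):
            if col in st.columns and ((st[col] < 0) | (st[col] > 1)).any():
                hard.append(f"stimuli: {col} outside [0, 1]")
    if "perception" in tables:
        tr = tables["perception"]
        for col in ("subject_id", "stimulus_id", "condition", "response", "rt"):
            if col not in tr.columns:
                hard.append(f"perception: missing column {col}")
        if "rt" in tr.columns and (tr["rt"].dropna() <= 0).any():
            hard.append("perception: non-positive rt")
        if "condition" in tr.columns:
            bad = set(tr["condition"].dropna()) - {"merit", "need", "control"}
            if bad:
                hard.append(f"perception: unknown conditions {sorted(bad)}")
    if "altruism" in tables:
        tr = tables["altruism"]
        for col in ("subject_id", "partner_merit", "need_level", "offer_self",
                    "offer_other", "response", "rt"):
            if col not in tr.columns:
                hard.append(f"altruism: missing column {col}")
        if "rt" in tr.columns and (tr["rt"].dropna() <= 0).any():
            hard.append("altruism: non-positive rt")
        if "partner_merit" in tr.columns:
            bad = set(tr["partner_merit"].dropna()) - {"high", "unknown", "low"}
            if bad:
                hard.append(f"altruism: unknown merit levels {sorted(bad)}")
        for col in ("offer_self", "offer_other"):
            if col in tr.columns and (tr[col] < 0).any():
                hard.append(f"altruism: negative {col}")
        if {"need_level", "need_cue_pct"} <= set(tr.columns):
            hi = tr["need_level"] == "high"
            out_band = (
                (hi & ~tr["need_cue_pct"].between(76, 84))
                | (~hi & ~tr["need_cue_pct"].between(16, 24))
            )
            if out_band.any():
                soft.append(
                    f"altruism: {int(out_band.sum())} need cues outside the "
                    "80+/-4 / 20+/-4 jitter bands"
                )
    return {"hard": hard, "soft": soft, "ok": not hard}


def build_subject_summary(
    perception_fits: dict | None,
    altruism_fits: dict | None,
    altruism_trials: pd.DataFrame | None,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per subject: perception S/Bias, overall and change weights,
    generosity fractions, neural covariate and delay (when available)."""
    rows: dict[str, dict] = {}
    if perception_fits:
        for sid, (params, _) in perception_fits.items():
            rows.setdefault(sid, {"subject_id": sid}).update(
                extract_bias_sensitivity(params)
            )
    if altruism_fits:
        for sid, (params, _) in altruism_fits.items():
            cs = change_scores(params)
            rows.setdefault(sid, {"subject_id": sid}).update(cs)
    if altruism_trials is not None:
        for sid, sub in altruism_trials.groupby("subject_id"):
            gt = generosity_fractions(sub)
            r = rows.setdefault(sid, {"subject_id": sid})
            r["generosity_overall"] = gt.overall
            for (m, n), frac in gt.cells.items():
                r[f"generosity_{m}_{n}"] = frac
            hi_m = np.nanmean([gt.cells[("high", n)] for n in ("high", "low")])
            lo_m = np.nanmean([gt.cells[("low", n)] for n in ("high", "low")])
            hi_n = np.nanmean([gt.cells[(m, "high")] for m in ("high", "unknown", "low")])
            lo_n = np.nanmean([gt.cells[(m, "low")] for m in ("high", "unknown", "low")])
            r["dgen_merit"] = hi_m - lo_m
            r["dgen_need"] = hi_n - lo_n
    df = pd.DataFrame(list(rows.values()))
    if truth is not None:
        extra = truth[["subject_id", "rTPJ_beta", "inter_task_delay_days"]]
        df = df.merge(extra, on="subject_id", how="left")
    return df.sort_values("subject_id").reset_index(drop=True)


def link_cohort(summary: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Correlation/regression battery over a subject summary table."""
    out: dict = {}
    need_cols = ["S_merit", "dgen_merit", "dmerit_other", "dmerit_self",
                 "Bias_merit", "overall_other"]
    if all(c in summary.columns for c in need_cols):
        s = summary.dropna(subset=need_cols)
        if len(s) < 5:
            return {"skipped": f"only {len(s)} complete subjects (< 5)"}
        pairs = {
            "S_merit~dgen_merit": (s["S_merit"], s["dgen_merit"]),
            "S_merit~dmerit_other": (s["S_merit"], s["dmerit_other"]),
            "S_merit~dmerit_self": (s["S_merit"], s["dmerit_self"]),
            "Bias_merit~overall_other": (s["Bias_merit"], s["overall_other"]),
        }
        out["spearman"] = lstats.spearman_fdr(pairs).to_dict(orient="records")
        if "rTPJ_beta" in s.columns and s["rTPJ_beta"].notna().all() and len(s) >= 5:
            keep_y, bad = lstats.remove_outliers_3sd(s["dmerit_other"].to_numpy())
            idx = np.setdiff1d(np.arange(len(s)), bad)
            out["linking_regression_dwother"] = lstats.linking_regression(
                s["dmerit_other"].to_numpy()[idx],
                s["S_merit"].to_numpy()[idx],
                s["rTPJ_beta"].to_numpy()[idx],
            )
        if ("inter_task_delay_days" in s.columns
                and s["inter_task_delay_days"].notna().all() and len(s) >= 6):
            r, p = lstats.partial_spearman(
                s["S_merit"], s["dmerit_other"], s["inter_task_delay_days"]
            )
            out["partial_S_merit~dmerit_other|delay"] = {"r": r, "p": p}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``out_dir``). Idempotent given (inputs, config, seed)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    synthetic = config.perception_trials is None and config.altruism_trials is None
    truth = None
    if synthetic:
        logger.info("generating synthetic cohort (seed=%d)", config.seed)
        bundle = generate_linked_cohort(
            CohortConfig(n_subjects=config.n_subjects), seed=config.seed
        )
        stimuli = bundle["stimuli"]
        perc_trials = bundle["perception_trials"]
        alt_trials = bundle["altruism_trials"]
        truth = bundle["truth"]
        truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        stimuli = center_evidence(_read_table(config.stimuli)) if config.stimuli else None
        perc_trials = _read_table(config.perception_trials) if config.perception_trials else None
        alt_trials = _read_table(config.altruism_trials) if config.altruism_trials else None
        tables = {}
        if stimuli is not None:
            tables["stimuli"] = stimuli
        if perc_trials is not None:
            tables["perception"] = perc_trials
        if alt_trials is not None:
            tables["altruism"] = alt_trials
        val = validate_inputs(tables)
        report["validation"] = val
        if not val["ok"]:
            raise ValueError(f"input validation failed: {val['hard']}")

    fit_cfg = {"n_restarts": config.n_restarts, "random_state": config.seed}
    perc_fits = alt_fits = None
    if config.run_perception and perc_trials is not None:
        logger.info("fitting perception model (%d subjects)",
                    perc_trials["subject_id"].nunique())
        try:
            perc_fits = fit_cohort_perception(
                perc_trials, stimuli, fit_cfg, shrinkage=config.shrinkage
            )
        except Exception as exc:
            raise RuntimeError(f"stage=fit-perception failed: {exc}") from exc
        pdir = out / "perception_params"
        pdir.mkdir(exist_ok=True)
        for sid, (params, diag) in perc_fits.items():
            (pdir / f"{sid}.json").write_text(params.to_json(**diag, seed_master=config.seed))

    if config.run_altruism and alt_trials is not None:
        qc = qc_exclusions(alt_trials)
        qc.to_csv(out / "qc_report.csv", index=False)
        keep = set(qc.loc[qc["keep"], "subject_id"])
        alt_kept = alt_trials[alt_trials["subject_id"].isin(keep)]
        logger.info("fitting altruism model (%d subjects kept of %d)",
                    len(keep), qc.shape[0])
        try:
            alt_fits = fit_cohort_altruism(alt_kept, fit_cfg, shrinkage=config.shrinkage)
        except Exception as exc:
            raise RuntimeError(f"stage=fit-altruism failed: {exc}") from exc
        adir = out / "altruism_params"
        adir.mkdir(exist_ok=True)
        for sid, (params, diag) in alt_fits.items():
            (adir / f"{sid}.json").write_text(params.to_json(**diag, seed_master=config.seed))
        # cohort generosity table (Table-2-shaped)
        gt_rows = []
        for sid in sorted(keep):
            t = generosity_fractions(alt_kept[alt_kept["subject_id"] == sid]).to_frame()
            t.insert(0, "subject_id", sid)
            gt_rows.append(t)
        pd.concat(gt_rows, ignore_index=True).to_csv(out / "generosity.csv", index=False)

    summary = build_subject_summary(
        perc_fits, alt_fits,
        alt_trials if alt_fits else None, truth,
    )
    summary.to_csv(out / "subject_summary.csv", index=False)

    stats_report: dict = {}
    if alt_fits:
        wide = _condition_weight_table(alt_fits)
        stats_report["weight_contrasts"] = lstats.weight_condition_contrasts(
            wide
        ).to_dict(orient="records")
        alt_for_glmm = alt_trials.copy()
        from .metrics import _classify_vec

        alt_for_glmm["generous"] = _classify_vec(alt_for_glmm)
        alt_for_glmm = alt_for_glmm.dropna(subset=["generous"])
        if alt_for_glmm["subject_id"].nunique() >= 2:
            stats_report["glmm"] = lstats.fit_generosity_glmm(alt_for_glmm)
    if perc_fits and alt_fits:
        stats_report["linking"] = link_cohort(summary, alpha=config.alpha)
    report["stats"] = stats_report
    (out / "statistics.json").write_text(json.dumps(report, indent=1, default=_json_default))
    (out / "report.txt").write_text(_text_report(report, summary))
    logger.info("pipeline complete: %s", out)
    return report


def _condition_weight_table(alt_fits: dict) -> pd.DataFrame:
    from .altruism import condition_weights, MERIT_LEVELS, NEED_LEVELS, WEIGHT_NAMES

    rows = []
    for sid, (params, _) in alt_fits.items():
        row = {"subject_id": sid}
        for attr in ("self", "other", "fairness"):
            j = WEIGHT_NAMES.index(attr)
            for m in ("high", "low"):
                vals = [condition_weights(params, m, n)[j] for n in NEED_LEVELS]
                row[f"{attr}_merit_{m}"] = float(np.mean(vals))
            for n in ("high", "low"):
                vals = [condition_weights(params, m, n)[j] for m in MERIT_LEVELS]
                row[f"{attr}_need_{n}"] = float(np.mean(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _text_report(report: dict, summary: pd.DataFrame) -> str:
    lines = [
        "socialddm pipeline report",
        f"seed: {report['seed']}  config: {report['config_hash']}",
        "",
        f"subjects summarized: {len(summary)}",
    ]
    stats = report.get("stats", {})
    if "glmm" in stats:
        g = stats["glmm"]
        lines += ["", "Mixed logistic regression of generous choice:"]
        for k, v in g["fixed_effects"].items():
            lo, hi = g["ci95"][k]
            lines.append(f"  {k:24s} beta={v: .3f}  95% CI [{lo: .3f}, {hi: .3f}]")
        lines.append(f"  random-intercept SD = {g['re_sd']:.3f}; "
                     f"R2 marginal/conditional = {g['r2_marginal']:.2f}/{g['r2_conditional']:.2f}")
        lrt = g["lrt_full_vs_null"]
        lines.append(f"  LRT vs null: chi2({lrt['df']}) = {lrt['chi2']:.2f}, p = {lrt['p']:.3g}")
    if "weight_contrasts" in stats:
        lines += ["", "Wilcoxon condition contrasts on attribute weights (BH-adjusted):"]
        for r in stats["weight_contrasts"]:
            lines.append(
                f"  {r['attribute']:9s} {r['manipulation']:5s} high-low "
                f"median diff = {r['median_diff']: .3f}, p_fdr = {r['p_fdr']:.3g}"
            )
    if "linking" in stats and "spearman" in stats["linking"]:
        lines += ["", "Cross-task Spearman correlations (BH within family):"]
        for r in stats["linking"]["spearman"]:
            lines.append(f"  {r['pair']:26s} r = {r['r']: .3f}, p_fdr = {r['p_fdr']:.3g} (n={r['n']})")
    return "\n".join(lines) + "\n"
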