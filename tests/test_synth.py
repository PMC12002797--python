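"""Synthetic generators: design conformance, determinism, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socialddm.perception import EVIDENCE_DIMS, PerceptionParameters, CONDITIONS
from socialddm.synth import (
    CohortConfig,
    draw_cohort,
    generate_altruism_dataset,
    generate_altruism_design,
    generate_linked_cohort,
    generate_neural_covariate,
    generate_normative_stimuli,
    generate_perception_dataset,
    truth_to_params,
)


class TestStimuli:
    def test_design_size_and_ranges(self, stimuli):
        assert len(stimuli) == 64
        for dim in EVIDENCE_DIMS:
            col = stimuli[f"{dim}_prop"]
            assert ((col >= 0) & (col <= 1)).all()
            assert abs(stimuli[dim].mean()) < 1e-12  # centered columns

    def test_requested_evidence_correlation(self):
        rs = []
        for seed in range(8):
            st = generate_normative_stimuli(seed=seed,
                                            config={"merit_need_corr": 0.3})
            rs.append(np.corrcoef(st["merit_prop"], st["need_prop"])[0, 1])
        assert abs(np.mean(rs) - 0.3) < 0.15

    def test_determinism_and_validation(self):
        a = generate_normative_stimuli(seed=5)
        b = generate_normative_stimuli(seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            generate_normative_stimuli(n_images=1)
        with pytest.raises(ValueError):
            generate_normative_stimuli(config={"merit_need_corr": 1.5}, seed=0)


class TestCohort:
    def test_group_moments_match_config(self):
        cfg = CohortConfig(n_subjects=400)
        truth = draw_cohort(cfg, seed=3)
        assert truth["S_merit|merit"].mean() == pytest.approx(2.84, abs=0.15)
        assert truth["S_merit|merit"].std() == pytest.approx(1.02, abs=0.15)
        assert truth["Bias_need"].mean() == pytest.approx(-0.17, abs=0.06)
        # implied overall weights hit the reported means
        overall_self = truth["base_self"] \
            + (truth["dmh_self"] + truth["dml_self"]) / 3 + truth["dnh_self"] / 2
        assert overall_self.mean() == pytest.approx(0.97, abs=0.1)

    def test_configured_couplings_present(self):
        truth = draw_cohort(CohortConfig(n_subjects=400), seed=4)
        r_bias = np.corrcoef(truth["Bias_merit"], truth["Bias_need"])[0, 1]
        assert r_bias == pytest.approx(0.73, abs=0.1)
        dmerit_other = truth["dmh_other"] - truth["dml_other"]
        assert np.corrcoef(truth["S_merit|merit"], dmerit_other)[0, 1] > 0.4
        dmerit_self = truth["dmh_self"] - truth["dml_self"]
        assert np.corrcoef(truth["S_merit|merit"], dmerit_self)[0, 1] < -0.4

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="negative SD"):
            cfg = CohortConfig()
            cfg.perception["a_sd"] = -1.0
            CohortConfig(perception=cfg.perception)
        with pytest.raises(ValueError, match="coupling"):
            bad = CohortConfig().coupling | {"s_merit_delta": 1.5}
            CohortConfig(coupling=bad)


class TestPerceptionDataset:
    def test_trial_count_and_determinism(self, stimuli,
                                          group_mean_perception_params):
        t1 = generate_perception_dataset([group_mean_perception_params],
                                         stimuli, seed=11)
        t2 = generate_perception_dataset([group_mean_perception_params],
                                         stimuli, seed=11)
        assert len(t1) == 192  # 64 images x 3 conditions
        pd.testing.assert_frame_equal(t1, t2)

    def test_yes_rate_monotone_in_merit_evidence(self, stimuli):
        p = PerceptionParameters(
            sensitivity={c: {d: (8.0 if c == d == "merit" else 0.0)
                             for d in EVIDENCE_DIMS} for c in CONDITIONS},
            bias={c: 0.0 for c in CONDITIONS},
            threshold={c: 1.5 for c in CONDITIONS},
            ndt={c: 0.3 for c in CONDITIONS},
            start={c: 0.5 for c in CONDITIONS},
        )
        trials = generate_perception_dataset([p], stimuli, seed=12)
        merit = trials[trials["condition"] == "merit"].merge(
            stimuli[["stimulus_id", "merit"]], on="stimulus_id"
        )
        merit = merit[~merit["timed_out"]]
        merit["q"] = pd.qcut(merit["merit"], 4, labels=False)
        rates = merit.groupby("q")["response"].apply(lambda s: (s == "yes").mean())
        assert rates.is_monotonic_increasing


class TestAltruismDesign:
    def test_printed_design_constants(self):
        d = generate_altruism_design(seed=1)
        assert len(d) == 300
        assert d.groupby("partner").size().eq(100).all()
        assert d.groupby("run").size().eq(60).all()
        assert d.groupby(["partner", "need_level"]).size().eq(50).all()
        assert set(d["partner_merit"]) == {"high", "unknown", "low"}

    def test_cue_jitter_bands(self):
        d = generate_altruism_design(seed=2)
        hi = d[d["need_level"] == "high"]["need_cue_pct"]
        lo = d[d["need_level"] == "low"]["need_cue_pct"]
        assert hi.between(76, 84).all()
        assert lo.between(16, 24).all()

    def test_mean_high_cue_near_80_over_seeds(self):
        means = [
            generate_altruism_design(seed=s).query("need_level == 'high'")
            ["need_cue_pct"].mean()
            for s in range(10)
        ]
        assert abs(np.mean(means) - 80.0) < 1.0

    def test_offer_ranges_and_tradeoff_emphasis(self):
        d = generate_altruism_design(seed=3)
        assert d["offer_self"].between(5, 39).all()
        assert d["offer_other"].between(5, 39).all()
        tradeoff = ((d["offer_self"] > 20) & (d["offer_other"] < 20)) | (
            (d["offer_self"] < 20) & (d["offer_other"] > 20)
        )
        assert tradeoff.mean() > 0.6

    def test_partner_order_counterbalance(self):
        d0 = generate_altruism_design(seed=4, order_index=0)
        d1 = generate_altruism_design(seed=4, order_index=1)
        first0 = d0[d0["run"] == 1]["partner"].iloc[0]
        first1 = d1[d1["run"] == 1]["partner"].iloc[0]
        assert first0 != first1


class TestAltruismDataset:
    def test_determinism(self):
        truth = draw_cohort(CohortConfig(n_subjects=2), seed=5)
        design = generate_altruism_design(seed=6)
        a = generate_altruism_dataset(truth, design, seed=7)
        b = generate_altruism_dataset(truth, design, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_need_delta_raises_generosity(self):
        # positive other-regard response to need must surface behaviorally
        from socialddm.metrics import generosity_fractions

        cfg = CohortConfig(n_subjects=10)
        truth = draw_cohort(cfg, seed=8)
        design = generate_altruism_design(seed=9)
        trials = generate_altruism_dataset(truth, design, seed=10)
        gt = generosity_fractions(trials)
        hi = np.mean([gt.cells[(m, "high")] for m in ("high", "unknown", "low")])
        lo = np.mean([gt.cells[(m, "low")] for m in ("high", "unknown", "low")])
        assert hi > lo


class TestNeuralCovariate:
    def test_noiseless_coupling(self):
        s = np.random.default_rng(0).normal(2.8, 1.0, 30)
        r = generate_neural_covariate(s, coupling=1.0, noise_sd=0.0, seed=1)
        assert sps.spearmanr(s, r).statistic == pytest.approx(1.0)

    def test_zero_coupling_null(self):
        rng = np.random.default_rng(2)
        hits = 0
        for seed in range(20):
            s = rng.normal(2.8, 1.0, 25)
            r = generate_neural_covariate(s, coupling=0.0, noise_sd=0.8, seed=seed)
            hits += abs(np.corrcoef(s, r)[0, 1]) < 0.3
        assert hits >= 16  # >= 80% of seeds

    def test_default_coupling_detectable(self):
        rng = np.random.default_rng(3)
        hits = 0
        for seed in range(20):
            s = rng.normal(2.8, 1.0, 44)
            r = generate_neural_covariate(s, coupling=1.0, noise_sd=0.8, seed=seed)
            hits += sps.spearmanr(s, r).pvalue < 0.05
        assert hits >= 16

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            generate_neural_covariate(np.ones(5), coupling=-0.1)


def test_linked_cohort_bundle():
    bundle = generate_linked_cohort(CohortConfig(n_subjects=3), seed=33)
    assert len(bundle["truth"]) == 3
    assert len(bundle["perception_trials"]) == 3 * 192
    assert len(bundle["altruism_trials"]) == 3 * 300
    # ground truth round-trips into parameter objects
    pp, ap = truth_to_params(bundle["truth"].iloc[0])
    pp.validate()
    ap.validate()
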