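"""Mixed-effects stage: LMM, trial-level GLMM, EMM contrasts, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from socialrl import (
    ModelSpec,
    emm_contrasts,
    estimated_marginal_means,
    fit_glmm,
    fit_lmm,
    report,
    simulate_rate_table,
)
from socialrl.inference import effect_size_value

RATE_SPEC = ModelSpec("rate", ("session", "condition", "pe_valence"))


class TestLMM:
    def test_planted_interaction_recovered_within_2se(self):
        """A known session x condition shift of the printed magnitude is
        recovered within 2 SE at the full cohort size."""
        hits = 0
        for rep in range(5):
            data = simulate_rate_table(
                53, seed=500 + rep, effects={"session x condition": -0.02}
            )
            m = fit_lmm(data, RATE_SPEC)
            row = m.summary_table.set_index("term").loc["session x condition"]
            se = (row.ci_high - row.ci_low) / (2 * 1.97)
            if abs(row.estimate - (-0.02)) <= 2 * se:
                hits += 1
        assert hits >= 4

    def test_null_world_fixed_effects_near_zero(self):
        """Null generator: non-intercept estimates within 2 SE of zero in
        >= 90% of coefficient draws over replicate cohorts."""
        within = total = 0
        for rep in range(10):
            data = simulate_rate_table(20, seed=900 + rep)
            m = fit_lmm(data, RATE_SPEC)
            tab = m.summary_table.iloc[1:]
            within += int((tab.t.abs() <= 2).sum())
            total += len(tab)
        assert within / total >= 0.9

    def test_intercept_is_grand_mean_under_effects_coding(self):
        data = simulate_rate_table(30, seed=3)
        m = fit_lmm(data, RATE_SPEC)
        assert m.params[0] == pytest.approx(data.rate.mean(), abs=0.01)

    def test_variance_components_recovered(self):
        data = simulate_rate_table(
            120, seed=8, subject_sd=0.04, resid_sd=0.08
        )
        m = fit_lmm(data, RATE_SPEC)
        assert np.sqrt(m.sigma2) == pytest.approx(0.08, abs=0.015)
        assert np.sqrt(m.tau00) == pytest.approx(0.04, abs=0.02)
        re = m.summary_table.attrs["random_effects"]
        assert 0 < re["icc"] < 1
        assert re["r2_marginal"] <= re["r2_conditional"]

    def test_pure_noise_flags_singular_fit(self, rng):
        data = simulate_rate_table(15, seed=4, subject_sd=0.0, resid_sd=0.05)
        m = fit_lmm(data, RATE_SPEC)
        assert any("singular" in w for w in m.warnings)

    def test_power_in_configured_nonnull_scenario(self):
        """The session x condition interaction (-0.04 scenario) is detected
        at p < .05 in the majority of full-size replicates."""
        detected = 0
        n_reps = 9
        for rep in range(n_reps):
            data = simulate_rate_table(
                53, seed=7000 + rep, effects={"session x condition": -0.04}
            )
            m = fit_lmm(data, RATE_SPEC)
            p = m.summary_table.set_index("term").loc["session x condition", "p"]
            detected += int(p < 0.05)
        assert detected > n_reps / 2


def make_binary_cohort(rng, n_subj=40, n_trials=16, effects=None):
    effects = effects or {}
    rows = []
    intercepts = rng.normal(0, 0.6, n_subj)
    for i in range(n_subj):
        cond = "CBM-I" if i < n_subj // 2 else "EMA-only"
        xc = -0.5 if cond == "CBM-I" else 0.5
        for s, xs in (("1", -0.5), ("2", 0.5)):
            for tt, xt in (("avoid_punish", -0.5), ("choose_reward", 0.5)):
                eta = (
                    1.4
                    + intercepts[i]
                    + effects.get("session", 0) * xs
                    + effects.get("session x condition", 0) * xs * xc
                )
                p = 1 / (1 + np.exp(-eta))
                for k in range(n_trials):
                    rows.append(
                        {"subject_id": f"S{i}", "condition": cond, "session": s,
                         "trial_type": tt, "correct": int(rng.random() < p)}
                    )
    return pd.DataFrame(rows)


class TestGLMM:
    SPEC = ModelSpec("correct", ("session", "condition", "trial_type"),
                     link="logit")

    def test_intercept_matches_observed_odds(self, rng):
        """Balanced intercept-only model: OR intercept ~ observed odds."""
        data = make_binary_cohort(rng, n_subj=60)
        m = fit_glmm(data, ModelSpec("correct", (), link="logit"))
        observed_odds = data.correct.mean() / (1 - data.correct.mean())
        # the marginal odds are attenuated relative to the conditional
        # intercept by the random-intercept variance
        attenuation = np.sqrt(1 + 0.346 * m.tau00)
        assert np.exp(m.params[0] / attenuation) == pytest.approx(
            observed_odds, rel=0.15
        )

    def test_planted_session_effect_recovered_within_2se(self, rng):
        data = make_binary_cohort(rng, n_subj=50, effects={"session": 0.5})
        m = fit_glmm(data, self.SPEC)
        row = m.summary_table.set_index("term").loc["session"]
        se = row.estimate / row.z
        assert abs(row.estimate - 0.5) <= 2 * se

    def test_near_chance_generator_gives_or_near_one(self, rng):
        data = make_binary_cohort(rng, n_subj=40)
        m = fit_glmm(data, self.SPEC)
        ors = m.summary_table.set_index("term").odds_ratio
        for term in ("session", "condition", "trial_type"):
            assert ors[term] == pytest.approx(1.0, abs=0.25)

    def test_binary_response_required(self, rng):
        data = make_binary_cohort(rng, n_subj=10)
        data["correct"] = data["correct"] + 0.5
        with pytest.raises(ValueError, match="binary"):
            fit_glmm(data, self.SPEC)


class TestEMMs:
    def test_family_of_one_is_unadjusted(self):
        data = simulate_rate_table(30, seed=11)
        m = fit_lmm(data, RATE_SPEC)
        for c in emm_contrasts(m, ["session"], by=["condition"]):
            assert c.p_adjusted == pytest.approx(c.p_unadjusted)

    def test_symmetric_data_gives_zero_contrast(self):
        rows = []
        for i in range(20):
            for s in ("1", "2"):
                for v in ("negative", "positive"):
                    rows.append(
                        {"subject_id": f"S{i}", "condition": "CBM-I",
                         "session": s, "pe_valence": v,
                         "rate": 0.2 + 0.01 * (i % 3)}
                    )
        m = fit_lmm(pd.DataFrame(rows),
                    ModelSpec("rate", ("session", "pe_valence")))
        for c in emm_contrasts(m, ["session"]):
            assert c.estimate == pytest.approx(0.0, abs=1e-10)
            assert c.effect_size == pytest.approx(0.0, abs=1e-8)

    def test_grand_mean_of_emms_is_overall_mean(self):
        data = simulate_rate_table(25, seed=13)
        m = fit_lmm(data, RATE_SPEC)
        emms = estimated_marginal_means(
            m, ["session", "condition", "pe_valence"]
        )
        assert emms.emmean.mean() == pytest.approx(m.params[0], abs=1e-10)

    def test_tukey_adjustment_monotone(self):
        data = simulate_rate_table(20, seed=17)
        data["cat3"] = np.tile(["a", "b", "c"], len(data) // 3 + 1)[: len(data)]
        m = fit_lmm(data, ModelSpec("rate", ("session", "cat3")))
        for c in emm_contrasts(m, ["cat3"]):
            assert c.p_adjusted >= c.p_unadjusted

    def test_three_level_tukey_matches_independent_oracle(self, rng):
        """Adjusted p for a one-way 3-group comparison agrees with
        statsmodels' Tukey HSD on the raw data."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = np.repeat(["a", "b", "c"], 30)
        y = rng.normal(0, 1, 90) + np.repeat([0.0, 0.4, 0.7], 30)
        data = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(90)], "g": groups, "y": y}
        )
        m = fit_lmm(data, ModelSpec("y", ("g",)))
        ours = {c.label: c.p_adjusted for c in emm_contrasts(m, ["g"])}
        hsd = pairwise_tukeyhsd(y, groups)
        for (g1, g2), p_ref in zip(
            [("a", "b"), ("a", "c"), ("b", "c")], hsd.pvalues
        ):
            assert ours[f"{g1} - {g2}"] == pytest.approx(p_ref, abs=0.02)


class TestEffectSize:
    def test_unit_contrast_on_total_sd_scale(self):
        data = simulate_rate_table(40, seed=19)
        m = fit_lmm(data, RATE_SPEC)
        total_sd = np.sqrt(m.tau00 + m.sigma2)
        assert effect_size_value(total_sd, m) == pytest.approx(1.0)
        assert effect_size_value(0.0, m) == 0.0
        assert effect_size_value(-0.5 * total_sd, m) == pytest.approx(-0.5)


class TestReport:
    def test_full_report_and_missing_stage_flag(self, tmp_path):
        data = simulate_rate_table(20, seed=23)
        m = fit_lmm(data, RATE_SPEC)
        outputs = {
            "learning_rate_model": m,
            "accuracy_model": None,
            "weight_models": {"pe_valence": m},
            "loo_table": pd.DataFrame({"delta_looic": [0.0]}),
            "contrasts": {"rates": emm_contrasts(m, ["session"])},
        }
        text = report(outputs, tmp_path / "r.md", seed=1)
        assert "[missing stage: accuracy_model]" in text
        assert "Learning rates" in text
        assert "Tukey" in text
        text2 = report(outputs, tmp_path / "r2.md", seed=1)
        assert text == text2
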