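import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clingaze.stats import (
    headline_report,
    pearson_correlation,
    posthoc_power_t,
    students_t_independent,
)
from _oracles import mc_power_oracle, permutation_t_pvalue


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert res.df == 4

    def test_shifted_groups_closed_form(self):
        # shift +10 with identical spread: t = 10 / sqrt(2/3) on 4 df
        res = students_t_independent([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(10.0 / np.sqrt(2.0 / 3.0))
        assert res.p_value < 0.001

    def test_matches_scipy_reference(self):
        g1 = [5.1, 4.9, 5.0, 5.2]
        g2 = [5.6, 5.8, 5.5, 5.7]
        res = students_t_independent(g1, g2)
        t_ref, p_ref = sps.ttest_ind(g1, g2, equal_var=True)
        assert res.t_statistic == pytest.approx(t_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)
        assert res.df == 6

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(17)
        g1 = rng.normal(0.0, 1.0, 8)
        g2 = rng.normal(1.0, 1.0, 8)
        res = students_t_independent(g1, g2)
        p_perm = permutation_t_pvalue(g1, g2, n_perm=20_000, seed=3)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)

    def test_group_ci_contains_mean_and_is_symmetric(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(5.0, 2.0, 20)
        g2 = rng.normal(5.0, 2.0, 25)
        res = students_t_independent(g1, g2)
        lo, hi = res.ci95_1
        assert lo < res.mean_1 < hi
        assert (res.mean_1 - lo) == pytest.approx(hi - res.mean_1)

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(ValueError):
            students_t_independent([1.0, 1.0], [2.0, 2.0])

    def test_welch_option(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 5, 30)
        res = students_t_independent(g1, g2, welch=True)
        t_ref, p_ref = sps.ttest_ind(g1, g2, equal_var=False)
        assert res.t_statistic == pytest.approx(t_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            students_t_independent([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_antisymmetric(self):
        res = pearson_correlation([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.r == pytest.approx(-1.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(11)
        res = pearson_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.r) < 0.1
        assert res.n == 1000

    def test_constant_input_undefined_with_note(self):
        res = pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.r) and res.note == "constant input"

    def test_missing_pairs_dropped(self):
        res = pearson_correlation([1, 2, 3, np.nan], [2, 4, 6, 1])
        assert res.n == 3 and res.r == pytest.approx(1.0)


class TestPower:
    def test_null_effect_gives_alpha(self):
        res = posthoc_power_t(0.0, 19, 19, alpha=0.05)
        assert res.power == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_size(self):
        p1 = posthoc_power_t(0.3, 19, 19).power
        p2 = posthoc_power_t(0.8, 19, 19).power
        assert p2 > p1

    def test_monotone_in_sample_size(self):
        p1 = posthoc_power_t(0.5, 10, 10).power
        p2 = posthoc_power_t(0.5, 40, 40).power
        assert p2 > p1

    def test_matches_monte_carlo_small(self):
        # light version; the 1e5-replicate check lives in the acceptance suite
        res = posthoc_power_t(0.5, 19, 19, alpha=0.05)
        mc = mc_power_oracle(0.5, 19, 19, 0.05, n_rep=20_000, seed=2)
        assert res.power == pytest.approx(mc, abs=0.02)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power_t(0.5, 19, 19, alpha=1.5)


def _toy_tables(n_participants=6, rng=None):
    """Hand-built attention/behaviour/trials tables for report tests."""
    rng = rng or np.random.default_rng(0)
    rois = ["ai_screen", "ai_recommendation", "xai_qdiff", "xai_mortality",
            "xai_features", "xai_examples", "icu_chart", "patient_mannequin",
            "vitals_monitor"]
    att_rows, beh_rows, trial_rows = [], [], []
    for p in range(n_participants):
        pid = f"P{p:02d}"
        for sid in range(1, 7):
            cond = "unsafe" if sid <= 2 else "safe"
            for roi in rois:
                base = 900 if (roi == "ai_screen" and cond == "unsafe") else 700
                att_rows.append({
                    "participant_id": pid, "scenario_id": sid, "condition": cond,
                    "roi_id": roi, "gaze_time_ms": rng.uniform(5e3, 6e4),
                    "n_fixations": max(0, int(rng.normal(base, 120))),
                    "mean_fixation_duration_ms": rng.normal(140, 10),
                    "blink_rate_bpm": rng.normal(20 if roi.startswith(("ai", "xai")) else 12, 3),
                    "actual_gaze_proportion": 0.2, "chance_gaze_proportion": 0.05,
                    "actual_to_chance_ratio": 4.0,
                })
            for drug in ("fluid", "vasopressor"):
                beh_rows.append({
                    "participant_id": pid, "scenario_id": sid, "condition": cond,
                    "drug": drug, "influence_raw": rng.uniform(0, 1),
                    "influence_clamped": rng.uniform(0, 1),
                    "influence_defined": True,
                    "practice_variation": rng.uniform(0, 300),
                    "advice_distance": rng.uniform(0, 200),
                })
                trial_rows.append({
                    "participant_id": pid, "scenario_id": sid, "condition": cond,
                    "order_index": sid, "drug": drug, "initial_dose": 200.0,
                    "final_dose": 180.0, "ai_dose": 150.0,
                    "rating_qdiff": rng.integers(0, 5),
                    "rating_mortality": rng.integers(0, 5),
                    "rating_features": rng.integers(0, 5),
                    "rating_examples": rng.integers(0, 5),
                    "seniority": "SpR",
                })
    return (pd.DataFrame(att_rows), pd.DataFrame(beh_rows), pd.DataFrame(trial_rows))


class TestHeadlineReport:
    def test_detects_planted_ai_screen_difference(self):
        att, beh, trials = _toy_tables()
        rep = headline_report(att, beh, trials)
        row = rep.tables["safe_unsafe_fixations"].iloc[0]
        assert row["computable"]
        assert row["mean_1"] > row["mean_2"]  # unsafe > safe
        assert row["p"] < 0.05

    def test_single_unsafe_trial_not_computable(self):
        att, beh, trials = _toy_tables()
        keep = (att["condition"] == "safe") | (
            (att["participant_id"] == "P00") & (att["scenario_id"] == 1))
        rep = headline_report(att[keep], beh, trials)
        row = rep.tables["safe_unsafe_fixations"].iloc[0]
        assert not row["computable"] and np.isnan(row["p"])

    def test_deterministic_given_inputs(self):
        att, beh, trials = _toy_tables()
        r1 = headline_report(att, beh, trials)
        r2 = headline_report(att, beh, trials)
        for name in r1.tables:
            pd.testing.assert_frame_equal(r1.tables[name], r2.tables[name])
        assert r1.summary_md == r2.summary_md

    def test_footer_states_no_adjustment(self):
        att, beh, trials = _toy_tables()
        rep = headline_report(att, beh, trials)
        assert "No multiple-testing adjustment" in rep.summary_md

    def test_all_expected_tables_present(self):
        att, beh, trials = _toy_tables()
        rep = headline_report(att, beh, trials)
        assert set(rep.tables) == {
            "safe_unsafe_fixations", "blink_conventional_vs_ai",
            "per_roi_metrics", "chance_gaze", "correlations"}
        assert len(rep.tables["safe_unsafe_fixations"]) == 5  # screen + 4 panels

    def test_participant_level_aggregation(self):
        att, beh, trials = _toy_tables()
        rep = headline_report(att, beh, trials, participant_level=True)
        row = rep.tables["safe_unsafe_fixations"].iloc[0]
        assert row["n_1"] == row["n_2"] == 6  # one mean per participant per arm
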