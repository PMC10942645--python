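import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from conflictspace import behavior_cse as bc
from conflictspace import behavior_sim as bs
from conflictspace.mixedlm import MixedLM, RandomTerm

from conftest import make_toy_trials


class TestFiltering:
    def test_toy_run_rules_by_hand(self):
        """[ok, error, ok, ok]: first, error and post-error go; #4 stays."""
        rows = [
            ("Stroop", "C", 500.0, 1),
            ("Simon", "I", 520.0, 0),
            ("Stroop", "I", 530.0, 1),
            ("Simon", "C", 510.0, 1),
        ]
        trials = make_toy_trials(rows)
        kept, report = bc.filter_trials(trials, "RT")
        assert list(kept["trial"]) == [3]
        assert report.removed == {
            "first_of_block": 1, "error": 1, "rt_outlier": 0, "post_error": 1
        }

    def test_short_rt_removed(self):
        rows = [("Stroop", "C", 500.0, 1)] + [
            ("Simon", "C", 150.0 if i == 3 else 500.0, 1) for i in range(8)
        ]
        kept, report = bc.filter_trials(make_toy_trials(rows), "RT")
        assert report.removed["rt_outlier"] == 1
        assert 150.0 not in kept["rt"].to_numpy()

    def test_er_rules_keep_error_trials(self):
        rows = [
            ("Stroop", "C", 500.0, 1),
            ("Simon", "I", 520.0, 0),
            ("Stroop", "I", 530.0, 1),
            ("Simon", "C", 510.0, 0),
        ]
        kept, _ = bc.filter_trials(make_toy_trials(rows), "ER")
        # trial 1 (error) kept; trial 0 (first) and trial 2 (post-error) gone
        assert list(kept["trial"]) == [1, 3]
        assert (kept["accuracy"] == 0).sum() == 2

    def test_empty_result_raises(self):
        rows = [("Stroop", "C", 500.0, 0), ("Simon", "I", 500.0, 0)]
        with pytest.raises(ValueError, match="no trials survive"):
            bc.filter_trials(make_toy_trials(rows), "RT")


class TestCentering:
    def _trials_with_rep(self, rep_rt, alt_rt, n=40):
        rows = [("Stroop", "C", 500.0, 1)]
        # alternate directions so repetition/alternation both occur
        recs = make_toy_trials(rows * (n + 1))
        rng = np.random.default_rng(0)
        recs["correct_response"] = rng.choice(["left", "right"], len(recs))
        recs = bc._annotate_context(recs)
        recs["rt"] = np.where(recs["response_repetition"] == 1.0, rep_rt, alt_rt)
        return recs

    def test_equal_class_means_are_unchanged(self):
        t = self._trials_with_rep(520.0, 520.0)
        out = bc.center_response_repetition(t, "RT")
        assert np.allclose(out["rt"], t["rt"])

    def test_shift_arithmetic(self):
        t = self._trials_with_rep(500.0, 540.0).dropna(
            subset=["response_repetition"]
        )
        out = bc.center_response_repetition(t, "RT")
        grand = t["rt"].mean()
        rep_mask = t["response_repetition"] == 1.0
        assert np.allclose(out.loc[rep_mask, "rt"], grand)
        assert np.allclose(out.loc[~rep_mask, "rt"], grand)
        # per-subject grand mean is preserved exactly
        assert out["rt"].mean() == pytest.approx(t["rt"].mean())

    def test_missing_class_warns_and_passes_through(self):
        t = self._trials_with_rep(500.0, 540.0)
        t["response_repetition"] = 1.0
        with pytest.warns(UserWarning, match="class is absent"):
            out = bc.center_response_repetition(t, "RT")
        assert np.allclose(out["rt"], t["rt"])


class TestDesign:
    @pytest.mark.parametrize(
        "pair,cell,expected",
        [
            (("Stroop", "Stroop"), "CI", 1.0),
            (("Stroop", "Simon"), "II", -0.0),
            (("StHSmL", "Stroop"), "CC", -np.cos(np.radians(22.5))),
        ],
    )
    def test_regressor_values(self, pair, cell, expected):
        cells = pd.DataFrame(
            {
                "subject": [0],
                "pair": [bc._pair_key(*pair)],
                "cse_cell": [cell],
                "similarity": [bs.type_similarity(*pair)],
                "value": [0.0],
                "n": [1],
            }
        )
        out = bc.build_similarity_cse_design(cells)
        assert out["x"].iloc[0] == pytest.approx(expected, abs=1e-4)

    def test_cse_contrast_orthogonal_to_main_effects(self):
        loads = np.array([bc.CSE_LOADING[(p, c)] for p in "CI" for c in "CI"])
        prev_i = np.array([1.0 * (p == "I") for p in "CI" for c in "CI"])
        curr_i = np.array([1.0 * (c == "I") for p in "CI" for c in "CI"])
        assert loads.sum() == 0.0
        assert loads @ (prev_i - prev_i.mean()) == 0.0
        assert loads @ (curr_i - curr_i.mean()) == 0.0


class TestOneStage:
    @pytest.fixture(scope="class")
    def calibrated_cells(self, exp1_small_schedule):
        p = bs.calibrate_cse_gain(
            bs.BehaviorGenParams(seed=4), exp1_small_schedule, "RT", target=0.10
        )
        trials = bs.simulate_trials(p, exp1_small_schedule)
        return bc.cse_cells(trials, "RT")

    def test_slope_recovered_within_sampling_error(self, calibrated_cells):
        res = bc.fit_one_stage(calibrated_cells)
        s = res.slope
        assert s["beta"] == pytest.approx(0.10, abs=3 * max(s["se"], 0.03))
        assert len(res.per_subject_slopes) == calibrated_cells["subject"].nunique()

    def test_proximity_control_runs(self, exp1_small_schedule):
        p = bs.BehaviorGenParams(seed=8)
        cells = bc.cse_cells(bs.simulate_trials(p, exp1_small_schedule), "RT")
        res = bc.fit_one_stage(cells, proximity_control=True)
        assert "proximity" in res.model.names
        assert np.isfinite(res.slope["beta"])

    def test_session_interaction_f_test(self, exp1_small_schedule):
        p = bs.BehaviorGenParams(seed=8)
        trials = bs.simulate_trials(p, exp1_small_schedule)
        cells = bc.cse_cells(trials, "RT", keep_session=True)
        res = bc.fit_one_stage(cells, session_interaction=True)
        F, df1, df2, pval = res.interaction_F
        assert df1 == 2
        assert F >= 0 and 0 <= pval <= 1

    def test_null_generator_slope_near_zero(self, exp1_small_schedule):
        p = bs.BehaviorGenParams(seed=13, cse_gain=0.0, error_cse_gain=0.0)
        cells = bc.cse_cells(bs.simulate_trials(p, exp1_small_schedule), "RT")
        res = bc.fit_one_stage(cells)
        s = res.slope
        assert abs(s["beta"]) < 2.5 * s["se"] + 0.02


class TestTwoStage:
    def test_constant_cells_give_zero_cse(self):
        rows = []
        for pair in ("Stroop|Stroop", "Stroop|Simon"):
            for cell in ("CC", "CI", "IC", "II"):
                rows.append(dict(subject=0, pair=pair, cse_cell=cell,
                                 similarity=1.0, value=500.0))
        tab = bc.stage_one_cse(pd.DataFrame(rows))
        assert np.allclose(tab["cse"], 0.0)

    def test_noiseless_linear_generator_exact(self, exp1_small_schedule):
        g = 6.0
        p = bs.BehaviorGenParams(
            cse_gain=g, congruency_effect=(0.0,) * 5, subject_sd=0.0,
            cse_condition_sd=0.0, trial_sd=0.0, response_repetition_effect=0.0,
            post_error_slowing=0.0, error_base_rate=1e-4,
            error_congruency_increment=0.0, error_cse_gain=0.0, seed=0,
        )
        trials = bs.simulate_trials(p, exp1_small_schedule)
        # the generator contract is exact before repetition centering
        filt, _ = bc.filter_trials(trials, "RT")
        cells = bc.build_similarity_cse_design(bc.build_cse_cells(filt, "RT"))
        tab, fit = bc.two_stage_cse(cells)
        assert np.allclose(tab["cse"], 2.0 * g * tab["similarity"], atol=1e-9)
        assert fit.slope["beta"] > 0

    def test_one_and_two_stage_slopes_positively_correlated(
        self, exp1_small_schedule
    ):
        """Subjects with genuinely different CSE gains: both estimators must
        rank them consistently."""
        gains = np.linspace(0.0, 30.0, exp1_small_schedule["subject"].nunique())
        parts = []
        for gain, (subj, sub) in zip(
            gains, exp1_small_schedule.groupby("subject")
        ):
            p = bs.BehaviorGenParams(seed=17 + subj, cse_gain=float(gain))
            parts.append(bs.simulate_trials(p, sub))
        trials = pd.concat(parts, ignore_index=True)
        cells = bc.cse_cells(trials, "RT")
        one = bc.fit_one_stage(cells).per_subject_slopes
        _, two = bc.two_stage_cse(cells)
        joined = pd.concat([one, two.per_subject_slopes], axis=1).dropna()
        assert joined.iloc[:, 0].std() > 0 and joined.iloc[:, 1].std() > 0
        r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        assert r > 0


class TestLeaveOneOut:
    def test_noiseless_generator_perfect_prediction(self, exp1_small_schedule):
        p = bs.BehaviorGenParams(
            cse_gain=6.0, congruency_effect=(0.0,) * 5, subject_sd=0.0,
            cse_condition_sd=0.0, trial_sd=0.0, response_repetition_effect=0.0,
            post_error_slowing=0.0, error_base_rate=1e-4,
            error_congruency_increment=0.0, error_cse_gain=0.0, seed=0,
        )
        trials = bs.simulate_trials(p, exp1_small_schedule)
        filt, _ = bc.filter_trials(trials, "RT")
        cells = bc.build_similarity_cse_design(bc.build_cse_cells(filt, "RT"))
        out, r = bc.loo_similarity_prediction(cells)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert set(out["delta_deg"]) == set(bc.SIMILARITY_LEVELS)

    def test_moderate_noise_high_positive_r(self, exp1_small_schedule):
        p = bs.calibrate_cse_gain(
            bs.BehaviorGenParams(seed=19, trial_sd=50.0),
            exp1_small_schedule, "RT", target=0.2,
        )
        cells = bc.cse_cells(bs.simulate_trials(p, exp1_small_schedule), "RT")
        _, r = bc.loo_similarity_prediction(cells)
        assert r > 0.3


class TestCongruencySummary:
    def test_recovers_generator_effects(self, exp1_small_schedule):
        effects = (30.0, 50.0, 60.0, 50.0, 40.0)
        p = bs.BehaviorGenParams(
            congruency_effect=effects, cse_gain=0.0, subject_sd=10.0,
            cse_condition_sd=0.0, trial_sd=40.0, seed=2,
        )
        trials = bs.simulate_trials(p, exp1_small_schedule)
        per_subject, group = bc.congruency_effect_summary(trials)
        rt = group.query("measure == 'RT'").set_index("conflict_type")["group_mean"]
        assert np.allclose(
            rt.reindex(list(bs.CONFLICT_TYPE_NAMES)).to_numpy(), effects, atol=4.0
        )
        # incongruent slower: all effects positive
        assert (rt > 0).all()
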