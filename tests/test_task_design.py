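import math

import numpy as np
import pytest

from conflictspace import task_design as td


class TestConflictTypes:
    def test_ordered_angles_and_weights(self):
        types = td.conflict_types()
        assert [t.name for t in types] == list(td.CONFLICT_TYPE_NAMES)
        assert [t.axis_angle for t in types] == [90.0, 67.5, 45.0, 22.5, 0.0]
        for t in types:
            assert t.stroop_weight**2 + t.simon_weight**2 == pytest.approx(1.0)
        # pure types sit on the axes
        assert types[0].simon_weight == pytest.approx(0.0, abs=1e-12)
        assert types[-1].stroop_weight == pytest.approx(0.0, abs=1e-12)
        deltas = np.diff([t.axis_angle for t in types])
        assert np.allclose(deltas, -22.5)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("Stroop", "Stroop", 1.0),
            ("Stroop", "Simon", 0.0),
            ("Stroop", "StHSmL", math.cos(math.radians(22.5))),
            ("StMSmM", "Simon", math.cos(math.radians(45.0))),
        ],
    )
    def test_conflict_similarity(self, a, b, expected):
        ta, tb = td.conflict_type_by_name(a), td.conflict_type_by_name(b)
        assert td.conflict_similarity(ta, tb) == pytest.approx(expected, abs=1e-12)
        assert td.conflict_similarity(tb, ta) == pytest.approx(expected, abs=1e-12)

    def test_similarity_matrix_is_psd(self):
        m = td.conflict_similarity_matrix()
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() >= -1e-10


class TestOrientation:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            (22.5, 202.5, 1.0),  # same axis, opposite endpoints
            (22.5, 157.5, math.cos(math.radians(45.0))),
            (0.0, 90.0, 0.0),  # horizontal vs vertical
        ],
    )
    def test_orientation_similarity(self, p, q, expected):
        lp, lq = td.StimulusLocation(p), td.StimulusLocation(q)
        assert td.orientation_similarity(lp, lq) == pytest.approx(expected, abs=1e-12)


class TestConditionLocation:
    def test_examples(self):
        prof_trbl = td.SubjectProfile(0, "TR-BL")
        stroop_c_up = td.Condition(td.conflict_type_by_name("Stroop"), "C", "up")
        assert td.condition_location(stroop_c_up, prof_trbl).polar_angle == 90.0
        simon_c_up = td.Condition(td.conflict_type_by_name("Simon"), "C", "up")
        assert td.condition_location(simon_c_up, prof_trbl).polar_angle == 0.0
        mixed = td.Condition(td.conflict_type_by_name("StHSmL"), "I", "down")
        assert td.condition_location(mixed, prof_trbl).polar_angle == 67.5

    def test_round_trip_congruency(self):
        """Recomputing both congruency sources from the chosen location must
        reproduce the condition's congruency flag, for every condition and
        both participant groups."""
        for group in td.GROUPS:
            prof = td.SubjectProfile(0, group)
            for cond in td.conditions():
                loc = td.condition_location(cond, prof)
                resp = prof.response_for(cond.direction)
                want = cond.congruency == "C"
                if abs(loc.y) > 1e-9:
                    assert ((cond.direction == "up") == (loc.y > 0)) == want
                if abs(loc.x) > 1e-9:
                    assert ((resp == "right") == (loc.x > 0)) == want

    def test_malformed_profile_raises(self):
        bad = td.SubjectProfile(0, "TR-BL", response_mapping="up-left")
        cond = td.Condition(td.conflict_type_by_name("StHSmL"), "I", "down")
        with pytest.raises(ValueError, match="congruency coincidence"):
            td.condition_location(cond, bad)

    def test_ten_locations_per_group(self):
        for group in td.GROUPS:
            prof = td.SubjectProfile(0, group)
            locs = {
                td.condition_location(c, prof).polar_angle for c in td.conditions()
            }
            assert len(locs) == 10
            # horizontal and vertical endpoints are shared by both groups
            assert {0.0, 90.0, 180.0, 270.0} <= locs


class TestBalancedSequence:
    @pytest.mark.parametrize("k", range(1, 11))
    def test_every_transition_exactly_once(self, k):
        labels = [f"c{i}" for i in range(k)]
        seq = td.generate_balanced_sequence(labels, seed=k)
        assert len(seq) == k * k + 1
        counts = np.zeros((k, k), dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[labels.index(a), labels.index(b)] += 1
        assert (counts == 1).all()

    def test_seed_reproducible_and_varied(self):
        labels = list("abcde")
        s1 = td.generate_balanced_sequence(labels, seed=1)
        s2 = td.generate_balanced_sequence(labels, seed=1)
        s3 = td.generate_balanced_sequence(labels, seed=2)
        assert s1 == s2
        assert s1 != s3

    def test_k2_enumeration(self):
        seq = td.generate_balanced_sequence(["A", "B"], seed=0)
        assert len(seq) == 5
        pairs = set(zip(seq[:-1], seq[1:]))
        assert pairs == {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}


class TestBuildExperiment:
    def test_exp1_shape(self, exp1_small_schedule):
        per_subject = exp1_small_schedule.groupby("subject").size()
        assert (per_subject == 30 * 101).all()
        assert exp1_small_schedule["session"].nunique() == 3
        runs = exp1_small_schedule.groupby(["subject", "run"]).size()
        assert (runs == 101).all()

    def test_exp2_shape_and_counts(self, exp2_small_schedule):
        per_subject = exp2_small_schedule.groupby("subject").size()
        assert (per_subject == 340).all()
        type_counts = exp2_small_schedule.groupby(["subject", "conflict_type"]).size()
        assert type_counts.between(64, 73).all()

    def test_fixation_jitter_and_timing(self, exp1_small_schedule):
        fix = exp1_small_schedule["fix1_ms"]
        assert fix.between(100, 300).all()

    def test_direction_cells_balanced(self, exp1_small_schedule):
        cells = exp1_small_schedule.groupby(
            ["subject", "conflict_type", "congruency", "direction"]
        ).size()
        # 303 trials per task condition per subject, split nearly evenly
        assert cells.min() >= 140 and cells.max() <= 163

    def test_unknown_experiment(self, profiles6):
        with pytest.raises(ValueError, match="unknown experiment"):
            td.build_experiment({"experiment": "exp3"}, profiles6)
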