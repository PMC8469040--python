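"""RULA engine: banding rules, lookup tables, adjustments, composition."""

import hashlib
import itertools
import json
from importlib import resources

import pydantic
import pytest

from ergorula import (
    ArmWristScores,
    DomainError,
    NeckTrunkLegsScores,
    action_level,
    consolidate,
    force_load_score,
    grand_score,
    muscle_use_score,
    posture_score_a,
    posture_score_b,
    score_arm_wrist,
    score_neck_trunk_legs,
    score_task,
)
from ergorula.simulate import SimulationConfig, default_templates, simulate_observations


class TestSegmentBanding:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({}, (1, 1, 1, 1)),  # neutral standing posture
            (
                dict(
                    upper_arm_flexion=100,
                    shoulder_raised=True,
                    upper_arm_abducted=True,
                    lower_arm_flexion=80,
                    wrist_flexion=10,
                ),
                (6, 1, 2, 1),
            ),
            (
                dict(
                    upper_arm_flexion=30,
                    lower_arm_flexion=120,
                    arm_across_midline_or_out=True,
                    wrist_flexion=20,
                    wrist_deviated=True,
                    wrist_twist_end_range=True,
                ),
                (2, 3, 4, 2),
            ),
            # boundary: wrist exactly 15 deg stays in the 0-15 band
            (dict(wrist_flexion=15), (1, 1, 2, 1)),
            # extension beyond 20 deg scores 2; arm support floors at 1
            (dict(upper_arm_flexion=-30, arm_supported_or_leaning=True), (1, 1, 1, 1)),
            # negative wrist deviation bands by magnitude
            (dict(wrist_flexion=-20), (1, 1, 3, 1)),
        ],
    )
    def test_arm_wrist_banding(self, make_obs, overrides, expected):
        s = score_arm_wrist(make_obs(**overrides))
        assert (s.upper_arm, s.lower_arm, s.wrist, s.wrist_twist) == expected

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({}, (1, 1, 1)),  # neutral
            (
                dict(
                    neck_flexion=25,
                    neck_twisted=True,
                    trunk_flexion=65,
                    trunk_side_bent=True,
                    legs_and_feet_supported=False,
                ),
                (4, 5, 2),
            ),
            (dict(neck_flexion=15, trunk_flexion=40), (2, 3, 1)),
            # shared boundary 20 deg is lower-inclusive for the 20-60 band
            (dict(trunk_flexion=20), (1, 3, 1)),
            (dict(neck_in_extension=True), (4, 1, 1)),
        ],
    )
    def test_neck_trunk_legs_banding(self, make_obs, overrides, expected):
        s = score_neck_trunk_legs(make_obs(**overrides))
        assert (s.neck, s.trunk, s.legs) == expected

    def test_non_finite_angle_rejected(self, make_obs):
        with pytest.raises(pydantic.ValidationError):
            make_obs(upper_arm_flexion=float("nan"))
        with pytest.raises(pydantic.ValidationError):
            make_obs(trunk_flexion=float("inf"))


class TestLookupTables:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((1, 1, 1, 1), 1),
            ((6, 3, 4, 2), 9),
            ((4, 1, 3, 1), 4),
            ((3, 2, 2, 1), 4),
            ((2, 3, 3, 1), 4),
        ],
    )
    def test_table_a_cells(self, scores, expected):
        assert posture_score_a(ArmWristScores(*scores)) == expected

    @pytest.mark.parametrize(
        "scores, expected",
        [((1, 1, 1), 1), ((6, 6, 2), 9), ((2, 3, 1), 4), ((2, 4, 2), 5), ((1, 3, 2), 4)],
    )
    def test_table_b_cells(self, scores, expected):
        assert posture_score_b(NeckTrunkLegsScores(*scores)) == expected

    @pytest.mark.parametrize(
        "cd, expected", [((1, 1), 1), ((8, 7), 7), ((12, 9), 7), ((3, 3), 3), ((5, 5), 6)]
    )
    def test_table_c_cells(self, cd, expected):
        assert grand_score(*cd) == expected

    def test_table_a_total_and_monotone(self):
        domain = list(itertools.product(range(1, 7), range(1, 4), range(1, 5), range(1, 3)))
        values = {t: posture_score_a(ArmWristScores(*t)) for t in domain}
        assert all(1 <= v <= 9 for v in values.values())
        for t in domain:
            for axis in range(4):
                bumped = list(t)
                bumped[axis] += 1
                if tuple(bumped) in values:
                    assert values[tuple(bumped)] >= values[t], (t, axis)

    def test_table_b_total_and_monotone(self):
        domain = list(itertools.product(range(1, 7), range(1, 7), range(1, 3)))
        values = {t: posture_score_b(NeckTrunkLegsScores(*t)) for t in domain}
        assert all(1 <= v <= 9 for v in values.values())
        for t in domain:
            for axis in range(3):
                bumped = list(t)
                bumped[axis] += 1
                if tuple(bumped) in values:
                    assert values[tuple(bumped)] >= values[t], (t, axis)

    def test_table_c_monotone_and_clamped(self):
        for c in range(1, 16):
            for d in range(1, 16):
                g = grand_score(c, d)
                assert 1 <= g <= 7
                assert g == grand_score(min(c, 8), min(d, 7))
                assert grand_score(c + 1, d) >= g
                assert grand_score(c, d + 1) >= g

    def test_out_of_range_lookups_raise(self):
        with pytest.raises(DomainError):
            ArmWristScores(7, 1, 1, 1)
        with pytest.raises(DomainError):
            NeckTrunkLegsScores(1, 1, 3)
        with pytest.raises(DomainError):
            grand_score(0, 1)

    def test_assets_match_recorded_checksums(self):
        data = resources.files("ergorula.data")
        recorded = json.loads(data.joinpath("checksums.json").read_text())
        for name, expected in recorded.items():
            text = data.joinpath(name).read_text(encoding="utf-8")
            assert hashlib.sha256(text.encode()).hexdigest() == expected, name


class TestAdjustments:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            (dict(repetitions_per_min=12), 1),
            (dict(repetitions_per_min=0), 0),
            (dict(posture_static_over_1min=True), 1),
            (dict(repetitions_per_min=4), 0),  # threshold is strictly greater
            (dict(repetitions_per_min=4.5), 1),
        ],
    )
    def test_muscle_use(self, make_obs, overrides, expected):
        assert muscle_use_score(make_obs(**overrides)) == expected

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            (dict(load_kg=1), 0),
            (dict(load_kg=5), 1),
            (dict(load_kg=5, load_static_or_repeated=True), 2),
            (dict(load_kg=15, load_static_or_repeated=True), 3),
            (dict(load_kg=12), 3),
            (dict(load_kg=1, shock_or_rapid_force=True), 3),
            (dict(load_kg=10), 1),  # 10 kg sits in the 2-10 band; >10 is strict
            (dict(load_kg=2), 1),
        ],
    )
    def test_force_load(self, make_obs, overrides, expected):
        assert force_load_score(make_obs(**overrides)) == expected

    def test_negative_load_rejected(self, make_obs):
        with pytest.raises(pydantic.ValidationError):
            make_obs(load_kg=-1)


class TestGrandScoreAndActionLevel:
    def test_action_level_footnote_mapping(self):
        assert [action_level(g) for g in range(1, 8)] == [1, 1, 2, 2, 3, 3, 4]

    def test_action_level_monotone(self):
        levels = [action_level(g) for g in range(1, 8)]
        assert levels == sorted(levels)

    @pytest.mark.parametrize("grand", [0, 8, 3.5])
    def test_action_level_domain(self, grand):
        with pytest.raises(DomainError):
            action_level(grand)


class TestScoreTask:
    def test_neutral_posture_scores_minimum(self, neutral_obs):
        b = score_task(neutral_obs)
        assert b.grand == 1
        assert b.action_level == 1

    def test_equals_composition_of_parts(self):
        config = SimulationConfig(n_workers=112, tasks=tuple(default_templates()), seed=20210908)
        table = simulate_observations(config)
        assert len(table.rows) >= 1000
        for obs in table.rows:
            b = score_task(obs)
            aw = score_arm_wrist(obs)
            ntl = score_neck_trunk_legs(obs)
            pa, pb = posture_score_a(aw), posture_score_b(ntl)
            m, f = muscle_use_score(obs), force_load_score(obs)
            assert b.arm_wrist == aw and b.neck_trunk_legs == ntl
            assert (b.score_c, b.score_d) == (pa + m + f, pb + m + f)
            assert b.grand == grand_score(b.score_c, b.score_d)
            assert b.action_level == action_level(b.grand)


class TestConsolidate:
    def _with_grand(self, make_obs, grand_targets):
        """Build breakdowns with the requested grand scores for one worker-task."""
        recipes = {
            1: {},
            5: dict(upper_arm_flexion=100, trunk_flexion=40, load_kg=5),
            6: dict(upper_arm_flexion=100, trunk_flexion=40, load_kg=5,
                    repetitions_per_min=12),
            7: dict(upper_arm_flexion=100, shoulder_raised=True, trunk_flexion=65,
                    repetitions_per_min=12, load_kg=15),
        }
        out = []
        for i, g in enumerate(grand_targets):
            obs = make_obs(observer_id=f"obs{i}", **recipes[g])
            b = score_task(obs)
            assert b.grand == g, "recipe must hit the target grand score"
            out.append(b)
        return out

    def test_unanimity(self, make_obs):
        bs = self._with_grand(make_obs, [5, 5, 5])
        assert consolidate(bs) == bs[0]

    def test_mode_wins(self, make_obs):
        bs = self._with_grand(make_obs, [5, 5, 7])
        assert consolidate(bs).grand == 5

    def test_tie_breaks_high(self, make_obs):
        bs = self._with_grand(make_obs, [5, 7])
        assert consolidate(bs).grand == 7

    def test_empty_and_mixed_rejected(self, make_obs):
        with pytest.raises(DomainError):
            consolidate([])
        a = score_task(make_obs())
        b = score_task(make_obs(task_id="other"))
        with pytest.raises(DomainError):
            consolidate([a, b])
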