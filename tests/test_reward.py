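"""Staged scoring: filter, partial reward, 2D reward, harmonic combination."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaffhop import chem
from scaffhop.reward import (
    ReferencePack,
    RewardConfig,
    final_reward,
    molecule_filter,
    score_2d,
    score_design,
)
from scaffhop.scaffoldfinder import find_scaffold

GENEROUS = RewardConfig(mw_max=1000.0, rotatable_max=20, stereocenter_max=10)

unit = st.floats(0.01, 1.0, allow_nan=False)
weight = st.floats(0.1, 10.0, allow_nan=False)


class TestMoleculeFilter:
    def test_benzene_passes_generous_thresholds(self):
        assert molecule_filter(chem.canonicalize("c1ccccc1"), GENEROUS)

    def test_each_threshold_fails_independently(self):
        mol = chem.canonicalize("CCCCCCCCCCCCCCCC")  # MW 226, 13 rotors
        assert not molecule_filter(mol, RewardConfig(mw_max=100.0, rotatable_max=20, stereocenter_max=5))
        assert not molecule_filter(mol, RewardConfig(mw_max=1000.0, rotatable_max=3, stereocenter_max=5))

    def test_reference_survives_its_own_derived_thresholds(self, task):
        cfg = RewardConfig().resolve_thresholds(task.reference)
        assert molecule_filter(task.reference, cfg)

    def test_unresolved_thresholds_raise(self):
        with pytest.raises(ValueError):
            molecule_filter(chem.canonicalize("C"), RewardConfig())


class TestScore2D:
    def test_identical_scaffolds_score_zero(self, reference_pack):
        assert score_2d(reference_pack.scaffold, reference_pack.scaffold_fp) == 0.0

    def test_different_ring_systems_score_inbetween(self, task, reference_pack):
        hop = chem.canonicalize("CCc1ccc(CN)nc1")  # pyridine analog
        decomp = find_scaffold(hop, list(task.decorations), alpha=1.0)
        s2d = score_2d(decomp.scaffold, reference_pack.scaffold_fp)
        assert 0.0 < s2d < 1.0


class TestFinalReward:
    @given(s=unit, w2d=weight, w3d=weight)
    @settings(deadline=None)
    def test_equal_inputs_pass_through(self, s, w2d, w3d):
        cfg = RewardConfig(w_2d=w2d, w_3d=w3d, mw_max=1.0, rotatable_max=1, stereocenter_max=1)
        assert final_reward(s, s, cfg) == pytest.approx(s)

    def test_hand_worked_example(self):
        # (1.5 + 1.0) / (1.5/0.5 + 1.0/1.0) = 2.5 / 4.0
        assert final_reward(0.5, 1.0, RewardConfig()) == pytest.approx(0.625)

    @pytest.mark.parametrize("s2d,s3d", [(0.0, 0.8), (0.7, 0.0), (0.0, 0.0)])
    def test_zero_annihilates(self, s2d, s3d):
        assert final_reward(s2d, s3d, RewardConfig()) == 0.0

    @given(a=unit, b=unit, w2d=weight, w3d=weight)
    @settings(deadline=None)
    def test_harmonic_mean_bounds(self, a, b, w2d, w3d):
        cfg = RewardConfig(w_2d=w2d, w_3d=w3d)
        sf = final_reward(a, b, cfg)
        assert min(a, b) - 1e-12 <= sf <= max(a, b) + 1e-12

    @given(a=unit, b=unit, delta=st.floats(0.01, 0.5))
    @settings(deadline=None)
    def test_monotone_in_each_argument(self, a, b, delta):
        cfg = RewardConfig()
        assert final_reward(min(a + delta, 1.0), b, cfg) >= final_reward(a, b, cfg)
        assert final_reward(a, min(b + delta, 1.0), cfg) >= final_reward(a, b, cfg)

    def test_weight_shift_pulls_toward_2d(self):
        s2d, s3d = 0.3, 0.9
        light = final_reward(s2d, s3d, RewardConfig(w_2d=1.0, w_3d=1.0))
        heavy = final_reward(s2d, s3d, RewardConfig(w_2d=5.0, w_3d=1.0))
        assert abs(heavy - s2d) < abs(light - s2d)


class TestScoreDesignPipeline:
    def test_no_decorations_scores_zero(self, reference_pack, task):
        cfg = RewardConfig().resolve_thresholds(task.reference)
        b = score_design(
            chem.canonicalize("c1ccccc1"), reference_pack, cfg, scorer_3d=lambda *a: 1.0
        )
        assert b.final == 0.0 and b.success_score == 0.0

    def test_partial_inclusion_earns_flat_reward_without_3d(self, reference_pack, task):
        cfg = RewardConfig().resolve_thresholds(task.reference)
        calls = []

        def counting_scorer(mol, ref, c):
            calls.append(mol)
            return 1.0

        partial = chem.canonicalize(task.partial_designs[0])
        b = score_design(partial, reference_pack, cfg, scorer_3d=counting_scorer)
        assert b.final == pytest.approx(0.3)
        assert b.s2d is None and b.s3d is None
        assert calls == []  # 3D stage short-circuited

    def test_filter_failure_scores_zero_before_matching(self, reference_pack, task):
        cfg = RewardConfig(mw_max=10.0, rotatable_max=0, stereocenter_max=0)
        b = score_design(task.reference, reference_pack, cfg, scorer_3d=lambda *a: 1.0)
        assert b.filtered and b.final == 0.0

    def test_reference_against_itself_is_the_worst_hop(self, reference_pack, task):
        cfg = RewardConfig().resolve_thresholds(task.reference)
        b = score_design(task.reference, reference_pack, cfg, scorer_3d=lambda *a: 1.0)
        assert b.success_score == 1.0
        assert b.s2d == 0.0
        assert b.final == 0.0  # perfect self-copy: zero 2D distance

    def test_true_hop_rewarded(self, reference_pack, task):
        cfg = RewardConfig().resolve_thresholds(task.reference)
        hop = chem.canonicalize("CCc1cc(CN)cs1")  # thiophene core, both decorations
        b = score_design(hop, reference_pack, cfg, scorer_3d=lambda *a: 1.0)
        assert b.success_score == 1.0
        assert 0.0 < b.s2d <= 1.0
        assert b.final == pytest.approx(
            final_reward(b.s2d, 1.0, cfg)
        )


class TestReferencePack:
    def test_build_requires_exact_self_decomposition(self, task):
        with pytest.raises(ValueError):
            ReferencePack.build(
                chem.canonicalize("c1ccccc1"), list(task.decorations)
            )

    def test_scaffold_keeps_attachment_dummies(self, reference_pack):
        dummies = [
            a
            for a in reference_pack.scaffold.mol.GetAtoms()
            if a.GetAtomicNum() == 0
        ]
        assert len(dummies) == len(reference_pack.decorations)
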