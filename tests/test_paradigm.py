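"""Schedule generation: blocks, decay blocks, closed-loop de-adaptation."""

import numpy as np
import pandas as pd
import pytest

import dualadapt as da
from dualadapt.paradigm import (adaptation_block_plan, build_decay_block,
                                build_standard_block, schedule_from_csv,
                                schedule_to_csv)

ADAPT_MAP = {1: 1.0, 2: -1.0}


def block_df(trials):
    return pd.DataFrame(trials, columns=["cue", "trial_type", "field_sign",
                                         "decay_flag"])


class TestStandardBlock:
    @pytest.mark.parametrize("seed", range(100))
    def test_composition_for_any_seed(self, seed):
        """16 trials, 8 per cue, exactly one channel trial per cue."""
        block = block_df(build_standard_block(ADAPT_MAP,
                                              np.random.default_rng(seed)))
        assert len(block) == 16
        for cue in (1, 2):
            sub = block[block["cue"] == cue]
            assert len(sub) == 8
            assert (sub["trial_type"] == "channel").sum() == 1

    def test_same_multiset_across_seeds(self):
        b1 = build_standard_block(ADAPT_MAP, np.random.default_rng(1))
        b2 = build_standard_block(ADAPT_MAP, np.random.default_rng(2))
        assert sorted(b1) == sorted(b2)


class TestDecayBlock:
    def test_exp1_motif(self):
        """Exposure trial, then 5 same-cue channel trials, then an exposure
        trial of the opposite cue."""
        block = block_df(build_decay_block(1, ADAPT_MAP, 5, True,
                                           np.random.default_rng(0)))
        assert len(block) == 16
        assert block.iloc[0].tolist() == [1, "field", 1.0, False]
        run = block.iloc[1:6]
        assert (run["cue"] == 1).all() and (run["trial_type"] == "channel").all()
        assert run["decay_flag"].all()
        assert block.iloc[6]["cue"] == 2 and block.iloc[6]["trial_type"] == "field"
        # standard composition preserved: 8 per cue, 1 non-decay channel for
        # the opposite cue
        assert (block["cue"] == 1).sum() == (block["cue"] == 2).sum() == 8
        other = block[(block["cue"] == 2)]
        assert (other["trial_type"] == "channel").sum() == 1

    def test_exp2_motif(self):
        block = block_df(build_decay_block(2, ADAPT_MAP, 3, False,
                                           np.random.default_rng(0)))
        assert block.iloc[0].tolist() == [2, "field", -1.0, False]
        run = block.iloc[1:4]
        assert (run["cue"] == 2).all() and (run["trial_type"] == "channel").all()
        assert run["decay_flag"].all()
        assert (block["cue"] == 1).sum() == 8


class TestAdaptationPlan:
    def test_exp1_decay_region(self):
        plan = adaptation_block_plan(da.ExperimentConfig.exp1())
        assert len(plan) == 47
        region = plan[25:45]  # blocks 26-45, 1-based
        decays = [c for c in region if c is not None]
        assert len(decays) == 10
        assert decays == [1, 2] * 5
        # interspersed standard blocks alternate with decay blocks
        assert region[0] is not None and region[1] is None
        assert all(c is None for c in plan[:25]) and plan[45] is None

    def test_exp2_decay_region(self):
        plan = adaptation_block_plan(da.ExperimentConfig.exp2())
        assert len(plan) == 60
        region = plan[40:50]
        assert region == [1, 2] * 5
        assert all(c is None for c in plan[:40]) and all(
            c is None for c in plan[50:])


class TestTerminationRule:
    @pytest.mark.parametrize("exp,m1,m2,expected", [
        ("exp1", -0.05, 0.02, True),
        ("exp1", 0.10, -0.20, False),
        ("exp2", -0.01, 0.03, True),
        ("exp2", -0.01, -0.02, False),
        ("exp2", 0.01, 0.03, False),
    ])
    def test_criteria(self, exp, m1, m2, expected):
        assert da.deadaptation_should_stop(exp, m1, m2) is expected

    def test_not_evaluable_returns_false(self):
        assert da.deadaptation_should_stop("exp1", None, 0.1) is False


class TestClosedLoop:
    def test_exp1_phase_trial_counts(self, exp1_dataset):
        counts = exp1_dataset.phase_counts()
        assert counts["pre"] == 160
        assert counts["adaptation"] == 752
        assert 64 <= counts["deadaptation"] <= 400
        assert counts["clamp"] == 320

    def test_exp2_phase_trial_counts(self, exp2_dataset):
        counts = exp2_dataset.phase_counts()
        assert counts["pre"] == 160
        assert counts["adaptation"] == 960
        assert 64 <= counts["deadaptation"] <= 320
        assert counts["clamp"] == 160

    def test_phase_field_mapping(self, exp1_dataset):
        df = exp1_dataset.df
        pre = df[df["phase"] == "pre"]
        assert (pre["field_sign"] == 0.0).all()
        adapt = df[df["phase"] == "adaptation"]
        assert (adapt.loc[adapt["cue"] == 1, "field_sign"] == 1.0).all()
        deadapt = df[df["phase"] == "deadaptation"]
        assert (deadapt.loc[deadapt["cue"] == 1, "field_sign"] == -1.0).all()

    def test_clamp_phase_all_channel_balanced(self, exp1_dataset):
        clamp = exp1_dataset.df[exp1_dataset.df["phase"] == "clamp"]
        assert (clamp["trial_type"] == "channel").all()
        for _, block in clamp.groupby("block"):
            assert (block["cue"] == 1).sum() == (block["cue"] == 2).sum() == 8

    def test_frozen_participant_hits_cap(self, exp1_config):
        """A participant that never de-adapts (frozen state: all learning
        rates 0, noise-free) runs the de-adaptation phase to its cap."""
        frozen = da.ParameterSet(A_f=1.0, A_s=1.0)
        ds = da.generate_participant(da.ModelSpec.from_id("2f_2s_bin"),
                                     frozen, exp1_config, 0.0, seed=0)
        assert ds.deadapt_blocks == 25
        assert ds.termination == "cap"
        assert ds.phase_counts()["deadaptation"] == 400

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_deadaptation_within_bounds(self, true_model, exp2_config, seed):
        spec, params = true_model
        ds = da.generate_participant(spec, params, exp2_config,
                                     da.NOISE_HALFWIDTH["exp2"], seed=seed)
        assert 4 <= ds.deadapt_blocks <= 20

    def test_determinism_under_fixed_seed(self, true_model, exp2_config):
        spec, params = true_model
        a = da.generate_participant(spec, params, exp2_config, 0.05, seed=42)
        b = da.generate_participant(spec, params, exp2_config, 0.05, seed=42)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_block_sizes(self, exp1_dataset):
        sizes = exp1_dataset.df.groupby("block").size()
        assert (sizes == 16).all()

    def test_schedule_csv_roundtrip(self, exp2_dataset, tmp_path):
        path = tmp_path / "schedule.csv"
        schedule_to_csv(exp2_dataset.schedule, path)
        back = schedule_from_csv(path)
        pd.testing.assert_frame_equal(back, exp2_dataset.schedule)

    def test_csv_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"trial": [0], "cue": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            schedule_from_csv(path)
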