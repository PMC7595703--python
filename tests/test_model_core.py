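"""Dynamics of the twelve-model family: gating, stepping, decay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dualadapt as da
from dualadapt.model_core import simulate_outputs_fast

from conftest import classic_two_state


def make_schedule(cues, types, signs):
    return pd.DataFrame({
        "cue": cues,
        "trial_type": types,
        "field_sign": signs,
    })


SMITH = da.SMITH_DUAL_RATE


class TestSpecs:
    def test_twelve_valid_combinations(self):
        assert len(da.MODEL_SPECS) == 12
        assert len(set(da.MODEL_IDS)) == 12

    @pytest.mark.parametrize("model_id,k", [
        ("1f_2s_bin", 4), ("1f_2s_wgt", 5), ("2f_3s_bin", 6),
        ("2f_3s_wgt", 7), ("1f_4s_bin", 8), ("2f_4s_wgt", 9),
    ])
    def test_parameter_count(self, model_id, k):
        assert da.ModelSpec.from_id(model_id).k == k

    def test_id_roundtrip(self):
        for spec in da.MODEL_SPECS:
            assert da.ModelSpec.from_id(spec.model_id) == spec

    def test_invalid_id(self):
        with pytest.raises(ValueError, match="unknown model id"):
            da.ModelSpec.from_id("3f_2s_bin")

    def test_absent_timescales_zeroed(self):
        p = da.ParameterSet(A_f=0.9, A_s=0.99, A_us=0.999, A_hs=0.9999,
                            B_f=0.2, B_s=0.05, B_us=0.01, B_hs=0.005, c=0.8)
        dual = p.for_spec(da.ModelSpec.from_id("2f_2s_bin"))
        assert dual.A_us == dual.B_us == dual.A_hs == dual.B_hs == 0.0
        assert dual.c == 1.0  # binary behaves as c = 1


class TestGateVector:
    def test_binary_is_unit_vector(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        assert da.gate_vector(spec, da.ParameterSet(), 1) == (1.0, 0.0)
        assert da.gate_vector(spec, da.ParameterSet(), 2) == (0.0, 1.0)

    def test_weighted_limit_equals_binary(self):
        spec = da.ModelSpec.from_id("2f_2s_wgt")
        assert da.gate_vector(spec, da.ParameterSet(c=1.0), 2) == (0.0, 1.0)

    def test_weighted_mixture(self):
        spec = da.ModelSpec.from_id("2f_2s_wgt")
        g = da.gate_vector(spec, da.ParameterSet(c=0.92), 2)
        assert g == pytest.approx((0.08, 0.92))

    def test_invalid_cue_raises(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        with pytest.raises(ValueError, match="cue"):
            da.gate_vector(spec, da.ParameterSet(), 3)


class TestPredictOutput:
    def test_zero_state_zero_output(self):
        for spec in da.MODEL_SPECS:
            out = da.predict_output(spec, da.ParameterSet(c=0.7),
                                    da.MemoryState(), 1)
            assert out == 0.0

    def test_binary_gating_zeroes_other_memory(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        state = da.MemoryState(fast=np.array([0.1, 0.4]),
                               slow=np.array([0.2, -0.3]))
        assert da.predict_output(spec, da.ParameterSet(), state, 1) == \
            pytest.approx(0.3)

    def test_shared_fast_is_ungated(self):
        spec = da.ModelSpec.from_id("1f_2s_bin")
        state = da.MemoryState(fast=np.array([0.05, 0.0]),
                               slow=np.array([0.0, 0.2]))
        assert da.predict_output(spec, da.ParameterSet(), state, 2) == \
            pytest.approx(0.25)


class TestStepTrial:
    def test_first_field_trial_from_zero(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        out, err, new = da.step_trial(spec, SMITH, da.MemoryState(),
                                      da.TrialInput(cue=1, trial_type="field",
                                                    field_sign=1.0))
        assert out == 0.0 and err == 1.0
        assert new.fast[0] == pytest.approx(SMITH.B_f)
        assert new.slow[0] == pytest.approx(SMITH.B_s)
        assert new.fast[1] == new.slow[1] == 0.0

    def test_channel_trial_pure_retention(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        state = da.MemoryState(fast=np.array([0.5, 0.0]))
        out, err, new = da.step_trial(spec, SMITH, state,
                                      da.TrialInput(cue=1, trial_type="channel"))
        assert err == 0.0
        assert new.fast[0] == pytest.approx(0.92 * 0.5)

    def test_asymptote_matches_closed_form(self):
        # fixed point of the dual-rate model under a constant unit field:
        # x* = (Bf/(1-Af) + Bs/(1-As)) / (1 + Bf/(1-Af) + Bs/(1-As))
        rf = SMITH.B_f / (1 - SMITH.A_f)
        rs = SMITH.B_s / (1 - SMITH.A_s)
        expected = (rf + rs) / (1 + rf + rs)
        n = 10_000
        sched = make_schedule([1] * n, ["field"] * n, [1.0] * n)
        res = da.simulate_schedule(da.ModelSpec.from_id("2f_2s_bin"), SMITH,
                                   sched)
        assert res.outputs[-1] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.filterwarnings("ignore:invalid value")
    def test_parameter_blowup_raises(self):
        spec = da.ModelSpec.from_id("2f_2s_bin")
        bad = da.ParameterSet(A_f=1.0, B_f=1.0, A_s=1.0, B_s=1.0)
        state = da.MemoryState(fast=np.array([np.inf, 0.0]))
        with pytest.raises(FloatingPointError):
            da.step_trial(spec, bad, state,
                          da.TrialInput(cue=1, field_sign=1.0))


class TestSimulateSchedule:
    @pytest.mark.parametrize("model_id", ["1f_2s_bin", "2f_3s_wgt", "2f_4s_wgt"])
    def test_matches_step_trial_fold(self, model_id):
        """The fast kernel and the readable stepping API agree trial for
        trial (state and output)."""
        spec = da.ModelSpec.from_id(model_id)
        params = da.TABLE1_MEDIANS[model_id]
        rng = np.random.default_rng(5)
        n = 300
        cues = rng.integers(1, 3, n)
        types = np.where(rng.random(n) < 0.2, "channel", "field")
        signs = np.where(cues == 1, 1.0, -1.0)
        sched = make_schedule(cues, types, signs)
        res = da.simulate_schedule(spec, params, sched)
        state = da.MemoryState()
        for i in range(n):
            out, _, state = da.step_trial(
                spec, params, state,
                da.TrialInput(int(cues[i]), str(types[i]), float(signs[i])))
            assert out == pytest.approx(res.outputs[i], abs=1e-12)
            np.testing.assert_allclose(state.to_vector(), res.states[i],
                                       atol=1e-12)

    def test_channel_only_schedule_outputs_zero(self):
        n = 50
        sched = make_schedule([1, 2] * (n // 2), ["channel"] * n, [0.0] * n)
        for model_id in ("1f_2s_bin", "2f_4s_wgt"):
            res = da.simulate_schedule(da.ModelSpec.from_id(model_id),
                                       da.TABLE1_MEDIANS[model_id], sched)
            assert np.all(res.outputs == 0.0)

    def test_retention_only_decay_on_channel_trials(self):
        """After any channel trial each state equals its previous value
        times its retention rate, to machine precision."""
        spec = da.ModelSpec.from_id("2f_3s_wgt")
        params = da.TABLE1_MEDIANS["2f_3s_wgt"]
        sched = make_schedule([1] * 20 + [1, 2] * 5,
                              ["field"] * 20 + ["channel"] * 10,
                              [1.0] * 20 + [0.0] * 10)
        res = da.simulate_schedule(spec, params, sched)
        rates = np.array([params.A_f] * 2 + [params.A_s] * 2 +
                         [params.A_us] * 2 + [params.A_hs] * 2)
        for i in range(20, 30):
            np.testing.assert_array_equal(res.states[i],
                                          rates * res.states[i - 1])

    def test_single_cue_reduction_to_classic_two_state(self):
        """With only cue-1 trials the two-fast binary model is trial for
        trial the classic single-task two-state model."""
        rng = np.random.default_rng(7)
        n = 1000
        signs = np.where(rng.random(n) < 0.5, 1.0, 1.0)
        types = np.where(rng.random(n) < 0.15, "channel", "field")
        sched = make_schedule([1] * n, types, signs)
        res = da.simulate_schedule(da.ModelSpec.from_id("2f_2s_bin"), SMITH,
                                   sched)
        oracle = classic_two_state(SMITH.A_f, SMITH.B_f, SMITH.A_s, SMITH.B_s,
                                   signs, types == "channel")
        assert np.max(np.abs(res.outputs - oracle)) == 0.0

    @pytest.mark.parametrize("model_id", ["1f_3s_wgt", "2f_2s_wgt", "2f_4s_wgt"])
    def test_weighted_c1_matches_binary(self, model_id):
        spec_w = da.ModelSpec.from_id(model_id)
        spec_b = da.ModelSpec(spec_w.n_timescales, spec_w.fast_mode, "binary")
        params = da.TABLE1_MEDIANS[model_id.replace("wgt", "bin")]
        params_c1 = da.ParameterSet.from_dict({**params.to_dict(), "c": 1.0})
        rng = np.random.default_rng(3)
        n = 400
        cues = rng.integers(1, 3, n)
        types = np.where(rng.random(n) < 0.2, "channel", "field")
        sched = make_schedule(cues, types, np.where(cues == 1, 1.0, -1.0))
        out_w = da.simulate_schedule(spec_w, params_c1, sched).outputs
        out_b = da.simulate_schedule(spec_b, params, sched).outputs
        np.testing.assert_array_equal(out_w, out_b)

    @pytest.mark.parametrize("model_id", ["2f_2s_bin", "2f_3s_bin", "2f_4s_bin"])
    def test_antisymmetry_of_opposing_cues(self, model_id):
        """Alternating cues with opposing fields: cue-2 outputs are the
        negation of cue-1 outputs (exact for the binary switch, whose two
        memories receive no cross-cue learning)."""
        spec = da.ModelSpec.from_id(model_id)
        params = da.TABLE1_MEDIANS[model_id]
        n = 600
        cues = np.tile([1, 2], n // 2)
        types = np.array((["field"] * 14 + ["channel"] * 2) * (n // 16) +
                         ["field"] * (n % 16))
        sched = make_schedule(cues, types, np.where(cues == 1, 1.0, -1.0))
        out = da.simulate_schedule(spec, params, sched).outputs
        sums = out[cues == 1] + out[cues == 2]
        assert np.max(np.abs(sums)) < 1e-12

    def test_empty_schedule_raises(self):
        with pytest.raises(ValueError, match="empty"):
            da.simulate_schedule(da.ModelSpec.from_id("2f_2s_bin"), SMITH,
                                 make_schedule([], [], []))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_boundedness_inside_fitting_bounds(self, seed):
        """Outputs stay in a fixed finite band for any parameters inside
        the fitting boxes and |field_sign| <= 1 over 10,000 trials."""
        rng = np.random.default_rng(seed)
        spec = da.MODEL_SPECS[rng.integers(len(da.MODEL_SPECS))]
        bounds = da.parameter_bounds(spec)
        vals = {n: rng.uniform(lo, hi) for n, (lo, hi) in
                zip(bounds.names, bounds.box)}
        params = da.ParameterSet.from_dict(
            {k: vals.get(k, 0.0) for k in da.ParameterSet().to_dict()}
            | ({"c": vals.get("c", 1.0)}))
        n = 10_000
        cues = rng.integers(1, 3, n).astype(np.int64)
        is_channel = rng.random(n) < 0.1
        signs = rng.choice([-1.0, 0.0, 1.0], n)
        out = simulate_outputs_fast(spec, params, cues, is_channel, signs)
        assert np.all(np.abs(out) < 10.0)


class TestSimulateDecay:
    def test_constant_at_rate_one(self):
        np.testing.assert_array_equal(da.simulate_decay(1.0, 0.7, 25),
                                      np.full(25, 0.7))

    def test_halving(self):
        np.testing.assert_allclose(da.simulate_decay(0.5, 1.0, 3),
                                   [0.5, 0.25, 0.125], rtol=0, atol=0)

    def test_matches_iterative_product(self):
        # oracle: repeated multiplication
        A, x0 = 0.993, 1.0
        series = da.simulate_decay(A, x0, 100)
        x = x0
        for m in range(100):
            x *= A
            assert series[m] == pytest.approx(x, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            da.simulate_decay(0.5, 1.0, 0)
        with pytest.raises(ValueError):
            da.simulate_decay(1.5, 1.0, 5)
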