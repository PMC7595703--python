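"""Trial schedules for the two dual-adaptation experiments.

Both experiments follow an A-B-error-clamp design run simultaneously for two
contextual cues with opposing force fields:

* pre-exposure: 10 blocks in the null field,
* adaptation: 47 blocks (exp 1) / 60 blocks (exp 2) with cue 1 -> field +1
  and cue 2 -> field -1 (canonical counterbalance), including a region of
  memory-decay blocks,
* de-adaptation: the cue-field mapping is reversed; the phase length is
  closed-loop, ending when a per-participant performance criterion on the
  channel-trial force compensation is met (or at the block cap),
* error-clamp: 20 blocks (exp 1) / 10 blocks (exp 2) of channel trials only.

Blocks hold 16 trials, 8 per cue; in standard blocks each cue contributes
7 field trials and 1 channel trial, pseudo-randomised by a seeded uniform
shuffle.  Decay blocks embed a run of consecutive same-cue channel trials
(5 in exp 1, 3 in exp 2) directly after an exposure trial of that cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .specs import ModelSpec, ParameterSet

__all__ = [
    "ExperimentConfig",
    "PHASES",
    "build_standard_block",
    "build_decay_block",
    "adaptation_block_plan",
    "build_schedule_prefix",
    "build_clamp_phase",
    "deadaptation_should_stop",
    "run_closed_loop",
    "schedule_to_csv",
    "schedule_from_csv",
]

PHASES = ("pre", "adaptation", "deadaptation", "clamp")

SCHEDULE_COLUMNS = ["trial", "block", "phase", "cue", "trial_type",
                    "field_sign", "decay_flag"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design constants of one experiment.

    Block indices are 1-based within the adaptation phase;
    ``decay_block_range`` is inclusive.  ``deadapt_min``/``deadapt_max``
    bound the closed-loop de-adaptation phase in blocks.
    """

    experiment: str
    pre_blocks: int
    adapt_blocks: int
    decay_block_range: tuple[int, int]
    decay_interspersed: bool
    decay_run_length: int
    deadapt_min: int
    deadapt_max: int
    clamp_blocks: int
    trials_per_block: int = 16
    trials_per_cue: int = 8
    channel_per_cue: int = 1

    @classmethod
    def exp1(cls) -> "ExperimentConfig":
        return cls("exp1", pre_blocks=10, adapt_blocks=47,
                   decay_block_range=(26, 45), decay_interspersed=True,
                   decay_run_length=5, deadapt_min=4, deadapt_max=25,
                   clamp_blocks=20)

    @classmethod
    def exp2(cls) -> "ExperimentConfig":
        return cls("exp2", pre_blocks=10, adapt_blocks=60,
                   decay_block_range=(41, 50), decay_interspersed=False,
                   decay_run_length=3, deadapt_min=4, deadapt_max=20,
                   clamp_blocks=10)

    @classmethod
    def from_name(cls, name: str) -> "ExperimentConfig":
        if name == "exp1":
            return cls.exp1()
        if name == "exp2":
            return cls.exp2()
        raise ValueError(f"unknown experiment {name!r}; expected 'exp1' or 'exp2'")


# A trial is represented while building as (cue, trial_type, field_sign,
# decay_flag); phase/block/trial indices are attached on assembly.
_Trial = tuple[int, str, float, bool]


def _field_sign(cue: int, mapping: dict[int, float]) -> float:
    return mapping[cue]


def build_standard_block(mapping: dict[int, float],
                         rng: np.random.Generator) -> list[_Trial]:
    """One pseudo-randomised standard block: per cue 7 field + 1 channel.

    ``mapping`` gives the field sign per cue (0.0 for null-field blocks).
    """
    trials: list[_Trial] = []
    for cue in (1, 2):
        fs = _field_sign(cue, mapping)
        trials += [(cue, "field", fs, False)] * 7
        trials += [(cue, "channel", fs, False)]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def build_decay_block(decay_cue: int, mapping: dict[int, float],
                      run_length: int, interspersed: bool,
                      rng: np.random.Generator) -> list[_Trial]:
    """One memory-decay block.

    The block opens with an exposure (field) trial of ``decay_cue`` followed
    by ``run_length`` channel trials of the same cue (the decay run).  In the
    exp-1 layout (``interspersed=True``) the run is immediately followed by an
    exposure trial of the opposite cue.  Remaining trials fill the block to
    16 using the standard per-cue composition (field trials plus one channel
    trial for the opposite cue), shuffled.
    """
    other = 2 if decay_cue == 1 else 1
    fs_d = _field_sign(decay_cue, mapping)
    fs_o = _field_sign(other, mapping)
    head: list[_Trial] = [(decay_cue, "field", fs_d, False)]
    head += [(decay_cue, "channel", fs_d, True)] * run_length
    if interspersed:
        head.append((other, "field", fs_o, False))

    n_decay_cue_used = 1 + run_length
    n_other_used = 1 if interspersed else 0
    filler: list[_Trial] = []
    filler += [(decay_cue, "field", fs_d, False)] * (8 - n_decay_cue_used)
    filler += [(other, "field", fs_o, False)] * (8 - n_other_used - 1)
    filler += [(other, "channel", fs_o, False)]
    order = rng.permutation(len(filler))
    block = head + [filler[i] for i in order]
    assert len(block) == 16
    return block


def adaptation_block_plan(config: ExperimentConfig) -> list[int | None]:
    """Per adaptation block: the decay cue (1/2) or None for a standard block.

    Decay blocks sit in ``decay_block_range`` and alternate cues starting
    with cue 1 (5 blocks per cue); in exp 1 a standard block is interspersed
    between consecutive decay blocks.
    """
    lo, hi = config.decay_block_range
    plan: list[int | None] = []
    decay_count = 0
    for b in range(1, config.adapt_blocks + 1):
        if lo <= b <= hi:
            offset = b - lo
            if config.decay_interspersed:
                if offset % 2 == 0:
                    plan.append(1 if decay_count % 2 == 0 else 2)
                    decay_count += 1
                else:
                    plan.append(None)
            else:
                plan.append(1 if decay_count % 2 == 0 else 2)
                decay_count += 1
        else:
            plan.append(None)
    return plan


def _assemble(blocks: list[list[_Trial]], phases: list[str],
              start_trial: int = 0, start_block: int = 0) -> pd.DataFrame:
    records = []
    t = start_trial
    for b, (block, phase) in enumerate(zip(blocks, phases), start=start_block):
        for cue, ttype, fs, dflag in block:
            records.append((t, b, phase, cue, ttype, fs, dflag))
            t += 1
    return pd.DataFrame.from_records(records, columns=SCHEDULE_COLUMNS)


def build_schedule_prefix(config: ExperimentConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Pre-exposure and adaptation phases (fixed-length part of a schedule)."""
    null_map = {1: 0.0, 2: 0.0}
    adapt_map = {1: 1.0, 2: -1.0}
    blocks: list[list[_Trial]] = []
    phases: list[str] = []
    for _ in range(config.pre_blocks):
        blocks.append(build_standard_block(null_map, rng))
        phases.append("pre")
    for decay_cue in adaptation_block_plan(config):
        if decay_cue is None:
            blocks.append(build_standard_block(adapt_map, rng))
        else:
            blocks.append(build_decay_block(decay_cue, adapt_map,
                                            config.decay_run_length,
                                            config.decay_interspersed, rng))
        phases.append("adaptation")
    return _assemble(blocks, phases)


def build_clamp_phase(config: ExperimentConfig, rng: np.random.Generator,
                      start_trial: int, start_block: int) -> pd.DataFrame:
    """Error-clamp phase: all channel trials, 8 per cue per block, shuffled."""
    blocks = []
    for _ in range(config.clamp_blocks):
        trials: list[_Trial] = [(1, "channel", 0.0, False)] * 8
        trials += [(2, "channel", 0.0, False)] * 8
        order = rng.permutation(16)
        blocks.append([trials[i] for i in order])
    return _assemble(blocks, ["clamp"] * config.clamp_blocks,
                     start_trial, start_block)


def deadaptation_should_stop(experiment: str,
                             cue1_last3_mean: float | None,
                             cue2_last3_mean: float | None) -> bool:
    """Closed-loop termination criterion of the de-adaptation phase.

    Inputs are the means of the last three channel-trial force-compensation
    values per cue, computed online on the canonical sign convention (cue 1
    adapts positive).  Experiment 1 ends the phase when the cue difference
    switches sign (cue1 - cue2 < 0); experiment 2 when both cues have crossed
    zero (cue1 < 0 and cue2 > 0).  Not evaluable (fewer than 3 channel
    trials for a cue) -> False.
    """
    if cue1_last3_mean is None or cue2_last3_mean is None:
        return False
    if experiment == "exp1":
        return (cue1_last3_mean - cue2_last3_mean) < 0.0
    if experiment == "exp2":
        return cue1_last3_mean < 0.0 and cue2_last3_mean > 0.0
    raise ValueError(f"unknown experiment {experiment!r}")


def run_closed_loop(spec: ModelSpec, params: ParameterSet,
                    config: ExperimentConfig, noise_halfwidth: float,
                    seed: int, counterbalance: str = "A"):
    """Simulate one participant through the full adaptive paradigm.

    The participant is the given model; channel-trial observations carry
    additive uniform observation noise on [-w, +w], and the noisy values
    drive the online de-adaptation termination, as in the real experiment.
    Returns a :class:`dualadapt.synthetic.Dataset`.
    """
    # local import: synthetic builds on this module
    from .synthetic import Dataset
    from .model_core import simulate_outputs_fast, N_STATE

    if counterbalance not in ("A", "B"):
        raise ValueError(f"counterbalance must be 'A' or 'B', got {counterbalance!r}")
    rng = np.random.default_rng(seed)
    state = np.zeros(N_STATE)

    def simulate_segment(df: pd.DataFrame) -> np.ndarray:
        cue = df["cue"].to_numpy(np.int64)
        is_ch = (df["trial_type"] == "channel").to_numpy()
        fs = df["field_sign"].to_numpy(float)
        out = simulate_outputs_fast(spec, params, cue, is_ch, fs, state)
        obs = np.full(len(df), np.nan)
        if is_ch.any():
            noise = rng.uniform(-noise_halfwidth, noise_halfwidth,
                                int(is_ch.sum()))
            obs[is_ch] = out[is_ch] + noise
        return obs

    prefix = build_schedule_prefix(config, rng)
    segments = [prefix]
    observations = [simulate_segment(prefix)]

    deadapt_map = {1: -1.0, 2: 1.0}
    next_trial = len(prefix)
    next_block = int(prefix["block"].iloc[-1]) + 1
    cue1_obs: list[float] = []
    cue2_obs: list[float] = []
    termination = "cap"
    n_deadapt = 0
    for b in range(config.deadapt_max):
        block_df = _assemble([build_standard_block(deadapt_map, rng)],
                             ["deadaptation"], next_trial, next_block)
        obs = simulate_segment(block_df)
        segments.append(block_df)
        observations.append(obs)
        next_trial += len(block_df)
        next_block += 1
        n_deadapt += 1
        ch = block_df["trial_type"].to_numpy() == "channel"
        for cue_val, store in ((1, cue1_obs), (2, cue2_obs)):
            sel = ch & (block_df["cue"].to_numpy() == cue_val)
            store.extend(obs[np.flatnonzero(sel)])
        if n_deadapt < config.deadapt_min:
            continue
        m1 = float(np.mean(cue1_obs[-3:])) if len(cue1_obs) >= 3 else None
        m2 = float(np.mean(cue2_obs[-3:])) if len(cue2_obs) >= 3 else None
        if deadaptation_should_stop(config.experiment, m1, m2):
            termination = "criterion"
            break

    clamp = build_clamp_phase(config, rng, next_trial, next_block)
    segments.append(clamp)
    observations.append(simulate_segment(clamp))

    schedule = pd.concat(segments, ignore_index=True)
    obs = np.concatenate(observations)
    if counterbalance == "B":
        schedule = schedule.assign(field_sign=-schedule["field_sign"])
        obs = -obs
    df = schedule.assign(fc_observed=obs)
    return Dataset(df=df, counterbalance=counterbalance,
                   noise_halfwidth=noise_halfwidth, spec_id=spec.model_id,
                   params=params, seed=seed, deadapt_blocks=n_deadapt,
                   termination=termination)


def build_spontaneous_recovery_schedule(params: ParameterSet | None = None,
                                        seed: int = 0) -> pd.DataFrame:
    """Schedule for the headline one-fast vs two-fast contrast.

    Pre-exposure and adaptation phases of standard blocks, then a
    de-adaptation phase truncated at the exact trial where a reference
    one-fast-two-slow (binary) model's cue-output difference first returns
    to zero — i.e. where its two slow memories have been driven back to
    equality — then a full error-clamp phase.  On this schedule a
    one-fast-two-slow model shows no spontaneous recovery in the clamp
    phase while a two-fast-two-slow model rebounds toward the first-learned
    field.
    """
    from .model_core import simulate_schedule
    from .specs import SMITH_DUAL_RATE

    if params is None:
        params = SMITH_DUAL_RATE
    config = ExperimentConfig.exp1()
    rng = np.random.default_rng(seed)
    null_map = {1: 0.0, 2: 0.0}
    adapt_map = {1: 1.0, 2: -1.0}
    deadapt_map = {1: -1.0, 2: 1.0}
    blocks, phases = [], []
    for _ in range(config.pre_blocks):
        blocks.append(build_standard_block(null_map, rng))
        phases.append("pre")
    for _ in range(config.adapt_blocks):
        blocks.append(build_standard_block(adapt_map, rng))
        phases.append("adaptation")
    for _ in range(config.deadapt_max):
        blocks.append(build_standard_block(deadapt_map, rng))
        phases.append("deadaptation")
    prefix = _assemble(blocks, phases)

    ref_spec = ModelSpec(2, "one_fast", "binary")
    res = simulate_schedule(ref_spec, params, prefix)
    # for the one-fast model the cue-output difference equals the slow-state
    # difference (the shared fast state cancels)
    slow_diff = res.states[:, 2] - res.states[:, 3]
    in_deadapt = (prefix["phase"] == "deadaptation").to_numpy()
    crossed = np.flatnonzero(in_deadapt & (slow_diff <= 0.0))
    cut = crossed[0] if len(crossed) else len(prefix) - 1
    prefix = prefix.iloc[: cut + 1]

    clamp = build_clamp_phase(config, rng, len(prefix),
                              int(prefix["block"].iloc[-1]) + 1)
    return pd.concat([prefix, clamp], ignore_index=True)


def schedule_to_csv(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False)


def schedule_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    df["decay_flag"] = df["decay_flag"].astype(bool)
    return df
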