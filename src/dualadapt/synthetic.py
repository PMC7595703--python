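"""Synthetic participants: noisy force-compensation datasets.

The generator stands in for human data: it runs a ground-truth model through
the adaptive paradigm and observes its output on channel trials with
additive, independent uniform noise on [-w, +w].  The noise halfwidths
mirror the pre-exposure force-compensation variability of the two cohorts
(w = 0.0831 in experiment 1, w = 0.0715 in experiment 2).  Noise is pure
observation noise: it never enters the state update, but the noisy values do
drive the online de-adaptation termination, as in the real experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import simulate_outputs_fast
from .paradigm import ExperimentConfig, run_closed_loop, SCHEDULE_COLUMNS
from .specs import (DEFAULT_TRUE_MODEL, TABLE1_MEDIANS, ModelSpec,
                    ParameterSet)

__all__ = [
    "Dataset",
    "NOISE_HALFWIDTH",
    "generate_participant",
    "generate_cohort",
    "simulate_on_schedule",
]

#: Uniform observation-noise halfwidths estimated from pre-exposure
#: variability, per experiment.
NOISE_HALFWIDTH = {"exp1": 0.0831, "exp2": 0.0715}


@dataclass
class Dataset:
    """One synthetic participant.

    ``df`` holds the realised schedule plus ``fc_observed`` (the observed
    force compensation, NaN on non-channel trials).  ``counterbalance`` is
    'A' (canonical: cue 1 adapts to field +1) or 'B' (all signs flipped).
    """

    df: pd.DataFrame
    counterbalance: str
    noise_halfwidth: float
    spec_id: str | None = None
    params: ParameterSet | None = None
    seed: int | None = None
    deadapt_blocks: int | None = None
    termination: str | None = None

    @property
    def schedule(self) -> pd.DataFrame:
        return self.df[SCHEDULE_COLUMNS]

    @property
    def channel_mask(self) -> np.ndarray:
        return (self.df["trial_type"] == "channel").to_numpy()

    @property
    def observations(self) -> np.ndarray:
        """Observed force compensation at channel trials, in trial order."""
        return self.df.loc[self.channel_mask, "fc_observed"].to_numpy(float)

    def phase_counts(self) -> dict[str, int]:
        return self.df["phase"].value_counts().to_dict()

    def noise_free_outputs(self) -> np.ndarray:
        """Re-simulate the generating model over the realised schedule."""
        if self.spec_id is None or self.params is None:
            raise ValueError("dataset has no generating model metadata")
        spec = ModelSpec.from_id(self.spec_id)
        sign = -1.0 if self.counterbalance == "B" else 1.0
        out = simulate_outputs_fast(
            spec, self.params,
            self.df["cue"].to_numpy(np.int64),
            self.channel_mask,
            sign * self.df["field_sign"].to_numpy(float))
        return sign * out

    # -- serialization ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the trial table as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {
            "counterbalance": self.counterbalance,
            "noise_halfwidth": self.noise_halfwidth,
            "spec_id": self.spec_id,
            "params": self.params.to_dict() if self.params else None,
            "seed": self.seed,
            "deadapt_blocks": self.deadapt_blocks,
            "termination": self.termination,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        df["decay_flag"] = df["decay_flag"].astype(bool)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        params = meta.get("params")
        return cls(
            df=df,
            counterbalance=meta.get("counterbalance", "A"),
            noise_halfwidth=meta.get("noise_halfwidth", 0.0),
            spec_id=meta.get("spec_id"),
            params=ParameterSet.from_dict(params) if params else None,
            seed=meta.get("seed"),
            deadapt_blocks=meta.get("deadapt_blocks"),
            termination=meta.get("termination"),
        )


def generate_participant(spec: ModelSpec | str, params: ParameterSet,
                         config: ExperimentConfig, noise_halfwidth: float,
                         seed: int, counterbalance: str = "A") -> Dataset:
    """One synthetic participant with an adaptively terminated schedule."""
    if noise_halfwidth < 0:
        raise ValueError("noise_halfwidth must be >= 0")
    if isinstance(spec, str):
        spec = ModelSpec.from_id(spec)
    return run_closed_loop(spec, params, config, noise_halfwidth, seed,
                           counterbalance)


def generate_cohort(spec: ModelSpec | str, params: ParameterSet,
                    config: ExperimentConfig, n_participants: int,
                    noise_halfwidth: float, master_seed: int) -> list[Dataset]:
    """A cohort of synthetic participants with alternating counterbalance.

    Participant seeds are derived deterministically from ``master_seed``;
    even-indexed participants are counterbalance group A, odd-indexed B.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_participants)
    datasets = []
    for i in range(n_participants):
        datasets.append(generate_participant(
            spec, params, config, noise_halfwidth,
            seed=int(seeds[i] % (2 ** 31)),
            counterbalance="A" if i % 2 == 0 else "B"))
    return datasets


def simulate_on_schedule(spec: ModelSpec | str, params: ParameterSet,
                         schedule: pd.DataFrame, noise_halfwidth: float,
                         seed: int, counterbalance: str = "A") -> Dataset:
    """Synthetic dataset over a fixed, already-realised schedule.

    This is the fixed-schedule mode the model-recovery analysis uses: all
    generating models share the identical trial sequence of one participant
    design.  ``schedule`` must be on the canonical sign convention.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_id(spec)
    rng = np.random.default_rng(seed)
    cue = schedule["cue"].to_numpy(np.int64)
    is_ch = (schedule["trial_type"] == "channel").to_numpy()
    fs = schedule["field_sign"].to_numpy(float)
    out = simulate_outputs_fast(spec, params, cue, is_ch, fs)
    obs = np.full(len(schedule), np.nan)
    obs[is_ch] = out[is_ch] + rng.uniform(-noise_halfwidth, noise_halfwidth,
                                          int(is_ch.sum()))
    df = schedule.copy()
    if counterbalance == "B":
        df["field_sign"] = -df["field_sign"]
        obs = -obs
    df["fc_observed"] = obs
    return Dataset(df=df, counterbalance=counterbalance,
                   noise_halfwidth=noise_halfwidth, spec_id=spec.model_id,
                   params=params, seed=seed)


def default_true_params() -> tuple[ModelSpec, ParameterSet]:
    """The default ground-truth model: two-fast-weighted-triple-rate at the
    median best-fit parameters."""
    return (ModelSpec.from_id(DEFAULT_TRUE_MODEL),
            TABLE1_MEDIANS[DEFAULT_TRUE_MODEL])
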