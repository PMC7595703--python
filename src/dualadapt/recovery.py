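"""Model-recovery analysis and retention-rate decay comparison.

Model recovery asks whether the fitting pipeline can identify the model
that generated the data: for each generating model, noisy datasets are
simulated over fixed, already-realised participant schedules, every
candidate model is fit to every dataset, and the best-fit identities are
tallied into a confusion matrix p(best-fit model | generating model),
alongside the mean BIC difference of each candidate to the per-dataset best
model.  At the full study settings this is 8 replicates x 10 participant
designs = 80 datasets per generating model per experiment; scaled-down
defaults (2 replicates, 3 designs) keep routine runs fast.

The decay comparison extracts the two windows of the paradigm where states
decay untouched by error — the in-adaptation decay-block channel runs and
the terminal error-clamp phase — and lays the measured force compensation
alongside pure-retention reference curves x_{m} = A^m x0 for retention
rates between 0.5 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import MultiRateModel
from .model_core import simulate_decay
from .paradigm import ExperimentConfig
from .preprocessing import flip_counterbalance
from .specs import (DECAY_RATES, MODEL_IDS, TABLE1_MEDIANS, ModelSpec,
                    ParameterSet)
from .synthetic import Dataset, generate_cohort, simulate_on_schedule

__all__ = [
    "ConfusionMatrix",
    "realize_designs",
    "generate_recovery_corpus",
    "run_model_recovery",
    "DecayComparison",
    "decay_comparison",
]


@dataclass
class ConfusionMatrix:
    """Recovery summary over generating x candidate models.

    ``probs``: p(best-fit candidate | generating model); rows sum to 1.
    ``mean_delta``: mean BIC of the per-dataset best model minus the
    candidate's BIC (0 for the best model of every dataset, negative
    otherwise).  ``n_datasets``: datasets per generating model.
    """

    probs: pd.DataFrame
    mean_delta: pd.DataFrame
    n_datasets: int

    def to_csv(self, probs_path, delta_path=None) -> None:
        self.probs.to_csv(probs_path)
        if delta_path is not None:
            self.mean_delta.to_csv(delta_path)


def realize_designs(config: ExperimentConfig, n_designs: int, seed: int,
                    spec: ModelSpec | str = "2f_3s_wgt",
                    params: ParameterSet | None = None,
                    noise_halfwidth: float | None = None) -> list[pd.DataFrame]:
    """Realised participant schedules (canonical convention) for recovery.

    Each design is produced by running the adaptive closed loop once with a
    behaving participant model (by default the overall best-fit model at its
    median parameters), fixing the de-adaptation length; all generating
    models then share these trial sequences.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_id(spec)
    if params is None:
        params = TABLE1_MEDIANS[spec.model_id]
    if noise_halfwidth is None:
        from .synthetic import NOISE_HALFWIDTH
        noise_halfwidth = NOISE_HALFWIDTH[config.experiment]
    cohort = generate_cohort(spec, params, config, n_designs,
                             noise_halfwidth, master_seed=seed)
    return [flip_counterbalance(d).schedule for d in cohort]


def generate_recovery_corpus(schedules: list[pd.DataFrame],
                             generating: list[str],
                             n_reps: int, noise_halfwidth: float,
                             seed: int) -> dict[str, list[Dataset]]:
    """Noisy datasets per generating model over the fixed schedules.

    Returns {generating model id: [n_designs * n_reps datasets]}.
    """
    corpus: dict[str, list[Dataset]] = {}
    child = np.random.SeedSequence(seed).generate_state(
        len(generating) * len(schedules) * n_reps) % (2 ** 31)
    i = 0
    for gen_id in generating:
        params = TABLE1_MEDIANS[gen_id]
        datasets = []
        for sched in schedules:
            for _ in range(n_reps):
                datasets.append(simulate_on_schedule(
                    gen_id, params, sched, noise_halfwidth, int(child[i])))
                i += 1
        corpus[gen_id] = datasets
    return corpus


def run_model_recovery(schedules: list[pd.DataFrame],
                       noise_halfwidth: float, seed: int,
                       generating: list[str] | None = None,
                       candidates: list[str] | None = None,
                       n_reps: int = 2,
                       n_restarts: int = 3) -> ConfusionMatrix:
    """Simulate, fit and tally the recovery confusion matrix.

    Parameters follow the scaled-down defaults; pass ``n_reps=8`` over ten
    designs with ``n_restarts=10`` for the full analysis.
    """
    generating = list(generating if generating is not None else MODEL_IDS)
    candidates = list(candidates if candidates is not None else MODEL_IDS)
    corpus = generate_recovery_corpus(schedules, generating, n_reps,
                                      noise_halfwidth, seed)
    n_datasets = len(schedules) * n_reps
    fit_seeds = np.random.SeedSequence([seed, 1]).generate_state(
        len(generating) * n_datasets * len(candidates)) % (2 ** 31)
    seed_iter = iter(fit_seeds)
    counts = pd.DataFrame(0.0, index=generating, columns=candidates)
    delta_sum = pd.DataFrame(0.0, index=generating, columns=candidates)
    for gen_id, datasets in corpus.items():
        for d_i, dataset in enumerate(datasets):
            bics = {}
            for cand in candidates:
                res = MultiRateModel(dataset, cand).fit(
                    n_restarts=n_restarts, seed=int(next(seed_iter)))
                bics[cand] = res.bic
            best = min(bics, key=lambda m: (bics[m],
                                            ModelSpec.from_id(m).k,
                                            candidates.index(m)))
            counts.loc[gen_id, best] += 1
            for cand in candidates:
                delta_sum.loc[gen_id, cand] += bics[best] - bics[cand]
    probs = counts / n_datasets
    mean_delta = delta_sum / n_datasets
    return ConfusionMatrix(probs=probs, mean_delta=mean_delta,
                           n_datasets=n_datasets)


# ---------------------------------------------------------------------------
# decay comparison


@dataclass
class DecayComparison:
    """Observed decay series aligned with simulated retention curves.

    ``decay_runs``: mean cue-signed force compensation at each position of
    the decay-block channel runs (position 0 = first channel trial of the
    run).  ``clamp``: clamp-phase cue-difference series, each point the mean
    of three consecutive per-cue means.  ``simulated``: per retention rate,
    the pure-decay curve from ``x0`` over the clamp series length.
    """

    decay_runs: pd.DataFrame
    clamp: pd.DataFrame
    simulated: pd.DataFrame
    x0: float

    def to_csv(self, path) -> None:
        out = self.clamp.copy()
        for col in self.simulated.columns:
            out[col] = self.simulated[col].to_numpy()
        out.to_csv(path, index=False)


def _cue_signed(obs: np.ndarray, cues: np.ndarray) -> np.ndarray:
    """Align the two cues' signs (cue 2 adapts negative canonically)."""
    return np.where(cues == 1, obs, -obs)


def decay_comparison(dataset: Dataset,
                     retention_rates=DECAY_RATES,
                     x0: float | None = None) -> DecayComparison:
    """Compare measured decay against pure-retention reference curves."""
    canonical = flip_counterbalance(dataset)
    df = canonical.df

    runs = df[df["decay_flag"]]
    if len(runs) == 0:
        raise ValueError("schedule contains no decay blocks")
    # decay runs are contiguous same-cue channel stretches; group by block
    per_position = []
    for _, block in runs.groupby("block"):
        vals = _cue_signed(block["fc_observed"].to_numpy(float),
                           block["cue"].to_numpy())
        per_position.append(vals)
    run_matrix = np.vstack(per_position)
    decay_runs = pd.DataFrame({
        "position": np.arange(run_matrix.shape[1]),
        "observed_mean": run_matrix.mean(axis=0),
    })

    clamp_df = df[df["phase"] == "clamp"]
    if len(clamp_df) == 0:
        raise ValueError("schedule contains no error-clamp phase")
    signed = _cue_signed(clamp_df["fc_observed"].to_numpy(float),
                         clamp_df["cue"].to_numpy())
    # mean of three consecutive trials per point, per cue then combined:
    # average in trial order over windows of 3 per-trial signed values
    n_points = len(signed) // 3
    clamp_means = signed[: n_points * 3].reshape(n_points, 3).mean(axis=1)
    clamp = pd.DataFrame({"point": np.arange(n_points),
                          "observed_mean": clamp_means})

    if x0 is None:
        # default: the generating model's clamp-entry output level
        if dataset.spec_id is not None and dataset.params is not None:
            out = canonical.noise_free_outputs()
            loc = int(np.flatnonzero((df["phase"] == "clamp").to_numpy())[0])
            x0 = float(abs(out[loc]))
        else:
            x0 = float(clamp_means[0])

    sim = {}
    for rate in retention_rates:
        curve = simulate_decay(rate, x0, n_points)
        sim[f"A_{rate:g}"] = curve
    simulated = pd.DataFrame(sim)
    return DecayComparison(decay_runs=decay_runs, clamp=clamp,
                           simulated=simulated, x0=x0)
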