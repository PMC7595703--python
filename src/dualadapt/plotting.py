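"""Quick-look plots for datasets, fits and the decay comparison."""

from __future__ import annotations

import numpy as np

from .fitting import MultiRateResults
from .preprocessing import flip_counterbalance
from .recovery import DecayComparison
from .synthetic import Dataset

__all__ = ["plot_dataset", "plot_fit", "plot_decay_comparison"]

_PHASE_SHADE = {"pre": "1.0", "adaptation": "0.92", "deadaptation": "0.82",
                "clamp": "0.95"}


def _shade_phases(ax, df) -> None:
    for phase, sub in df.groupby("phase", sort=False):
        ax.axvspan(sub["trial"].min(), sub["trial"].max(),
                   color=_PHASE_SHADE.get(phase, "1.0"), zorder=0)


def plot_dataset(dataset: Dataset, ax=None):
    """Channel-trial force compensation per cue over the experiment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    df = flip_counterbalance(dataset).df
    _shade_phases(ax, df)
    ch = df[df["trial_type"] == "channel"]
    for cue, color in ((1, "tab:red"), (2, "tab:blue")):
        sub = ch[ch["cue"] == cue]
        ax.plot(sub["trial"], sub["fc_observed"], ".", ms=3, color=color,
                label=f"cue {cue}")
    ax.axhline(0, color="k", lw=0.5)
    ax.set(xlabel="trial", ylabel="force compensation")
    ax.legend(frameon=False)
    return ax


def plot_fit(results: MultiRateResults, ax=None):
    """Centered observations against the fitted centered predictions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    model = results.model
    trials = model.dataset.df.loc[model.dataset.channel_mask, "trial"]
    ax.plot(trials, model.endog, ".", ms=3, color="0.6", label="observed")
    ax.plot(trials, results.fittedvalues, "-", lw=1, color="tab:green",
            label=f"fit ({results.spec.model_id})")
    ax.axhline(0, color="k", lw=0.5)
    ax.set(xlabel="trial", ylabel="centered force compensation")
    ax.legend(frameon=False)
    return ax


def plot_decay_comparison(dc: DecayComparison, ax=None):
    """Clamp-phase decay against the simulated retention curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in dc.simulated.columns:
        ax.plot(np.arange(len(dc.simulated)), dc.simulated[col], "k:",
                lw=0.8)
        ax.annotate(col.replace("A_", "A="),
                    (len(dc.simulated) - 1, dc.simulated[col].iloc[-1]),
                    fontsize=6, va="center")
    ax.plot(dc.clamp["point"], dc.clamp["observed_mean"], "-",
            color="tab:orange", label="error-clamp phase")
    ax.set(xlabel="point (3 trials each)", ylabel="force compensation")
    ax.legend(frameon=False)
    return ax
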