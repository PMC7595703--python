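"""Preprocessing of force-compensation series before model fitting.

Two steps put every participant on a common scale:

1. counterbalance flip — participants whose cue-field pairing was mirrored
   (group B) have all signs negated so cue 1 always adapts positive;
2. blockwise cue-mean subtraction — within each 16-trial block the mean of
   the two cues' per-cue channel means is subtracted from every channel
   observation, removing any common-mode bias so the two cues' series are
   symmetric and the models (which assume equal and opposite adaptation)
   can be fit.

Section averaging (used for display of the variable-length de-adaptation
phase) lives here too.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .synthetic import Dataset

__all__ = [
    "flip_counterbalance",
    "BlockCenterer",
    "subtract_blockwise_cue_mean",
    "center_dataset",
    "section_means",
]


def flip_counterbalance(dataset: Dataset) -> Dataset:
    """Return the dataset on the canonical sign convention (group A).

    Group-B observations and field signs are negated; group-A data are
    returned unchanged.  Idempotent on canonical data.
    """
    if dataset.counterbalance is None:
        raise ValueError("dataset has no counterbalance flag")
    if dataset.counterbalance == "A":
        return dataset
    if dataset.counterbalance != "B":
        raise ValueError(f"invalid counterbalance flag {dataset.counterbalance!r}")
    df = dataset.df.assign(field_sign=-dataset.df["field_sign"],
                           fc_observed=-dataset.df["fc_observed"])
    return replace(dataset, df=df, counterbalance="A")


class BlockCenterer:
    """Blockwise cue-mean subtraction as a reusable linear operator.

    Built once from the channel-trial structure of a schedule (block id and
    cue of every channel trial, in trial order), then applied to any series
    aligned with those channel trials — the observed data and, during
    fitting, the model predictions, so both pass through the identical
    operator.

    Within each block the per-cue means of the block's channel values are
    averaged with equal weight per cue (regardless of how many channel
    trials each cue contributed, which differs in decay and clamp blocks)
    and the result is subtracted from every channel value in the block.
    """

    def __init__(self, block_ids: np.ndarray, cues: np.ndarray):
        block_ids = np.asarray(block_ids)
        cues = np.asarray(cues)
        if block_ids.shape != cues.shape:
            raise ValueError("block_ids and cues must have equal length")
        if block_ids.size == 0:
            raise ValueError("no channel observations to center")
        self.n = len(block_ids)
        uniq, block_idx = np.unique(block_ids, return_inverse=True)
        self.n_blocks = len(uniq)
        self.block_idx = block_idx
        # per (block, cue) group index: 2*block + (cue - 1)
        self.group_idx = 2 * block_idx + (cues == 2).astype(int)
        self.group_counts = np.bincount(self.group_idx, minlength=2 * self.n_blocks)
        present = (self.group_counts > 0).reshape(self.n_blocks, 2)
        self.cues_per_block = present.sum(axis=1)
        if np.any(self.cues_per_block == 0):
            raise ValueError("block with channel observations from neither cue")

    def block_cue_means(self, values: np.ndarray) -> np.ndarray:
        """(n_blocks, 2) per-cue means; NaN where a cue is absent."""
        values = np.asarray(values, dtype=float)
        sums = np.bincount(self.group_idx, weights=values,
                           minlength=2 * self.n_blocks)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / self.group_counts
        return means.reshape(self.n_blocks, 2)

    def block_means(self, values: np.ndarray) -> np.ndarray:
        """Mean over the available per-cue means, per block."""
        cue_means = self.block_cue_means(values)
        return np.nansum(cue_means, axis=1) / self.cues_per_block

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError(f"expected series of length {self.n}, got {values.shape}")
        return values - self.block_means(values)[self.block_idx]


def subtract_blockwise_cue_mean(values: np.ndarray, block_ids: np.ndarray,
                                cues: np.ndarray) -> np.ndarray:
    """Centered series: blockwise cue-mean subtraction (functional form)."""
    return BlockCenterer(block_ids, cues).transform(values)


def center_dataset(dataset: Dataset) -> tuple[np.ndarray, BlockCenterer]:
    """Centered channel observations of a (canonical) dataset.

    Returns the centered series plus the fitted operator, so the same
    centering can be applied to model predictions.
    """
    canonical = flip_counterbalance(dataset)
    mask = canonical.channel_mask
    ch = canonical.df.loc[mask]
    centerer = BlockCenterer(ch["block"].to_numpy(), ch["cue"].to_numpy())
    return centerer.transform(ch["fc_observed"].to_numpy(float)), centerer


def section_means(series: np.ndarray, n_sections: int) -> np.ndarray:
    """Means over contiguous, near-equal sections (longer sections first).

    Used to average the variable-length de-adaptation phase into a fixed
    number of sections so participants can be compared.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if n_sections < 1 or series.size < n_sections:
        raise ValueError(
            f"cannot split {series.size} values into {n_sections} sections")
    base, extra = divmod(series.size, n_sections)
    lengths = [base + 1] * extra + [base] * (n_sections - extra)
    bounds = np.cumsum([0] + lengths)
    return np.array([series[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
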