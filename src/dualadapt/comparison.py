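"""BIC model selection across the twelve-model family.

BIC uses the Gaussian least-squares form

    BIC = n ln(SSE / n) + k ln(n)

with n the number of fitted channel observations and k the count of
structural free parameters (two per active timescale plus one for a
weighted switch).  All comparisons are BIC differences at fixed n, so
additive constants cancel.  Differences are read on the conventional
evidence scale: <2 no difference, 2-6 positive, 6-10 strong, >10 very
strong.  The "BIC improvement" of a model is the referent model's BIC
(one-fast-two-slow-binary) minus the model's BIC, so positive is better
than the referent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import MultiRateResults
from .specs import MODEL_IDS, REFERENT_ID, ModelSpec

__all__ = [
    "compute_bic",
    "evidence_category",
    "ComparisonTable",
    "frequency_table",
]

#: Evidence thresholds on the BIC-difference scale.
EVIDENCE_THRESHOLDS = (2.0, 6.0, 10.0)
EVIDENCE_LABELS = ("none", "positive", "strong", "very_strong")

#: BIC-difference band within which two models count as tied.
TIE_BAND = 2.0


def compute_bic(sse: float, n_obs: int, k: int) -> float:
    """Bayesian information criterion for a least-squares fit."""
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0:
        raise ValueError(
            "sse is exactly 0 (degenerate noise-free fit); apply an SSE "
            "floor such as 1e-12 before computing BIC")
    if not n_obs > k >= 1:
        raise ValueError(f"need n_obs > k >= 1, got n_obs={n_obs}, k={k}")
    return n_obs * math.log(sse / n_obs) + k * math.log(n_obs)


def evidence_category(delta_bic: float) -> str:
    """Evidence label for a non-negative BIC difference."""
    if delta_bic < 0:
        raise ValueError("delta_bic must be >= 0")
    for threshold, label in zip(EVIDENCE_THRESHOLDS, EVIDENCE_LABELS):
        if delta_bic < threshold:
            return label
    return EVIDENCE_LABELS[-1]


def _rank_key(model_id: str) -> tuple[int, int]:
    """Tie-break ordering: fewer parameters first, then canonical id order."""
    return (ModelSpec.from_id(model_id).k, MODEL_IDS.index(model_id))


@dataclass
class ComparisonTable:
    """Per-participant BIC comparison across a set of fitted models.

    ``table`` is long-format with one row per (participant, model):
    bic, delta_vs_referent (referent BIC minus model BIC; the referent's own
    value is 0), rank (1 = lowest BIC, ties broken by fewer parameters then
    canonical model order) and tie_flag (True when within 2 BIC of the
    participant's best model, i.e. statistically indistinguishable from it).
    """

    table: pd.DataFrame
    model_ids: tuple[str, ...]

    @classmethod
    def from_results(
        cls, results: dict[str, dict[str, MultiRateResults]] | dict[str, dict[str, float]],
        referent: str = REFERENT_ID,
    ) -> "ComparisonTable":
        """Build from {participant: {model_id: MultiRateResults | BIC}}."""
        participants = list(results)
        model_sets = [frozenset(r) for r in results.values()]
        if len(set(model_sets)) != 1:
            missing = []
            all_models = frozenset().union(*model_sets)
            for p, fitted in results.items():
                missing += [(p, m) for m in sorted(all_models - set(fitted))]
            raise ValueError(f"incomplete fits for (participant, model): {missing}")
        model_ids = tuple(sorted(model_sets[0], key=MODEL_IDS.index)
                          if model_sets[0] <= set(MODEL_IDS)
                          else sorted(model_sets[0]))
        rows = []
        for p in participants:
            bics = {m: (r.bic if isinstance(r, MultiRateResults) else float(r))
                    for m, r in results[p].items()}
            ref_bic = bics.get(referent)
            order = sorted(model_ids, key=lambda m: (bics[m], _rank_key(m)))
            ranks = {m: i + 1 for i, m in enumerate(order)}
            best = min(bics.values())
            for m in model_ids:
                rows.append({
                    "participant": p,
                    "model_id": m,
                    "bic": bics[m],
                    "delta_vs_referent": (ref_bic - bics[m]
                                          if ref_bic is not None else np.nan),
                    "rank": ranks[m],
                    "tie_flag": bool(bics[m] - best < TIE_BAND),
                })
        return cls(table=pd.DataFrame(rows), model_ids=model_ids)

    @property
    def n_participants(self) -> int:
        return self.table["participant"].nunique()

    def best_models(self) -> pd.Series:
        """Rank-1 model per participant."""
        t = self.table[self.table["rank"] == 1]
        return t.set_index("participant")["model_id"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def frequency_table(comparison: ComparisonTable) -> pd.DataFrame:
    """Model x rank counts: entry (m, r) = participants ranking model m r-th.

    Every row and every column sums to the number of participants.
    """
    t = comparison.table
    n_models = len(comparison.model_ids)
    freq = pd.DataFrame(0, index=list(comparison.model_ids),
                        columns=range(1, n_models + 1))
    for _, row in t.iterrows():
        freq.loc[row["model_id"], row["rank"]] += 1
    return freq
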