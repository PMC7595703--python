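"""Model family definitions and parameter containers.

The package models trial-by-trial dual adaptation with a family of twelve
linear state-space learning models.  Each model is identified by three
structural choices:

* the number of timescales (2 = dual-rate: fast+slow; 3 = triple-rate adds an
  ultraslow process; 4 = quadruple-rate adds a hyperslow process),
* whether there is a single fast process shared between the two contextual
  cues (``one_fast``) or one fast process per cue (``two_fast``),
* whether the contextual-cue switch is a hard binary gate or a weighted
  mixture with weight ``c`` on the cued memory.

Every process ``p`` has a retention rate ``A_p`` (per-trial multiplicative
persistence) and a learning rate ``B_p`` (per-trial error gain), all
unitless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "MODEL_IDS",
    "MODEL_SPECS",
    "TABLE1_MEDIANS",
    "SMITH_DUAL_RATE",
    "DECAY_RATES",
]

_N_TO_CODE = {2: "2s", 3: "3s", 4: "4s"}
_CODE_TO_N = {v: k for k, v in _N_TO_CODE.items()}
_FAST_TO_CODE = {"one_fast": "1f", "two_fast": "2f"}
_CODE_TO_FAST = {v: k for k, v in _FAST_TO_CODE.items()}
_SWITCH_TO_CODE = {"binary": "bin", "weighted": "wgt"}
_CODE_TO_SWITCH = {v: k for k, v in _SWITCH_TO_CODE.items()}

#: Timescale names in canonical order.
PROCESSES = ("fast", "slow", "ultraslow", "hyperslow")


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one member of the twelve-model family.

    Parameters
    ----------
    n_timescales : int
        2 (dual-rate), 3 (triple-rate) or 4 (quadruple-rate).
    fast_mode : {"one_fast", "two_fast"}
        Single shared fast process versus one fast process per cue.
    switch_mode : {"binary", "weighted"}
        Hard contextual gate versus weighted mixture parameterised by ``c``.
    """

    n_timescales: int
    fast_mode: str
    switch_mode: str

    def __post_init__(self) -> None:
        if self.n_timescales not in (2, 3, 4):
            raise ValueError(f"n_timescales must be 2, 3 or 4, got {self.n_timescales}")
        if self.fast_mode not in _FAST_TO_CODE:
            raise ValueError(f"fast_mode must be 'one_fast' or 'two_fast', got {self.fast_mode!r}")
        if self.switch_mode not in _SWITCH_TO_CODE:
            raise ValueError(
                f"switch_mode must be 'binary' or 'weighted', got {self.switch_mode!r}"
            )

    @property
    def weighted(self) -> bool:
        return self.switch_mode == "weighted"

    @property
    def one_fast(self) -> bool:
        return self.fast_mode == "one_fast"

    @property
    def k(self) -> int:
        """Number of free parameters: one (A, B) pair per timescale plus c."""
        return 2 * self.n_timescales + (1 if self.weighted else 0)

    @property
    def processes(self) -> tuple[str, ...]:
        """Active timescales for this spec."""
        return PROCESSES[: self.n_timescales]

    @property
    def model_id(self) -> str:
        """Canonical id, e.g. ``'2f_3s_wgt'``."""
        return "_".join(
            (
                _FAST_TO_CODE[self.fast_mode],
                _N_TO_CODE[self.n_timescales],
                _SWITCH_TO_CODE[self.switch_mode],
            )
        )

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        try:
            f, n, s = model_id.split("_")
            return cls(_CODE_TO_N[n], _CODE_TO_FAST[f], _CODE_TO_SWITCH[s])
        except (ValueError, KeyError):
            raise ValueError(
                f"unknown model id {model_id!r}; valid ids: {', '.join(MODEL_IDS)}"
            ) from None

    def __str__(self) -> str:
        return self.model_id


def _all_specs() -> Iterator[ModelSpec]:
    for n in (2, 3, 4):
        for fast in ("one_fast", "two_fast"):
            for switch in ("binary", "weighted"):
                yield ModelSpec(n, fast, switch)


#: The twelve specs in canonical order (referent model '1f_2s_bin' first).
MODEL_SPECS: tuple[ModelSpec, ...] = tuple(_all_specs())
MODEL_IDS: tuple[str, ...] = tuple(s.model_id for s in MODEL_SPECS)

#: The referent model all BIC improvements are measured against.
REFERENT_ID = "1f_2s_bin"


@dataclass
class ParameterSet:
    """Retention rates, learning rates and the switch weight.

    Fields for timescales absent from a spec are fixed at 0 so that one
    stepping routine serves all twelve model structures (the corresponding
    states then stay identically zero).  ``c`` is only meaningful for
    weighted specs; binary specs behave as ``c = 1``.
    """

    A_f: float = 0.0
    A_s: float = 0.0
    A_us: float = 0.0
    A_hs: float = 0.0
    B_f: float = 0.0
    B_s: float = 0.0
    B_us: float = 0.0
    B_hs: float = 0.0
    c: float = 1.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"parameter {name}={value} outside [0, 1]")

    def gate_weight(self, spec: ModelSpec) -> float:
        """Weight on the cued memory: ``c`` if weighted, else 1."""
        return self.c if spec.weighted else 1.0

    def for_spec(self, spec: ModelSpec) -> "ParameterSet":
        """Copy with parameters of absent timescales zeroed."""
        out = replace(self)
        if spec.n_timescales < 4:
            out.A_hs = 0.0
            out.B_hs = 0.0
        if spec.n_timescales < 3:
            out.A_us = 0.0
            out.B_us = 0.0
        if not spec.weighted:
            out.c = 1.0
        return out

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        return cls(**d)


#: Classic two-state (dual-rate) parameters used for the headline
#: spontaneous-recovery simulations (fast: A=0.92, B=0.05; slow: A=0.999,
#: B=0.01).
SMITH_DUAL_RATE = ParameterSet(A_f=0.92, A_s=0.999, B_f=0.05, B_s=0.01)

#: Median best-fit parameters per model across both experiments (used as
#: ground-truth values when generating synthetic participants).  The
#: '2f_3s_wgt' row is the overall best-fit model.
TABLE1_MEDIANS: dict[str, ParameterSet] = {
    "1f_2s_bin": ParameterSet(A_f=0.50000, A_s=0.95000, B_f=0.10000, B_s=0.08501),
    "1f_2s_wgt": ParameterSet(A_f=0.50000, A_s=0.99818, B_f=0.10000, B_s=0.02509, c=0.86623),
    "2f_2s_bin": ParameterSet(A_f=0.81324, A_s=0.95000, B_f=0.26232, B_s=0.02000),
    "2f_2s_wgt": ParameterSet(A_f=0.87438, A_s=0.99953, B_f=0.16488, B_s=0.02000, c=0.78895),
    "1f_3s_bin": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.99989, B_f=0.10000, B_s=0.02432, B_us=0.00564
    ),
    "1f_3s_wgt": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.99989, B_f=0.10000, B_s=0.02432, B_us=0.00546,
        c=1.00000,
    ),
    "2f_3s_bin": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.99989, B_f=0.10000, B_s=0.02000, B_us=0.00591
    ),
    "2f_3s_wgt": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.99990, B_f=0.15124, B_s=0.02000, B_us=0.00759,
        c=0.91995,
    ),
    "1f_4s_bin": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.95899, A_hs=0.99998,
        B_f=0.10000, B_s=0.02320, B_us=0.00000, B_hs=0.00537,
    ),
    "1f_4s_wgt": ParameterSet(
        A_f=0.50177, A_s=0.95000, A_us=0.95795, A_hs=0.99997,
        B_f=0.10000, B_s=0.02305, B_us=0.00121, B_hs=0.00506, c=1.00000,
    ),
    "2f_4s_bin": ParameterSet(
        A_f=0.50000, A_s=0.95000, A_us=0.97525, A_hs=0.99997,
        B_f=0.10000, B_s=0.02000, B_us=0.00000, B_hs=0.00558,
    ),
    "2f_4s_wgt": ParameterSet(
        A_f=0.50051, A_s=0.95000, A_us=0.97564, A_hs=0.99993,
        B_f=0.16488, B_s=0.02000, B_us=0.00000, B_hs=0.00617, c=0.91993,
    ),
}

#: Default ground-truth model for synthetic participants.
DEFAULT_TRUE_MODEL = "2f_3s_wgt"

#: Retention rates of the reference decay curves used in the decay analysis.
DECAY_RATES = (0.5, 0.8, 0.9, 0.95, 0.98, 0.993, 0.997, 0.999, 1.0)
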