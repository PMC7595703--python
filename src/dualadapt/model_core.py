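"""Trial-by-trial dynamics of the twelve-model family.

Each model maintains, for each of the two contextual cues j, a memory made of
up to four processes (fast, slow, ultraslow, hyperslow).  On trial n with cue
code c the model outputs

    one_fast : x = x_f + sum_j g_j (x_s,j + x_us,j + x_hs,j)
    two_fast : x = sum_j g_j (x_f,j + x_s,j + x_us,j + x_hs,j)

where the gate (g_1, g_2) is the unit vector selecting the cued memory for
binary-switch models and (c, 1-c) on the cued/uncued memory for weighted
models.  The trial error is e = f - x on field trials (f the unit-normalised
environmental force) and e = 0 on channel (error-clamp) trials, after which
every process decays by its retention rate and learns its gated share of the
error:

    x_p,j <- A_p x_p,j + B_p e g_j

with the shared fast state of one_fast models learning ungated
(x_f <- A_f x_f + B_f e).  The gate and the prediction both use the cue of
the trial being executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .specs import ModelSpec, ParameterSet

__all__ = [
    "MemoryState",
    "TrialInput",
    "gate_vector",
    "predict_output",
    "step_trial",
    "simulate_schedule",
    "simulate_decay",
    "SimulationResult",
]

# State vector layout used by the fast kernel:
#   [f1, f2, s1, s2, us1, us2, hs1, hs2]
# For one_fast specs the shared fast state lives in slot 0 and slot 1 is 0.
N_STATE = 8


def _kernel_outputs(cue, is_channel, field_sign,
                    Af, As, Aus, Ahs, Bf, Bs, Bus, Bhs, c,
                    one_fast, state, outputs):
    """Simulate outputs in place; `state` is mutated to the final state.

    Written in a numba-compilable subset of Python; also runs as plain
    Python (fallback when JIT compilation is unavailable).
    """
    f1 = state[0]; f2 = state[1]
    s1 = state[2]; s2 = state[3]
    u1 = state[4]; u2 = state[5]
    h1 = state[6]; h2 = state[7]
    n = cue.shape[0]
    for i in range(n):
        if cue[i] == 1:
            g1 = c
            g2 = 1.0 - c
        else:
            g1 = 1.0 - c
            g2 = c
        if one_fast:
            x = f1 + g1 * (s1 + u1 + h1) + g2 * (s2 + u2 + h2)
        else:
            x = g1 * (f1 + s1 + u1 + h1) + g2 * (f2 + s2 + u2 + h2)
        outputs[i] = x
        if is_channel[i]:
            e = 0.0
        else:
            e = field_sign[i] - x
        if one_fast:
            f1 = Af * f1 + Bf * e
        else:
            f1 = Af * f1 + Bf * e * g1
            f2 = Af * f2 + Bf * e * g2
        s1 = As * s1 + Bs * e * g1
        s2 = As * s2 + Bs * e * g2
        u1 = Aus * u1 + Bus * e * g1
        u2 = Aus * u2 + Bus * e * g2
        h1 = Ahs * h1 + Bhs * e * g1
        h2 = Ahs * h2 + Bhs * e * g2
    state[0] = f1; state[1] = f2
    state[2] = s1; state[3] = s2
    state[4] = u1; state[5] = u2
    state[6] = h1; state[7] = h2


def _kernel_trajectory(cue, is_channel, field_sign,
                       Af, As, Aus, Ahs, Bf, Bs, Bus, Bhs, c,
                       one_fast, state, outputs, states):
    """Like _kernel_outputs but also records the post-update state per trial."""
    for i in range(cue.shape[0]):
        _kernel_outputs(cue[i:i + 1], is_channel[i:i + 1], field_sign[i:i + 1],
                        Af, As, Aus, Ahs, Bf, Bs, Bus, Bhs, c,
                        one_fast, state, outputs[i:i + 1])
        for j in range(N_STATE):
            states[i, j] = state[j]


try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _kernel_outputs = njit(cache=False)(_kernel_outputs)
    _kernel_trajectory = njit(cache=False)(_kernel_trajectory)
except Exception:  # pragma: no cover
    pass


def _param_tuple(spec: ModelSpec, params: ParameterSet) -> tuple:
    p = params.for_spec(spec)
    return (p.A_f, p.A_s, p.A_us, p.A_hs, p.B_f, p.B_s, p.B_us, p.B_hs,
            p.c if spec.weighted else 1.0)


def simulate_outputs_fast(spec: ModelSpec, params: ParameterSet,
                          cue: np.ndarray, is_channel: np.ndarray,
                          field_sign: np.ndarray,
                          state: np.ndarray | None = None) -> np.ndarray:
    """Low-level simulation over pre-extracted trial arrays.

    Mutates ``state`` (length-8 float array) in place when given; starts from
    zero state otherwise.  This is the hot path used by the fitting
    objective.
    """
    if state is None:
        state = np.zeros(N_STATE)
    outputs = np.empty(len(cue))
    _kernel_outputs(cue, is_channel, field_sign, *_param_tuple(spec, params),
                    spec.one_fast, state, outputs)
    if not np.all(np.isfinite(outputs)):
        raise FloatingPointError("simulation diverged: non-finite motor output")
    return outputs


@dataclass
class MemoryState:
    """Per-cue process states.

    Each field is a length-2 array (memory for cue 1 and cue 2).  For
    ``one_fast`` specs the shared fast state is held in ``fast[0]`` with
    ``fast[1]`` fixed at 0.  Absent timescales stay identically 0.
    """

    fast: np.ndarray = field(default_factory=lambda: np.zeros(2))
    slow: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ultraslow: np.ndarray = field(default_factory=lambda: np.zeros(2))
    hyperslow: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.fast, self.slow, self.ultraslow, self.hyperslow])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MemoryState":
        v = np.asarray(v, dtype=float)
        return cls(v[0:2].copy(), v[2:4].copy(), v[4:6].copy(), v[6:8].copy())

    def copy(self) -> "MemoryState":
        return MemoryState.from_vector(self.to_vector())


@dataclass(frozen=True)
class TrialInput:
    """One trial: cue (1 or 2), trial type and unit-normalised field sign.

    ``field_sign`` is +1/-1 for the two opposing fields and 0 in the null
    field; it is irrelevant on channel trials, where the error is clamped
    to zero.
    """

    cue: int
    trial_type: str = "field"
    field_sign: float = 0.0

    def __post_init__(self) -> None:
        if self.cue not in (1, 2):
            raise ValueError(f"cue must be 1 or 2, got {self.cue}")
        if self.trial_type not in ("field", "channel"):
            raise ValueError(f"trial_type must be 'field' or 'channel', got {self.trial_type!r}")

    @property
    def is_channel(self) -> bool:
        return self.trial_type == "channel"


def gate_vector(spec: ModelSpec, params: ParameterSet, cue: int) -> tuple[float, float]:
    """Contextual switch weights (g_1, g_2) for a trial with the given cue.

    Binary switch: the unit vector selecting the cued memory.  Weighted
    switch: weight ``c`` on the cued memory and ``1 - c`` on the other.
    """
    if cue not in (1, 2):
        raise ValueError(f"malformed trial: cue must be 1 or 2, got {cue}")
    w = params.gate_weight(spec)
    return (w, 1.0 - w) if cue == 1 else (1.0 - w, w)


def predict_output(spec: ModelSpec, params: ParameterSet,
                   state: MemoryState, cue: int) -> float:
    """Motor output x (fraction of perfect compensation) at the current state."""
    g = gate_vector(spec, params, cue)
    slow_part = sum(
        g[j] * (state.slow[j] + state.ultraslow[j] + state.hyperslow[j])
        for j in (0, 1)
    )
    if spec.one_fast:
        return float(state.fast[0] + slow_part)
    return float(sum(g[j] * state.fast[j] for j in (0, 1)) + slow_part)


def step_trial(spec: ModelSpec, params: ParameterSet, state: MemoryState,
               trial: TrialInput) -> tuple[float, float, MemoryState]:
    """Execute one trial: returns (output, error, new state).

    The output and gate use the current trial's cue; on channel trials the
    error is forced to 0 so every state undergoes pure retention decay.
    """
    p = params.for_spec(spec)
    g = gate_vector(spec, p, trial.cue)
    x = predict_output(spec, p, state, trial.cue)
    e = 0.0 if trial.is_channel else trial.field_sign - x

    new = state.copy()
    if spec.one_fast:
        new.fast[0] = p.A_f * state.fast[0] + p.B_f * e
        new.fast[1] = 0.0
    else:
        for j in (0, 1):
            new.fast[j] = p.A_f * state.fast[j] + p.B_f * e * g[j]
    for j in (0, 1):
        new.slow[j] = p.A_s * state.slow[j] + p.B_s * e * g[j]
        new.ultraslow[j] = p.A_us * state.ultraslow[j] + p.B_us * e * g[j]
        new.hyperslow[j] = p.A_hs * state.hyperslow[j] + p.B_hs * e * g[j]
    if not np.all(np.isfinite(new.to_vector())):
        raise FloatingPointError("state blew up: non-finite value after update")
    return x, e, new


@dataclass
class SimulationResult:
    """Noise-free simulation of a schedule: outputs, errors and state path."""

    outputs: np.ndarray          # motor output per trial
    errors: np.ndarray           # experienced error per trial (0 on channel)
    states: np.ndarray           # (n_trials, 8) post-update state vectors
    final_state: MemoryState


def _schedule_arrays(schedule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (cue, is_channel, field_sign) from a schedule DataFrame."""
    cue = np.asarray(schedule["cue"], dtype=np.int64)
    is_channel = np.asarray(schedule["trial_type"] == "channel")
    field_sign = np.asarray(schedule["field_sign"], dtype=float)
    return cue, is_channel, field_sign


def simulate_schedule(spec: ModelSpec, params: ParameterSet, schedule,
                      initial_state: MemoryState | None = None) -> SimulationResult:
    """Deterministic fold of the trial update over a schedule.

    Parameters
    ----------
    schedule : pandas.DataFrame
        Must carry columns ``cue``, ``trial_type`` and ``field_sign``
        (see :mod:`dualadapt.paradigm`).
    initial_state : MemoryState, optional
        Starting state; zero by default.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    cue, is_channel, field_sign = _schedule_arrays(schedule)
    state = (initial_state.to_vector().copy() if initial_state is not None
             else np.zeros(N_STATE))
    outputs = np.empty(len(cue))
    states = np.empty((len(cue), N_STATE))
    _kernel_trajectory(cue, is_channel, field_sign,
                       *_param_tuple(spec, params), spec.one_fast,
                       state, outputs, states)
    if not np.all(np.isfinite(outputs)):
        raise FloatingPointError("simulation diverged: non-finite motor output")
    errors = np.where(is_channel, 0.0, field_sign - outputs)
    return SimulationResult(outputs=outputs, errors=errors, states=states,
                            final_state=MemoryState.from_vector(state))


def simulate_decay(A: float, x0: float, n: int) -> np.ndarray:
    """Pure retention decay x_{m} = A^m x0 for m = 1..n.

    This is the reference curve the decay analysis compares measured
    error-clamp series against, for retention rates between 0.5 and 1.
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"retention rate A={A} outside [0, 1]")
    if n < 1:
        raise ValueError(f"trial count n={n} must be >= 1")
    return x0 * A ** np.arange(1, n + 1, dtype=float)
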