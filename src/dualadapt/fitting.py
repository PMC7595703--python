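"""Constrained multi-start least-squares fitting of the model family.

The estimation problem: given one participant's channel-trial force
compensation (counterbalance-flipped and blockwise cue-mean centered), find
the retention rates, learning rates and switch weight of a chosen model
structure minimising the sum of squared residuals between the centered
observations and the model's noise-free predictions at the same channel
trials, passed through the identical centering operator.

Parameters are constrained to the literature-motivated boxes

    0.5 < A_f < 0.95 < A_s, A_us < A_hs < 1
    0.1 < B_f < 0.35
    0 < B_hs, B_us < 0.02 < B_s < 0.35
    B_s < B_f
    0.5 < c < 1

which pin each process to its intended timescale.  Optimisation is
derivative-free (Nelder-Mead) inside the boxes via a sin^2 transform
(fminsearchbnd-style); the ordering constraints are enforced by a large
finite penalty.  Each fit restarts from several random feasible initial
points and keeps the best.

The public surface follows the Model/Results convention:
``MultiRateModel(dataset, spec).fit()`` returns a :class:`MultiRateResults`
carrying estimates, fit diagnostics, BIC and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import N_STATE, simulate_outputs_fast
from .preprocessing import BlockCenterer, center_dataset, flip_counterbalance
from .specs import ModelSpec, ParameterSet
from .synthetic import Dataset

__all__ = [
    "ParameterBounds",
    "parameter_bounds",
    "objective",
    "fit_model",
    "MultiRateModel",
    "MultiRateResults",
    "FitResult",
    "PENALTY_SSE",
]

#: Finite sentinel returned by the objective when ordering constraints are
#: violated (never raised as an exception so simplex search can recover).
PENALTY_SSE = 1e6

#: Open printed bounds are realised as closed intervals this far inside.
BOUND_EPS = 1e-6

#: SSE floor applied before BIC on (near-)perfect noise-free fits.
SSE_FLOOR = 1e-12

_BOXES = {
    "A_f": (0.5, 0.95),
    "A_s": (0.95, 1.0),
    "A_us": (0.95, 1.0),
    "A_hs": (0.95, 1.0),
    "B_f": (0.1, 0.35),
    "B_s": (0.02, 0.35),
    "B_us": (0.0, 0.02),
    "B_hs": (0.0, 0.02),
    "c": (0.5, 1.0),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds plus ordering constraints for one model structure."""

    names: tuple[str, ...]
    box: tuple[tuple[float, float], ...]
    orderings: tuple[tuple[str, str], ...]  # pairs (smaller, larger)

    @property
    def k(self) -> int:
        return len(self.names)

    def violation(self, values: dict[str, float]) -> float:
        """Total ordering-constraint violation (0 when feasible)."""
        v = 0.0
        for small, large in self.orderings:
            v += max(0.0, values[small] - values[large])
        return v


def _free_names(spec: ModelSpec) -> tuple[str, ...]:
    names = ["A_f", "A_s"]
    if spec.n_timescales >= 3:
        names.append("A_us")
    if spec.n_timescales == 4:
        names.append("A_hs")
    names += ["B_f", "B_s"]
    if spec.n_timescales >= 3:
        names.append("B_us")
    if spec.n_timescales == 4:
        names.append("B_hs")
    if spec.weighted:
        names.append("c")
    return tuple(names)


def parameter_bounds(spec: ModelSpec) -> ParameterBounds:
    """Bounds and ordering constraints for the model structure's active
    parameters."""
    names = _free_names(spec)
    orderings = [("B_s", "B_f")]
    if spec.n_timescales == 4:
        orderings += [("A_s", "A_hs"), ("A_us", "A_hs")]
    return ParameterBounds(names=names,
                           box=tuple(_BOXES[n] for n in names),
                           orderings=tuple(orderings))


def _params_from_vector(spec: ModelSpec, vec: np.ndarray,
                        names: tuple[str, ...]) -> ParameterSet:
    p = ParameterSet()
    for name, value in zip(names, vec):
        setattr(p, name, float(value))
    return p.for_spec(spec)


class MultiRateModel:
    """A multi-rate learning model bound to one participant's data.

    Parameters
    ----------
    dataset : Dataset
        Trial table with observed force compensation on channel trials.
        Flipped to the canonical counterbalance and blockwise-centered on
        construction.
    spec : ModelSpec or str
        Which of the twelve model structures to fit, e.g. ``"2f_3s_wgt"``.

    Examples
    --------
    >>> model = MultiRateModel(dataset, "2f_3s_wgt")
    >>> res = model.fit(n_restarts=10, seed=0)
    >>> print(res.summary())
    """

    def __init__(self, dataset: Dataset, spec: ModelSpec | str):
        if isinstance(spec, str):
            spec = ModelSpec.from_id(spec)
        self.spec = spec
        self.dataset = flip_counterbalance(dataset)
        self.bounds = parameter_bounds(spec)

        df = self.dataset.df
        self._cue = df["cue"].to_numpy(np.int64)
        self._is_channel = (df["trial_type"] == "channel").to_numpy()
        self._field_sign = df["field_sign"].to_numpy(float)
        self.endog, self.centerer = center_dataset(self.dataset)
        self.n_obs = len(self.endog)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec | str,
                       counterbalance: str = "A",
                       noise_halfwidth: float = 0.0) -> "MultiRateModel":
        """Build from a raw trial table (schedule columns + fc_observed)."""
        return cls(Dataset(df=df, counterbalance=counterbalance,
                           noise_halfwidth=noise_halfwidth), spec)

    # -- objective -------------------------------------------------------
    def predict(self, params: ParameterSet) -> np.ndarray:
        """Noise-free model outputs over the full realised schedule."""
        return simulate_outputs_fast(self.spec, params, self._cue,
                                     self._is_channel, self._field_sign,
                                     np.zeros(N_STATE))

    def fittedvalues(self, params: ParameterSet) -> np.ndarray:
        """Centered predictions at channel trials (the fitted series)."""
        pred = self.predict(params)[self._is_channel]
        return self.centerer.transform(pred)

    def sse(self, params: ParameterSet) -> float:
        """Sum of squared residuals of the centered fit.

        Ordering-constraint violations return the finite ``PENALTY_SSE``
        sentinel (scaled by the violation) rather than raising.
        """
        values = params.to_dict()
        bad = self.bounds.violation(values)
        if bad > 0 or not all(0.0 <= values[n] <= 1.0 for n in self.bounds.names):
            return PENALTY_SSE * (1.0 + bad)
        resid = self.fittedvalues(params) - self.endog
        return float(resid @ resid)

    def _sse_vector(self, vec: np.ndarray) -> float:
        return self.sse(_params_from_vector(self.spec, vec, self.bounds.names))

    # -- optimisation ----------------------------------------------------
    def _sample_start(self, rng: np.random.Generator) -> np.ndarray:
        lo = np.array([b[0] + BOUND_EPS for b in self.bounds.box])
        hi = np.array([b[1] - BOUND_EPS for b in self.bounds.box])
        for _ in range(1000):
            x = rng.uniform(lo, hi)
            values = dict(zip(self.bounds.names, x))
            if self.bounds.violation(values) == 0.0:
                return x
        raise RuntimeError("could not sample a feasible start")

    def fit(self, n_restarts: int = 10, seed: int = 0,
            maxfev: int | None = None) -> "MultiRateResults":
        """Multi-start bounded Nelder-Mead fit; best restart wins.

        Restart seeds are derived deterministically from ``seed``.
        """
        lo = np.array([b[0] + BOUND_EPS for b in self.bounds.box])
        hi = np.array([b[1] - BOUND_EPS for b in self.bounds.box])
        span = hi - lo

        def to_theta(x: np.ndarray) -> np.ndarray:
            frac = np.clip((x - lo) / span, 0.0, 1.0)
            return np.arcsin(np.sqrt(frac))

        def to_x(theta: np.ndarray) -> np.ndarray:
            return lo + span * np.sin(theta) ** 2

        def obj(theta: np.ndarray) -> float:
            return self._sse_vector(to_x(theta))

        n = self.bounds.k
        maxfev = maxfev or 600 * n
        best_x = None
        best_sse = np.inf
        restart_sses = []
        for r in range(n_restarts):
            rng = np.random.default_rng([seed, r])
            x0 = self._sample_start(rng)
            try:
                res = optimize.minimize(
                    obj, to_theta(x0), method="Nelder-Mead",
                    options={"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-10})
            except FloatingPointError:
                restart_sses.append(np.inf)
                continue
            restart_sses.append(float(res.fun))
            if res.fun < best_sse:
                best_sse = float(res.fun)
                best_x = to_x(res.x)
        if best_x is None:
            raise RuntimeError("all restarts failed")
        params = _params_from_vector(self.spec, best_x, self.bounds.names)
        return MultiRateResults(model=self, params=params, sse=best_sse,
                                restart_sses=restart_sses, seed=seed)


@dataclass
class MultiRateResults:
    """Fit results: estimates, residual error and model-selection score."""

    model: MultiRateModel
    params: ParameterSet
    sse: float
    restart_sses: list[float] = dc_field(default_factory=list)
    seed: int | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def bic(self) -> float:
        from .comparison import compute_bic
        return compute_bic(max(self.sse, SSE_FLOOR), self.n_obs, self.k)

    def predict(self) -> np.ndarray:
        """Fitted noise-free outputs over the full schedule."""
        return self.model.predict(self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.fittedvalues(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def summary(self) -> str:
        lines = [
            "Multi-rate adaptation model fit",
            "=" * 46,
            f"model:          {self.spec.model_id}",
            f"timescales:     {self.spec.n_timescales}"
            f"  fast: {self.spec.fast_mode}  switch: {self.spec.switch_mode}",
            f"n channel obs:  {self.n_obs}",
            f"free params k:  {self.k}",
            f"SSE:            {self.sse:.6g}",
            f"BIC:            {self.bic:.4f}",
            "-" * 46,
        ]
        for name in self.model.bounds.names:
            lo, hi = _BOXES[name]
            lines.append(f"  {name:<5} = {getattr(self.params, name):.5f}"
                         f"   (bounds {lo:g}..{hi:g})")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "params": {n: getattr(self.params, n)
                       for n in self.model.bounds.names},
            "sse": self.sse,
            "n_obs": self.n_obs,
            "k": self.k,
            "bic": self.bic,
            "restart_sses": self.restart_sses,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


#: Alias kept for the functional surface.
FitResult = MultiRateResults


def objective(spec: ModelSpec | str, params: ParameterSet,
              dataset: Dataset) -> float:
    """SSE of one parameter set on one (centered) dataset."""
    return MultiRateModel(dataset, spec).sse(params)


def fit_model(spec: ModelSpec | str, dataset: Dataset, n_restarts: int = 10,
              seed: int = 0) -> MultiRateResults:
    """Fit one model structure to one participant (functional form)."""
    return MultiRateModel(dataset, spec).fit(n_restarts=n_restarts, seed=seed)
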