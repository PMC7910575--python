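"""Markov switching between swimming and hidden states.

The transition from step n-1 to step n is governed by a 2x2 row-stochastic
matrix

    T_n = [[p, 1-p],
           [1-q, q]]

where p is the probability of continuing to swim and q the probability of
remaining hidden.  Two binary covariates — daylight and presence of a
motorboat-noise peak — select one of four such matrices (8 free
probabilities per fish).  A logit-linear link is provided as the continuous
covariate extension; the default fitter uses the four-matrix form.

Convention: the matrix applied to the n-1 -> n transition is selected by
the covariates observed at step n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit, logit as _logit

from .errors import ConfigurationError
from .movement import BehaviourState

__all__ = [
    "CELL_NAMES",
    "TransitionMatrix",
    "TransitionParams",
    "CovariateSeries",
    "transition_matrix",
    "select_matrix",
    "logit_link",
    "logit",
    "simulate_states",
]

#: Covariate cell index = 2*daylight + noise.
CELL_NAMES = {
    (1, 1): "day_noise",
    (1, 0): "day_silence",
    (0, 1): "night_noise",
    (0, 0): "night_silence",
}


@dataclass(frozen=True)
class TransitionMatrix:
    """Stay probabilities of the two-state chain: p (swimming), q (hidden)."""

    p: float
    q: float

    def __post_init__(self) -> None:
        for name, val in (("p", self.p), ("q", self.q)):
            if not np.isfinite(val) or not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {val}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.p, 1.0 - self.p], [1.0 - self.q, self.q]])


def transition_matrix(p: float, q: float) -> np.ndarray:
    """Build the 2x2 row-stochastic transition matrix [[p, 1-p], [1-q, q]]."""
    return TransitionMatrix(p, q).as_array()


@dataclass(frozen=True)
class TransitionParams:
    """One TransitionMatrix per (daylight, noise) covariate combination."""

    matrices: Mapping[tuple[int, int], TransitionMatrix]

    def __post_init__(self) -> None:
        keys = set(self.matrices)
        if keys != set(CELL_NAMES):
            raise ConfigurationError(
                f"need exactly the 4 covariate cells {sorted(CELL_NAMES)}, got {sorted(keys)}"
            )

    @classmethod
    def from_probs(cls, probs: Mapping[str, float]) -> "TransitionParams":
        """Build from a flat mapping like ``{"p_day_noise": 0.8, "q_day_noise": ...}``."""
        mats = {}
        for key, name in CELL_NAMES.items():
            mats[key] = TransitionMatrix(probs[f"p_{name}"], probs[f"q_{name}"])
        return cls(mats)

    def to_probs(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, name in CELL_NAMES.items():
            out[f"p_{name}"] = self.matrices[key].p
            out[f"q_{name}"] = self.matrices[key].q
        return out


def select_matrix(
    params: TransitionParams, daylight: int, noise: int
) -> TransitionMatrix:
    """Return the transition matrix for the given covariate combination."""
    key = (int(daylight), int(noise))
    if key not in CELL_NAMES:
        raise ConfigurationError(f"covariates must be binary, got {key}")
    try:
        return params.matrices[key]
    except KeyError as exc:  # pragma: no cover - blocked by __post_init__
        raise ConfigurationError(f"no transition matrix for cell {key}") from exc


def logit_link(beta1: float, beta2: float, v: float) -> float:
    """Inverse-logit of a linear predictor: the continuous-covariate extension.

    Returns expit(beta1 + beta2 * v), a sigmoid response in (0, 1).
    """
    vals = np.array([beta1, beta2, v], float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("logit_link inputs must be finite")
    return float(expit(beta1 + beta2 * v))


def logit(p) -> np.ndarray:
    """Log-odds, the inverse of the sigmoid link."""
    return _logit(p)


@dataclass
class CovariateSeries:
    """Per-step binary covariates: daylight and motorboat-noise presence."""

    daylight: np.ndarray
    noise: np.ndarray
    times: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.daylight = np.asarray(self.daylight, int)
        self.noise = np.asarray(self.noise, int)
        if self.times is None:
            self.times = np.arange(len(self.daylight))
        self.times = np.asarray(self.times, int)
        if not (len(self.daylight) == len(self.noise) == len(self.times)):
            raise ValueError("covariate series must have equal lengths")
        for name, arr in (("daylight", self.daylight), ("noise", self.noise)):
            if not np.all(np.isin(arr, (0, 1))):
                raise ValueError(f"{name} must be binary")

    def __len__(self) -> int:
        return len(self.daylight)

    @property
    def cell_index(self) -> np.ndarray:
        """Covariate cell per step: 2*daylight + noise, in {0, 1, 2, 3}."""
        return 2 * self.daylight + self.noise


def simulate_states(
    params: TransitionParams,
    covariates: CovariateSeries,
    init: BehaviourState | int,
    seed: int,
) -> np.ndarray:
    """Simulate the behavioural-state Markov chain along a covariate series.

    ``states[0] = init``; for n >= 1 the matrix selected by the covariates
    at step n governs the n-1 -> n transition.  Deterministic given seed.
    """
    n = len(covariates)
    if n == 0:
        raise ValueError("covariate series must be non-empty")
    init = int(init)
    if init not in (1, 2):
        raise ValueError("init must be SWIMMING (1) or HIDDEN (2)")
    # stay[cell, state-1] = probability of remaining in `state`
    stay = np.empty((4, 2))
    for (day, noi), name in CELL_NAMES.items():
        m = params.matrices[(day, noi)]
        stay[2 * day + noi] = (m.p, m.q)
    cells = covariates.cell_index
    u = np.random.default_rng(seed).random(n)
    states = np.empty(n, int)
    states[0] = init
    for i in range(1, n):
        prev = states[i - 1]
        if u[i] < stay[cells[i], prev - 1]:
            states[i] = prev
        else:
            states[i] = 3 - prev
    return states
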