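"""Biased-random-walk movement with a frozen-position hidden state.

A resident fish alternates between two behavioural states: SWIMMING, in
which it performs a biased random walk (BRW) attracted to the centre of its
home range, and HIDDEN, in which it shelters and keeps its previous
position exactly.

The swimming step is a discrete-time Ornstein-Uhlenbeck (AR(1)) update,
independently per axis::

    x[n] = x[n-1] + k*dt*(hr_x - x[n-1]) + eps,    eps ~ N(0, v)

The innovation variance ``v`` is calibrated so that ``radius`` is the 95%
quantile of the stationary distance to the home-range centre::

    v = radius**2 / chi2_95 * (1 - (1 - k*dt)**2)

where ``chi2_95`` is the 0.95 quantile of a chi-square distribution with
2 degrees of freedom (~5.991; the squared distance is a sum of two squared
Gaussian axes).  In the limit k*dt -> 0 this reduces to the continuous-time
OU diffusion rate 2*k*radius**2/chi2_95 * dt; at finite k*dt it keeps the
quantile calibration exact for the discretized chain.  The update requires
k*dt < 1 (the Euler-type discretization diverges beyond that).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import StabilityError

__all__ = [
    "CHI2_95_2DF",
    "BehaviourState",
    "MovementParams",
    "Track",
    "brw_step",
    "simulate_track",
    "swim_logpdf",
]

#: 0.95 quantile of chi-square with 2 df; calibrates radius as the 95%
#: quantile of the stationary distance-to-centre distribution.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


class BehaviourState(enum.IntEnum):
    """Behavioural state coding: 1 = swimming (BRW), 2 = hidden (frozen)."""

    SWIMMING = 1
    HIDDEN = 2


@dataclass(frozen=True)
class MovementParams:
    """Home-range BRW parameters.

    Parameters
    ----------
    hr_x, hr_y
        Home-range centre, local planar metres.
    k
        Attraction strength towards the centre, per second.
    radius
        Home-range radius in metres: the 95% quantile of the stationary
        distance to the centre while swimming.
    dt
        Time-step length in seconds (default 720 s = 12 min, the step
        imposed by the duty-cycled noise recordings).
    """

    hr_x: float
    hr_y: float
    k: float
    radius: float
    dt: float = 720.0

    def __post_init__(self) -> None:
        vals = np.array([self.hr_x, self.hr_y, self.k, self.radius, self.dt], float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("movement parameters must be finite")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.hr_x, self.hr_y])

    @property
    def stationary_var(self) -> float:
        """Per-axis stationary variance of the swimming process."""
        return self.radius**2 / CHI2_95_2DF

    @property
    def step_var(self) -> float:
        """Per-axis innovation variance of one swimming step.

        Raises
        ------
        StabilityError
            If k*dt >= 1.
        """
        kdt = self.k * self.dt
        if kdt >= 1.0:
            raise StabilityError(
                f"k*dt = {kdt:.3g} >= 1: discrete BRW update diverges"
            )
        # 1 - (1-kdt)^2 written as kdt*(2-kdt) to avoid cancellation at tiny k
        return self.stationary_var * kdt * (2.0 - kdt)


@dataclass
class Track:
    """A simulated or latent fish trajectory on the 12-min step grid.

    Invariants: equal lengths; wherever ``states[n] == HIDDEN`` the position
    is bitwise equal to the previous one.
    """

    positions: np.ndarray  # (N, 2) metres
    states: np.ndarray  # (N,) values in {1, 2}
    times: np.ndarray = field(default=None)  # (N,) step indices
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.states = np.asarray(self.states, int)
        if self.times is None:
            self.times = np.arange(len(self.states))
        self.times = np.asarray(self.times, int)
        self.validate()

    def validate(self) -> None:
        n = len(self.states)
        if self.positions.shape != (n, 2) or self.times.shape != (n,):
            raise ValueError("positions, states and times must have equal length")
        if n == 0:
            raise ValueError("track must contain at least one step")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isin(self.states, (1, 2))):
            raise ValueError("states must be 1 (swimming) or 2 (hidden)")
        hid = np.flatnonzero(self.states[1:] == BehaviourState.HIDDEN) + 1
        if hid.size and not np.array_equal(
            self.positions[hid], self.positions[hid - 1]
        ):
            raise ValueError("hidden steps must keep the previous position exactly")

    def __len__(self) -> int:
        return len(self.states)


def brw_step(
    prev,
    params: MovementParams,
    state: BehaviourState | int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance one time step from position ``prev``.

    Hidden fish return ``prev`` exactly; swimming fish take one AR(1) step
    towards the home-range centre plus Gaussian noise.
    """
    prev = np.asarray(prev, float)
    if prev.shape != (2,) or not np.all(np.isfinite(prev)):
        raise ValueError("prev must be a finite (x, y) pair")
    if int(state) == BehaviourState.HIDDEN:
        return prev.copy()
    sd = np.sqrt(params.step_var)  # raises StabilityError when k*dt >= 1
    mean = prev + params.k * params.dt * (params.centre - prev)
    return mean + rng.normal(0.0, sd, size=2)


def simulate_track(
    params: MovementParams,
    states,
    start,
    seed: int,
) -> Track:
    """Simulate a track for a given behavioural state sequence.

    The first position is ``start``; subsequent positions follow the
    two-state movement rule.  Deterministic given ``seed``.
    """
    states = np.asarray([int(s) for s in np.atleast_1d(states)], int)
    if states.size == 0:
        raise ValueError("state sequence must be non-empty")
    if not np.all(np.isin(states, (1, 2))):
        raise ValueError("states must be 1 (swimming) or 2 (hidden)")
    start = np.asarray(start, float)
    if start.shape != (2,) or not np.all(np.isfinite(start)):
        raise ValueError("start must be a finite (x, y) pair")

    n = states.size
    rng = np.random.default_rng(seed)
    if np.any(states == BehaviourState.SWIMMING):
        sd = np.sqrt(params.step_var)
    else:
        sd = 0.0
    # Draw the full noise array up front: the realization is then a pure
    # function of the seed regardless of the state pattern.
    noise = rng.normal(0.0, 1.0, size=(n, 2)) * sd
    kdt = params.k * params.dt
    centre = params.centre
    pos = np.empty((n, 2))
    pos[0] = start
    for i in range(1, n):
        if states[i] == BehaviourState.HIDDEN:
            pos[i] = pos[i - 1]
        else:
            pos[i] = pos[i - 1] + kdt * (centre - pos[i - 1]) + noise[i]
    return Track(positions=pos, states=states, seed=seed)


def swim_logpdf(prev, cur, params: MovementParams) -> np.ndarray:
    """Log-density of a swimming transition ``prev -> cur``.

    Vectorized over leading dimensions; the two axes are independent
    Gaussians with the calibrated innovation variance.
    """
    prev = np.asarray(prev, float)
    cur = np.asarray(cur, float)
    v = params.step_var
    mean = prev + params.k * params.dt * (params.centre - prev)
    sq = np.sum((cur - mean) ** 2, axis=-1)
    return -np.log(2.0 * np.pi * v) - sq / (2.0 * v)
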