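"""Acoustic-telemetry observation model and raw-log preprocessing.

The observed data are counts of decoded tag transmissions per receiver per
12-min step.  Given the (latent) fish position, each receiver decodes each
of the ``emissions_per_step`` transmissions independently with probability

    PD(d) = expit(slope * (d - d50))

a decreasing logistic function of the fish-receiver distance d, so counts
are Binomial(emissions_per_step, PD).  ``d50`` is the inflection point (the
distance with 50% detection probability) and ``slope`` is negative.

Also here: binning of raw detection logs onto the step grid and day/night
classification of timestamps from a sunrise/sunset table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .movement import Track

__all__ = [
    "ReceiverArray",
    "DetectionParams",
    "DetectionSeries",
    "detection_probability",
    "simulate_detections",
    "bin_detections",
    "classify_day_night",
]


@dataclass(frozen=True)
class ReceiverArray:
    """Identifiers and planar coordinates (metres) of the receiver grid."""

    ids: tuple
    coords: np.ndarray  # (J, 2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("receiver ids must be unique")
        if self.coords.shape != (len(self.ids), 2) or not np.all(
            np.isfinite(self.coords)
        ):
            raise ValueError("coords must be a finite (n_receivers, 2) array")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, receiver_id) -> int:
        try:
            return self.ids.index(str(receiver_id))
        except ValueError as exc:
            raise ConfigurationError(f"unknown receiver id {receiver_id!r}") from exc


@dataclass(frozen=True)
class DetectionParams:
    """Logistic detection curve: inflection point d50 (m), negative slope (1/m)."""

    d50: float
    slope: float
    emissions_per_step: int = 6

    def __post_init__(self) -> None:
        if not np.isfinite(self.d50) or not np.isfinite(self.slope):
            raise ValueError("d50 and slope must be finite")
        if self.slope >= 0:
            raise ValueError(f"slope must be negative, got {self.slope}")
        if self.emissions_per_step < 1:
            raise ValueError("emissions_per_step must be >= 1")


@dataclass
class DetectionSeries:
    """Step x receiver matrix of detection counts (the observed data)."""

    counts: np.ndarray  # (N, J) non-negative integers
    step_duration: float = 720.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D step x receiver matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_receivers(self) -> int:
        return self.counts.shape[1]


def detection_probability(distance, params: DetectionParams) -> np.ndarray:
    """Detection probability at the given fish-receiver distance(s)."""
    distance = np.asarray(distance, float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    return expit(params.slope * (distance - params.d50))


def simulate_detections(
    track: Track,
    receivers: ReceiverArray,
    params: DetectionParams,
    seed: int,
) -> DetectionSeries:
    """Draw binomial detection counts for every step and receiver."""
    track.validate()
    d = np.linalg.norm(
        track.positions[:, None, :] - receivers.coords[None, :, :], axis=-1
    )
    pd_ = detection_probability(d, params)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(params.emissions_per_step, pd_)
    return DetectionSeries(counts=counts)


def bin_detections(
    events: pd.DataFrame,
    receivers: ReceiverArray,
    step_duration: float = 720.0,
    origin=None,
    n_steps: int | None = None,
) -> DetectionSeries:
    """Discretize a raw detection log onto half-open 12-min bins.

    ``events`` must have columns ``timestamp`` and ``receiver_id`` (a
    ``tag_id`` column, if present, is ignored — callers filter per fish).
    Bin n covers [origin + n*step, origin + (n+1)*step).  The total count
    is conserved: the sum of the output equals the number of events.
    """
    if origin is None:
        raise ValueError("origin timestamp is required")
    origin = pd.Timestamp(origin)
    if origin.tzinfo is None:
        origin = origin.tz_localize("UTC")
    if len(events) == 0:
        if n_steps is None:
            raise ValueError("n_steps is required for an empty log")
        return DetectionSeries(
            counts=np.zeros((n_steps, len(receivers)), int),
            step_duration=step_duration,
        )
    ts = pd.to_datetime(events["timestamp"], utc=True)
    offsets = (ts - origin).dt.total_seconds().to_numpy()
    if np.any(offsets < 0):
        raise ValueError("event before the binning origin")
    steps = (offsets // step_duration).astype(int)
    if n_steps is None:
        n_steps = int(steps.max()) + 1
    elif np.any(steps >= n_steps):
        raise ValueError("event beyond the last bin")
    jidx = np.array([receivers.index_of(r) for r in events["receiver_id"]])
    counts = np.zeros((n_steps, len(receivers)), int)
    np.add.at(counts, (steps, jidx), 1)
    return DetectionSeries(counts=counts, step_duration=step_duration)


def classify_day_night(timestamps: Iterable, sun_table: Mapping | pd.DataFrame) -> np.ndarray:
    """Classify UTC timestamps as day (1) or night (0).

    ``sun_table`` maps each calendar date to its (sunrise, sunset) UTC
    times; a DataFrame with columns ``date``, ``sunrise``, ``sunset`` is
    also accepted.  Convention: day iff sunrise <= t < sunset
    (sunrise-inclusive, sunset-exclusive).
    """
    if isinstance(sun_table, pd.DataFrame):
        table = {
            pd.Timestamp(row["date"]).date(): (
                pd.Timestamp(row["sunrise"]),
                pd.Timestamp(row["sunset"]),
            )
            for _, row in sun_table.iterrows()
        }
    else:
        table = {
            pd.Timestamp(k).date(): (pd.Timestamp(v[0]), pd.Timestamp(v[1]))
            for k, v in sun_table.items()
        }
    norm_table = {}
    for date, (rise, sset) in table.items():
        if rise.tzinfo is None:
            rise = rise.tz_localize("UTC")
        if sset.tzinfo is None:
            sset = sset.tz_localize("UTC")
        norm_table[date] = (rise, sset)

    out = []
    for t in timestamps:
        t = pd.Timestamp(t)
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        key = t.date()
        if key not in norm_table:
            raise ConfigurationError(f"sun table does not cover date {key}")
        rise, sset = norm_table[key]
        out.append(1 if rise <= t < sset else 0)
    return np.array(out, int)
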