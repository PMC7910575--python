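"""Plain-text columnar readers and writers.

Every format is headered CSV (timestamps ISO-8601 UTC, step indices
0-based, bins half-open); track and detection-series files carry a JSON
sidecar with their parameters so they round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviour import CovariateSeries
from .movement import Track
from .observation import DetectionSeries, ReceiverArray

__all__ = [
    "read_receivers",
    "write_receivers",
    "read_track",
    "write_track",
    "read_detection_series",
    "write_detection_series",
    "read_covariates",
    "write_covariates",
    "read_detection_log",
    "read_sun_table",
    "write_noise_flags",
    "write_draws",
    "write_summary",
]


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_receivers(path, receivers: ReceiverArray) -> None:
    pd.DataFrame(
        {
            "receiver_id": receivers.ids,
            "x": receivers.coords[:, 0],
            "y": receivers.coords[:, 1],
        }
    ).to_csv(path, index=False)


def read_receivers(path) -> ReceiverArray:
    df = pd.read_csv(path)
    return ReceiverArray(ids=tuple(df["receiver_id"].astype(str)), coords=df[["x", "y"]].to_numpy())


def write_track(path, track: Track, meta: dict | None = None) -> None:
    pd.DataFrame(
        {
            "step": track.times,
            "x": track.positions[:, 0],
            "y": track.positions[:, 1],
            "state": track.states,
        }
    ).to_csv(path, index=False)
    sidecar = {"seed": track.seed, **(meta or {})}
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_track(path) -> tuple[Track, dict]:
    df = pd.read_csv(path)
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    track = Track(
        positions=df[["x", "y"]].to_numpy(),
        states=df["state"].to_numpy(),
        times=df["step"].to_numpy(),
        seed=meta.get("seed"),
    )
    return track, meta


def write_detection_series(
    path, series: DetectionSeries, receivers: ReceiverArray
) -> None:
    n, j = series.counts.shape
    df = pd.DataFrame(
        {
            "step": np.repeat(np.arange(n), j),
            "receiver_id": np.tile(np.asarray(receivers.ids), n),
            "count": series.counts.reshape(-1),
        }
    )
    df.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"step_duration": series.step_duration}, sort_keys=True)
    )


def read_detection_series(path, receivers: ReceiverArray) -> DetectionSeries:
    df = pd.read_csv(path)
    meta_path = _sidecar(path)
    step_duration = 720.0
    if meta_path.exists():
        step_duration = json.loads(meta_path.read_text()).get("step_duration", 720.0)
    n = int(df["step"].max()) + 1
    counts = np.zeros((n, len(receivers)), int)
    jidx = df["receiver_id"].astype(str).map({r: i for i, r in enumerate(receivers.ids)})
    if jidx.isna().any():
        raise ValueError("detection series references unknown receiver ids")
    counts[df["step"].to_numpy(), jidx.to_numpy(int)] = df["count"].to_numpy()
    return DetectionSeries(counts=counts, step_duration=step_duration)


def write_covariates(path, covariates: CovariateSeries) -> None:
    pd.DataFrame(
        {
            "step": covariates.times,
            "daylight": covariates.daylight,
            "noise": covariates.noise,
        }
    ).to_csv(path, index=False)


def read_covariates(path) -> CovariateSeries:
    df = pd.read_csv(path)
    return CovariateSeries(
        daylight=df["daylight"].to_numpy(),
        noise=df["noise"].to_numpy(),
        times=df["step"].to_numpy(),
    )


def read_detection_log(path) -> pd.DataFrame:
    """Raw detection log: timestamp (ISO-8601 UTC), tag_id, receiver_id."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def read_sun_table(path) -> pd.DataFrame:
    """Sunrise/sunset table: date, sunrise, sunset (UTC)."""
    df = pd.read_csv(path)
    df["sunrise"] = pd.to_datetime(df["sunrise"], utc=True)
    df["sunset"] = pd.to_datetime(df["sunset"], utc=True)
    return df


def write_noise_flags(path, series) -> None:
    origin = series.origin
    n = len(series.flags)
    if origin is not None:
        starts = origin + pd.to_timedelta(
            np.arange(n) * series.step_duration, unit="s"
        )
        utc = [t.isoformat() for t in starts]
    else:
        utc = [""] * n
    pd.DataFrame(
        {"step": np.arange(n), "utc_start": utc, "noise_flag": series.flags}
    ).to_csv(path, index=False)


def write_draws(path, samples) -> None:
    samples.to_frame().to_csv(path, index=False)


def write_summary(path, summary: pd.DataFrame) -> None:
    summary.to_csv(path)
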