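"""Plain-CSV interchange for trajectories, EMG and MVIC references.

Canonical formats (all deterministic to the byte for a given run):

* trajectory CSV — columns ``time_s, hand, x_m, y_m, z_m`` (long format, both
  hands in one file);
* EMG CSV — ``time_s`` plus one column per channel named ``side_muscle``;
* MVIC CSV — ``channel, reference_rms_mv, reference_mean_abs_mv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from .emg import MVICReference
from .errors import InvalidArgumentError
from .synthetic import CHANNELS, EMGTrial, MotionTrial

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_emg_csv",
    "read_emg_csv",
    "write_mvic_csv",
    "read_mvic_csv",
]

_FLOAT_FMT = "%.12g"


def write_trajectory_csv(path: Path | str, trial: MotionTrial) -> None:
    frames = []
    for side in ("left", "right"):
        traj = trial.hand(side)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.timestamps,
                    "hand": side,
                    "x_m": traj.positions[:, 0],
                    "y_m": traj.positions[:, 1],
                    "z_m": traj.positions[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path: Path | str) -> dict[str, kin.TrajectorySeries]:
    """Read a trajectory CSV into per-hand series; frame rate inferred from the
    time column."""
    df = pd.read_csv(path)
    required = {"time_s", "hand", "x_m", "y_m", "z_m"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"trajectory CSV missing columns {sorted(missing)}")
    out = {}
    for side, sub in df.groupby("hand", sort=True):
        t = sub["time_s"].to_numpy()
        if len(t) < 2:
            raise InvalidArgumentError(f"hand {side}: too few samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        out[str(side)] = kin.TrajectorySeries(
            timestamps=t,
            positions=sub[["x_m", "y_m", "z_m"]].to_numpy(),
            frame_rate=rate,
        )
    return out


def write_emg_csv(path: Path | str, trial: EMGTrial) -> None:
    n = len(next(iter(trial.channels.values())))
    data = {"time_s": np.arange(n) / trial.sample_rate}
    for name in CHANNELS:
        data[name] = trial.channels[name]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_emg_csv(path: Path | str) -> tuple[dict[str, np.ndarray], float]:
    """Read an EMG CSV; returns (channels, sample_rate)."""
    df = pd.read_csv(path)
    missing = ({"time_s"} | set(CHANNELS)) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"EMG CSV missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise InvalidArgumentError("EMG CSV too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    channels = {name: df[name].to_numpy(dtype=float) for name in CHANNELS}
    return channels, rate


def write_mvic_csv(path: Path | str, mvic: MVICReference) -> None:
    rows = [
        {
            "channel": name,
            "reference_rms_mv": mvic.reference_rms[name],
            "reference_mean_abs_mv": mvic.reference_mean_abs[name],
        }
        for name in sorted(mvic.reference_rms)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_mvic_csv(path: Path | str) -> MVICReference:
    df = pd.read_csv(path)
    missing = {"channel", "reference_rms_mv", "reference_mean_abs_mv"} - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"MVIC CSV missing columns {sorted(missing)}")
    return MVICReference(
        reference_rms=dict(zip(df["channel"], df["reference_rms_mv"].astype(float))),
        reference_mean_abs=dict(
            zip(df["channel"], df["reference_mean_abs_mv"].astype(float))
        ),
    )
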