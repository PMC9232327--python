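"""Hand-trajectory kinematics: path length, plane projections, speed, braking.

Movement amplitude is quantified by the *action track length*: the cumulative
Euclidean length of the sampled 3D hand path,

    L = sum_n sqrt((x_{n+1}-x_n)^2 + (y_{n+1}-y_n)^2 + (z_{n+1}-z_n)^2),

optionally projected onto an anatomical plane and normalized by subject height
(relative track length).  Braking is quantified per metronome beat by the speed
drop from the within-beat speed peak to the end of the deceleration phase,
Δv = v_end − v_peak, and the mean acceleration ā = Δv/Δt over that interval.

Axis convention: X mediolateral, Y anteroposterior, Z vertical, so XY is the
horizontal (transverse) plane, XZ the frontal plane and YZ the sagittal plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, SegmentationError

__all__ = [
    "PlaneCode",
    "TrajectorySeries",
    "SpeedSeries",
    "TrackLengthSummary",
    "BeatBraking",
    "track_length",
    "plane_track_length",
    "relative_track_length",
    "summarize_track",
    "hand_average",
    "linear_speed",
    "smooth_positions",
    "segment_beats",
    "braking_metrics",
]

logger = logging.getLogger(__name__)


class PlaneCode(str, Enum):
    """Anatomical plane, identified by the pair of retained coordinate axes."""

    XY = "XY"  # horizontal / transverse
    XZ = "XZ"  # frontal / coronal
    YZ = "YZ"  # sagittal

    @property
    def anatomical_name(self) -> str:
        return {"XY": "horizontal", "XZ": "frontal", "YZ": "sagittal"}[self.value]

    @property
    def axes(self) -> tuple[int, int]:
        return {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}[self.value]


@dataclass(frozen=True)
class TrajectorySeries:
    """Uniformly sampled 3D position time series for one hand.

    Parameters
    ----------
    timestamps : (n,) array, seconds, strictly increasing and uniform.
    positions : (n, 3) array, meters.
    frame_rate : sampling rate in Hz; consecutive timestamps must differ from
        ``1/frame_rate`` by less than 1e-9 s.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "positions", p)
        if t.ndim != 1 or p.ndim != 2 or p.shape[1] != 3:
            raise InvalidArgumentError("timestamps must be (n,), positions (n, 3)")
        if len(t) != len(p):
            raise InvalidArgumentError("timestamps and positions lengths differ")
        if len(t) < 2:
            raise InsufficientDataError("a trajectory needs at least 2 samples")
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame_rate must be positive")
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / self.frame_rate) >= 1e-9):
            raise InvalidArgumentError("timestamps are not uniform at frame_rate")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SpeedSeries:
    """Scalar speed magnitude per frame, same sampling as the source trajectory."""

    timestamps: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, float))
        object.__setattr__(self, "speed", np.asarray(self.speed, float))
        if len(self.timestamps) != len(self.speed):
            raise InvalidArgumentError("timestamps and speed lengths differ")
        if np.any(self.speed < 0):
            raise InvalidArgumentError("speed magnitudes must be nonnegative")


@dataclass(frozen=True)
class TrackLengthSummary:
    """Track lengths (3D and per plane) with height-normalized relatives."""

    hand: str  # "left" | "right" | "averaged"
    height: float  # subject height, m
    length_3d: float
    plane_lengths: Mapping[PlaneCode, float]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidArgumentError("height must be positive")

    @property
    def relative_3d(self) -> float:
        return relative_track_length(self.length_3d, self.height)

    @property
    def relative_lengths(self) -> dict[PlaneCode, float]:
        return {
            plane: relative_track_length(length, self.height)
            for plane, length in self.plane_lengths.items()
        }


@dataclass(frozen=True)
class BeatBraking:
    """Per-beat braking record: peak-to-end speed drop and mean deceleration.

    ``a_bar`` always satisfies ``a_bar * delta_t == delta_v`` by construction;
    a negative sign denotes deceleration.
    """

    beat_index: int  # 1-based
    t_peak: float
    v_peak: float
    t_end: float
    v_end: float
    delta_v: float = field(init=False)
    delta_t: float = field(init=False)
    a_bar: float = field(init=False)

    def __post_init__(self) -> None:
        if self.v_end > self.v_peak:
            raise InvalidArgumentError("v_end cannot exceed v_peak")
        if self.t_end <= self.t_peak:
            raise InvalidArgumentError("braking interval must have delta_t > 0")
        object.__setattr__(self, "delta_v", self.v_end - self.v_peak)
        object.__setattr__(self, "delta_t", self.t_end - self.t_peak)
        object.__setattr__(self, "a_bar", self.delta_v / self.delta_t)


# ---------------------------------------------------------------------------
# track length


def track_length(traj: TrajectorySeries) -> float:
    """Cumulative Euclidean length of the sampled 3D path, in meters."""
    steps = np.diff(traj.positions, axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def plane_track_length(traj: TrajectorySeries, plane: PlaneCode) -> float:
    """Track length of the path projected onto an anatomical plane.

    The third coordinate is dropped; by the triangle inequality the result
    never exceeds the full 3D track length.
    """
    plane = PlaneCode(plane)
    steps = np.diff(traj.positions[:, plane.axes], axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def relative_track_length(length: float, height: float) -> float:
    """Track length divided by subject height (dimensionless); removes stature."""
    if height <= 0:
        raise InvalidArgumentError("height must be positive")
    if length < 0:
        raise InvalidArgumentError("length must be nonnegative")
    return length / height


def summarize_track(
    traj: TrajectorySeries,
    height: float,
    hand: str,
    subject_id: str | None = None,
) -> TrackLengthSummary:
    """Compute the full per-hand amplitude summary (3D + all three planes)."""
    return TrackLengthSummary(
        hand=hand,
        height=height,
        length_3d=track_length(traj),
        plane_lengths={p: plane_track_length(traj, p) for p in PlaneCode},
        subject_id=subject_id,
    )


def hand_average(left: TrackLengthSummary, right: TrackLengthSummary) -> TrackLengthSummary:
    """Arithmetic mean of the left- and right-hand summaries of one subject."""
    if left.subject_id != right.subject_id:
        raise InvalidArgumentError("cannot average summaries of different subjects")
    if left.height != right.height:
        raise InvalidArgumentError("cannot average summaries with different heights")
    if set(left.plane_lengths) != set(right.plane_lengths):
        raise InvalidArgumentError("plane sets differ between hands")
    return TrackLengthSummary(
        hand="averaged",
        height=left.height,
        length_3d=0.5 * (left.length_3d + right.length_3d),
        plane_lengths={
            p: 0.5 * (left.plane_lengths[p] + right.plane_lengths[p])
            for p in left.plane_lengths
        },
        subject_id=left.subject_id,
    )


# ---------------------------------------------------------------------------
# speed and braking


def smooth_positions(traj: TrajectorySeries, window: int) -> TrajectorySeries:
    """Optional centered moving-average position smoothing (window in frames).

    ``window <= 1`` is the identity.  Edges use a shrunken window so the series
    length is preserved.
    """
    if window <= 1:
        return traj
    kernel = np.ones(window) / window
    smoothed = np.column_stack(
        [
            np.convolve(traj.positions[:, k], kernel, mode="same")
            / np.convolve(np.ones(len(traj)), kernel, mode="same")
            for k in range(3)
        ]
    )
    return TrajectorySeries(traj.timestamps, smoothed, traj.frame_rate)


def linear_speed(traj: TrajectorySeries) -> SpeedSeries:
    """Linear speed magnitude per frame.

    Velocity is estimated by central finite differences at interior frames and
    one-sided differences at the two ends (exact for motion affine in time).
    """
    if len(traj) < 3:
        raise InsufficientDataError("linear speed needs at least 3 samples")
    velocity = np.gradient(traj.positions, 1.0 / traj.frame_rate, axis=0)
    return SpeedSeries(traj.timestamps, np.linalg.norm(velocity, axis=1))


def segment_beats(
    n_frames: int, tempo: float, frame_rate: float, n_beats: int
) -> np.ndarray:
    """Beat-boundary sample indices for a metronome-paced trial.

    Parameters
    ----------
    n_frames : index of the last sample (the series has ``n_frames + 1``
        samples); must equal ``n_beats * (60/tempo) * frame_rate`` within one
        frame.
    tempo : beats per minute.

    Returns
    -------
    (n_beats + 1,) int array of boundary indices; first 0, last ``n_frames``,
    interior boundaries at rounded multiples of the per-beat frame count.
    """
    if tempo <= 0 or frame_rate <= 0:
        raise InvalidArgumentError("tempo and frame_rate must be positive")
    if n_beats < 1 or n_frames < n_beats:
        raise InvalidArgumentError("need n_frames >= n_beats >= 1")
    step = (60.0 / tempo) * frame_rate
    expected = int(round(n_beats * step))
    if abs(expected - n_frames) > 1:
        raise SegmentationError(
            f"{n_frames} frames inconsistent with {n_beats} beats at "
            f"{tempo} bpm / {frame_rate} Hz (expected ~{expected})"
        )
    boundaries = np.array(
        [int(round(k * step)) for k in range(n_beats)] + [int(n_frames)], dtype=int
    )
    if np.any(np.diff(boundaries) < 1):
        raise SegmentationError("beat boundaries are not strictly increasing")
    return boundaries


def braking_metrics(
    speed: SpeedSeries,
    boundaries: Sequence[int],
    zero_threshold: float = 1e-3,
) -> list[BeatBraking]:
    """Per-beat braking records from a speed series and beat boundaries.

    For each beat window (inclusive of both boundary samples) the braking
    interval runs from the frame of maximum speed to the earlier of (a) the
    first post-peak frame where speed drops to ``zero_threshold`` or below and
    (b) the beat's final frame.  Beats whose speed peak falls on the final
    frame have no deceleration phase; they are logged and excluded.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries[0] < 0 or boundaries[-1] > len(speed.speed) - 1:
        raise InvalidArgumentError("boundaries outside the speed series")
    records: list[BeatBraking] = []
    for b in range(len(boundaries) - 1):
        lo, hi = int(boundaries[b]), int(boundaries[b + 1])
        window = speed.speed[lo : hi + 1]
        peak = lo + int(np.argmax(window))
        if peak == hi:
            logger.warning(
                "beat %d: speed peak at the final frame; no deceleration phase, "
                "record excluded",
                b + 1,
            )
            continue
        after = speed.speed[peak + 1 : hi + 1]
        below = np.nonzero(after <= zero_threshold)[0]
        end = peak + 1 + int(below[0]) if below.size else hi
        records.append(
            BeatBraking(
                beat_index=b + 1,
                t_peak=float(speed.timestamps[peak]),
                v_peak=float(speed.speed[peak]),
                t_end=float(speed.timestamps[end]),
                v_end=float(speed.speed[end]),
            )
        )
    return records
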