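"""Seeded synthetic motion-capture and sEMG data with the structure the
analysis assumes.

The generator emulates a two-group cohort performing metronome-paced arm
lifting combinations:

* **Motion**: each beat is a point-to-point hand movement between canonical
  via-points (shoulder-origin geometry), following a minimum-jerk profile
  ``s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`` that starts and ends at rest — which gives every
  beat a well-defined speed peak and a terminal braking phase.  Group amplitude
  differences scale the whole geometry; group braking differences warp the time
  profile (``τ → τ^k``) so the speed peak falls later and the deceleration is
  steeper.  Measurement noise is additive zero-mean Gaussian per coordinate.
* **EMG**: eight channels ({left,right} × {biceps brachii, triceps brachii,
  deltoid middle, latissimus dorsi}) at 1000 Hz.  Each channel is an amplitude
  envelope (proportional to the hand's instantaneous speed, the group's muscle
  weight, and a right-over-left asymmetry factor) multiplying a band-limited
  (20–450 Hz) zero-mean unit-RMS Gaussian carrier, plus additive noise.
* **MVIC**: a constant-envelope burst per channel whose drive exceeds any task
  envelope, so standardized task values stay bounded.

Everything is reproducible bit-for-bit from ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from . import emg as emg_mod
from . import kinematics as kin
from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "MUSCLES",
    "SIDES",
    "CHANNELS",
    "ArmGeometry",
    "SubjectProfile",
    "BeatSpec",
    "CombinationScript",
    "CohortConfig",
    "MotionTrial",
    "EMGTrial",
    "CohortBundle",
    "min_jerk_segment",
    "build_combination_script",
    "generate_motion_trial",
    "generate_emg_trial",
    "generate_mvic",
    "generate_cohort",
    "resolve_muscle_weight",
]

MUSCLES = ("biceps_brachii", "triceps_brachii", "deltoid_middle", "latissimus_dorsi")
SIDES = ("left", "right")
CHANNELS = tuple(f"{side}_{muscle}" for side in SIDES for muscle in MUSCLES)

COMBO_BEATS = {1: 8, 2: 4}

# Beat-by-beat action sequences.  Combination 1 is the symmetric eight-beat
# front/up/side/down lift pattern (front on beats 1 and 7, up on 2 and 6, side
# on 3 and 5, down on 4 and 8).  Combination 2 is the four-beat chest-cross +
# side-up/side-down lift loop with the chest cross on beats 1 and 3.
COMBO_ACTIONS = {
    1: ("front_lift", "up_lift", "side_lift", "down_lift",
        "side_lift", "up_lift", "front_lift", "down_lift"),
    2: ("chest_cross", "side_up_lift", "chest_cross", "side_down_lift"),
}
COMBO_START_POSE = {1: "down_lift", 2: "side_down_lift"}


@dataclass(frozen=True)
class ArmGeometry:
    """Canonical via-point geometry (meters, shoulder-centric).

    The side lift sits slightly forward of pure lateral (70° azimuth) and the
    chest cross reaches across the midline; with these choices combination 1
    moves most in the sagittal plane and combination 2 most in the horizontal
    plane, matching the qualitative amplitude structure the analysis targets.
    """

    shoulder_height_m: float = 1.45
    shoulder_halfwidth_m: float = 0.20
    arm_length_m: float = 0.60
    side_azimuth_deg: float = 70.0
    side_elevation_deg: float = 45.0
    down_forward: float = 0.10  # slight forward bias of the hanging arm
    # chest-cross hand position relative to the same-side shoulder (right hand;
    # the left hand mirrors the X component)
    chest_cross_offset_m: tuple[float, float, float] = (-0.30, 0.50, 0.05)

    def pose(self, action: str, side: str) -> np.ndarray:
        """Absolute hand position (m) for a named end pose, one side."""
        sign = 1.0 if side == "right" else -1.0
        shoulder = np.array([sign * self.shoulder_halfwidth_m, 0.0, self.shoulder_height_m])
        L = self.arm_length_m
        az = math.radians(self.side_azimuth_deg)
        el = math.radians(self.side_elevation_deg)
        if action == "down_lift":
            d = np.array([0.0, self.down_forward, -1.0])
            return shoulder + L * d / np.linalg.norm(d)
        if action == "front_lift":
            return shoulder + np.array([0.0, L, 0.0])
        if action == "up_lift":
            return shoulder + np.array([0.0, 0.0, L])
        if action == "side_lift":
            return shoulder + L * np.array([sign * math.sin(az), math.cos(az), 0.0])
        if action == "side_up_lift":
            return shoulder + L * np.array([sign * math.cos(el), 0.0, math.sin(el)])
        if action == "side_down_lift":
            return shoulder + L * np.array([sign * math.cos(el), 0.0, -math.sin(el)])
        if action == "chest_cross":
            off = np.array(self.chest_cross_offset_m)
            return shoulder + np.array([sign * off[0], off[1], off[2]])
        raise InvalidArgumentError(f"unknown action {action!r}")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str  # "A" | "B"
    height: float  # m
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise InvalidArgumentError("group must be 'A' or 'B'")
        if self.height <= 0:
            raise InvalidArgumentError("height must be positive")
        if self.handedness not in SIDES:
            raise InvalidArgumentError("handedness must be 'left' or 'right'")


@dataclass(frozen=True)
class BeatSpec:
    beat_index: int  # 1-based
    action_name: str
    left_start: np.ndarray
    left_end: np.ndarray
    right_start: np.ndarray
    right_end: np.ndarray


@dataclass(frozen=True)
class CombinationScript:
    combo_id: int
    tempo: float  # beats per minute
    beats: tuple[BeatSpec, ...]

    def __post_init__(self) -> None:
        if self.tempo <= 0:
            raise InvalidArgumentError("tempo must be positive")
        expected = COMBO_BEATS.get(self.combo_id)
        if expected is None or len(self.beats) != expected:
            raise InvalidArgumentError(
                f"combination {self.combo_id} must have {expected} beats"
            )

    @property
    def n_beats(self) -> int:
        return len(self.beats)


@dataclass(frozen=True)
class CohortConfig:
    """Seeded study conditions for the synthetic cohort.

    Defaults encode the emulated study: 4 + 11 subjects, 120 bpm, 30 Hz motion
    capture, 1000 Hz EMG, a 15% group-A amplitude surplus, sharper group-A
    braking, latissimus-dominant group-A muscle weights versus left-triceps /
    right-biceps-dominant group B, and a 1.3 right-over-left asymmetry.
    """

    n_group_a: int = 4
    n_group_b: int = 11
    seed: int = 0
    frame_rate: float = 30.0  # Hz
    emg_rate: float = 1000.0  # Hz
    tempo: float = 120.0  # beats/min
    amplitude_scale: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.15, "B": 1.0}
    )
    braking_sharpness: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.2, "B": 1.0}
    )
    muscle_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "A": {
                "latissimus_dorsi": 1.0,
                "triceps_brachii": 0.50,
                "deltoid_middle": 0.45,
                "biceps_brachii": 0.13,
            },
            # group B: side-specific weights (left triceps and right biceps
            # dominant); side-keyed entries bypass the asymmetry factor
            "B": {
                "left_triceps_brachii": 0.75,
                "right_biceps_brachii": 0.72,
                "left_biceps_brachii": 0.11,
                "right_triceps_brachii": 0.45,
                "left_deltoid_middle": 0.35,
                "right_deltoid_middle": 0.50,
                "left_latissimus_dorsi": 0.20,
                "right_latissimus_dorsi": 0.45,
            },
        }
    )
    side_asymmetry: float = 1.3  # right-channel envelope multiplier
    subject_amplitude_sd: float = 0.07  # between-trial multiplicative CV
    coord_noise_sd: float = 0.003  # m
    emg_noise_sd: float = 0.01  # mV
    emg_gain_mv: float = 0.1  # mV per (m/s) of envelope drive
    mvic_drive: float = 8.0  # m/s-equivalent constant MVIC drive
    mvic_duration_s: float = 3.0
    emg_carrier_band: tuple[float, float] = (20.0, 450.0)
    height_mean_m: float = 1.77
    height_sd_m: float = 0.09
    right_handed_fraction: float = 0.9
    geometry: ArmGeometry = field(default_factory=ArmGeometry)

    def __post_init__(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0:
            raise ConfigurationError("group sizes must be positive")
        for name in ("frame_rate", "emg_rate", "tempo", "emg_gain_mv", "mvic_drive"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for g in ("A", "B"):
            if self.amplitude_scale.get(g, 0) <= 0:
                raise ConfigurationError(f"amplitude_scale[{g}] must be positive")
            if self.braking_sharpness.get(g, 0) <= 0:
                raise ConfigurationError(f"braking_sharpness[{g}] must be positive")
            if g not in self.muscle_weights:
                raise ConfigurationError(f"muscle_weights[{g}] missing")
        if self.coord_noise_sd < 0 or self.emg_noise_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b


@dataclass(frozen=True)
class MotionTrial:
    subject: SubjectProfile
    combo_id: int
    left: kin.TrajectorySeries
    right: kin.TrajectorySeries
    boundaries: np.ndarray  # beat boundary frame indices, n_beats + 1

    def __post_init__(self) -> None:
        if not np.array_equal(self.left.timestamps, self.right.timestamps):
            raise InvalidArgumentError("hands must share timestamps")

    @property
    def duration(self) -> float:
        return float(self.left.timestamps[-1])

    def hand(self, side: str) -> kin.TrajectorySeries:
        return self.left if side == "left" else self.right


@dataclass(frozen=True)
class EMGTrial:
    subject: SubjectProfile
    combo_id: int
    sample_rate: float
    channels: Mapping[str, np.ndarray]  # 8 channels keyed side_muscle

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise InvalidArgumentError("an EMG trial needs exactly the 8 study channels")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise InvalidArgumentError("all channels must have equal length")


@dataclass(frozen=True)
class CohortBundle:
    config: CohortConfig
    profiles: tuple[SubjectProfile, ...]
    scripts: Mapping[int, CombinationScript]
    motion: Mapping[tuple[str, int], MotionTrial]
    emg: Mapping[tuple[str, int], EMGTrial]
    mvic: Mapping[str, emg_mod.MVICReference]


# ---------------------------------------------------------------------------
# movement model


def _quintic(tau: np.ndarray) -> np.ndarray:
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _min_jerk_steps(
    p0: np.ndarray, p1: np.ndarray, n_steps: int, warp: float
) -> np.ndarray:
    tau = np.arange(n_steps + 1) / n_steps
    s = _quintic(tau**warp)
    return np.asarray(p0) + s[:, None] * (np.asarray(p1) - np.asarray(p0))


def min_jerk_segment(
    p0: Sequence[float],
    p1: Sequence[float],
    duration: float,
    rate: float,
    warp: float = 1.0,
) -> np.ndarray:
    """Positions of a straight-line minimum-jerk move from ``p0`` to ``p1``.

    Returns ``round(duration*rate) + 1`` samples at ``1/rate`` spacing,
    following ``s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`` so the move starts and ends at rest
    with peak speed ``15·d/(8·T)``.  ``warp > 1`` substitutes ``τ^warp`` for τ,
    shifting the speed peak later (sharper terminal braking) while preserving
    the rest boundary conditions.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    if warp <= 0:
        raise InvalidArgumentError("warp must be positive")
    n_steps = max(1, int(round(duration * rate)))
    return _min_jerk_steps(np.asarray(p0, float), np.asarray(p1, float), n_steps, warp)


def build_combination_script(
    combo_id: int,
    geometry: ArmGeometry | None = None,
    tempo: float = 120.0,
) -> CombinationScript:
    """Via-point script for one of the two test combinations.

    Combination 1: eight beats, front/up/side/down lifts in the symmetric
    order (front on beats 1 and 7).  Combination 2: four beats, chest cross on
    beats 1 and 3 framed by the side-up and side-down lifts.  Consecutive
    beats chain: each beat starts where the previous one ended, per hand.
    """
    if combo_id not in COMBO_ACTIONS:
        raise InvalidArgumentError(f"unknown combination id {combo_id!r}")
    geometry = geometry or ArmGeometry()
    beats = []
    prev = {side: geometry.pose(COMBO_START_POSE[combo_id], side) for side in SIDES}
    for k, action in enumerate(COMBO_ACTIONS[combo_id], start=1):
        end = {side: geometry.pose(action, side) for side in SIDES}
        beats.append(
            BeatSpec(
                beat_index=k,
                action_name=action,
                left_start=prev["left"],
                left_end=end["left"],
                right_start=prev["right"],
                right_end=end["right"],
            )
        )
        prev = end
    return CombinationScript(combo_id=combo_id, tempo=tempo, beats=tuple(beats))


def generate_motion_trial(
    profile: SubjectProfile,
    script: CombinationScript,
    config: CohortConfig,
    rng: np.random.Generator,
) -> MotionTrial:
    """One metronome-paced motion trial for one subject.

    Each beat lasts ``60/tempo`` s; each hand follows a (possibly time-warped)
    minimum-jerk segment between its chained via-points.  The whole geometry is
    scaled by the group amplitude scale times a per-trial multiplicative factor
    (between-trial variability), then zero-mean coordinate noise is added.
    """
    step = (60.0 / script.tempo) * config.frame_rate
    if round(step) < 2:
        raise ConfigurationError(
            "frame rate too low: fewer than 2 frames per beat at this tempo"
        )
    n_frames = int(round(script.n_beats * step))
    boundaries = kin.segment_beats(n_frames, script.tempo, config.frame_rate, script.n_beats)
    warp = config.braking_sharpness[profile.group]
    trial_scale = config.amplitude_scale[profile.group] * max(
        0.5, 1.0 + config.subject_amplitude_sd * rng.standard_normal()
    )

    hands: dict[str, np.ndarray] = {}
    for side in SIDES:
        pieces = [np.asarray(getattr(script.beats[0], f"{side}_start"), float)[None, :]]
        for b, beat in enumerate(script.beats):
            n_steps = int(boundaries[b + 1] - boundaries[b])
            seg = _min_jerk_steps(
                getattr(beat, f"{side}_start"),
                getattr(beat, f"{side}_end"),
                n_steps,
                warp,
            )
            pieces.append(seg[1:])
        hands[side] = trial_scale * np.concatenate(pieces, axis=0)

    # one noise draw per hand, in a fixed order, so trials are reproducible
    for side in SIDES:
        if config.coord_noise_sd > 0:
            hands[side] = hands[side] + rng.normal(
                0.0, config.coord_noise_sd, size=hands[side].shape
            )

    timestamps = np.arange(n_frames + 1) / config.frame_rate
    return MotionTrial(
        subject=profile,
        combo_id=script.combo_id,
        left=kin.TrajectorySeries(timestamps, hands["left"], config.frame_rate),
        right=kin.TrajectorySeries(timestamps, hands["right"], config.frame_rate),
        boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# EMG model


def resolve_muscle_weight(
    weights: Mapping[str, float], side: str, muscle: str, asymmetry: float
) -> float:
    """Channel weight lookup: side-specific key wins; muscle-level keys get the
    right-over-left asymmetry factor applied to the right side."""
    key = f"{side}_{muscle}"
    if key in weights:
        return float(weights[key])
    if muscle in weights:
        w = float(weights[muscle])
        return w * asymmetry if side == "right" else w
    raise ConfigurationError(f"no weight configured for channel {key}")


def _carrier(n: int, rate: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Band-limited zero-mean Gaussian carrier, normalized to unit RMS."""
    white = rng.standard_normal(n)
    lo, hi = band
    if hi < rate / 2:  # skip filtering when the band is not representable
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=rate, output="sos")
        white = sps.sosfiltfilt(sos, white)
    r = np.sqrt(np.mean(np.square(white)))
    return white / r if r > 0 else white


def generate_emg_trial(
    motion: MotionTrial,
    profile: SubjectProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> EMGTrial:
    """Eight-channel sEMG aligned to a motion trial.

    Per channel: ``signal = gain · weight · side_factor · speed(t) · carrier(t)
    + noise``, where speed is the same-side hand's instantaneous linear speed
    resampled to the EMG rate.  Group A weights peak at the latissimus dorsi
    bilaterally; group B at the left triceps and right biceps.
    """
    duration = motion.duration
    n = int(round(duration * config.emg_rate))
    times = np.arange(n) / config.emg_rate
    weights = config.muscle_weights[profile.group]

    envelopes = {}
    for side in SIDES:
        speed = kin.linear_speed(motion.hand(side))
        envelopes[side] = np.interp(times, speed.timestamps, speed.speed)

    channels: dict[str, np.ndarray] = {}
    for side in SIDES:
        for muscle in MUSCLES:
            w = resolve_muscle_weight(weights, side, muscle, config.side_asymmetry)
            carrier = _carrier(n, config.emg_rate, config.emg_carrier_band, rng)
            sig = config.emg_gain_mv * w * envelopes[side] * carrier
            if config.emg_noise_sd > 0:
                sig = sig + rng.normal(0.0, config.emg_noise_sd, size=n)
            channels[f"{side}_{muscle}"] = sig
    return EMGTrial(
        subject=profile,
        combo_id=motion.combo_id,
        sample_rate=config.emg_rate,
        channels=channels,
    )


def generate_mvic(
    profile: SubjectProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> emg_mod.MVICReference:
    """Per-channel MVIC reference from a synthesized constant-effort burst.

    The constant envelope ``gain · mvic_drive`` exceeds any task envelope
    (task drives are speed × weight × asymmetry, all below ``mvic_drive``), so
    standardized task values stay bounded.  The stored reference is the best
    1-s sliding-window RMS of the burst.
    """
    n = int(round(config.mvic_duration_s * config.emg_rate))
    level = config.emg_gain_mv * config.mvic_drive
    ref_rms: dict[str, float] = {}
    ref_mabs: dict[str, float] = {}
    for name in CHANNELS:
        carrier = _carrier(n, config.emg_rate, config.emg_carrier_band, rng)
        sig = level * carrier
        if config.emg_noise_sd > 0:
            sig = sig + rng.normal(0.0, config.emg_noise_sd, size=n)
        r, m = emg_mod.mvic_reference(sig, config.emg_rate, window_s=1.0)
        ref_rms[name] = r
        ref_mabs[name] = m
    return emg_mod.MVICReference(reference_rms=ref_rms, reference_mean_abs=ref_mabs)


# ---------------------------------------------------------------------------
# cohort


def _draw_height(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd²) truncated to positive values (rejection sampling)."""
    while True:
        h = rng.normal(mean, sd)
        if h > 0:
            return float(h)


def generate_cohort(config: CohortConfig, include_emg: bool = True) -> CohortBundle:
    """Full synthetic study: profiles, both combinations, EMG and MVIC.

    Reproducible bit-for-bit from ``config.seed``; per-trial random streams are
    spawned from a single seed sequence so that skipping EMG generation
    (``include_emg=False``) leaves the motion data unchanged.
    """
    root = np.random.SeedSequence(config.seed)
    n = config.n_subjects
    children = root.spawn(5 * n + 1)
    base_rng = np.random.default_rng(children[-1])

    profiles = []
    for i in range(n):
        group = "A" if i < config.n_group_a else "B"
        index = i + 1 if group == "A" else i + 1 - config.n_group_a
        profiles.append(
            SubjectProfile(
                subject_id=f"{group}{index:02d}",
                group=group,
                height=_draw_height(base_rng, config.height_mean_m, config.height_sd_m),
                handedness=(
                    "right"
                    if base_rng.random() < config.right_handed_fraction
                    else "left"
                ),
            )
        )

    scripts = {
        c: build_combination_script(c, config.geometry, config.tempo) for c in (1, 2)
    }
    motion: dict[tuple[str, int], MotionTrial] = {}
    emg_trials: dict[tuple[str, int], EMGTrial] = {}
    mvic: dict[str, emg_mod.MVICReference] = {}
    for i, profile in enumerate(profiles):
        mvic[profile.subject_id] = generate_mvic(
            profile, config, np.random.default_rng(children[5 * i])
        )
        for j, combo in enumerate((1, 2)):
            trial = generate_motion_trial(
                profile,
                scripts[combo],
                config,
                np.random.default_rng(children[5 * i + 1 + 2 * j]),
            )
            motion[(profile.subject_id, combo)] = trial
            if include_emg:
                emg_trials[(profile.subject_id, combo)] = generate_emg_trial(
                    trial,
                    profile,
                    config,
                    np.random.default_rng(children[5 * i + 2 + 2 * j]),
                )
    return CohortBundle(
        config=config,
        profiles=tuple(profiles),
        scripts=scripts,
        motion=motion,
        emg=emg_trials,
        mvic=mvic,
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of a config with a different seed (convenience for seeded sweeps)."""
    return replace(config, seed=seed)
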