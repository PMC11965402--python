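"""Forward-kinematic generator of seated lower-limb exercise sequences.

The generator emulates the landmark streams a pose estimator would emit for
a seated subject performing hip flexion, hip external rotation or knee
extension, with fully known ground truth: the commanded knee-angle
trajectory, the frame window of every repetition and the commanded range of
motion.  It exists so the angle-extraction, grading, counting and
classification layers can be tested end-to-end without clinical video.

The body is a 2-D planar linkage (trunk, thigh, shank, foot) in normalized
image coordinates with the hip anchored; the hip-knee-ankle angle of the
exercising side follows a smooth per-repetition profile between a start
angle (leg at rest, near 180 deg) and an end angle (deepest excursion),
with dwells at both extremes.  Noise is modelled as Gaussian jitter on the
commanded angle, Gaussian jitter on every landmark coordinate, and random
per-frame visibility dropout of the exercising leg's landmarks — a
deliberately simple stand-in for pose-estimator error.  All randomness is
driven by an explicit seed; identical configuration and seed give
bit-identical output.

Landmarks not involved in the leg model (face, arms, the resting leg) are
emitted at plausible static positions with visibility 1 so that generated
files are schema-complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .knn import PoseDataset, PoseSample, embed_pose
from .pose_io import (
    LANDMARK_INDEX,
    N_LANDMARKS,
    Landmark3D,
    LandmarkFrame,
    LandmarkSequence,
)

_EXERCISES = ("hip_flexion", "hip_external_rotation", "knee_extension")


@dataclass(frozen=True)
class MotionProfile:
    """Commanded knee-angle trajectory for one session.

    ``theta_end`` may be a single value or one value per repetition (used to
    jitter the per-rep range of motion).  Each repetition lasts
    ``rep_period`` seconds: move to the end angle, dwell, move back, dwell.
    """

    exercise: str
    reps: int = 10
    theta_start: float = 170.0
    theta_end: float | tuple[float, ...] = 10.0
    rep_period: float = 4.0
    dwell: float = 0.5
    waveform: str = "smoothstep"

    def __post_init__(self) -> None:
        if self.exercise not in _EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if self.reps < 0:
            raise ValueError("reps must be >= 0")
        ends = self.ends_per_rep()
        if any(e == self.theta_start for e in ends):
            raise ValueError("theta_end must differ from theta_start")
        if self.reps and len(ends) != self.reps:
            raise ValueError("theta_end must be scalar or one value per repetition")
        if self.rep_period <= 2 * self.dwell:
            raise ValueError("rep_period must exceed twice the dwell time")
        if self.waveform not in ("smoothstep", "sinusoid"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        for th in (self.theta_start, *ends):
            if not 0.0 < th < 180.0:
                raise ValueError(f"profile angles must lie strictly inside (0, 180): {th}")

    def ends_per_rep(self) -> tuple[float, ...]:
        if isinstance(self.theta_end, (int, float)):
            return tuple([float(self.theta_end)] * max(self.reps, 1))
        return tuple(float(e) for e in self.theta_end)


@dataclass(frozen=True)
class BodyModel:
    """Planar segment lengths (normalized image units) and hip anchor."""

    trunk: float = 0.28
    thigh: float = 0.20
    shank: float = 0.20
    foot: float = 0.06
    hip_anchor: tuple[float, float] = (0.42, 0.55)
    side: str = "left"

    def __post_init__(self) -> None:
        for name in ("trunk", "thigh", "shank", "foot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be left|right")
        hx, hy = self.hip_anchor
        # horizontal reach: extended leg; vertical reach: shank+foot hanging
        # below the horizontal thigh, and head ~1.5 trunks above the hip
        reach_x = self.thigh + self.shank + self.foot
        reach_down = self.shank + self.foot
        if not (
            0.0 < hx - 0.15
            and hx + reach_x < 1.0
            and 0.0 < hy - 1.5 * self.trunk
            and hy + reach_down < 1.0
        ):
            raise ValueError("body segments would leave the unit image frame")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian landmark/angle jitter and visibility dropout, seeded."""

    coord_sd: float = 0.0
    angle_jitter_sd: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coord_sd < 0 or self.angle_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually commanded, for oracle-style testing."""

    exercise: str
    rep_count: int
    rep_windows: tuple[tuple[int, int], ...]  # (first_frame, last_frame) per rep
    rom_per_rep: tuple[float, ...]
    theta: np.ndarray  # commanded (pre-noise) angle per frame, degrees
    fps: float

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise,
            "rep_count": self.rep_count,
            "rep_windows": [list(w) for w in self.rep_windows],
            "rom_per_rep_deg": list(self.rom_per_rep),
            "fps": self.fps,
        }


def _ease(u: np.ndarray, waveform: str) -> np.ndarray:
    if waveform == "smoothstep":
        return u * u * (3.0 - 2.0 * u)
    return 0.5 * (1.0 - np.cos(np.pi * u))  # sinusoid


def _theta_profile(
    profile: MotionProfile, fps: float
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Commanded angle per frame plus the frame window of each repetition."""
    n_dwell = max(int(round(profile.dwell * fps)), 1)
    n_move = int(round((profile.rep_period - 2 * profile.dwell) / 2 * fps))
    if n_move < 1:
        raise ValueError("rep_period too short for this fps")
    lead = np.full(n_dwell, profile.theta_start)
    if profile.reps == 0:
        return lead, ()
    u = _ease(np.linspace(0.0, 1.0, n_move, endpoint=False), profile.waveform)
    pieces = [lead]
    windows = []
    pos = n_dwell
    for end in profile.ends_per_rep():
        down = profile.theta_start + (end - profile.theta_start) * u
        bottom = np.full(n_dwell, end)
        up = end + (profile.theta_start - end) * u
        top = np.full(n_dwell, profile.theta_start)
        rep = np.concatenate([down, bottom, up, top])
        pieces.append(rep)
        windows.append((pos, pos + len(rep) - 1))
        pos += len(rep)
    return np.concatenate(pieces), tuple(windows)


# static landmark positions (relative to the hip anchor, y down) for the
# parts of the body the planar leg model does not articulate
def _static_layout(body: BodyModel) -> dict[int, tuple[float, float]]:
    hx, hy = body.hip_anchor
    sy = hy - body.trunk          # shoulder line
    head_y = sy - 0.45 * body.trunk
    pos: dict[str, tuple[float, float]] = {
        "nose": (hx, head_y),
        "left_eye_inner": (hx + 0.01, head_y - 0.01),
        "left_eye": (hx + 0.02, head_y - 0.01),
        "left_eye_outer": (hx + 0.03, head_y - 0.01),
        "right_eye_inner": (hx - 0.01, head_y - 0.01),
        "right_eye": (hx - 0.02, head_y - 0.01),
        "right_eye_outer": (hx - 0.03, head_y - 0.01),
        "left_ear": (hx + 0.04, head_y),
        "right_ear": (hx - 0.04, head_y),
        "mouth_left": (hx + 0.015, head_y + 0.02),
        "mouth_right": (hx - 0.015, head_y + 0.02),
        "left_shoulder": (hx + 0.05, sy),
        "right_shoulder": (hx - 0.05, sy),
        "left_elbow": (hx + 0.09, sy + 0.12),
        "right_elbow": (hx - 0.09, sy + 0.12),
        "left_wrist": (hx + 0.10, sy + 0.24),
        "right_wrist": (hx - 0.10, sy + 0.24),
        "left_pinky": (hx + 0.11, sy + 0.27),
        "right_pinky": (hx - 0.11, sy + 0.27),
        "left_index": (hx + 0.115, sy + 0.27),
        "right_index": (hx - 0.115, sy + 0.27),
        "left_thumb": (hx + 0.105, sy + 0.265),
        "right_thumb": (hx - 0.105, sy + 0.265),
        "left_hip": (hx + 0.03, hy),
        "right_hip": (hx - 0.03, hy),
    }
    return {LANDMARK_INDEX[name]: xy for name, xy in pos.items()}


def _leg_points(
    hip: tuple[float, float], theta_deg: float, body: BodyModel
) -> dict[str, tuple[float, float]]:
    """Planar leg at a given hip-knee-ankle angle (thigh held horizontal)."""
    hx, hy = hip
    kx, ky = hx + body.thigh, hy  # knee: thigh points toward +x (seated)
    th = math.radians(theta_deg)
    # knee->hip is -x; knee->ankle at the commanded interior angle, ankle
    # below the knee for theta < 180 (y grows downward)
    ax = kx + body.shank * (-math.cos(th))
    ay = ky + body.shank * math.sin(th)
    # heel just past the ankle along the shank, foot tip perpendicular to it
    heel = (ax - 0.4 * body.foot * math.cos(th), ay + 0.4 * body.foot * math.sin(th))
    tip = (ax + body.foot * math.sin(th), ay + body.foot * math.cos(th))
    return {"knee": (kx, ky), "ankle": (ax, ay), "heel": heel, "foot_index": tip}


def _session_frames(
    theta: np.ndarray, body: BodyModel, noise: NoiseModel, fps: float
) -> list[LandmarkFrame]:
    rng = np.random.default_rng(noise.seed)
    n = len(theta)
    side, other = (body.side, "right" if body.side == "left" else "left")
    static = _static_layout(body)
    hip_active = static[LANDMARK_INDEX[f"{side}_hip"]]
    hip_rest = static[LANDMARK_INDEX[f"{other}_hip"]]
    rest_leg = _leg_points(hip_rest, 90.0, body)  # resting leg stays seated

    theta_noisy = theta + rng.normal(0.0, noise.angle_jitter_sd, size=n) \
        if noise.angle_jitter_sd > 0 else theta
    coord_noise = rng.normal(0.0, noise.coord_sd, size=(n, N_LANDMARKS, 2)) \
        if noise.coord_sd > 0 else None
    dropped = rng.random(n) < noise.dropout_prob if noise.dropout_prob > 0 else None

    leg_names = ("knee", "ankle", "heel", "foot_index")
    active_idx = [LANDMARK_INDEX[f"{side}_{nm}"] for nm in leg_names]
    active_idx.append(LANDMARK_INDEX[f"{side}_hip"])

    frames: list[LandmarkFrame] = []
    for i in range(n):
        xy = np.empty((N_LANDMARKS, 2))
        for idx, p in static.items():
            xy[idx] = p
        for nm, p in rest_leg.items():
            xy[LANDMARK_INDEX[f"{other}_{nm}"]] = p
        active = _leg_points(hip_active, float(np.clip(theta_noisy[i], 0.5, 179.5)), body)
        for nm, p in active.items():
            xy[LANDMARK_INDEX[f"{side}_{nm}"]] = p
        if coord_noise is not None:
            xy = xy + coord_noise[i]
        vis = np.ones(N_LANDMARKS)
        if dropped is not None and dropped[i]:
            vis[active_idx] = 0.3
        frames.append(
            LandmarkFrame(
                i,
                i / fps,
                tuple(
                    Landmark3D(float(xy[j, 0]), float(xy[j, 1]), 0.0, float(vis[j]))
                    for j in range(N_LANDMARKS)
                ),
            )
        )
    return frames


def default_profile(exercise: str, reps: int = 10) -> MotionProfile:
    """Default motion profile per exercise, spanning its trajectory condition."""
    presets = {
        "hip_flexion": (170.0, 10.0),           # condition: > 160 then < 15
        "hip_external_rotation": (170.0, 20.0),  # condition: > 150 then < 30
        "knee_extension": (85.0, 170.0),         # condition: < 95 then > 160
    }
    if exercise not in presets:
        raise ValueError(f"unknown exercise {exercise!r}")
    start, end = presets[exercise]
    return MotionProfile(exercise=exercise, reps=reps, theta_start=start, theta_end=end)


def generate_session(
    profile: MotionProfile,
    body: BodyModel | None = None,
    noise: NoiseModel | None = None,
    fps: float = 30.0,
) -> tuple[LandmarkSequence, GroundTruth]:
    """Generate one exercise session plus its ground truth."""
    body = body or BodyModel()
    noise = noise or NoiseModel()
    theta, windows = _theta_profile(profile, fps)
    frames = _session_frames(theta, body, noise, fps)
    ends = profile.ends_per_rep()
    seq = LandmarkSequence(
        frames,
        fps=fps,
        metadata={"exercise": profile.exercise, "side": body.side, "synthetic": True},
    )
    truth = GroundTruth(
        exercise=profile.exercise,
        rep_count=profile.reps,
        rep_windows=windows,
        rom_per_rep=tuple(abs(profile.theta_start - e) for e in ends[: profile.reps]),
        theta=theta,
        fps=fps,
    )
    return seq, truth


@dataclass(frozen=True)
class CohortSession:
    subject: int
    leg: str
    sequence: LandmarkSequence
    truth: GroundTruth


def generate_cohort(
    n_subjects: int = 30,
    legs_per_subject: int = 2,
    reps_per_leg: int = 10,
    rom_mean: float = 160.0,
    rom_between_sd: float = 0.0,
    rom_within_sd: float = 0.0,
    exercise: str = "hip_flexion",
    theta_start: float = 170.0,
    noise: NoiseModel | None = None,
    fps: float = 30.0,
    seed: int = 0,
) -> list[CohortSession]:
    """Generate a cohort of sessions with a two-level ROM distribution.

    Each subject draws a ROM from N(rom_mean, rom_between_sd^2); each
    repetition jitters it by N(0, rom_within_sd^2).  End angles are clipped
    to stay inside (0, 180).  Every session is seeded deterministically from
    the master seed.
    """
    if n_subjects < 1 or legs_per_subject < 1 or reps_per_leg < 1:
        raise ValueError("cohort dimensions must be >= 1")
    master = np.random.default_rng(seed)
    base_noise = noise or NoiseModel()
    sessions: list[CohortSession] = []
    for subj in range(n_subjects):
        rom_subj = rom_mean + master.normal(0.0, rom_between_sd) if rom_between_sd > 0 \
            else rom_mean
        for leg_i in range(legs_per_subject):
            leg = ("left", "right")[leg_i % 2]
            rom_reps = rom_subj + (
                master.normal(0.0, rom_within_sd, size=reps_per_leg)
                if rom_within_sd > 0
                else np.zeros(reps_per_leg)
            )
            ends = tuple(
                float(np.clip(theta_start - r, 1.0, 179.0)) if theta_start > 90
                else float(np.clip(theta_start + r, 1.0, 179.0))
                for r in rom_reps
            )
            profile = replace(
                default_profile(exercise, reps=reps_per_leg),
                theta_start=theta_start,
                theta_end=ends,
            )
            session_seed = int(master.integers(0, 2**31 - 1))
            seq, truth = generate_session(
                profile,
                body=BodyModel(side=leg),
                noise=replace(base_noise, seed=session_seed),
                fps=fps,
            )
            seq.metadata["subject"] = subj
            sessions.append(CohortSession(subject=subj, leg=leg, sequence=seq, truth=truth))
    return sessions


def generate_pose_dataset(
    exercise: str = "hip_flexion",
    n_per_class: int = 100,
    cluster_separation: float = 160.0,
    noise_sd: float = 2.0,
    coord_sd: float = 0.003,
    seed: int = 0,
    test_fraction: float = 0.3,
    k: int = 10,
    side: str = "left",
) -> tuple[PoseDataset, list[PoseSample]]:
    """Sample labelled terminal-state frames at the two profile extremes.

    The "down" class sits at the resting angle (170 deg for the hip
    exercises); the "up" class at ``170 - cluster_separation`` degrees
    (reversed for knee extension, which starts low).  ``noise_sd`` jitters
    the angle of every sample, ``coord_sd`` every landmark coordinate.
    Returns a training dataset and a held-out test list.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    body = BodyModel(side=side)
    base = default_profile(exercise)
    down_angle = base.theta_start
    sign = -1.0 if base.theta_start > base.ends_per_rep()[0] else 1.0
    up_angle = float(np.clip(down_angle + sign * cluster_separation, 1.0, 179.0))

    samples: list[PoseSample] = []
    for label, center in ((f"{exercise}_down", down_angle), (f"{exercise}_up", up_angle)):
        for _ in range(n_per_class):
            th = float(np.clip(center + rng.normal(0.0, noise_sd), 0.5, 179.5)) \
                if noise_sd > 0 else center
            frame = _session_frames(
                np.array([th]), body,
                NoiseModel(coord_sd=coord_sd, seed=int(rng.integers(0, 2**31 - 1))),
                fps=30.0,
            )[0]
            samples.append(PoseSample(embed_pose(frame), label))
    perm = rng.permutation(len(samples))
    n_test = int(round(test_fraction * len(samples)))
    test = [samples[i] for i in perm[:n_test]]
    train = [samples[i] for i in perm[n_test:]]
    if len(train) < k:
        raise ValueError("not enough training samples for the requested k")
    return PoseDataset(train, k=k), test
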