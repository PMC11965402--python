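"""Fuzzy rule-based exercise grading, repetition counting and ROM reporting.

The instantaneous joint angle is mapped into one of five ordered status
bands — ST (starting position), LOW, OKAY, GOOD, PERFECT — by exercise-specific
threshold rules.  Bands are half-open intervals ``(lower, upper]`` ("less
than or equal" on each upper edge), with the best band closed at the
extreme, so every angle in [0, 180] maps to exactly one band.

Repetitions are counted with hysteresis: a repetition is recorded each time
the angle leaves the start region (e.g. > 160 deg for hip flexion), reaches
the target region (e.g. < 15 deg) and returns to the start region.  Region
entries must persist for ``min_rep_frames`` consecutive frames (debounce),
which makes the counter robust to frame-level jitter near a threshold.

The three built-in exercises are the seated lower-limb movements used in
post-stroke rehabilitation — hip flexion, hip external rotation and knee
extension — each graded on the hip-knee-ankle angle of the exercising side.
The status rules follow the biofeedback convention of starting near 180
degrees (leg at rest) rather than re-zeroing at a neutral position.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .kinematics import AngleTrace, JointTriple, angle_trace
from .pose_io import DEFAULT_VISIBILITY_THRESHOLD, LandmarkSequence, filter_visibility


class StatusBand(enum.IntEnum):
    """Five ordered movement-quality bands, worst (ST) to best (PERFECT)."""

    ST = 0
    LOW = 1
    OKAY = 2
    GOOD = 3
    PERFECT = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


EXERCISES = ("hip_flexion", "hip_external_rotation", "knee_extension")

# Hip-knee-ankle triples (vertex = knee) per exercising side.
_LEG_TRIPLES = {
    "left": JointTriple(start=23, vertex=25, end=27),   # left hip/knee/ankle
    "right": JointTriple(start=24, vertex=26, end=28),  # right hip/knee/ankle
}


@dataclass(frozen=True)
class ExerciseSpec:
    """Thresholds and joint triple for one exercise on one side.

    ``bands`` is an ordered tuple of ``(upper_edge_deg, band)`` pairs with
    strictly increasing edges ending at 180; an angle maps to the first band
    whose upper edge it does not exceed, which realises the half-open
    ``(lower, upper]`` convention.

    ``rep_start_threshold`` / ``rep_target_threshold`` define the hysteresis
    regions for repetition counting and are deliberately separate from the
    status-band edges: a movement may be graded PERFECT without the counting
    condition being configured identically.
    """

    name: str
    side: str
    triple: JointTriple
    bands: tuple[tuple[float, StatusBand], ...]
    direction: str  # "decreasing" | "increasing" (which way theta moves toward PERFECT)
    rep_start_threshold: float
    rep_target_threshold: float
    min_rep_frames: int = 3

    def __post_init__(self) -> None:
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError(f"direction must be decreasing|increasing, got {self.direction!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left|right, got {self.side!r}")
        edges = [e for e, _ in self.bands]
        if not edges or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        if edges[-1] != 180.0:
            raise ValueError("the last band edge must be 180 so the bands tile [0, 180]")
        for thr in (self.rep_start_threshold, self.rep_target_threshold):
            if not 0.0 <= thr <= 180.0:
                raise ValueError(f"repetition threshold outside [0, 180]: {thr}")
        if self.direction == "decreasing":
            if not self.rep_start_threshold > self.rep_target_threshold:
                raise ValueError("decreasing exercise needs start threshold > target threshold")
        elif not self.rep_start_threshold < self.rep_target_threshold:
            raise ValueError("increasing exercise needs start threshold < target threshold")
        if self.min_rep_frames < 1:
            raise ValueError("min_rep_frames must be >= 1")

    # region membership for repetition hysteresis (strict inequalities:
    # "greater than 160 and smaller than 15")
    def in_start_region(self, theta: float) -> bool:
        if self.direction == "decreasing":
            return theta > self.rep_start_threshold
        return theta < self.rep_start_threshold

    def in_target_region(self, theta: float) -> bool:
        if self.direction == "decreasing":
            return theta < self.rep_target_threshold
        return theta > self.rep_target_threshold


# Status-band edges.  Hip flexion and hip external rotation follow the
# five-step rules (ST above 130, then LOW/OKAY/GOOD down to PERFECT at the
# deepest flexion); they differ only in the GOOD/PERFECT edge (15 vs 30).
# Knee extension improves with *increasing* angle; its five bands mirror the
# same progression over its two trajectory thresholds (95 and 160) and are a
# package-defined default, overridable per spec.
_BAND_TABLE: dict[str, tuple[tuple[float, StatusBand], ...]] = {
    "hip_flexion": (
        (15.0, StatusBand.PERFECT),
        (60.0, StatusBand.GOOD),
        (100.0, StatusBand.OKAY),
        (130.0, StatusBand.LOW),
        (180.0, StatusBand.ST),
    ),
    "hip_external_rotation": (
        (30.0, StatusBand.PERFECT),
        (60.0, StatusBand.GOOD),
        (100.0, StatusBand.OKAY),
        (130.0, StatusBand.LOW),
        (180.0, StatusBand.ST),
    ),
    "knee_extension": (
        (95.0, StatusBand.ST),
        (115.0, StatusBand.LOW),
        (140.0, StatusBand.OKAY),
        (160.0, StatusBand.GOOD),
        (180.0, StatusBand.PERFECT),
    ),
}

# Trajectory-condition thresholds for repetition counting.
_REP_THRESHOLDS = {
    "hip_flexion": ("decreasing", 160.0, 15.0),
    "hip_external_rotation": ("decreasing", 150.0, 30.0),
    "knee_extension": ("increasing", 95.0, 160.0),
}


def default_spec(name: str, side: str = "left", min_rep_frames: int = 3) -> ExerciseSpec:
    """Built-in :class:`ExerciseSpec` for one of the three seated exercises."""
    if name not in EXERCISES:
        raise ValueError(f"unknown exercise {name!r}; expected one of {EXERCISES}")
    direction, start_thr, target_thr = _REP_THRESHOLDS[name]
    return ExerciseSpec(
        name=name,
        side=side,
        triple=_LEG_TRIPLES[side],
        bands=_BAND_TABLE[name],
        direction=direction,
        rep_start_threshold=start_thr,
        rep_target_threshold=target_thr,
        min_rep_frames=min_rep_frames,
    )


def classify_status(theta: float, spec: ExerciseSpec) -> StatusBand:
    """Map an angle (degrees, [0, 180]) to its status band."""
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta outside [0, 180]: {theta}")
    for upper, band in spec.bands:
        if theta <= upper:
            return band
    raise AssertionError("bands do not tile [0, 180]")  # unreachable by construction


@dataclass(frozen=True)
class Repetition:
    """One counted repetition and the angular excursion it covered."""

    index: int  # 1-based
    start_frame: int
    end_frame: int
    theta_min: float
    theta_max: float
    best_band: StatusBand

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("repetition must span at least two frames")
        if self.theta_max < self.theta_min:
            raise ValueError("theta_max must be >= theta_min")

    @property
    def rom(self) -> float:
        """Range of motion: max minus min angle over the repetition window."""
        return self.theta_max - self.theta_min


def count_repetitions(trace: AngleTrace, spec: ExerciseSpec) -> list[Repetition]:
    """Hysteresis repetition counter over an angle trace.

    A repetition = debounced occupancy of the start region, an excursion that
    reaches the target region (debounced), and a debounced return to the
    start region.  Each repetition's window runs from the end of the
    previous repetition (or the first confirmed start-region frame) to the
    frame of re-entry, so it covers the full excursion including the dwell
    at the resting extreme; windows are disjoint and ordered.  NaN
    (degenerate) frames break debounce runs but are otherwise skipped.
    """
    theta = trace.theta
    frames = trace.frame_index
    n = len(theta)
    reps: list[Repetition] = []
    if n == 0:
        return reps

    need = spec.min_rep_frames
    start_run = target_run = 0
    state = "seeking_start"  # -> "in_start" -> "excursion" -> back to "in_start"
    window_start = 0
    target_reached = False
    ever_started = False

    for i in range(n):
        th = theta[i]
        if np.isnan(th):
            start_run = target_run = 0
            continue
        in_start = spec.in_start_region(th)
        in_target = spec.in_target_region(th)
        start_run = start_run + 1 if in_start else 0
        target_run = target_run + 1 if in_target else 0

        if state == "seeking_start":
            if start_run >= need:
                state = "in_start"
                ever_started = True
                window_start = i - start_run + 1
        elif state == "in_start":
            if not in_start:
                state = "excursion"
                target_reached = False
        else:  # excursion
            if target_run >= need:
                target_reached = True
            if start_run >= need:
                entry_pos = i - start_run + 1
                if target_reached:
                    window = theta[window_start : entry_pos + 1]
                    window = window[~np.isnan(window)]
                    tmin, tmax = float(window.min()), float(window.max())
                    extreme = tmin if spec.direction == "decreasing" else tmax
                    reps.append(
                        Repetition(
                            index=len(reps) + 1,
                            start_frame=int(frames[window_start]),
                            end_frame=int(frames[entry_pos]),
                            theta_min=tmin,
                            theta_max=tmax,
                            best_band=classify_status(extreme, spec),
                        )
                    )
                    window_start = entry_pos + 1
                state = "in_start"

    if not ever_started:
        warnings.warn("angle trace never enters the start region; 0 repetitions",
                      stacklevel=2)
    return reps


def extract_rom(rep: Repetition, trace: AngleTrace) -> float:
    """Range of motion (degrees) of one repetition, recomputed from the trace."""
    sel = (trace.frame_index >= rep.start_frame) & (trace.frame_index <= rep.end_frame)
    window = trace.theta[sel]
    window = window[~np.isnan(window)]
    if window.size == 0:
        raise ValueError("repetition window contains no valid frames")
    return float(window.max() - window.min())


@dataclass
class SessionReport:
    """End-to-end result of grading one exercise session."""

    exercise: str
    side: str
    trace: AngleTrace
    bands: list[StatusBand | None]
    repetitions: list[Repetition]
    summary: dict = field(default_factory=dict)

    @property
    def rep_count(self) -> int:
        return len(self.repetitions)

    @property
    def rom_series(self) -> list[float]:
        return [r.rom for r in self.repetitions]

    def frames_dataframe(self) -> pd.DataFrame:
        df = self.trace.to_frame()
        df["band"] = [b.name if b is not None else "" for b in self.bands]
        return df

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise,
            "side": self.side,
            "rep_count": self.rep_count,
            "rom_series_deg": self.rom_series,
            "repetitions": [
                {
                    "index": r.index,
                    "start_frame": r.start_frame,
                    "end_frame": r.end_frame,
                    "theta_min_deg": r.theta_min,
                    "theta_max_deg": r.theta_max,
                    "rom_deg": r.rom,
                    "best_band": r.best_band.name,
                }
                for r in self.repetitions
            ],
            "summary": self.summary,
        }


def run_session(
    seq: LandmarkSequence,
    spec: ExerciseSpec,
    smooth_window: int = 1,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    visibility_policy: str = "hold_last",
) -> SessionReport:
    """Full pipeline: visibility handling -> angle trace -> bands -> repetitions.

    The per-frame band is exactly ``classify_status`` of the per-frame angle;
    frames with degenerate geometry carry no band.
    """
    if len(seq):
        seq, _mask = filter_visibility(
            seq,
            indices=[spec.triple.start, spec.triple.vertex, spec.triple.end],
            threshold=visibility_threshold,
            policy=visibility_policy,
        )
    trace = angle_trace(seq, spec.triple, smooth_window=smooth_window)
    bands: list[StatusBand | None] = [
        classify_status(float(t), spec) if ok else None
        for t, ok in zip(trace.theta, trace.valid)
    ]
    with warnings.catch_warnings():
        if len(trace) == 0:
            warnings.simplefilter("ignore")
        reps = count_repetitions(trace, spec)
    roms = [r.rom for r in reps]
    summary = _metrics.rom_summary(roms) if roms else {}
    return SessionReport(
        exercise=spec.name,
        side=spec.side,
        trace=trace,
        bands=bands,
        repetitions=reps,
        summary=summary,
    )
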