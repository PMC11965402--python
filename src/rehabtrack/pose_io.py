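"""Data model and file I/O for 33-landmark body-pose streams.

The landmark topology is the fixed 33-point BlazePose scheme (nose ...
right_foot_index) produced by commodity pose estimators.  Coordinates
follow that convention: ``x`` and ``y`` are image-normalized (origin at the
top-left corner, ``y`` increasing downward), ``z`` is a relative,
hip-centred depth (negative toward the camera) and ``visibility`` is the
estimator's per-landmark confidence in ``[0, 1]``.

Two plain-text dialects are supported:

* JSONL — one frame per line:
  ``{"frame": int, "t": float, "landmarks": [{"name", "x", "y", "z", "v"} x 33]}``
* CSV — long format with columns ``frame,t,name,x,y,z,v`` (33 rows per frame).

The module also carries the basic single-camera geometry: a rigid
world-to-camera transform (rotation + translation) and the pinhole
projection onto the image plane.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: The 33-point BlazePose landmark topology, in canonical index order.
LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer",
    "left_ear", "right_ear",
    "mouth_left", "mouth_right",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_pinky", "right_pinky",
    "left_index", "right_index",
    "left_thumb", "right_thumb",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_foot_index", "right_foot_index",
)

N_LANDMARKS = len(LANDMARK_NAMES)  # 33

#: name -> canonical index
LANDMARK_INDEX: dict[str, int] = {n: i for i, n in enumerate(LANDMARK_NAMES)}

#: Default visibility confidence cut below which a landmark is unreliable.
DEFAULT_VISIBILITY_THRESHOLD = 0.9


def landmark_index(key: int | str) -> int:
    """Resolve a landmark given either its canonical index or its name.

    Unknown names and out-of-range indices are rejected rather than passed
    through.
    """
    if isinstance(key, str):
        try:
            return LANDMARK_INDEX[key]
        except KeyError:
            raise KeyError(f"unknown landmark name: {key!r}") from None
    idx = int(key)
    if not 0 <= idx < N_LANDMARKS:
        raise KeyError(f"landmark index out of range 0..{N_LANDMARKS - 1}: {idx}")
    return idx


@dataclass(frozen=True, slots=True)
class Landmark3D:
    """One landmark: normalized image coordinates, relative depth, confidence."""

    x: float
    y: float
    z: float = 0.0
    visibility: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError(f"landmark coordinates must be finite, got {(self.x, self.y, self.z)}")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError(f"visibility must lie in [0, 1], got {self.visibility}")


@dataclass(frozen=True, slots=True)
class LandmarkFrame:
    """All 33 landmarks of a single video frame."""

    frame_index: int
    timestamp: float
    landmarks: tuple[Landmark3D, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be non-negative, got {self.frame_index}")
        if len(self.landmarks) != N_LANDMARKS:
            raise FormatError(
                f"frame {self.frame_index}: expected {N_LANDMARKS} landmarks, "
                f"got {len(self.landmarks)}"
            )
        object.__setattr__(self, "landmarks", tuple(self.landmarks))

    def coords(self, indices: Sequence[int | str], dims: int = 2) -> np.ndarray:
        """Coordinates of the requested landmarks as an ``(len(indices), dims)`` array."""
        idx = [landmark_index(i) for i in indices]
        out = np.empty((len(idx), dims), dtype=float)
        for row, i in enumerate(idx):
            lm = self.landmarks[i]
            out[row, 0] = lm.x
            out[row, 1] = lm.y
            if dims == 3:
                out[row, 2] = lm.z
        return out


@dataclass(slots=True)
class LandmarkSequence:
    """An ordered landmark stream plus capture metadata.

    ``metadata`` carries free-form tags such as ``subject``, ``exercise``
    and ``side``; nothing in the angle pipeline depends on them.
    """

    frames: list[LandmarkFrame]
    fps: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        prev_idx, prev_t = -1, -math.inf
        for f in self.frames:
            if f.frame_index <= prev_idx:
                raise FormatError(
                    f"frame_index must be strictly increasing "
                    f"({prev_idx} then {f.frame_index})"
                )
            if f.timestamp < prev_t:
                raise FormatError(
                    f"timestamps must be non-decreasing at frame {f.frame_index}"
                )
            prev_idx, prev_t = f.frame_index, f.timestamp

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> LandmarkFrame:
        return self.frames[i]

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def coords(self, indices: Sequence[int | str], dims: int = 2) -> np.ndarray:
        """Stacked coordinates, shape ``(n_frames, len(indices), dims)``."""
        idx = [landmark_index(i) for i in indices]
        out = np.empty((len(self.frames), len(idx), dims), dtype=float)
        for r, f in enumerate(self.frames):
            for c, i in enumerate(idx):
                lm = f.landmarks[i]
                out[r, c, 0] = lm.x
                out[r, c, 1] = lm.y
                if dims == 3:
                    out[r, c, 2] = lm.z
        return out

    def visibility(self, indices: Sequence[int | str] | None = None) -> np.ndarray:
        """Visibility confidences, shape ``(n_frames, len(indices))``."""
        idx = (
            list(range(N_LANDMARKS))
            if indices is None
            else [landmark_index(i) for i in indices]
        )
        return np.array(
            [[f.landmarks[i].visibility for i in idx] for f in self.frames], dtype=float
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = {".jsonl": "jsonl", ".json": "jsonl", ".csv": "csv"}.get(path.suffix.lower(), "")
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unsupported landmark file format: {format or path.suffix!r}")
    return fmt


def _frame_from_records(
    frame_index: int, timestamp: float | None, records: list[dict], fps: float
) -> LandmarkFrame:
    by_name: dict[str, Landmark3D] = {}
    for rec in records:
        name = rec["name"]
        if name not in LANDMARK_INDEX:
            raise FormatError(f"frame {frame_index}: unknown landmark name {name!r}")
        if name in by_name:
            raise FormatError(f"frame {frame_index}: duplicate landmark {name!r}")
        by_name[name] = Landmark3D(
            float(rec["x"]), float(rec["y"]), float(rec.get("z", 0.0)),
            float(rec.get("v", 1.0)),
        )
    missing = [n for n in LANDMARK_NAMES if n not in by_name]
    if missing:
        raise FormatError(
            f"frame {frame_index}: missing {len(missing)} landmark(s), "
            f"e.g. {missing[:3]}"
        )
    t = float(timestamp) if timestamp is not None else frame_index / fps
    return LandmarkFrame(frame_index, t, tuple(by_name[n] for n in LANDMARK_NAMES))


def read_landmarks(
    path: str | Path,
    format: str | None = None,
    fps: float = 30.0,
    metadata: dict | None = None,
) -> LandmarkSequence:
    """Read a landmark stream from a JSONL or CSV file.

    ``format`` is inferred from the filename suffix when omitted.
    Timestamps are optional in files; when absent they are synthesized as
    ``frame_index / fps``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    frames: list[LandmarkFrame] = []
    if fmt == "jsonl":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{path}:{line_no}: invalid JSON: {exc}") from exc
                frames.append(
                    _frame_from_records(
                        int(obj["frame"]), obj.get("t"), obj["landmarks"], fps
                    )
                )
    else:
        df = pd.read_csv(path)
        required = {"frame", "name", "x", "y"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: CSV must have columns frame,t,name,x,y,z,v "
                f"(missing {sorted(required - set(df.columns))})"
            )
        for frame_index, grp in df.groupby("frame", sort=True):
            t_col = grp["t"] if "t" in grp.columns else pd.Series(dtype=float)
            t = None
            if len(t_col) and not pd.isna(t_col.iloc[0]):
                t = float(t_col.iloc[0])
            records = [
                {
                    "name": row["name"],
                    "x": row["x"],
                    "y": row["y"],
                    "z": row.get("z", 0.0),
                    "v": row.get("v", 1.0),
                }
                for _, row in grp.iterrows()
            ]
            frames.append(_frame_from_records(int(frame_index), t, records, fps))
    return LandmarkSequence(frames, fps=fps, metadata=dict(metadata or {}))


def write_landmarks(
    seq: LandmarkSequence, path: str | Path, format: str | None = None
) -> None:
    """Write a landmark stream to JSONL or CSV, readable by :func:`read_landmarks`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for f in seq:
                obj = {
                    "frame": f.frame_index,
                    "t": f.timestamp,
                    "landmarks": [
                        {"name": n, "x": lm.x, "y": lm.y, "z": lm.z, "v": lm.visibility}
                        for n, lm in zip(LANDMARK_NAMES, f.landmarks)
                    ],
                }
                fh.write(json.dumps(obj) + "\n")
    else:
        rows = [
            (f.frame_index, f.timestamp, n, lm.x, lm.y, lm.z, lm.visibility)
            for f in seq
            for n, lm in zip(LANDMARK_NAMES, f.landmarks)
        ]
        pd.DataFrame(rows, columns=["frame", "t", "name", "x", "y", "z", "v"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Visibility filtering
# ---------------------------------------------------------------------------

def filter_visibility(
    seq: LandmarkSequence,
    indices: Sequence[int | str] | None = None,
    threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    policy: str = "hold_last",
) -> tuple[LandmarkSequence, np.ndarray]:
    """Handle frames in which any requested landmark falls below the
    visibility confidence cut (strict ``<``).

    Policies:

    * ``drop`` — remove flagged frames from the sequence;
    * ``hold_last`` — replace the affected landmarks with their value from
      the most recent confident frame (leading flagged frames take the
      first confident frame);
    * ``interpolate`` — linear interpolation of the affected landmark
      coordinates between the neighbouring confident frames; falls back to
      ``hold_last`` (with a warning) when fewer than two confident frames
      exist.

    Returns the handled sequence and a boolean mask over the *input*
    frames, ``True`` where a frame was flagged.
    """
    if policy not in ("drop", "hold_last", "interpolate"):
        raise ValueError(f"unknown visibility policy: {policy!r}")
    idx = (
        list(range(N_LANDMARKS))
        if indices is None
        else [landmark_index(i) for i in indices]
    )
    vis = seq.visibility(idx)  # (n, L)
    flagged = (vis < threshold).any(axis=1) if len(seq) else np.zeros(0, dtype=bool)

    if not flagged.any():
        return LandmarkSequence(list(seq.frames), fps=seq.fps, metadata=dict(seq.metadata)), flagged

    if policy == "drop":
        kept = [f for f, bad in zip(seq.frames, flagged) if not bad]
        return LandmarkSequence(kept, fps=seq.fps, metadata=dict(seq.metadata)), flagged

    good_pos = np.flatnonzero(~flagged)
    if policy == "interpolate" and len(good_pos) < 2:
        warnings.warn(
            "interpolate requires at least 2 confident frames; falling back to hold_last",
            stacklevel=2,
        )
        policy = "hold_last"
    if len(good_pos) == 0:
        warnings.warn("no frame passes the visibility threshold; sequence unchanged",
                      stacklevel=2)
        return LandmarkSequence(list(seq.frames), fps=seq.fps, metadata=dict(seq.metadata)), flagged

    def _patched_frame(pos: int) -> LandmarkFrame:
        frame = seq.frames[pos]
        lms = list(frame.landmarks)
        if policy == "hold_last":
            before = good_pos[good_pos < pos]
            src = seq.frames[before[-1] if len(before) else good_pos[0]]
            for i in idx:
                lms[i] = src.landmarks[i]
        else:  # interpolate
            before = good_pos[good_pos < pos]
            after = good_pos[good_pos > pos]
            if not len(before) or not len(after):
                src = seq.frames[before[-1] if len(before) else after[0]]
                for i in idx:
                    lms[i] = src.landmarks[i]
            else:
                lo, hi = seq.frames[before[-1]], seq.frames[after[0]]
                w = (frame.frame_index - lo.frame_index) / (hi.frame_index - lo.frame_index)
                for i in idx:
                    a, b = lo.landmarks[i], hi.landmarks[i]
                    lms[i] = Landmark3D(
                        a.x + w * (b.x - a.x),
                        a.y + w * (b.y - a.y),
                        a.z + w * (b.z - a.z),
                        min(a.visibility, b.visibility),
                    )
        return LandmarkFrame(frame.frame_index, frame.timestamp, tuple(lms))

    frames = [
        _patched_frame(pos) if flagged[pos] else f
        for pos, f in enumerate(seq.frames)
    ]
    return LandmarkSequence(frames, fps=seq.fps, metadata=dict(seq.metadata)), flagged


# ---------------------------------------------------------------------------
# Camera geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraExtrinsics:
    """Rigid transform from a world frame into the camera frame: ``p' = R p + T``."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        T = np.asarray(self.T, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"R must be 3x3, got {R.shape}")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"R is not orthonormal (max |R'R - I| = {err:.3g})")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("R must be a proper rotation (det R = +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float = 0.0
    cy: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")


def transform_point(p: Iterable[float], ext: CameraExtrinsics) -> np.ndarray:
    """Map a 3-vector from the world frame into the camera frame: ``R p + T``."""
    p = np.asarray(p, dtype=float).reshape(3)
    return ext.R @ p + ext.T


def transform_sequence(seq: LandmarkSequence, ext: CameraExtrinsics) -> LandmarkSequence:
    """Apply a rigid transform to every landmark of every frame (visibility kept)."""
    frames = []
    for f in seq:
        lms = tuple(
            Landmark3D(*transform_point((lm.x, lm.y, lm.z), ext), lm.visibility)
            for lm in f.landmarks
        )
        frames.append(LandmarkFrame(f.frame_index, f.timestamp, lms))
    return LandmarkSequence(frames, fps=seq.fps, metadata=dict(seq.metadata))


def project_point(p: Iterable[float], intr: CameraIntrinsics) -> tuple[float, float]:
    """Pinhole projection of a camera-frame point onto the image plane.

    ``u = (x/z) fx + cx``, ``v = (y/z) fy + cy``; the depth must be nonzero.
    """
    x, y, z = np.asarray(p, dtype=float).reshape(3)
    if z == 0:
        raise ValueError("cannot project a point with zero depth (z = 0)")
    return (x / z) * intr.fx + intr.cx, (y / z) * intr.fy + intr.cy
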