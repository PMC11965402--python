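"""Per-frame joint-angle extraction from landmark triples.

A joint angle is defined by three landmarks — a starting point, the joint
vertex (mid-point) and an end point.  Two equivalent formulations are
provided and kept as separate code paths so each can serve as an oracle for
the other:

* the vector rule, theta = arccos(a.b / |a||b|) with a = start - vertex and
  b = end - vertex;
* the law of cosines on the triangle side lengths, cos A = (b^2 + c^2 - a^2) / (2bc),
  where A is the vertex angle.

Angles are reported in degrees in [0, 180].  By default only the image-plane
x, y coordinates participate (``dims=2``); full 3-D angles are available via
``dims=3``.  Cosine arguments are clamped to [-1, 1] within a tolerance of
1e-9 before the arccos; a violation beyond that tolerance is an error rather
than a silent clamp, so distance round-off is absorbed but genuinely
inconsistent side lengths are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .pose_io import LandmarkFrame, LandmarkSequence, landmark_index

#: Tolerance for clamping cosine arguments against floating-point round-off.
COS_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class JointTriple:
    """Three distinct landmarks defining a joint angle at ``vertex``."""

    start: int
    vertex: int
    end: int
    dims: int = 2

    def __post_init__(self) -> None:
        s, v, e = (
            landmark_index(self.start),
            landmark_index(self.vertex),
            landmark_index(self.end),
        )
        if len({s, v, e}) != 3:
            raise ValueError(f"joint triple indices must be distinct, got {(s, v, e)}")
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "vertex", v)
        object.__setattr__(self, "end", e)


@dataclass
class AngleTrace:
    """A per-frame joint-angle series aligned with its source sequence.

    ``theta`` holds degrees in [0, 180]; frames with degenerate geometry
    (coincident landmarks) are NaN and marked ``False`` in ``valid``.
    """

    theta: np.ndarray
    frame_index: np.ndarray
    timestamps: np.ndarray
    method: str = "vector"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.valid is None:
            self.valid = ~np.isnan(self.theta)
        self.valid = np.asarray(self.valid, dtype=bool)
        finite = self.theta[self.valid]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ValueError("angle trace contains values outside [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.theta)

    def to_frame(self) -> pd.DataFrame:
        """Export as a tidy DataFrame (one row per frame)."""
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "t": self.timestamps,
                "theta_deg": self.theta,
                "method": self.method,
                "flag": np.where(self.valid, "", "degenerate"),
            }
        )


def _clamped_arccos_deg(c: float) -> float:
    if c > 1.0 + COS_CLAMP_TOL or c < -1.0 - COS_CLAMP_TOL:
        raise ValueError(f"cosine argument {c} outside [-1, 1] beyond tolerance")
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def vector_angle(a, b) -> float:
    """Angle in degrees between two vectors via the dot-product rule."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("zero-length vector: angle undefined")
    return _clamped_arccos_deg(float(np.dot(a, b)) / (na * nb))


def cosine_rule_angle(b: float, c: float, a: float) -> float:
    """Vertex angle A (degrees) of a triangle from its side lengths.

    ``b`` and ``c`` are the sides adjacent to the vertex, ``a`` the side
    opposite it.  A triangle-inequality violation beyond the clamp tolerance
    is an error.
    """
    if b <= 0.0 or c <= 0.0:
        raise DegenerateGeometryError("adjacent side of zero length: angle undefined")
    return _clamped_arccos_deg((b * b + c * c - a * a) / (2.0 * b * c))


def triple_angle(
    frame: LandmarkFrame, triple: JointTriple, method: str = "vector"
) -> float:
    """Joint angle (degrees) at the triple's vertex in a single frame."""
    pts = frame.coords([triple.start, triple.vertex, triple.end], dims=triple.dims)
    start, vertex, end = pts
    if method == "vector":
        return vector_angle(start - vertex, end - vertex)
    if method == "cosine_rule":
        b = float(np.linalg.norm(start - vertex))
        c = float(np.linalg.norm(end - vertex))
        a = float(np.linalg.norm(end - start))
        return cosine_rule_angle(b, c, a)
    raise ValueError(f"unknown method: {method!r}")


def angle_trace(
    seq: LandmarkSequence,
    triple: JointTriple,
    smooth_window: int = 1,
    method: str = "vector",
) -> AngleTrace:
    """Joint-angle series over a sequence, with optional moving-average smoothing.

    ``smooth_window`` is the width in frames of a centered moving average
    (odd; 1 disables smoothing).  Degenerate frames yield NaN with a flag
    and are excluded from the smoothing average.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    n = len(seq)
    if n == 0:
        return AngleTrace(
            np.empty(0), np.empty(0, dtype=int), np.empty(0), method=method
        )
    pts = seq.coords([triple.start, triple.vertex, triple.end], dims=triple.dims)
    a = pts[:, 0, :] - pts[:, 1, :]
    b = pts[:, 2, :] - pts[:, 1, :]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    valid = (na > 0) & (nb > 0)
    theta = np.full(n, np.nan)
    if method == "vector":
        cosv = np.einsum("ij,ij->i", a[valid], b[valid]) / (na[valid] * nb[valid])
    elif method == "cosine_rule":
        c = np.linalg.norm(pts[:, 2, :] - pts[:, 0, :], axis=1)
        bb, cc, aa = na[valid], nb[valid], c[valid]
        cosv = (bb * bb + cc * cc - aa * aa) / (2.0 * bb * cc)
    else:
        raise ValueError(f"unknown method: {method!r}")
    if cosv.size and (cosv.max() > 1 + COS_CLAMP_TOL or cosv.min() < -1 - COS_CLAMP_TOL):
        raise ValueError("cosine argument outside [-1, 1] beyond tolerance")
    theta[valid] = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    if smooth_window > 1:
        theta = (
            pd.Series(theta)
            .rolling(smooth_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        theta[~valid] = np.nan
    return AngleTrace(theta, seq.frame_indices, seq.timestamps, method=method, valid=valid)
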