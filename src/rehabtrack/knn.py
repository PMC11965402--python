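"""K-nearest-neighbour classification of exercise terminal states.

Each exercise has two terminal states (an "up" and a "down" pose); labelled
landmark frames of those states form the training set.  A frame is reduced
to a pose embedding — the 2-D (or 3-D) coordinates of a fixed landmark
subset, translated so the mid-hip point is the origin and scaled so the
torso (mid-hip to mid-shoulder) has unit length — which makes the feature
vector invariant to where the person stands and how large they appear.

Classification is plain k-NN with Euclidean distance: the class probability
is the vote fraction among the k nearest training samples, so with the
default k = 10 the per-class vote count is directly a 0-10 confidence
scale.  Tie-breaking is deterministic: neighbours are ordered by
(distance, insertion index), and class-vote ties are resolved by smaller
mean neighbour distance, then lexicographic class name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .errors import DegenerateGeometryError
from .pose_io import LandmarkFrame, LandmarkSequence, landmark_index

#: Torso + lower-limb landmarks used for the default embedding:
#: shoulders, hips, knees, ankles, heels, foot tips.
DEFAULT_EMBED_LANDMARKS: tuple[int, ...] = (11, 12, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32)

_LEFT_HIP, _RIGHT_HIP = 23, 24
_LEFT_SHOULDER, _RIGHT_SHOULDER = 11, 12


@dataclass(frozen=True)
class PoseEmbedding:
    """Translation- and scale-normalized flattened landmark coordinates."""

    vector: np.ndarray
    landmark_indices: tuple[int, ...]
    dims: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding contains non-finite values")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class PoseSample:
    embedding: PoseEmbedding
    label: str


@dataclass
class PoseDataset:
    """Labelled terminal-state samples plus the neighbour count ``k``."""

    samples: list[PoseSample]
    k: int = 10
    class_set: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.samples) < self.k:
            raise ValueError(
                f"dataset needs at least k={self.k} samples, got {len(self.samples)}"
            )
        self.class_set = tuple(sorted({s.label for s in self.samples}))

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([s.embedding.vector for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def to_csv(self, path: str | Path) -> None:
        mat = self.matrix
        df = pd.DataFrame(mat, columns=[f"e{i}" for i in range(mat.shape[1])])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, k: int = 10) -> "PoseDataset":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("e")]
        samples = [
            PoseSample(PoseEmbedding(row[cols].to_numpy(dtype=float), (), 2), row["label"])
            for _, row in df.iterrows()
        ]
        return cls(samples, k=k)


def embed_pose(
    frame: LandmarkFrame,
    landmark_subset: Sequence[int | str] = DEFAULT_EMBED_LANDMARKS,
    dims: int = 2,
) -> PoseEmbedding:
    """Normalize a frame into a pose embedding.

    Coordinates are translated so the mid-hip is the origin and scaled so
    the mid-hip to mid-shoulder distance is 1, then flattened in the fixed
    landmark order.  A pose with coincident mid-hip and mid-shoulder has no
    defined scale and raises :class:`DegenerateGeometryError`.
    """
    idx = tuple(landmark_index(i) for i in landmark_subset)
    coords = frame.coords(idx, dims=dims)
    hips = frame.coords([_LEFT_HIP, _RIGHT_HIP], dims=dims)
    shoulders = frame.coords([_LEFT_SHOULDER, _RIGHT_SHOULDER], dims=dims)
    mid_hip = hips.mean(axis=0)
    mid_shoulder = shoulders.mean(axis=0)
    scale = float(np.linalg.norm(mid_shoulder - mid_hip))
    if scale == 0.0:
        raise DegenerateGeometryError("mid-hip equals mid-shoulder: zero torso size")
    return PoseEmbedding(((coords - mid_hip) / scale).ravel(), idx, dims)


def euclidean_distance(x: PoseEmbedding, x2: PoseEmbedding) -> float:
    """Euclidean distance between two embeddings of equal dimension."""
    a, b = x.vector, x2.vector
    if a.shape != b.shape:
        raise ValueError(f"embedding dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass(frozen=True)
class KnnResult:
    votes: dict[str, int]
    probabilities: dict[str, float]
    predicted: str


def knn_classify(query: PoseEmbedding, data: PoseDataset) -> KnnResult:
    """Classify one embedding against the dataset.

    The k nearest samples (ordered by distance, ties by insertion index)
    vote; the probability of class j is votes_j / k.
    """
    mat = data.matrix
    if mat.shape[1] != query.vector.size:
        raise ValueError("query embedding dimension does not match the dataset")
    dists = np.linalg.norm(mat - query.vector, axis=1)
    order = np.lexsort((np.arange(len(dists)), dists))[: data.k]
    labels = data.labels
    votes = {c: 0 for c in data.class_set}
    dist_sum = {c: 0.0 for c in data.class_set}
    for i in order:
        votes[labels[i]] += 1
        dist_sum[labels[i]] += dists[i]
    best = max(votes.values())
    tied = [c for c, v in votes.items() if v == best]
    if len(tied) > 1:
        tied.sort(key=lambda c: (dist_sum[c] / votes[c], c))
    predicted = tied[0]
    probs = {c: v / data.k for c, v in votes.items()}
    return KnnResult(votes=votes, probabilities=probs, predicted=predicted)


@dataclass
class ClassificationTrace:
    """Per-frame vote counts, probabilities and smoothed confidences.

    ``votes`` and ``smoothed`` have shape ``(n_frames, n_classes)``; the
    smoothed confidence stays on the 0..k vote scale.
    """

    classes: tuple[str, ...]
    frame_index: np.ndarray
    votes: np.ndarray
    smoothed: np.ndarray
    predicted: list[str]
    k: int

    def confidence(self, label: str) -> np.ndarray:
        return self.smoothed[:, self.classes.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": self.frame_index, "predicted": self.predicted})
        for j, c in enumerate(self.classes):
            df[f"votes_{c}"] = self.votes[:, j]
            df[f"conf_{c}"] = self.smoothed[:, j]
        return df


def classify_sequence(
    seq: LandmarkSequence,
    data: PoseDataset,
    smoothing_alpha: float = 0.2,
    landmark_subset: Sequence[int | str] = DEFAULT_EMBED_LANDMARKS,
    dims: int = 2,
) -> ClassificationTrace:
    """Per-frame k-NN classification with exponential smoothing of the vote
    counts (``alpha = 1`` reproduces the raw votes)."""
    if not 0.0 < smoothing_alpha <= 1.0:
        raise ValueError("smoothing_alpha must lie in (0, 1]")
    classes = data.class_set
    n = len(seq)
    votes = np.zeros((n, len(classes)), dtype=float)
    predicted: list[str] = []
    for i, frame in enumerate(seq):
        res = knn_classify(embed_pose(frame, landmark_subset, dims), data)
        votes[i] = [res.votes[c] for c in classes]
        predicted.append(res.predicted)
    smoothed = np.empty_like(votes)
    if n:
        smoothed[0] = votes[0]
        for i in range(1, n):
            smoothed[i] = smoothing_alpha * votes[i] + (1 - smoothing_alpha) * smoothed[i - 1]
    return ClassificationTrace(
        classes=classes,
        frame_index=seq.frame_indices,
        votes=votes,
        smoothed=smoothed,
        predicted=predicted,
        k=data.k,
    )


def count_by_classification(
    trace: ClassificationTrace,
    target_class: str,
    enter_threshold: float = 8.0,
    exit_threshold: float = 2.0,
) -> int:
    """Count repetitions as rises of the target-state smoothed confidence.

    One count each time the confidence reaches ``enter_threshold`` after
    having been at or below ``exit_threshold`` (the counter starts armed, so
    a trace that begins confident counts once).
    """
    if not enter_threshold > exit_threshold:
        raise ValueError("enter_threshold must exceed exit_threshold")
    conf = trace.confidence(target_class)
    count, armed = 0, True
    for c in conf:
        if armed and c >= enter_threshold:
            count += 1
            armed = False
        elif not armed and c <= exit_threshold:
            armed = True
    return count


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    per_class: pd.DataFrame  # precision, recall, f1, support per class
    confusion: pd.DataFrame


def evaluate_classifier(data: PoseDataset, test: Sequence[PoseSample]) -> EvaluationResult:
    """Accuracy and per-class precision/recall of the dataset on a test set."""
    if not len(test):
        raise ValueError("empty test set")
    y_true = [s.label for s in test]
    y_pred = [knn_classify(s.embedding, data).predicted for s in test]
    classes = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support}, index=classes
    )
    confusion = pd.crosstab(
        pd.Series(y_true, name="true"), pd.Series(y_pred, name="predicted"),
        dropna=False,
    ).reindex(index=classes, columns=classes, fill_value=0)
    accuracy = float(np.mean(np.array(y_true) == np.array(y_pred)))
    return EvaluationResult(accuracy=accuracy, per_class=per_class, confusion=confusion)
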