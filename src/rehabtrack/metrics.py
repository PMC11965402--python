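"""Evaluation statistics for angle predictions and ROM reliability.

Covers the error metrics used to validate model-predicted joint angles
against manual geometric measurement (MAE, MSE, RMSE, coefficient of
determination) and the descriptive/reliability statistics used for
range-of-motion series (mean/median/SD with a t-based 95% CI, and the
one-way random-effects intraclass correlation coefficient ICC(1,1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError


@dataclass(frozen=True)
class PairedAngles:
    """Predicted vs. actually measured angles, optionally with an error
    column as originally reported (``predicted - actual``)."""

    predicted: np.ndarray
    actual: np.ndarray
    reported_error: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        a = np.asarray(self.actual, dtype=float)
        if p.ndim != 1 or p.shape != a.shape or p.size < 1:
            raise ValueError("predicted and actual must be equal-length 1-D arrays, n >= 1")
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "actual", a)
        if self.reported_error is not None:
            e = np.asarray(self.reported_error, dtype=float)
            if e.shape != p.shape:
                raise ValueError("reported_error must match predicted/actual in length")
            object.__setattr__(self, "reported_error", e)

    def __len__(self) -> int:
        return self.predicted.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedAngles":
        err = df["error_deg"].to_numpy() if "error_deg" in df.columns else None
        return cls(df["predicted_deg"].to_numpy(), df["actual_deg"].to_numpy(), err)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedAngles":
        return cls.from_dataframe(pd.read_csv(path))


def load_worked_example() -> PairedAngles:
    """The bundled worked example of predicted vs. manually measured
    lower-limb angles (nine observations across the three exercises),
    including the error column exactly as originally reported."""
    with resources.files("rehabtrack.data").joinpath("worked_example_angles.csv").open() as fh:
        return PairedAngles.from_dataframe(pd.read_csv(fh))


def error_metrics(p: PairedAngles, use_reported_errors: bool = False) -> dict[str, float]:
    """MAE, MSE and RMSE of the paired angles.

    With ``use_reported_errors`` the stored error column is used verbatim in
    place of ``predicted - actual`` — useful when a published error column
    is the quantity of record even where it disagrees with its own
    predicted/actual columns.  ``rmse`` is always the square root of ``mse``.
    """
    if use_reported_errors:
        if p.reported_error is None:
            raise ValueError("use_reported_errors requires a reported error column")
        err = p.reported_error
    else:
        err = p.predicted - p.actual
    mse = float(np.mean(err**2))
    return {"mae": float(np.mean(np.abs(err))), "mse": mse, "rmse": float(np.sqrt(mse))}


def r_squared(p: PairedAngles) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot.

    1 for a perfect prediction, 0 when the prediction is no better than the
    mean of the observed values; may be negative for a worse-than-mean fit.
    """
    ss_res = float(np.sum((p.actual - p.predicted) ** 2))
    ss_tot = float(np.sum((p.actual - p.actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError(
            "R^2 undefined: observed values have zero total sum of squares"
        )
    return 1.0 - ss_res / ss_tot


def rom_summary(roms: Sequence[float]) -> dict:
    """Sample mean, median, SD (n-1 denominator) and t-based 95% CI of a
    ROM series.  The CI (and SD) require n >= 2 and are NaN otherwise."""
    x = np.asarray(roms, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("rom_summary requires a non-empty 1-D series")
    n = x.size
    mean = float(x.mean())
    out = {
        "n": int(n),
        "mean": mean,
        "median": float(np.median(x)),
        "sd": float(x.std(ddof=1)) if n >= 2 else float("nan"),
    }
    if n >= 2 and np.isfinite(out["sd"]):
        half = stats.t.ppf(0.975, n - 1) * out["sd"] / np.sqrt(n)
        out["ci95"] = (mean - float(half), mean + float(half))
    else:
        out["ci95"] = (float("nan"), float("nan"))
    return out


@dataclass(frozen=True)
class GroupedMeasurements:
    """Repeated measurements with a group (subject) label per value."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.groups)
        if v.ndim != 1 or v.shape != g.shape:
            raise ValueError("values and groups must be equal-length 1-D arrays")
        labels, counts = np.unique(g, return_counts=True)
        if len(labels) < 2:
            raise UndefinedStatisticError("ICC requires at least 2 groups")
        if counts.min() < 2:
            raise UndefinedStatisticError("ICC requires >= 2 values per group")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "groups", g)


def icc(g: GroupedMeasurements) -> float:
    """One-way random-effects intraclass correlation coefficient ICC(1,1).

    Computed from the one-way ANOVA mean squares as
    ``(MSB - MSW) / (MSB + (kbar - 1) MSW)`` with ``kbar`` the mean group
    size; for a balanced random-intercept design this equals the
    between-subject share of total variance.  Invariant to adding a
    constant to every value and to positive rescaling.
    """
    v, labels = g.values, np.unique(g.groups)
    a = len(labels)
    n = v.size
    kbar = n / a
    grand = v.mean()
    ssb = ssw = 0.0
    for lab in labels:
        grp = v[g.groups == lab]
        ssb += grp.size * (grp.mean() - grand) ** 2
        ssw += float(np.sum((grp - grp.mean()) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (n - a)
    denom = msb + (kbar - 1.0) * msw
    if denom == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero variance in every direction")
    return float((msb - msw) / denom)
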