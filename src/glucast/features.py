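"""Feature engineering for glucose forecasting.

Each grid slot of an imputed segment is expanded into nine channels: the
glucose reading itself; two finite differences (one step back and six steps
back, i.e. 5 and 30 minutes); three rolling one-hour statistics (OLS trend
slope, mean, sample SD over the 12 samples ending at the slot, inclusive);
and three calendar channels (day part 1-7, day of week 1-7, hour of day
1-24).  Rolling windows look strictly backward, so no feature at time t
depends on samples after t.

Readings are additionally labeled with the clinical glycemic state:
hypoglycemia below 70 mg/dL, normal 70-180 mg/dL, hyperglycemia above
180 mg/dL.

:class:`FeatureTransform` maps channels to a common scale: strictly positive
channels (glucose, avg) get a natural log, the non-negative but possibly
zero std channel gets log1p, signed channels (diff1, diff6, trend) stay
linear; all six are then z-scored with statistics fitted on training rows
only, and calendar channels are scaled into (0, 1].  The glucose/target
channel transform is exactly invertible, so forecasts come back in mg/dL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GlucoseSeries

#: model input channels, in the fixed order the forecaster expects
CHANNELS = (
    "glucose",
    "diff1",
    "diff6",
    "trend",
    "avg",
    "std",
    "day_part",
    "day_of_week",
    "hour_of_day",
)
CLASSES = ("hypo", "normal", "hyper")

HOUR_WINDOW = 12  # one hour of 5-minute samples, inclusive of the current one

# seven clock-time parts of the day (night, early morning, morning, midday,
# afternoon, evening, late evening); boundaries are configurable
DAY_PART_EDGES = (0, 4, 8, 11, 14, 17, 21, 24)

_CALENDAR_SCALE = {"day_part": 7.0, "day_of_week": 7.0, "hour_of_day": 24.0}


@dataclass
class FeatureMatrix:
    """Per-timestamp feature rows for one segment.

    ``frame`` has the nine channel columns plus ``timestamp``, ``label`` and
    ``valid``; a row is valid iff the full 12-sample history exists inside the
    segment (the first 11 rows are warm-up)."""

    frame: pd.DataFrame
    segment_id: int = 0

    @property
    def n(self) -> int:
        return len(self.frame)

    def channel_array(self) -> np.ndarray:
        return self.frame[list(CHANNELS)].to_numpy(dtype=float)


def glycemic_label(glucose) -> np.ndarray | str:
    """Clinical glycemic state of a reading (or array of readings)."""
    g = np.asarray(glucose, dtype=float)
    if (g <= 0).any():
        raise ValueError("glucose must be positive")
    lab = np.where(g < 70.0, "hypo", np.where(g > 180.0, "hyper", "normal"))
    return lab if lab.ndim else str(lab)


def calendar_features(timestamps: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Day part (1-7), day of week (Monday=1..Sunday=7), hour of day (1-24)."""
    hours = timestamps.hour.to_numpy()
    day_part = np.digitize(hours, DAY_PART_EDGES[1:-1], right=False) + 1
    day_of_week = timestamps.dayofweek.to_numpy() + 1
    hour_of_day = hours + 1
    return day_part, day_of_week, hour_of_day


def _rolling_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trend (OLS slope per step), mean and sample SD over the trailing
    12-sample window, NaN where the window is incomplete."""
    n = len(g)
    trend = np.full(n, np.nan)
    avg = np.full(n, np.nan)
    std = np.full(n, np.nan)
    if n < HOUR_WINDOW:
        return trend, avg, std
    win = np.lib.stride_tricks.sliding_window_view(g, HOUR_WINDOW)
    avg[HOUR_WINDOW - 1 :] = win.mean(axis=1)
    std[HOUR_WINDOW - 1 :] = win.std(axis=1, ddof=1)
    # closed-form OLS slope against x = 0..11
    x = np.arange(HOUR_WINDOW, dtype=float)
    xc = x - x.mean()
    trend[HOUR_WINDOW - 1 :] = (win * xc).sum(axis=1) / (xc**2).sum()
    return trend, avg, std


def derive_features(segment: GlucoseSeries, segment_id: int = 0) -> FeatureMatrix:
    """Compute all nine channels plus labels for one fully valued segment."""
    if not segment.mask.all():
        raise ValueError("derive_features requires a fully valued segment")
    g = segment.values
    n = segment.n
    if n < HOUR_WINDOW:
        warnings.warn(f"segment of length {n} < {HOUR_WINDOW}: all rows invalid")
    diff1 = np.full(n, np.nan)
    diff6 = np.full(n, np.nan)
    diff1[1:] = g[1:] - g[:-1]
    if n > 6:
        diff6[6:] = g[6:] - g[:-6]
    trend, avg, std = _rolling_stats(g)
    ts = segment.timestamps
    day_part, day_of_week, hour_of_day = calendar_features(ts)
    valid = np.zeros(n, dtype=bool)
    valid[HOUR_WINDOW - 1 :] = True
    frame = pd.DataFrame(
        {
            "timestamp": ts,
            "glucose": g,
            "diff1": diff1,
            "diff6": diff6,
            "trend": trend,
            "avg": avg,
            "std": std,
            "day_part": day_part.astype(float),
            "day_of_week": day_of_week.astype(float),
            "hour_of_day": hour_of_day.astype(float),
            "label": glycemic_label(g),
            "valid": valid,
        }
    )
    return FeatureMatrix(frame, segment_id)


_KIND = {
    "glucose": "log",
    "avg": "log",
    "std": "log1p",
    "diff1": "identity",
    "diff6": "identity",
    "trend": "identity",
}


def _forward(kind: str, x: np.ndarray) -> np.ndarray:
    if kind == "log":
        return np.log(x)
    if kind == "log1p":
        return np.log1p(x)
    return x


@dataclass
class FeatureTransform:
    """Invertible channel scaling, fitted once on training rows then frozen.

    Continuous channels are (optionally log-)mapped then z-scored with the
    training mean/SD; calendar channels are divided by their range.  The
    target (glucose) uses the glucose channel's parameters, so
    ``invert_target(transform(g)) == g`` to machine precision."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def fit(self, matrices: list[FeatureMatrix]) -> "FeatureTransform":
        rows = pd.concat([m.frame[m.frame["valid"]] for m in matrices], ignore_index=True)
        if len(rows) == 0:
            raise ValueError("no valid rows to fit the transform on")
        for ch, kind in _KIND.items():
            x = _forward(kind, rows[ch].to_numpy(dtype=float))
            m, s = float(np.mean(x)), float(np.std(x))
            self.mean[ch] = m
            self.sd[ch] = s if s > 0 else 1.0
        self.fitted = True
        return self

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("FeatureTransform used before fitting")

    def apply(self, matrix: FeatureMatrix) -> np.ndarray:
        """Transformed n x 9 channel array in the canonical channel order.

        Never recomputes statistics — test/inference rows are scaled with the
        frozen training parameters."""
        self._require_fitted()
        cols = []
        for ch in CHANNELS:
            x = matrix.frame[ch].to_numpy(dtype=float)
            if ch in _KIND:
                cols.append((_forward(_KIND[ch], x) - self.mean[ch]) / self.sd[ch])
            else:
                cols.append(x / _CALENDAR_SCALE[ch])
        return np.column_stack(cols)

    def transform_target(self, glucose: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return (np.log(np.asarray(glucose, dtype=float)) - self.mean["glucose"]) / self.sd[
            "glucose"
        ]

    def invert_target(self, z: np.ndarray) -> np.ndarray:
        """Map transformed-space forecasts back to mg/dL."""
        self._require_fitted()
        return np.exp(np.asarray(z, dtype=float) * self.sd["glucose"] + self.mean["glucose"])

    def to_dict(self) -> dict:
        self._require_fitted()
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTransform":
        t = cls(mean=dict(d["mean"]), sd=dict(d["sd"]), fitted=True)
        return t
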