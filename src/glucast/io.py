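"""Reading, writing and grid-regularization of CGM traces.

A continuous glucose monitor reports interstitial glucose roughly every five
minutes.  The canonical in-memory representation here is :class:`GlucoseSeries`:
a uniform 5-minute grid anchored at ``t0`` with an explicit boolean mask for
missing slots.  Missingness is never encoded as a sentinel value — the mask is
the single source of truth, and values at missing slots are NaN by convention.

Two on-disk dialects are supported: a diff-friendly CSV with ``timestamp`` and
``glucose`` columns in which missing slots are simply absent, and a read-only
convenience parser for the OhioT1DM XML event format (``glucose_level`` stream
only; all other event streams are ignored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

STEP = pd.Timedelta(minutes=5)
#: default snap tolerance for raw device timestamps
SNAP_TOLERANCE = pd.Timedelta(seconds=60)

OHIO_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class EventSeries:
    """Raw, time-sorted CGM events not yet snapped to the 5-minute grid."""

    patient_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")


@dataclass
class GlucoseSeries:
    """One patient's CGM trace on a uniform 5-minute grid.

    Attributes
    ----------
    patient_id : str
        Opaque identifier.
    t0 : pd.Timestamp
        Timezone-naive local time of grid slot 0.  Local clock time is kept
        because the day-part / hour-of-day features describe the patient's day.
    values : np.ndarray
        Glucose in mg/dL, length ``n``; NaN at missing slots.
    mask : np.ndarray
        Boolean, True where a value is present.
    """

    patient_id: str
    t0: pd.Timestamp
    values: np.ndarray
    mask: np.ndarray
    step: pd.Timedelta = field(default=STEP)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D and of equal length")
        present = self.values[self.mask]
        if present.size and (~np.isfinite(present) | (present <= 0)).any():
            raise ValueError("present glucose values must be finite and > 0 mg/dL")
        # missing slots are normalized to NaN so a stale number can never leak
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.t0, periods=self.n, freq=self.step)

    def copy(self) -> "GlucoseSeries":
        return GlucoseSeries(
            self.patient_id, self.t0, self.values.copy(), self.mask.copy(), self.step
        )


def read_csv_series(
    path,
    column_map: dict[str, str] | None = None,
    patient_id: str | None = None,
) -> EventSeries:
    """Read a CSV of (timestamp, glucose) rows into a raw event list.

    The file must carry a header naming a timestamp column (ISO 8601) and a
    numeric glucose column; ``column_map`` may rename them, e.g.
    ``{"timestamp": "ts", "glucose": "value"}``.  Rows are kept in file order
    and not yet regularized — pass the result to :func:`regularize_to_grid`.
    """
    cmap = {"timestamp": "timestamp", "glucose": "glucose"}
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no records") from exc
    for role, name in cmap.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing {role} column {name!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no records")
    ts_raw = df[cmap["timestamp"]]
    try:
        ts = pd.to_datetime(ts_raw, format="ISO8601")
    except (ValueError, TypeError):
        bad = _first_bad_timestamp(ts_raw)
        raise FormatError(f"{path}: unparseable timestamp at row {bad}") from None
    gl_raw = pd.to_numeric(df[cmap["glucose"]], errors="coerce")
    if gl_raw.isna().any():
        row = int(gl_raw.index[gl_raw.isna()][0])
        raise FormatError(f"{path}: non-numeric glucose at row {row}")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate timestamp {dup}")
    return EventSeries(
        patient_id=patient_id or "unknown",
        timestamps=pd.DatetimeIndex(ts),
        values=gl_raw.to_numpy(dtype=float),
    )


def _first_bad_timestamp(col: pd.Series) -> int:
    for i, v in enumerate(col):
        try:
            pd.to_datetime(v, format="ISO8601")
        except (ValueError, TypeError):
            return i
    return -1


def read_ohio_xml(path, patient_id: str | None = None) -> EventSeries:
    """Read the ``glucose_level`` stream of an OhioT1DM-style XML document.

    Every other event stream (meals, insulin, exercise, ...) is ignored:
    the forecasting pipeline uses CGM readings only.  Timestamps follow the
    dataset's day-month-year dialect, e.g. ``07-12-2021 08:00:00``.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse XML ({exc})") from exc
    root = tree.getroot()
    node = root if root.tag == "glucose_level" else root.find(".//glucose_level")
    if node is None:
        raise FormatError(f"{path}: no glucose_level element")
    ts_list, val_list = [], []
    for ev in node:
        ts = ev.get("ts")
        value = ev.get("value")
        if ts is None or value is None:
            raise FormatError(f"{path}: glucose event missing ts or value attribute")
        try:
            ts_list.append(pd.to_datetime(ts, format=OHIO_TS_FORMAT))
        except ValueError:
            raise FormatError(f"{path}: unparseable timestamp {ts!r}") from None
        try:
            val_list.append(float(value))
        except ValueError:
            raise FormatError(f"{path}: non-numeric glucose {value!r}") from None
    if not ts_list:
        raise FormatError(f"{path}: no records")
    pid = patient_id or root.get("id") or "unknown"
    return EventSeries(pid, pd.DatetimeIndex(ts_list), np.asarray(val_list))


def regularize_to_grid(
    raw: EventSeries | GlucoseSeries,
    tolerance: pd.Timedelta = SNAP_TOLERANCE,
) -> tuple[GlucoseSeries, int]:
    """Snap raw events onto the wall-clock 5-minute grid.

    Grid slots sit at wall-clock times whose minute is a multiple of five
    (seconds zero).  Each event is snapped to the nearest slot if within
    ``tolerance`` (ties broken toward the earlier slot); events farther away
    are dropped with a warning.  Slots between the first and last kept event
    that claim no event become missing.  If two events snap to the same slot
    the nearer one wins.

    Returns the gridded series and the count of dropped events.  Applying this
    to an already-regular :class:`GlucoseSeries` is the identity.
    """
    if isinstance(raw, GlucoseSeries):
        ts = raw.timestamps[raw.mask]
        values = raw.values[raw.mask]
        pid = raw.patient_id
    else:
        order = np.argsort(raw.timestamps.values, kind="stable")
        ts = raw.timestamps[order]
        values = raw.values[order]
        pid = raw.patient_id
    if len(ts) == 0:
        raise ValueError("no events to regularize")

    step_ns = STEP.value
    t_ns = ts.asi8
    # nearest wall-clock 5-minute boundary; exact ties resolve to the earlier
    # slot because of the floor on (t + step/2)
    slot_ns = ((t_ns + step_ns // 2) // step_ns) * step_ns
    dist = np.abs(t_ns - slot_ns)
    keep = dist <= tolerance.value
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) farther than tolerance from the grid; dropped")
    if not keep.any():
        raise ValueError("all events dropped during regularization")
    slot_ns, dist, values = slot_ns[keep], dist[keep], values[keep]

    # collision resolution: keep the nearer event per slot (first wins on tie)
    best: dict[int, tuple[int, float]] = {}
    collided = 0
    for s, d, v in zip(slot_ns, dist, values):
        s = int(s)
        if s in best:
            collided += 1
            if d < best[s][0]:
                best[s] = (int(d), float(v))
        else:
            best[s] = (int(d), float(v))
    if collided:
        warnings.warn(f"{collided} event(s) collided on a grid slot; kept the nearer")

    slots = np.array(sorted(best), dtype=np.int64)
    first, last = slots[0], slots[-1]
    n = int((last - first) // step_ns) + 1
    vals = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    idx = ((slots - first) // step_ns).astype(int)
    vals[idx] = [best[int(s)][1] for s in slots]
    mask[idx] = True
    series = GlucoseSeries(pid, pd.Timestamp(first), vals, mask)
    return series, n_dropped


def write_csv_series(series: GlucoseSeries, path) -> None:
    """Write a series in the canonical CSV dialect (missing slots absent)."""
    ts = series.timestamps[series.mask]
    df = pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose": series.values[series.mask],
        }
    )
    df.to_csv(path, index=False)


def load_series(path, patient_id: str | None = None, **kwargs) -> GlucoseSeries:
    """Convenience: read the canonical CSV and regularize in one step."""
    series, _ = regularize_to_grid(read_csv_series(path, patient_id=patient_id, **kwargs))
    return series
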