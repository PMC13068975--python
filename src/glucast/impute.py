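"""Hybrid threshold-routed imputation of CGM gaps.

CGM traces lose samples to sensor warm-up, compression lows and transmitter
drop-outs, and the right repair depends on how much signal is missing.  Gaps
are routed by length:

* **short** (1-11 slots, under an hour): cubic-spline interpolation across the
  gap — local curvature carries enough information at this scale;
* **medium** (12-50 slots): an ARIMA model fitted to the history immediately
  before the gap forecasts across it; implausible fills are then purged and
  the residual hole is either splined (fewer than 12 slots remain) or the
  series is cut there (12 or more remain);
* **long** (51+ slots): no statistical fill is trustworthy — the series is cut
  into separate segments at the gap.

The training pipeline uses :func:`impute_hybrid` (which cuts); the inference
pipeline uses :func:`impute_for_inference`, which spline-fills every interior
gap regardless of length and never cuts, so forecasts stay aligned with the
original grid and can later be scored only at originally observed slots.

Observed values are never modified by any path here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import GlucoseSeries

# routing thresholds on consecutive missing-slot counts
SPLINE_MAX = 11  # "fewer than 12" -> spline
ARIMA_MAX = 50  # 12..50 -> ARIMA; 51+ -> cut
SECOND_ROUND_MAX = 11  # after purging: < 12 remaining -> spline, >= 12 -> cut

PHYSIO_RANGE = (40.0, 400.0)  # plausible CGM reporting range, mg/dL
FLANK_HALF = 12  # slots per side used for the local outlier band
MIN_ARIMA_HISTORY = 50
MAX_ARIMA_HISTORY = 288  # one day of context; ample for a 5-minute cadence
MAX_SPLINE_ANCHORS = 24  # per side
MIN_SEGMENT_LEN = 29  # shortest segment that yields at least one window
ARIMA_ORDERS = [(p, d, q) for p in range(3) for d in range(2) for q in range(3)]
ARIMA_FALLBACK_ORDER = (1, 1, 0)


class Branch(Enum):
    SPLINE = "spline"
    ARIMA = "arima"
    CUT = "cut"


class EscalateCut(Exception):
    """A fill path gave up on this gap; the caller must cut instead."""


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of consecutive missing grid slots."""

    start: int
    length: int
    boundary: bool = False  # touches the start or end of the series

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class SegmentedSeries:
    """Output of hybrid imputation: gap-free, time-disjoint segments.

    ``provenance`` tags each slot of the original grid with how its value
    arose (``observed`` / ``spline`` / ``arima``; dropped slots are ``cut``).
    ``gap_log`` records one entry per original gap: start, length, branch
    taken, and how many ARIMA fills were purged.
    """

    segments: list[GlucoseSeries]
    segment_starts: list[int]  # grid index of each segment's first slot
    provenance: np.ndarray  # dtype '<U8' over the original grid
    usable: list[bool] = field(default_factory=list)
    gap_log: list[dict] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return int((self.provenance == "cut").sum())


def find_gaps(series: GlucoseSeries) -> list[GapSegment]:
    """Maximal runs of missing slots, in index order.

    Runs touching the first or last slot are flagged ``boundary`` — they have
    no anchor on one side and can only be cut (or trimmed)."""
    mask = series.mask
    gaps: list[GapSegment] = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            gaps.append(GapSegment(i, j - i, boundary=(i == 0 or j == n)))
            i = j
        else:
            i += 1
    return gaps


def route_gap(length: int) -> Branch:
    """Pick the imputation branch from the gap length alone."""
    if length < 1:
        raise ValueError("gap length must be >= 1")
    if length <= SPLINE_MAX:
        return Branch.SPLINE
    if length <= ARIMA_MAX:
        return Branch.ARIMA
    return Branch.CUT


def _anchor_indices(values: np.ndarray, start: int, stop: int) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous present runs adjacent to a missing run [start, stop).

    The scan stops at the first missing slot on each side so anchors never
    reach across another (cut or not-yet-filled) gap; up to
    MAX_SPLINE_ANCHORS slots per side are used."""
    present = ~np.isnan(values)
    left = []
    i = start - 1
    while i >= 0 and present[i] and len(left) < MAX_SPLINE_ANCHORS:
        left.append(i)
        i -= 1
    right = []
    i = stop
    n = len(values)
    while i < n and present[i] and len(right) < MAX_SPLINE_ANCHORS:
        right.append(i)
        i += 1
    return np.array(left[::-1], dtype=int), np.array(right, dtype=int)


def fill_spline(series: GlucoseSeries, gap: GapSegment) -> GlucoseSeries:
    """Fill one gap by a not-a-knot cubic spline through flanking samples.

    Requires observed anchors on both sides and at least 4 anchors total
    (exactly the condition for a cubic fit); boundary gaps raise
    :class:`EscalateCut`.  Not-a-knot reproduces cubic polynomials exactly,
    which pins the implementation with a clean oracle.  Observed slots are
    never touched."""
    left, right = _anchor_indices(series.values, gap.start, gap.stop)
    if len(left) == 0 or len(right) == 0:
        raise EscalateCut(f"gap at {gap.start} has no anchor on one side")
    x = np.concatenate([left, right])
    if len(x) < 4:
        raise EscalateCut(f"gap at {gap.start}: only {len(x)} anchors, need 4")
    spline = CubicSpline(x, series.values[x], bc_type="not-a-knot")
    out = series.copy()
    idx = np.arange(gap.start, gap.stop)
    # glucose must stay positive; extreme extrapolation is clipped and will
    # be caught downstream by validity checks
    out.values[idx] = np.maximum(spline(idx), 1.0)
    out.mask[idx] = True
    return out


def _fit_arima_forecast(history: np.ndarray, steps: int) -> np.ndarray:
    from statsmodels.tsa.arima.model import ARIMA as _ARIMA

    best_aic, best_fit = np.inf, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for order in ARIMA_ORDERS:
            try:
                fit = _ARIMA(history, order=order, concentrate_scale=True).fit()
            except Exception:
                continue
            if np.isfinite(fit.aic) and fit.aic < best_aic:
                best_aic, best_fit = fit.aic, fit
        if best_fit is None:
            try:
                best_fit = _ARIMA(history, order=ARIMA_FALLBACK_ORDER, concentrate_scale=True).fit()
            except Exception as exc:
                raise EscalateCut(f"ARIMA fit failed even at fallback order: {exc}") from exc
        return np.asarray(best_fit.forecast(steps), dtype=float)


def fill_arima(series: GlucoseSeries, gap: GapSegment) -> GlucoseSeries:
    """Forecast across one gap with an ARIMA model fit on the run before it.

    Order is chosen by AIC over p in 0..2, d in 0..1, q in 0..2, fitted on the
    contiguous present run immediately preceding the gap (at most 500 slots).
    With fewer than 50 preceding slots the gap falls back to spline filling
    with a warning."""
    left, _ = _anchor_indices_unbounded(series.values, gap.start)
    if len(left) < MIN_ARIMA_HISTORY:
        warnings.warn(
            f"gap at {gap.start}: only {len(left)} preceding slots "
            f"(< {MIN_ARIMA_HISTORY}); falling back to spline"
        )
        return fill_spline(series, gap)
    history = series.values[left[-MAX_ARIMA_HISTORY:]]
    fc = _fit_arima_forecast(history, gap.length)
    out = series.copy()
    idx = np.arange(gap.start, gap.stop)
    out.values[idx] = np.maximum(fc, 1.0)
    out.mask[idx] = True
    return out


def _anchor_indices_unbounded(values: np.ndarray, start: int) -> tuple[np.ndarray, None]:
    """Full contiguous present run ending at start-1 (no per-side cap)."""
    present = ~np.isnan(values)
    i = start - 1
    left = []
    while i >= 0 and present[i]:
        left.append(i)
        i -= 1
    return np.array(left[::-1], dtype=int), None


def purge_imputed_outliers(
    series: GlucoseSeries,
    gap: GapSegment,
    observed_mask: np.ndarray | None = None,
) -> GlucoseSeries:
    """Re-blank implausible ARIMA fills inside one just-filled gap.

    An imputed slot is reset to missing iff its value is outside the
    physiological range [40, 400] mg/dL, or beyond mean +- 3 SD of the 24
    observed values flanking the gap (12 per side, fewer near a boundary).
    Only the imputed slots of this gap are examined — observed values are
    never flagged, however extreme."""
    if observed_mask is None:
        observed_mask = series.mask.copy()
        observed_mask[gap.start : gap.stop] = False
    flank = _flank_values(series.values, observed_mask, gap)
    lo, hi = PHYSIO_RANGE
    band_lo, band_hi = -np.inf, np.inf
    if flank.size >= 2:
        m, sd = float(np.mean(flank)), float(np.std(flank, ddof=1))
        band_lo, band_hi = m - 3.0 * sd - 1e-9, m + 3.0 * sd + 1e-9
    out = series.copy()
    idx = np.arange(gap.start, gap.stop)
    v = out.values[idx]
    bad = (v < lo) | (v > hi) | (v < band_lo) | (v > band_hi)
    out.mask[idx[bad]] = False
    out.values = np.where(out.mask, out.values, np.nan)
    return out


def _flank_values(values: np.ndarray, observed_mask: np.ndarray, gap: GapSegment) -> np.ndarray:
    n = len(values)
    left_idx = [i for i in range(gap.start - 1, -1, -1) if observed_mask[i]][:FLANK_HALF]
    right_idx = [i for i in range(gap.stop, n) if observed_mask[i]][:FLANK_HALF]
    idx = np.array(left_idx[::-1] + right_idx, dtype=int)
    return values[idx] if idx.size else np.empty(0)


def impute_hybrid(series: GlucoseSeries) -> SegmentedSeries:
    """Run the full threshold-routed repair on a training trace.

    Gaps are processed left to right.  Short gaps are splined; medium gaps are
    ARIMA-forecast, purged of implausible fills, then splined again if fewer
    than 12 slots remain missing or cut if 12 or more do; long and boundary
    gaps are cut.  The result is a list of fully valued, time-disjoint
    segments; segments shorter than 29 slots are kept but flagged unusable for
    windowing (they cannot produce a single supervised window)."""
    observed_mask = series.mask.copy()
    provenance = np.full(series.n, "", dtype="<U8")
    provenance[observed_mask] = "observed"
    working = series.copy()
    gap_log: list[dict] = []

    for gap in find_gaps(series):
        entry = {"start": gap.start, "length": gap.length, "purged": 0}
        if gap.boundary:
            entry["branch"] = "cut"
            provenance[gap.start : gap.stop] = "cut"
            gap_log.append(entry)
            continue
        branch = route_gap(gap.length)
        try:
            if branch is Branch.SPLINE:
                working = fill_spline(working, gap)
                provenance[gap.start : gap.stop] = "spline"
                entry["branch"] = "spline"
            elif branch is Branch.ARIMA:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    working = fill_arima(working, gap)
                fell_back = any("falling back to spline" in str(w.message) for w in caught)
                if fell_back:
                    provenance[gap.start : gap.stop] = "spline"
                    entry["branch"] = "spline-fallback"
                else:
                    working = purge_imputed_outliers(working, gap, observed_mask)
                    purged = int((~working.mask[gap.start : gap.stop]).sum())
                    entry["purged"] = purged
                    if purged == 0:
                        provenance[gap.start : gap.stop] = "arima"
                        entry["branch"] = "arima"
                    elif purged <= SECOND_ROUND_MAX:
                        # second interpolation round over the purged holes
                        purged_in_gap = ~working.mask[gap.start : gap.stop]
                        for sub in _missing_runs(working.mask, gap.start, gap.stop):
                            working = fill_spline(working, sub)
                        prov_gap = np.where(purged_in_gap, "spline", "arima")
                        provenance[gap.start : gap.stop] = prov_gap
                        entry["branch"] = "arima+spline"
                    else:
                        # too many purged fills: partition the series here
                        working.mask[gap.start : gap.stop] = False
                        working.values = np.where(working.mask, working.values, np.nan)
                        provenance[gap.start : gap.stop] = "cut"
                        entry["branch"] = "cut-after-purge"
            else:
                provenance[gap.start : gap.stop] = "cut"
                entry["branch"] = "cut"
        except EscalateCut as exc:
            warnings.warn(str(exc))
            working.mask[gap.start : gap.stop] = False
            working.values = np.where(working.mask, working.values, np.nan)
            provenance[gap.start : gap.stop] = "cut"
            entry["branch"] = "cut-escalated"
        gap_log.append(entry)

    return _segment(series, working, provenance, gap_log)


def _missing_runs(mask: np.ndarray, start: int, stop: int) -> list[GapSegment]:
    runs = []
    i = start
    while i < stop:
        if not mask[i]:
            j = i
            while j < stop and not mask[j]:
                j += 1
            runs.append(GapSegment(i, j - i))
            i = j
        else:
            i += 1
    return runs


def _segment(
    original: GlucoseSeries,
    working: GlucoseSeries,
    provenance: np.ndarray,
    gap_log: list[dict],
) -> SegmentedSeries:
    segments: list[GlucoseSeries] = []
    starts: list[int] = []
    usable: list[bool] = []
    n = working.n
    i = 0
    while i < n:
        if working.mask[i]:
            j = i
            while j < n and working.mask[j]:
                j += 1
            seg = GlucoseSeries(
                original.patient_id,
                original.t0 + i * original.step,
                working.values[i:j].copy(),
                np.ones(j - i, dtype=bool),
                original.step,
            )
            segments.append(seg)
            starts.append(i)
            usable.append(j - i >= MIN_SEGMENT_LEN)
            i = j
        else:
            provenance[i] = "cut"
            i += 1
    return SegmentedSeries(segments, starts, provenance, usable, gap_log)


def impute_for_inference(series: GlucoseSeries) -> tuple[GlucoseSeries, np.ndarray]:
    """Thresholdless inference-time repair: spline every gap, never cut.

    All interior gaps are spline-filled regardless of length so the series
    stays on one uninterrupted grid; leading/trailing missing runs (which have
    no anchor on one side) are trimmed.  Returns the filled series and the
    boolean mask of originally observed slots on the same (trimmed) grid, so
    evaluation can be restricted to values that were present in the original
    file."""
    present = np.flatnonzero(series.mask)
    if present.size == 0:
        raise ValueError("series has no observed values")
    a, b = int(present[0]), int(present[-1]) + 1
    trimmed = GlucoseSeries(
        series.patient_id,
        series.t0 + a * series.step,
        series.values[a:b].copy(),
        series.mask[a:b].copy(),
        series.step,
    )
    observed = trimmed.mask.copy()
    working = trimmed.copy()
    for gap in find_gaps(trimmed):
        working = fill_spline(working, gap)
    return working, observed
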