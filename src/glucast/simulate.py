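"""Seeded synthetic CGM generator.

Real CGM benchmark data (e.g. OhioT1DM) is distributed under data-use
agreements, so every downstream stage here is exercised on simulated traces
instead.  The generator is a statistical fixture, not a metabolic model: a
baseline plus a 24-hour circadian sinusoid, gamma-shaped post-meal excursions
with log-normal amplitudes, and stationary AR(1) sensor noise, clipped to the
physiological reporting range.  The design goal is a trace with hour-scale
learnable structure so that a forecaster can beat the persistence baseline,
and with ground-truth gap locations so imputation accuracy is measurable.

Trace dynamics and gap placement use two independent seeds, so missingness
patterns can be varied against a fixed physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GlucoseSeries
from .impute import GapSegment

SLOTS_PER_DAY = 288  # 24 h at 5-minute sampling

# gap-length regimes, matching the imputation routing thresholds
SHORT_RANGE = (1, 11)
MEDIUM_RANGE = (12, 50)
LONG_RANGE = (51, 150)
EDGE_EXCLUSION = 12  # gaps are never placed in the first/last 12 slots


@dataclass
class SimConfig:
    """Parameters of one simulated patient-trace.

    Units are mg/dL for amplitudes and minutes for durations.  ``noise_sd``
    is the stationary standard deviation of the AR(1) noise component.
    """

    days: int = 14
    baseline: float = 120.0
    circadian_amplitude: float = 15.0
    meal_times: tuple[float, ...] = (8.0, 13.0, 19.0)
    meal_amplitude_range: tuple[float, float] = (40.0, 90.0)
    meal_rise_minutes: float = 30.0
    meal_decay_minutes: float = 120.0
    ar_coefficient: float = 0.8
    noise_sd: float = 5.0
    floor: float = 40.0
    ceiling: float = 400.0
    seed: int = 0
    t0: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2024-01-01 00:00:00"))
    patient_id: str = "sim"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not self.floor < self.baseline < self.ceiling:
            raise ValueError("need floor < baseline < ceiling")
        lo, hi = self.meal_amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("meal_amplitude_range must be a non-negative interval")


@dataclass
class GapSpec:
    """Missingness profile: how many gaps per day and how long they are.

    ``length_mixture`` gives the probabilities of the short (1-11 slots),
    medium (12-50) and long (51-150) regimes; lengths are uniform within a
    regime.  The regime bounds deliberately mirror the hybrid-imputation
    routing thresholds so every branch is reachable.
    """

    rate_per_day: float = 2.0
    length_mixture: tuple[float, float, float] = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_day < 0:
            raise ValueError("rate_per_day must be >= 0")
        if abs(sum(self.length_mixture) - 1.0) > 1e-9:
            raise ValueError("length_mixture must sum to 1")
        if any(p < 0 for p in self.length_mixture):
            raise ValueError("length_mixture probabilities must be >= 0")


def _meal_kernel(tau_minutes: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Gamma-shaped excursion: 0 at meal time, peak 1 at ``rise`` minutes,
    then exponential-tailed decay on the ``decay`` scale."""
    theta = max(decay / 4.0, 1.0)
    a = max(rise / theta, 1e-6)
    tau = np.maximum(tau_minutes, 0.0)
    peak = rise
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (tau / peak) ** a * np.exp(a * (1.0 - tau / peak))
    return np.where(tau_minutes >= 0, k, 0.0)


def simulate_trace(config: SimConfig) -> GlucoseSeries:
    """Simulate a fully observed CGM trace of ``config.days`` days.

    value(i) = clip(baseline + circadian + sum of meal responses + AR(1)
    noise, floor, ceiling); identical config (incl. seed) gives a bitwise
    identical trace.
    """
    rng = np.random.default_rng(config.seed)
    n = config.days * SLOTS_PER_DAY
    minutes = np.arange(n, dtype=float) * 5.0
    hours = minutes / 60.0

    circadian = config.circadian_amplitude * np.cos(2 * np.pi * (hours % 24.0 - 15.0) / 24.0)

    meals = np.zeros(n)
    lo, hi = config.meal_amplitude_range
    for day in range(config.days):
        for mt in config.meal_times:
            # +-20 min timing jitter; log-normal amplitude clipped to range
            start_min = (day * 24.0 + mt) * 60.0 + rng.uniform(-20.0, 20.0)
            if hi > 0:
                amp = np.exp(rng.normal(np.log(np.sqrt(max(lo, 1e-6) * hi)), 0.25))
                amp = float(np.clip(amp, lo, hi))
            else:
                amp = 0.0
            meals += amp * _meal_kernel(
                minutes - start_min, config.meal_rise_minutes, config.meal_decay_minutes
            )

    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar_coefficient**2)
        w = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.noise_sd)
        for i in range(1, n):
            noise[i] = config.ar_coefficient * noise[i - 1] + w[i]
    else:
        noise = np.zeros(n)

    values = np.clip(config.baseline + circadian + meals + noise, config.floor, config.ceiling)
    return GlucoseSeries(config.patient_id, config.t0, values, np.ones(n, dtype=bool))


def _draw_gap_length(rng: np.random.Generator, mixture) -> int:
    regime = rng.choice(3, p=np.asarray(mixture, dtype=float))
    lo, hi = (SHORT_RANGE, MEDIUM_RANGE, LONG_RANGE)[regime]
    return int(rng.integers(lo, hi + 1))


def inject_missingness(
    series: GlucoseSeries, spec: GapSpec
) -> tuple[GlucoseSeries, list[GapSegment]]:
    """Punch seeded, non-overlapping gaps into a fully observed series.

    Gap count is Poisson(rate_per_day * days); placement is uniform at random
    away from the first/last 12 slots, with at least one observed slot kept
    between gaps so each stays a maximal missing run.  Returns the gapped
    series and the ground-truth gap list; observed values are unchanged.
    """
    if not series.mask.all():
        raise ValueError("inject_missingness expects a fully observed series")
    rng = np.random.default_rng(spec.seed)
    n = series.n
    days = n / SLOTS_PER_DAY
    n_gaps = int(rng.poisson(spec.rate_per_day * days))

    lengths = [_draw_gap_length(rng, spec.length_mixture) for _ in range(n_gaps)]
    if sum(lengths) > 0.5 * n:
        raise ValueError("requested gap mass exceeds 50% of the series")

    taken = np.zeros(n, dtype=bool)  # slots unavailable (gap or separator)
    placed: list[GapSegment] = []
    for length in sorted(lengths, reverse=True):
        lo, hi = EDGE_EXCLUSION, n - EDGE_EXCLUSION - length
        if hi < lo:
            continue
        for _ in range(200):  # rejection sampling
            start = int(rng.integers(lo, hi + 1))
            if not taken[max(start - 1, 0) : start + length + 1].any():
                taken[max(start - 1, 0) : start + length + 1] = True
                placed.append(GapSegment(start=start, length=length))
                break
    placed.sort(key=lambda g: g.start)

    out = series.copy()
    for g in placed:
        out.mask[g.start : g.start + g.length] = False
    out.values = np.where(out.mask, out.values, np.nan)
    return out, placed


def punch_gaps(series: GlucoseSeries, gaps: list[tuple[int, int]]) -> GlucoseSeries:
    """Set explicit (start, length) runs to missing — direct gap construction."""
    out = series.copy()
    for start, length in gaps:
        if start < 0 or start + length > series.n:
            raise ValueError(f"gap ({start}, {length}) outside series")
        out.mask[start : start + length] = False
    out.values = np.where(out.mask, out.values, np.nan)
    return out
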