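"""Hybrid threshold-routed gap imputation: routing, fills, purge, segmentation."""

import numpy as np
import pandas as pd
import pytest

from glucast.impute import (
    Branch,
    EscalateCut,
    GapSegment,
    fill_arima,
    fill_spline,
    find_gaps,
    impute_for_inference,
    impute_hybrid,
    purge_imputed_outliers,
    route_gap,
)
from glucast.simulate import GapSpec, SimConfig, inject_missingness, punch_gaps, simulate_trace

from conftest import cubic_trace, make_series


def brute_force_gaps(mask):
    """Independent run-length scan used as the find_gaps oracle."""
    gaps, i = [], 0
    while i < len(mask):
        if not mask[i]:
            j = i
            while j < len(mask) and not mask[j]:
                j += 1
            gaps.append((i, j - i))
            i = j
        else:
            i += 1
    return gaps


class TestFindGaps:
    def test_fully_observed_series_has_no_gaps(self, constant_series):
        assert find_gaps(constant_series) == []

    def test_interleaved_mask_matches_oracle(self):
        mask = np.array([True, False, False, True, False, True])
        s = make_series(np.where(mask, 100.0, np.nan), mask)
        gaps = find_gaps(s)
        assert [(g.start, g.length) for g in gaps] == [(1, 2), (4, 1)]
        assert not any(g.boundary for g in gaps)

    def test_random_masks_match_oracle(self, rng):
        for _ in range(50):
            mask = rng.random(60) > 0.4
            s = make_series(np.where(mask, 100.0, np.nan), mask)
            got = [(g.start, g.length) for g in find_gaps(s)]
            assert got == brute_force_gaps(mask)

    def test_all_missing_is_one_boundary_gap(self):
        s = make_series(np.full(10, np.nan), np.zeros(10, dtype=bool))
        gaps = find_gaps(s)
        assert len(gaps) == 1
        assert gaps[0] == GapSegment(0, 10, boundary=True)

    def test_leading_and_trailing_runs_are_boundary_flagged(self):
        mask = np.array([False, True, True, False, True, False])
        s = make_series(np.where(mask, 100.0, np.nan), mask)
        flags = [(g.start, g.boundary) for g in find_gaps(s)]
        assert flags == [(0, True), (3, False), (5, True)]


class TestRouteGap:
    def test_exhaustive_thresholds_1_to_200(self):
        for length in range(1, 201):
            expected = (
                Branch.SPLINE if length <= 11 else Branch.ARIMA if length <= 50 else Branch.CUT
            )
            assert route_gap(length) is expected

    @pytest.mark.parametrize(
        "length,branch",
        [(11, Branch.SPLINE), (12, Branch.ARIMA), (50, Branch.ARIMA), (51, Branch.CUT)],
    )
    def test_printed_boundaries(self, length, branch):
        assert route_gap(length) is branch

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            route_gap(0)


class TestFillSpline:
    @pytest.mark.parametrize("start,length", [(50, 5), (120, 11), (20, 1)])
    def test_cubic_polynomial_recovered_exactly(self, start, length):
        poly = cubic_trace()
        s = punch_gaps(make_series(poly), [(start, length)])
        filled = fill_spline(s, GapSegment(start, length))
        np.testing.assert_allclose(
            filled.values[start : start + length], poly[start : start + length], atol=1e-6
        )

    def test_constant_series_filled_with_constant(self, constant_series):
        s = punch_gaps(constant_series, [(40, 6)])
        filled = fill_spline(s, GapSegment(40, 6))
        np.testing.assert_allclose(filled.values[40:46], 130.0)

    def test_observed_slots_untouched(self, rng):
        values = 100.0 + 50.0 * rng.random(80)
        s = punch_gaps(make_series(values), [(30, 8)])
        before = s.values.copy()
        filled = fill_spline(s, GapSegment(30, 8))
        np.testing.assert_array_equal(filled.values[s.mask], before[s.mask])

    def test_boundary_gap_escalates_to_cut(self):
        s = make_series(np.r_[np.full(5, np.nan), np.full(20, 110.0)])
        with pytest.raises(EscalateCut):
            fill_spline(s, GapSegment(0, 5))


class TestFillArima:
    def test_constant_history_forecasts_the_constant(self):
        s = punch_gaps(make_series(np.full(150, 120.0)), [(100, 15)])
        filled = fill_arima(s, GapSegment(100, 15))
        np.testing.assert_allclose(filled.values[100:115], 120.0, atol=1e-3)

    def test_fills_exactly_the_gap_slots(self):
        s = punch_gaps(make_series(np.full(150, 120.0)), [(100, 15)])
        filled = fill_arima(s, GapSegment(100, 15))
        assert filled.mask.all()
        np.testing.assert_array_equal(np.flatnonzero(~s.mask), np.arange(100, 115))

    def test_ar1_gap_matches_closed_form_conditional_expectation(self):
        # AR(1): coefficient 0.8, mean 120, stationary SD 5, n = 2000
        rng = np.random.default_rng(7)
        phi, mu, sd, n = 0.8, 120.0, 5.0, 2000
        e = np.zeros(n)
        innov = sd * np.sqrt(1 - phi**2)
        for i in range(1, n):
            e[i] = phi * e[i - 1] + rng.normal(0, innov)
        y = mu + e
        start, length = 1500, 20
        s = punch_gaps(make_series(y), [(start, length)])
        filled = fill_arima(s, GapSegment(start, length))
        h = np.arange(1, length + 1)
        oracle = mu + phi**h * (y[start - 1] - mu)
        np.testing.assert_allclose(filled.values[start : start + length], oracle, atol=2.0)

    def test_short_history_falls_back_to_spline(self):
        values = np.full(100, 120.0)
        s = punch_gaps(make_series(values), [(30, 15)])  # only 30 preceding slots
        with pytest.warns(UserWarning, match="falling back to spline"):
            filled = fill_arima(s, GapSegment(30, 15))
        np.testing.assert_allclose(filled.values[30:45], 120.0, atol=1e-6)


class TestPurge:
    def _filled_series(self, bad_value=None):
        rng = np.random.default_rng(0)
        values = 120.0 + rng.normal(0, 3, 200)
        s = make_series(values)
        gap = GapSegment(100, 15)
        observed = np.ones(200, dtype=bool)
        observed[100:115] = False
        # pretend the gap was ARIMA-filled with plausible values
        s.values[100:115] = 120.0
        if bad_value is not None:
            s.values[105] = bad_value
        return s, gap, observed

    def test_plausible_fills_survive(self):
        s, gap, observed = self._filled_series()
        out = purge_imputed_outliers(s, gap, observed)
        assert out.mask.all()

    def test_out_of_range_fill_is_reblanked(self):
        s, gap, observed = self._filled_series(bad_value=700.0)
        out = purge_imputed_outliers(s, gap, observed)
        assert not out.mask[105]
        assert np.isnan(out.values[105])
        assert out.mask[100:105].all() and out.mask[106:115].all()

    def test_flank_band_catches_locally_implausible_fill(self):
        s, gap, observed = self._filled_series(bad_value=160.0)  # in range but >> flank band
        out = purge_imputed_outliers(s, gap, observed)
        assert not out.mask[105]

    def test_observed_extremes_are_never_purged(self):
        s, gap, observed = self._filled_series()
        s.values[50] = 350.0  # extreme but observed
        out = purge_imputed_outliers(s, gap, observed)
        assert out.mask[50] and out.values[50] == 350.0


class TestImputeHybrid:
    def test_gapless_series_is_single_identical_segment(self, constant_series):
        seg = impute_hybrid(constant_series)
        assert len(seg.segments) == 1
        np.testing.assert_array_equal(seg.segments[0].values, constant_series.values)
        assert (seg.provenance == "observed").all()

    def test_flowchart_trace_short_medium_long(self):
        # short gap splined, medium gap ARIMA-filled, long gap cut -> 2 segments
        base = simulate_trace(SimConfig(days=4, seed=10))
        s = punch_gaps(base, [(100, 5), (400, 20), (700, 60)])
        seg = impute_hybrid(s)
        branches = {e["start"]: e["branch"] for e in seg.gap_log}
        assert branches[100] == "spline"
        assert branches[400].startswith("arima")
        assert branches[700] == "cut"
        if branches[400] in ("arima", "arima+spline"):
            assert len(seg.segments) == 2
            assert [s.n for s in seg.segments] == [700, base.n - 760]

    def test_observed_values_bitwise_unchanged(self):
        base = simulate_trace(SimConfig(days=3, seed=4))
        s, _ = inject_missingness(base, GapSpec(seed=21))
        seg = impute_hybrid(s)
        reconstructed = np.full(s.n, np.nan)
        for start, segment in zip(seg.segment_starts, seg.segments):
            reconstructed[start : start + segment.n] = segment.values
        np.testing.assert_array_equal(reconstructed[s.mask], s.values[s.mask])

    def test_slot_conservation_and_gap_free_segments(self):
        base = simulate_trace(SimConfig(days=3, seed=4))
        s, _ = inject_missingness(base, GapSpec(rate_per_day=3.0, seed=22))
        seg = impute_hybrid(s)
        assert sum(x.n for x in seg.segments) + seg.n_dropped == s.n
        for segment in seg.segments:
            assert segment.mask.all()
            assert np.isfinite(segment.values).all()

    def test_purge_escalation_cuts_when_12_or_more_remain(self, monkeypatch):
        # force the ARIMA fill to produce garbage so >= 12 slots get purged
        import glucast.impute as imp

        monkeypatch.setattr(
            imp, "_fit_arima_forecast", lambda history, steps: np.full(steps, 700.0)
        )
        base = simulate_trace(SimConfig(days=2, seed=1))
        s = punch_gaps(base, [(200, 20)])
        seg = imp.impute_hybrid(s)
        entry = seg.gap_log[0]
        assert entry["branch"] == "cut-after-purge" and entry["purged"] == 20
        assert len(seg.segments) == 2
        assert seg.n_dropped == 20

    def test_partial_purge_triggers_second_spline_round(self, monkeypatch):
        # plausible fills except a few out-of-band values -> splined in round two
        import glucast.impute as imp

        real_fit = imp._fit_arima_forecast

        def spiky(history, steps):
            fc = real_fit(history, steps)
            fc[3:6] = 700.0
            return fc

        monkeypatch.setattr(imp, "_fit_arima_forecast", spiky)
        base = simulate_trace(SimConfig(days=2, seed=1))
        s = punch_gaps(base, [(200, 20)])
        seg = imp.impute_hybrid(s)
        entry = seg.gap_log[0]
        assert entry["branch"] == "arima+spline" and entry["purged"] == 3
        assert len(seg.segments) == 1 and seg.segments[0].mask.all()
        prov = seg.provenance[200:220]
        assert list(prov[3:6]) == ["spline"] * 3
        assert set(prov[:3]) == {"arima"}

    def test_boundary_gaps_are_cut(self):
        values = np.r_[np.full(5, np.nan), np.full(100, 120.0), np.full(3, np.nan)]
        seg = impute_hybrid(make_series(values))
        assert len(seg.segments) == 1 and seg.segments[0].n == 100
        assert seg.n_dropped == 8

    def test_short_segments_flagged_unusable(self):
        values = np.r_[np.full(20, 120.0), np.full(60, np.nan), np.full(100, 120.0)]
        seg = impute_hybrid(make_series(values))
        assert seg.usable == [False, True]


class TestImputeForInference:
    def test_long_gap_is_splined_not_cut(self):
        base = simulate_trace(SimConfig(days=2, seed=2))
        s = punch_gaps(base, [(200, 80)])
        filled, observed = impute_for_inference(s)
        assert filled.n == base.n
        assert filled.mask.all()

    def test_returned_mask_marks_originally_observed_slots(self):
        base = simulate_trace(SimConfig(days=2, seed=2))
        s = punch_gaps(base, [(200, 80), (500, 5)])
        filled, observed = impute_for_inference(s)
        np.testing.assert_array_equal(observed, s.mask)
        np.testing.assert_array_equal(filled.values[observed], s.values[s.mask])

    def test_gapless_series_is_identity_with_all_true_mask(self, constant_series):
        filled, observed = impute_for_inference(constant_series)
        assert observed.all()
        np.testing.assert_array_equal(filled.values, constant_series.values)

    def test_boundary_missing_runs_are_trimmed(self):
        values = np.r_[np.full(4, np.nan), np.full(50, 120.0)]
        s = make_series(values)
        filled, observed = impute_for_inference(s)
        assert filled.n == 50 and observed.all()
        assert filled.t0 == s.t0 + 4 * s.step


class TestImputationAccuracyOrdering:
    def test_spline_short_beats_arima_medium_beats_persistence(self):
        """Sanity ordering of imputation error on simulated truth: short-gap
        spline RMSE < medium-gap ARIMA RMSE < medium-gap persistence RMSE."""
        base = simulate_trace(SimConfig(days=6, seed=33))
        short_gaps = [(i * 300 + 50, 6) for i in range(5)]
        medium_gaps = [(i * 300 + 150, 20) for i in range(5)]

        def rmse_for(gaps, fill):
            errs = []
            for start, length in gaps:
                s = punch_gaps(base, [(start, length)])
                filled = fill(s, GapSegment(start, length))
                errs.append(filled.values[start : start + length] - base.values[start : start + length])
            return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

        def persistence_fill(s, gap):
            out = s.copy()
            out.values[gap.start : gap.stop] = s.values[gap.start - 1]
            out.mask[gap.start : gap.stop] = True
            return out

        spline_rmse = rmse_for(short_gaps, fill_spline)
        arima_rmse = rmse_for(medium_gaps, fill_arima)
        persist_rmse = rmse_for(medium_gaps, persistence_fill)
        assert spline_rmse < arima_rmse < persist_rmse
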