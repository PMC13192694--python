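"""Constrained peak detection: candidates, prominence, widths, filtering."""

import numpy as np
import pytest

from pulsetrace.errors import ParameterError
from pulsetrace.peaks import (
    DerivedPeakParams,
    derive_params,
    detect_peaks,
    find_candidate_maxima,
    prominence,
    width_at_half_prominence,
)
from pulsetrace.synthetic import REGIMES, generate_traces
from pulsetrace.traces import TraceMatrix, make_time_axis

from _bruteforce import brute_detect, brute_prominence


def loose_params(**kw):
    defaults = dict(
        min_height=-np.inf,
        min_prominence=0.0,
        min_separation_samples=1e-9,
        min_width_samples=1e-9,
        max_width_samples=np.inf,
    )
    defaults.update(kw)
    return DerivedPeakParams(**defaults)


class TestDeriveParams:
    def test_table_ratios(self):
        values = np.zeros((34, 2))
        values[5, 0], values[7, 1] = 80.0, 120.0  # per-trace maxima: mean 100
        tm = TraceMatrix(values, make_time_axis(34, 5.5), np.zeros_like(values, bool))
        p = derive_params(tm, 5.5)
        assert p.min_height == pytest.approx(10.0)
        assert p.min_prominence == pytest.approx(5.0)
        assert p.min_prominence == pytest.approx(p.min_height / 2)

    def test_width_and_separation_from_period(self):
        # 6 samples/hour over 5.5 h: 34 points, spacing 1/6 h
        values = np.ones((34, 1))
        tm = TraceMatrix(values, make_time_axis(34, 5.5), np.zeros_like(values, bool))
        p = derive_params(tm, 5.5)
        assert p.min_separation_samples == pytest.approx(3.3)  # R*P/10 = 6*5.5/10
        assert p.min_width_samples == p.min_separation_samples
        assert p.max_width_samples == pytest.approx(100 * p.min_width_samples)

    def test_user_override_flips_source(self):
        values = np.ones((10, 1))
        tm = TraceMatrix(values, make_time_axis(10, 9.0), np.zeros_like(values, bool))
        p = derive_params(tm, 3.0, overrides={"min_height": 42.0})
        assert p.min_height == 42.0
        assert p.source == "user_override"
        assert derive_params(tm, 3.0).source == "default_rules"

    def test_unknown_override_rejected(self):
        values = np.ones((10, 1))
        tm = TraceMatrix(values, make_time_axis(10, 9.0), np.zeros_like(values, bool))
        with pytest.raises(ParameterError, match="bogus"):
            derive_params(tm, 3.0, overrides={"bogus": 1.0})


class TestCandidates:
    @pytest.mark.parametrize(
        "trace,expected",
        [
            ([0, 1, 0], [1]),
            ([0, 2, 2, 0], [1]),  # plateau midpoint, lower index
            ([0, 2, 2, 2, 0], [2]),
            ([0, 1, 2, 3], []),  # monotone ramp
            ([3, 2, 1], []),
            ([0, 1, 0, 2, 0], [1, 3]),
            ([2, 2, 0], []),  # plateau touching the endpoint
            ([0, 2, 2], []),
            ([1, 0, 1], []),  # endpoints are never candidates
        ],
    )
    def test_examples(self, trace, expected):
        assert find_candidate_maxima(np.array(trace, float)) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            find_candidate_maxima(np.array([1.0, 2.0]))


class TestProminence:
    def test_single_peak(self):
        prom, lb, rb = prominence(np.array([0.0, 3.0, 0.0]), 1)
        assert (prom, lb, rb) == (3.0, 0, 2)

    def test_side_valley_limits_prominence(self):
        # apex 1 of [0,3,1,5,0]: left base value 0, right valley 1
        prom, lb, rb = prominence(np.array([0.0, 3.0, 1.0, 5.0, 0.0]), 1)
        assert prom == 2.0
        assert (lb, rb) == (0, 2)

    def test_global_maximum_spans_whole_trace(self, rng):
        # no higher sample exists, so both walks reach the trace ends and
        # prominence is the height above the higher of the two side minima
        x = rng.normal(size=50).cumsum()
        x[25] = x.max() + 5.0
        prom, _, _ = prominence(x, 25)
        side_min = max(x[:25].min(), x[26:].min())
        assert prom == pytest.approx(x[25] - side_min)

    def test_matches_bruteforce_on_random_traces(self, rng):
        for _ in range(200):
            x = rng.integers(0, 8, size=int(rng.integers(5, 30))).astype(float)
            for apex in find_candidate_maxima(x):
                assert prominence(x, apex) == brute_prominence(x, apex)


class TestWidth:
    def test_triangle_half_prominence(self):
        x = np.array([0.0, 4.0, 0.0])
        width, lc, rc, flagged = width_at_half_prominence(x, 1, 4.0, 0, 2)
        assert (lc, rc) == (0.5, 1.5)
        assert width == 1.0
        assert not flagged

    def test_fine_gaussian_matches_analytic_fwhm(self):
        # half-prominence width of an isolated Gaussian pulse = its FWHM
        t = np.linspace(0, 10, 2001)
        fwhm = 1.7
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.exp(-0.5 * ((t - 5) / sigma) ** 2)
        apex = int(np.argmax(x))
        prom, lb, rb = prominence(x, apex)
        width, lc, rc, _ = width_at_half_prominence(x, apex, prom, lb, rb)
        dt = t[1] - t[0]
        assert width * dt == pytest.approx(fwhm, rel=1e-4)
        assert abs((rc - apex) - (apex - lc)) < 1.0  # symmetric about apex

    def test_plateau_peak_width_exceeds_plateau(self):
        x = np.array([0.0, 3.0, 3.0, 3.0, 0.0])
        apex = find_candidate_maxima(x)[0]
        prom, lb, rb = prominence(x, apex)
        width, lc, rc, _ = width_at_half_prominence(x, apex, prom, lb, rb)
        assert lc < 1 and rc > 3
        assert width >= 2.0  # at least the plateau length


class TestDetectPeaks:
    def test_flat_trace_empty(self):
        assert detect_peaks(np.zeros(20), loose_params(min_height=0.1)) == []

    def test_two_planted_pulses(self):
        # noiseless pulses at 2 h and 7.5 h over 12 h
        from dataclasses import replace as dreplace

        params = loose_params(min_height=1.2, min_prominence=0.5,
                              min_separation_samples=3.3, min_width_samples=3.3,
                              max_width_samples=330.0)
        quiet, truth = generate_traces(
            dreplace(REGIMES["natural"], noise_sd=0.0, missing_fraction=0.0,
                     pulse_period_hours_sd=0.0),
            1, 12.0, 6.0, seed=3,
        )
        assert len(truth.pulses[0]) == 2
        peaks = detect_peaks(quiet.values[:, 0], params, quiet.time_hours)
        apex_times = [p.time_hours for p in peaks]
        assert len(apex_times) == len(truth.pulses[0])
        for found, (planted, _, _) in zip(apex_times, truth.pulses[0]):
            assert abs(found - planted) <= 1 / 6 + 1e-9  # within one sample

    def test_separation_keeps_leftmost_of_equal_pair(self):
        x = np.array([0.0, 5.0, 0.0, 5.0, 0.0])
        peaks = detect_peaks(x, loose_params(min_separation_samples=5.0))
        assert [p.index for p in peaks] == [1]

    def test_taller_peak_wins_separation(self):
        x = np.array([0.0, 4.0, 2.0, 6.0, 0.0])
        peaks = detect_peaks(x, loose_params(min_separation_samples=5.0))
        assert [p.index for p in peaks] == [3]

    def test_monotone_thresholds_never_add_peaks(self, rng):
        for _ in range(30):
            x = rng.normal(size=60).cumsum()
            base = len(detect_peaks(x, loose_params()))
            for h in np.linspace(x.min(), x.max(), 5):
                n = len(detect_peaks(x, loose_params(min_height=h)))
                assert n <= base
            for s in [1.0, 2.0, 5.0, 10.0]:
                n = len(detect_peaks(x, loose_params(min_separation_samples=s)))
                assert n <= base

    def test_translation_and_scale_covariance(self, rng):
        x = rng.normal(size=80).cumsum()
        params = loose_params(min_height=np.median(x), min_prominence=0.5,
                              min_separation_samples=2.0, min_width_samples=1.0,
                              max_width_samples=50.0)
        ref = detect_peaks(x, params)
        shifted = detect_peaks(
            x + 7.0, loose_params(min_height=np.median(x) + 7.0, min_prominence=0.5,
                                  min_separation_samples=2.0, min_width_samples=1.0,
                                  max_width_samples=50.0))
        assert [p.index for p in ref] == [p.index for p in shifted]
        assert [p.prominence for p in ref] == pytest.approx(
            [p.prominence for p in shifted])
        assert [p.width_samples for p in ref] == pytest.approx(
            [p.width_samples for p in shifted])
        a = 3.0
        scaled = detect_peaks(
            a * x, loose_params(min_height=a * np.median(x), min_prominence=a * 0.5,
                                min_separation_samples=2.0, min_width_samples=1.0,
                                max_width_samples=50.0))
        assert [p.index for p in ref] == [p.index for p in scaled]
        assert [a * p.height for p in ref] == pytest.approx(
            [p.height for p in scaled])

    def test_agrees_with_bruteforce(self, rng):
        """Exact apex-set agreement with the exhaustive checker."""
        for trial in range(200):
            integer = trial % 2 == 0
            n = int(rng.integers(5, 50))
            if integer:
                x = rng.integers(0, 6, size=n).astype(float)
            else:
                x = rng.normal(size=n).cumsum()
            mh = float(rng.uniform(x.min(), x.max()))
            mp = float(rng.uniform(0, np.ptp(x) / 2))
            ms = float(rng.uniform(0.5, 8.0))
            mw = float(rng.uniform(0.1, 4.0))
            xw = float(rng.uniform(mw + 0.5, 40.0))
            params = DerivedPeakParams(mh, mp, ms, mw, xw)
            ours = [p.index for p in detect_peaks(x, params)]
            theirs = brute_detect(x, mh, mp, ms, mw, xw)
            assert ours == theirs, f"trial {trial}: {ours} != {theirs}"
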