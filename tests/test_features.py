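"""Peak integrals, per-trace features, first-peak metrics, summaries."""

from dataclasses import replace

import numpy as np
import pytest

from pulsetrace.features import (
    extract_features,
    first_peak_metrics,
    peak_integral,
    summarize_condition,
)
from pulsetrace.peaks import Peak, detect_peaks, DerivedPeakParams
from pulsetrace.synthetic import REGIMES, generate_traces


def make_peak(t_apex=2.0, left=1.0, right=3.0, **kw):
    defaults = dict(
        trace_id="t",
        index=int(t_apex),
        time_hours=t_apex,
        height=1.0,
        prominence=1.0,
        width_hours=right - left,
        left_cross_hours=left,
        right_cross_hours=right,
        left_base_index=0,
        right_base_index=4,
    )
    defaults.update(kw)
    return Peak(**defaults)


def loose_params():
    return DerivedPeakParams(-np.inf, 0.0, 1e-9, 1e-9, np.inf)


class TestPeakIntegral:
    def test_rectangle(self):
        time = np.arange(10, dtype=float)
        trace = np.full(10, 3.0)
        pk = make_peak(t_apex=5.0, left=2.5, right=6.5)
        assert peak_integral(trace, time, pk) == pytest.approx(4.0 * 3.0, abs=1e-9)

    def test_triangle_window(self):
        # trace rises 0->4->0 over samples 0,1,2; window = half-prominence
        time = np.arange(3, dtype=float)
        trace = np.array([0.0, 4.0, 0.0])
        pk = make_peak(t_apex=1.0, left=0.5, right=1.5)
        # analytic area of the piecewise-linear segment over [0.5, 1.5]
        assert peak_integral(trace, time, pk) == pytest.approx(3.0, abs=1e-9)

    def test_zero_trace(self):
        time = np.arange(5, dtype=float)
        pk = make_peak()
        assert peak_integral(np.zeros(5), time, pk) == 0.0

    def test_scale_covariance(self, rng):
        time = np.linspace(0, 10, 61)
        trace = np.abs(rng.normal(size=61)) + 0.5
        pk = make_peak(t_apex=5.0, left=2.2, right=7.9)
        base = peak_integral(trace, time, pk)
        assert peak_integral(3.5 * trace, time, pk) == pytest.approx(3.5 * base)


class TestExtractFeatures:
    def test_no_peaks(self):
        time = np.arange(25, dtype=float)
        tf = extract_features(np.zeros(25), time, [], 24.0, "t0")
        assert tf.n_peaks == 0
        assert tf.frequency_per_hour == 0.0
        assert np.isnan(tf.first_peak_time_hours)
        assert np.isnan(tf.mean_interpeak_hours)

    def test_four_peaks_frequency(self):
        time = np.arange(25, dtype=float)
        peaks = [make_peak(t_apex=float(t)) for t in (3, 9, 14, 20)]
        tf = extract_features(np.ones(25), time, peaks, 24.0)
        assert tf.frequency_per_hour == pytest.approx(4 / 24)
        assert tf.frequency_per_hour * 24.0 == tf.n_peaks

    def test_mean_interpeak_spacing(self):
        time = np.arange(25, dtype=float)
        peaks = [make_peak(t_apex=t) for t in (2.0, 7.5, 13.0)]
        tf = extract_features(np.ones(25), time, peaks, 24.0)
        assert tf.mean_interpeak_hours == pytest.approx(5.5)

    def test_peaks_sorted_and_integrals_filled(self, rng):
        time = np.arange(30, dtype=float)
        trace = np.abs(rng.normal(size=30)) + 1.0
        peaks = [make_peak(t_apex=20.0, left=19.0, right=21.0),
                 make_peak(t_apex=5.0, left=4.0, right=6.0)]
        tf = extract_features(trace, time, peaks, 29.0)
        assert [p.time_hours for p in tf.peaks] == [5.0, 20.0]
        assert all(np.isfinite(p.integral) for p in tf.peaks)


class TestFirstPeakMetrics:
    def test_shared_apex_zero_dispersion(self):
        time = np.arange(25, dtype=float)
        fl = [
            extract_features(np.ones(25), time, [make_peak(t_apex=10.0)], 24.0, f"t{i}")
            for i in range(4)
        ]
        df = first_peak_metrics(fl)
        assert df.loc[0, "mean_first_peak_time_hours"] == 10.0
        assert df.loc[0, "sd_first_peak_time_hours"] == 0.0

    def test_mean_of_two(self):
        time = np.arange(25, dtype=float)
        fl = [
            extract_features(np.ones(25), time, [make_peak(t_apex=8.0)], 24.0, "a"),
            extract_features(np.ones(25), time, [make_peak(t_apex=12.0)], 24.0, "b"),
        ]
        assert first_peak_metrics(fl).loc[0, "mean_first_peak_time_hours"] == 10.0

    def test_no_peak_condition_gets_nan_row(self):
        time = np.arange(25, dtype=float)
        fl = [extract_features(np.ones(25), time, [], 24.0, "a", condition="empty")]
        df = first_peak_metrics(fl)
        assert df.loc[0, "n_no_peak"] == 1
        assert np.isnan(df.loc[0, "mean_first_peak_time_hours"])

    def test_planted_delays_recovered_in_order(self):
        # conditions differing only in first-pulse delay: recovered mean
        # first-peak times preserve the planted ordering
        # delays keep the first apex interior (an apex at t=0 sits on the
        # trace endpoint and is not a local maximum by definition)
        delays = [2.0, 6.0, 10.0]
        features = []
        for delay in delays:
            regime = replace(
                REGIMES["natural"],
                name=f"delay_{delay:g}",
                first_pulse_delay_hours=delay,
                noise_sd=0.02,
                missing_fraction=0.0,
            )
            tm, _ = generate_traces(regime, 10, 36.0, 6.0, seed=11)
            for j in range(tm.n_cells):
                pk = detect_peaks(
                    tm.values[:, j], _natural_params(), tm.time_hours, f"{delay}:{j}"
                )
                features.append(
                    extract_features(
                        tm.values[:, j], tm.time_hours, pk, 36.0,
                        trace_id=f"{delay}:{j}", condition=regime.name,
                    )
                )
        df = first_peak_metrics(features).set_index("condition")
        means = [df.loc[f"delay_{d:g}", "mean_first_peak_time_hours"] for d in delays]
        assert means[0] < means[1] < means[2]


def _natural_params():
    return DerivedPeakParams(
        min_height=0.2, min_prominence=0.15, min_separation_samples=3.3,
        min_width_samples=3.3, max_width_samples=330.0,
    )


class TestSummarizeCondition:
    def test_mean_amplitude(self):
        time = np.arange(25, dtype=float)
        fl = [
            extract_features(
                np.ones(25), time,
                [make_peak(t_apex=5.0, height=10.0), make_peak(t_apex=15.0, height=20.0)],
                24.0, "a", condition="c1",
            )
        ]
        s = summarize_condition(fl)[0]
        assert s.mean_amplitude == 15.0
        assert s.n_peaks == 2

    def test_empty_condition_nan_markers(self):
        time = np.arange(25, dtype=float)
        fl = [extract_features(np.ones(25), time, [], 24.0, "a", condition="c")]
        s = summarize_condition(fl)[0]
        assert s.n_peaks == 0
        assert np.isnan(s.mean_amplitude)
        assert s.mean_frequency == 0.0  # over traces, not peaks

    def test_long_duration_regime_widens_peaks(self):
        summaries = {}
        for name in ("natural", "long_duration"):
            regime = replace(REGIMES[name], noise_sd=0.02, missing_fraction=0.0)
            tm, _ = generate_traces(regime, 20, 48.0, 6.0, seed=21)
            fl = []
            for j in range(tm.n_cells):
                pk = detect_peaks(tm.values[:, j], _natural_params(), tm.time_hours)
                fl.append(
                    extract_features(tm.values[:, j], tm.time_hours, pk, 48.0,
                                     condition=name)
                )
            summaries[name] = summarize_condition(fl)[0]
        assert (
            summaries["long_duration"].mean_width_hours
            > summaries["natural"].mean_width_hours
        )


class TestPlantedRecovery:
    def test_height_and_width_recovered(self):
        """Isolated noiseless pulses: apex height recovers baseline +
        amplitude within 5%, half-prominence width recovers the planted
        FWHM within 15%."""
        regime = replace(
            REGIMES["natural"], noise_sd=0.0, missing_fraction=0.0,
            pulse_period_hours_sd=0.0,
        )
        tm, truth = generate_traces(regime, 40, 48.0, 6.0, seed=31)
        checked = 0
        for j in range(tm.n_cells):
            peaks = detect_peaks(tm.values[:, j], _natural_params(), tm.time_hours)
            planted = truth.pulses[j]
            assert len(peaks) == len(planted)
            for pk, (apex_t, amp, fwhm) in zip(peaks, planted):
                assert pk.height == pytest.approx(regime.baseline + amp, rel=0.05)
                assert pk.width_hours == pytest.approx(fwhm, rel=0.15)
                checked += 1
        assert checked >= 200
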