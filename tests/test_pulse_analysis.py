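import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import hysteresis_fsm
from pulsekit import (PulseConfig, VesselSimSpec, analyze_recording,
                      compute_amplitude, compute_frequency, detect_events,
                      generate_vessel_movie, summarize_trace)
from pulsekit.pulse_analysis import IntensityTrace, PulseEvent

trace_values = st.lists(
    st.floats(min_value=-500, max_value=500, allow_nan=False), min_size=1,
    max_size=40)


def kinds(events):
    return [(e.kind, e.frame_index) for e in events]


class TestDetectEvents:
    def test_constant_trace_has_no_events(self):
        assert detect_events([50.0] * 10, PulseConfig()) == []

    def test_worked_example_two_peaks_one_valley(self):
        events = detect_events([0, 100, 0, 100, 0], PulseConfig(threshold_au=40))
        assert kinds(events) == [("peak", 1), ("valley", 2), ("peak", 3)]

    def test_subthreshold_excursions_ignored(self):
        assert detect_events([0, 30, 0, 30, 0], PulseConfig(threshold_au=40)) == []

    def test_plateau_commits_first_sample(self):
        events = detect_events([0, 100, 100, 100, 0, 100],
                               PulseConfig(threshold_au=40))
        assert ("peak", 1) in kinds(events)

    def test_baseline_drift_does_not_defeat_hysteresis(self):
        # drifting baseline with two clear contractions riding on it
        t = np.arange(40, dtype=float)
        x = 0.5 * t + 200.0
        x[10] -= 100
        x[25] -= 100
        events = detect_events(x, PulseConfig(threshold_au=40))
        assert [e.kind for e in events].count("valley") == 2

    @given(trace_values, st.floats(min_value=1, max_value=200))
    def test_matches_finite_state_oracle(self, values, threshold):
        events = detect_events(values, PulseConfig(threshold_au=threshold))
        assert kinds(events) == hysteresis_fsm(values, threshold)

    @given(trace_values)
    def test_committed_events_strictly_alternate(self, values):
        events = detect_events(values, PulseConfig(threshold_au=25))
        for a, b in zip(events, events[1:]):
            assert a.kind != b.kind
            assert a.frame_index < b.frame_index

    @given(trace_values)
    def test_event_count_non_increasing_in_threshold(self, values):
        counts = [len(detect_events(values, PulseConfig(threshold_au=thr)))
                  for thr in (10, 20, 40, 80, 160)]
        assert counts == sorted(counts, reverse=True)


class TestFrequency:
    @pytest.mark.parametrize("np_c,nv_c,dt,expected", [
        (0, 0, 10.0, 0.0),
        (4, 4, 10.0, 0.4),
        (6, 6, 10.0, 0.6),
        (3, 2, 2.5, 1.0),
    ])
    def test_formula(self, np_c, nv_c, dt, expected):
        assert compute_frequency(np_c, nv_c, dt) == expected

    def test_identity_frequency_times_two_dt_is_event_count(self):
        for np_c in range(0, 13):
            for nv_c in range(0, 13):
                f = compute_frequency(np_c, nv_c, 7.3)
                assert f * 2 * 7.3 == pytest.approx(np_c + nv_c)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            compute_frequency(1, 1, 0.0)


class TestAmplitude:
    def test_single_pair_percentage(self):
        trace = [0, 200, 100, 200]
        events = [PulseEvent("peak", 1, 200.0), PulseEvent("valley", 2, 100.0)]
        assert compute_amplitude(trace, events) == pytest.approx(50.0)

    def test_no_pairs_is_missing(self):
        assert math.isnan(compute_amplitude([0, 100, 0], []))

    def test_nonpositive_maximum_flagged_missing(self):
        trace = [-300.0, -100.0, -300.0, -100.0]
        events = detect_events(trace, PulseConfig(threshold_au=40))
        assert len(events) >= 2
        with pytest.warns(RuntimeWarning, match="maximum"):
            assert math.isnan(compute_amplitude(trace, events))


class TestEndToEnd:
    def test_programmed_depth_recovered(self):
        spec = VesselSimSpec(seed=31)
        stack, truth = generate_vessel_movie(spec)
        from pulsekit import extract_trace
        trace = extract_trace(stack, truth.vessel_rois[0], truth.background_roi,
                              truth.frame_interval_s)
        metrics = summarize_trace(trace)
        assert metrics.np_count == 6 and metrics.nv_count == 6
        assert metrics.frequency_per_min == pytest.approx(0.6)
        assert metrics.amplitude_pct == pytest.approx(
            truth.modulation_depth_pct, rel=0.05)

    def test_five_identical_rois_give_identical_rows(self):
        spec = VesselSimSpec(seed=32)
        stack, truth = generate_vessel_movie(spec)
        table = analyze_recording(
            stack, [*truth.vessel_rois, truth.background_roi],
            frame_interval_s=truth.frame_interval_s, register=False)
        body = table[table.roi != "mean"]
        assert len(body) == 5
        assert body.Np.nunique() == 1 and body.Nv.nunique() == 1
        assert body.freq_per_min.nunique() == 1

    def test_zero_amplitude_movie_silent(self, quick_protocol):
        spec = VesselSimSpec(protocol=quick_protocol, contraction_times=(),
                             contraction_amplitude=1.0, seed=33)
        stack, truth = generate_vessel_movie(spec)
        table = analyze_recording(
            stack, [*truth.vessel_rois, truth.background_roi],
            frame_interval_s=truth.frame_interval_s, register=False)
        assert (table.freq_per_min == 0).all()

    def test_dt_defaults_to_recorded_duration(self, quick_protocol):
        spec = VesselSimSpec(protocol=quick_protocol,
                             contraction_times=(1.0,), seed=34)
        stack, truth = generate_vessel_movie(spec)
        from pulsekit import extract_trace
        trace = extract_trace(stack, truth.vessel_rois[0], truth.background_roi,
                              truth.frame_interval_s)
        metrics = summarize_trace(trace)
        assert metrics.dt_min == pytest.approx(2.5)

    def test_roi_requirements_enforced(self, quick_protocol):
        spec = VesselSimSpec(protocol=quick_protocol, seed=35)
        stack, truth = generate_vessel_movie(spec)
        with pytest.raises(ValueError, match="background"):
            analyze_recording(stack, truth.vessel_rois,
                              frame_interval_s=truth.frame_interval_s)
        with pytest.raises(ValueError, match="vessel"):
            analyze_recording(stack, [truth.background_roi],
                              frame_interval_s=truth.frame_interval_s)
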