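"""Contraction detection and summary metrics on ROI intensity traces.

A collecting lymphatic vessel pumps by phasic contractions; on a
fluorescence trace each contraction shows as an excursion between a peak
and a valley. Events are found with a hysteresis turning-point rule: a
running candidate extremum is tracked, and committed as a peak (or valley)
as soon as the signal departs from it by at least the detection threshold
(default 40 AU) in the opposite direction, at which point the search
direction reverses. The threshold is a hysteresis magnitude, not an
absolute intensity level, so baseline drift does not defeat detection.

Committed events strictly alternate. Boundary extrema are not events: the
trace's first and last samples are never committed, and the initial
extremum — the one the signal departs from when the search direction is
first established — is dropped as well, since it belongs to the truncated
segment before the first observed turning point (under noise it need not
sit exactly on sample 0). An interior candidate still pending when the
trace ends IS committed, so a contraction that has clearly turned before
the recording stops is counted. Because the final sample can never be
confirmed as a turning point, it never displaces a pending candidate
(though it still confirms reversals): the committed extremum of a
truncated excursion is its best interior sample.

Frequency is (Np + Nv) / (2 * dt) contractions per minute, where Np and Nv
are the peak and valley counts and dt the analysis time in minutes.
Amplitude is the mean absolute peak-to-valley intensity change over
adjacent committed pairs, expressed as a percentage of the maximum
intensity reached in the trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registration import register_stack
from .trace_extraction import IntensityTrace, Roi, extract_trace

DEFAULT_THRESHOLD_AU = 40.0


@dataclass(frozen=True)
class PulseConfig:
    """Detection threshold (AU) and optional fixed analysis duration (min).

    When ``dt_min`` is None the analysis time defaults to the recorded
    duration (frames x frame interval), which stays correct for truncated
    recordings.
    """

    threshold_au: float = DEFAULT_THRESHOLD_AU
    dt_min: float | None = None

    def __post_init__(self):
        if self.threshold_au <= 0:
            raise ValueError("threshold_au must be > 0")
        if self.dt_min is not None and self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")


@dataclass(frozen=True)
class PulseEvent:
    kind: str  # "peak" | "valley"
    frame_index: int
    value: float


@dataclass(frozen=True)
class PulseMetrics:
    """Per-ROI contraction summary: counts, frequency and amplitude."""

    roi_name: str
    np_count: int
    nv_count: int
    dt_min: float
    frequency_per_min: float
    amplitude_pct: float  # NaN when undefined
    max_intensity: float


def _trace_values(trace) -> np.ndarray:
    if isinstance(trace, IntensityTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def detect_events(trace, config: PulseConfig = PulseConfig()) -> list[PulseEvent]:
    """Hysteresis turning-point detection on a trace.

    Returns the committed events in frame order, strictly alternating in
    kind. A constant trace, or one whose excursions never reach the
    threshold, yields an empty list. Plateaus at an extremum commit the
    first sample of the plateau.
    """
    x = _trace_values(trace)
    if x.size == 0:
        raise ValueError("trace is empty")
    thr = float(config.threshold_au)
    n = x.size
    events: list[PulseEvent] = []

    def commit(kind: str, i: int):
        if i not in (0, n - 1):
            events.append(PulseEvent(kind=kind, frame_index=i, value=float(x[i])))

    direction = 0  # 0 unknown, +1 tracking a max, -1 tracking a min
    cand_max = 0
    cand_min = 0
    for i in range(1, n):
        if direction == 0:
            if x[i] > x[cand_max]:
                cand_max = i
            elif x[i] < x[cand_min]:
                cand_min = i
            # first reversal: establishes direction only; the initial
            # extremum is a boundary artifact and is not committed
            if x[cand_max] - x[i] >= thr:
                direction, cand_min = -1, i
            elif x[i] - x[cand_min] >= thr:
                direction, cand_max = 1, i
        elif direction == 1:
            # the unconfirmable last sample never displaces the candidate
            if x[i] > x[cand_max] and i < n - 1:
                cand_max = i
            elif x[cand_max] - x[i] >= thr:
                commit("peak", cand_max)
                direction, cand_min = -1, i
        else:
            if x[i] < x[cand_min] and i < n - 1:
                cand_min = i
            elif x[i] - x[cand_min] >= thr:
                commit("valley", cand_min)
                direction, cand_max = 1, i
    # pending interior turning point at stream end
    if direction == 1:
        commit("peak", cand_max)
    elif direction == -1:
        commit("valley", cand_min)
    return events


def compute_frequency(np_count: int, nv_count: int, dt_min: float) -> float:
    """(Np + Nv) / (2 * dt) contractions per minute."""
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    if np_count < 0 or nv_count < 0:
        raise ValueError("event counts must be >= 0")
    return (np_count + nv_count) / (2.0 * dt_min)


def compute_amplitude(trace, events: list[PulseEvent]) -> float:
    """Mean contraction amplitude as % of the trace maximum.

    Each adjacent committed pair (peak->valley or valley->peak) is one
    contraction's intensity change: |v_i - v_{i+1}| / max(trace) * 100.
    Returns NaN (a missing value) when fewer than one pair exists or the
    trace maximum is not positive.
    """
    x = _trace_values(trace)
    if x.size == 0:
        raise ValueError("trace is empty")
    if len(events) < 2:
        return math.nan
    peak = float(x.max())
    if peak <= 0:
        warnings.warn("trace maximum <= 0: amplitude percentage undefined",
                      RuntimeWarning, stacklevel=2)
        return math.nan
    diffs = [abs(a.value - b.value) for a, b in zip(events, events[1:])]
    return float(np.mean(diffs) / peak * 100.0)


def summarize_trace(trace: IntensityTrace, config: PulseConfig = PulseConfig()) -> PulseMetrics:
    """Detect events on one trace and assemble its PulseMetrics."""
    events = detect_events(trace, config)
    n_peaks = sum(e.kind == "peak" for e in events)
    n_valleys = sum(e.kind == "valley" for e in events)
    dt = config.dt_min if config.dt_min is not None else trace.duration_min
    return PulseMetrics(
        roi_name=trace.roi_name,
        np_count=n_peaks,
        nv_count=n_valleys,
        dt_min=dt,
        frequency_per_min=compute_frequency(n_peaks, n_valleys, dt),
        amplitude_pct=compute_amplitude(trace, events),
        max_intensity=float(trace.values.max()),
    )


METRICS_COLUMNS = ["roi", "Np", "Nv", "dt_min", "freq_per_min",
                   "amplitude_pct", "max_au"]


def analyze_recording(
    stack: np.ndarray,
    rois: list[Roi],
    config: PulseConfig = PulseConfig(),
    frame_interval_s: float = 1.0,
    register: bool = True,
    template_region=None,
    search_radius: int = 8,
) -> pd.DataFrame:
    """Full per-recording analysis: stabilize, extract, detect, summarize.

    Requires >= 1 vessel ROI and exactly one background ROI. Returns one
    metrics row per vessel ROI plus a recording-level "mean" row.
    """
    vessels = [r for r in rois if r.role == "vessel"]
    backgrounds = [r for r in rois if r.role == "background"]
    if not vessels:
        raise ValueError("need at least one vessel ROI")
    if len(backgrounds) != 1:
        raise ValueError(f"need exactly one background ROI, got {len(backgrounds)}")
    background = backgrounds[0]

    valid_mask = None
    if register:
        reg = register_stack(stack, template_region=template_region,
                             search_radius=search_radius)
        stack, valid_mask = reg.stabilized, reg.valid_mask

    rows = []
    for roi in vessels:
        trace = extract_trace(stack, roi, background, frame_interval_s,
                              valid_mask=valid_mask)
        m = summarize_trace(trace, config)
        rows.append({"roi": m.roi_name, "Np": m.np_count, "Nv": m.nv_count,
                     "dt_min": m.dt_min, "freq_per_min": m.frequency_per_min,
                     "amplitude_pct": m.amplitude_pct, "max_au": m.max_intensity})
    table = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    mean_row = table.drop(columns="roi").mean(numeric_only=True)
    table.loc[len(table)] = {"roi": "mean", **mean_row.to_dict()}
    return table
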