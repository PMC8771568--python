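"""Synthetic inputs with exact, machine-readable ground truth.

Every input modality of the pipeline can be generated here so that each
stage has a recovery test against known truth without any external data:

* a pulsating-vessel fluorescence movie (uniform frame interval, optional
  integer-pixel jitter and Gaussian noise) whose contraction events,
  per-frame shifts and programmed ROI waveform are emitted alongside;
* flow-cytometry event tables (sample / reagent-only background / detergent
  lysis) with Poisson counting statistics, spiked count beads, and the true
  EV concentration;
* correlated two-channel volumes with a target Pearson coefficient;
* feature x sample intensity matrices with planted fold changes.

Generation is reproducible: identical spec + seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ev_quant import Gate
from .registration import shift_image
from .trace_extraction import Roi

# --------------------------------------------------------------------------
# acquisition protocol and vessel movie
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Recording protocol: 326 frames over a 10-min session, 1 s exposure.

    Frame count and duration are independent protocol constants; the frame
    interval (duration / n_frames, here ~1.84 s) is derived from them and
    is the time base of every trace.
    """

    n_frames: int = 326
    duration_min: float = 10.0
    exposure_s: float = 1.0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be > 0")

    @property
    def frame_interval_s(self) -> float:
        return self.duration_min * 60.0 / self.n_frames

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def default_contraction_times(n_events: int = 6,
                              duration_min: float = 10.0) -> tuple:
    """Evenly spaced event times, centered in equal sub-intervals."""
    return tuple((i + 0.5) * duration_min / n_events for i in range(n_events))


@dataclass(frozen=True)
class VesselSimSpec:
    """Scene + dynamics of a synthetic contraction recording.

    The vessel is a tube of half-width ``vessel_radius_px`` around
    ``vessel_path``; its fluorescence drops from ``baseline_intensity`` by
    ``contraction_amplitude`` AU at each contraction, following a
    raised-cosine dip of ``contraction_width_s`` seconds, guaranteeing one
    unambiguous valley (and a recovery peak) per event. Field-of-view
    motion is an integer-pixel random walk with per-frame step up to
    ``jitter_px``, reflected at +/- ``max_drift_px`` so the truth stays
    within a registration search window.
    """

    protocol: AcquisitionProtocol = AcquisitionProtocol()
    image_shape: tuple = (64, 64)
    vessel_path: tuple = ((8.0, 32.0), (56.0, 32.0))
    vessel_radius_px: float = 4.0
    baseline_intensity: float = 320.0
    contraction_times: tuple | None = None  # default: 6 evenly spaced events
    contraction_amplitude: float = 100.0
    contraction_width_s: float = 15.0
    jitter_px: int = 0
    max_drift_px: int = 5
    noise_sigma: float = 0.0
    background_level: float = 20.0
    texture_sigma: float = 50.0
    texture_smooth_px: float = 1.5
    subpixel_jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.contraction_times is None:
            object.__setattr__(self, "contraction_times",
                               default_contraction_times(
                                   6, self.protocol.duration_min))
        if self.contraction_amplitude <= 0:
            raise ValueError("contraction_amplitude must be > 0")
        if any(t < 0 or t > self.protocol.duration_min
               for t in self.contraction_times):
            raise ValueError("contraction_times must lie within the recording")
        if self.jitter_px < 0 or self.noise_sigma < 0:
            raise ValueError("jitter_px and noise_sigma must be >= 0")
        if self.jitter_px > self.max_drift_px:
            raise ValueError("jitter_px cannot exceed max_drift_px")
        h, w = self.image_shape
        margin = self.vessel_radius_px
        for x, y in self.vessel_path:
            if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
                raise ValueError(
                    f"image too small to contain vessel_path: vertex ({x}, {y}) "
                    f"within {margin} px of a {h}x{w} frame border")

        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be >= 0")

    @property
    def modulation_depth_pct(self) -> float:
        """Programmed amplitude as % of the trace maximum (baseline)."""
        return self.contraction_amplitude \
            / (self.baseline_intensity - self.background_level) * 100.0


@dataclass
class VesselTruth:
    """Everything a recovery test needs: exact shifts, events, waveform, ROIs."""

    shifts: np.ndarray                 # (n_frames, 2) (dy, dx)
    contraction_times_min: tuple
    contraction_amplitude_au: float
    modulation_depth_pct: float
    waveform_au: np.ndarray            # programmed vessel-minus-background trace
    frame_interval_s: float
    vessel_rois: list
    background_roi: Roi


def _segment_distance(px, py, x1, y1, x2, y2):
    """Distance from grid points to the segment (x1,y1)-(x2,y2)."""
    vx, vy = x2 - x1, y2 - y1
    denom = vx * vx + vy * vy
    if denom == 0:
        return np.hypot(px - x1, py - y1)
    t = np.clip(((px - x1) * vx + (py - y1) * vy) / denom, 0.0, 1.0)
    return np.hypot(px - (x1 + t * vx), py - (y1 + t * vy))


def _vessel_mask(spec: VesselSimSpec) -> np.ndarray:
    h, w = spec.image_shape
    jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dist = np.full((h, w), np.inf)
    path = spec.vessel_path
    for (x1, y1), (x2, y2) in zip(path, path[1:]):
        dist = np.minimum(dist, _segment_distance(jj, ii, x1, y1, x2, y2))
    return dist <= spec.vessel_radius_px


def _raised_cosine(tau_s: np.ndarray, width_s: float) -> np.ndarray:
    """1 at the event center, 0 outside +/- width/2, smooth in between."""
    out = np.zeros_like(tau_s, dtype=float)
    inside = np.abs(tau_s) <= width_s / 2.0
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * tau_s[inside] / width_s))
    return out


def programmed_waveform(spec: VesselSimSpec) -> np.ndarray:
    """The vessel-minus-background trace the movie encodes, noise-free."""
    t_s = spec.protocol.frame_times_s()
    modulation = np.zeros_like(t_s)
    for tc_min in spec.contraction_times:
        modulation += _raised_cosine(t_s - tc_min * 60.0, spec.contraction_width_s)
    vessel = spec.baseline_intensity - spec.contraction_amplitude * modulation
    return vessel - spec.background_level


def default_rois(spec: VesselSimSpec, n_vessel: int = 5):
    """Vessel/background ROI rectangles for a horizontal vessel scene.

    Five abutting rectangles strictly inside the vessel tube (matching the
    five manually sketched regions of the in vivo protocol) plus one
    background rectangle in dye-free tissue above the vessel. Rectangles
    use half-integer vertices so no pixel center sits on an edge.
    """
    (x_a, y_a), (x_b, y_b) = spec.vessel_path[0], spec.vessel_path[-1]
    if y_a != y_b:
        raise ValueError("default_rois assumes a horizontal vessel path")
    h, w = spec.image_shape
    r = spec.vessel_radius_px
    margin = spec.max_drift_px + 3
    x_lo = max(min(x_a, x_b) + r, margin)
    x_hi = min(max(x_a, x_b) - r, w - 1 - margin)
    y_top, y_bot = y_a - r + 1.5, y_a + r - 1.5
    edges = np.linspace(x_lo, x_hi, n_vessel + 1)
    vessels = []
    for i in range(n_vessel):
        x0, x1 = edges[i] + 0.5, edges[i + 1] - 0.5
        vessels.append(Roi(
            name=f"roi_{i + 1}", role="vessel",
            vertices=((x0, y_top), (x1, y_top), (x1, y_bot), (x0, y_bot))))
    bg_top, bg_bot = margin + 0.5, y_a - r - 2.5
    if bg_bot - bg_top < 1:
        raise ValueError("no room for a background ROI above the vessel")
    background = Roi(name="background", role="background", vertices=(
        (x_lo, bg_top), (x_hi, bg_top), (x_hi, bg_bot), (x_lo, bg_bot)))
    return vessels, background


def _texture_field(spec: VesselSimSpec, rng) -> np.ndarray:
    """Static autofluorescence-like texture confined below the vessel.

    A translation-invariant scene (a straight vessel over flat background)
    cannot anchor the along-vessel component of registration, just as a real
    recording without tissue landmarks cannot. The texture is a smoothed
    Gaussian random field clipped to stay nonnegative, placed strictly
    outside the default ROI zones so traces remain exactly the programmed
    waveform.
    """
    h, w = spec.image_shape
    if spec.texture_sigma == 0:
        return np.zeros((h, w))
    from scipy.ndimage import gaussian_filter
    field = gaussian_filter(rng.standard_normal((h, w)), spec.texture_smooth_px)
    field *= spec.texture_sigma / max(field.std(), 1e-12)
    y_bottom = max(y for _, y in spec.vessel_path) + spec.vessel_radius_px
    zone = np.zeros((h, w), dtype=bool)
    zone[int(np.ceil(y_bottom)) + 6:, :] = True
    return np.clip(field, -spec.background_level, None) * zone


def generate_vessel_movie(spec: VesselSimSpec):
    """Render the movie and its ground truth.

    Returns ``(stack, truth)``: a uint16 (T, H, W) stack and a
    :class:`VesselTruth`. With ``subpixel_jitter`` the per-frame shifts are
    continuous (linear interpolation renders them) and truth shifts hold
    the rounded integer part.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    n = proto.n_frames
    mask = _vessel_mask(spec)
    waveform = programmed_waveform(spec)
    texture = _texture_field(spec, rng)

    # integer random walk reflected at +/- max_drift_px, starting at 0
    shifts = np.zeros((n, 2), dtype=float)
    if spec.jitter_px > 0:
        steps = rng.integers(-spec.jitter_px, spec.jitter_px + 1, size=(n - 1, 2))
        if spec.subpixel_jitter:
            steps = steps + rng.uniform(-0.5, 0.5, size=steps.shape)
        pos = np.zeros(2)
        m = float(spec.max_drift_px)
        for t in range(1, n):
            pos = pos + steps[t - 1]
            pos = np.where(pos > m, 2 * m - pos, pos)
            pos = np.where(pos < -m, -2 * m - pos, pos)
            shifts[t] = pos

    stack = np.empty((n, *spec.image_shape), dtype=np.uint16)
    bg = spec.background_level
    for t in range(n):
        frame = bg * (~mask) + (bg + waveform[t]) * mask + texture
        dy, dx = shifts[t]
        if dy or dx:
            if spec.subpixel_jitter:
                from scipy.ndimage import shift as nd_shift
                frame = nd_shift(frame, (dy, dx), order=1, mode="constant",
                                 cval=bg)
            else:
                frame = shift_image(frame, int(dy), int(dx), fill=bg)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        stack[t] = np.clip(np.round(frame), 0, np.iinfo(np.uint16).max)

    vessels, background = default_rois(spec)
    truth = VesselTruth(
        shifts=np.round(shifts).astype(int),
        contraction_times_min=tuple(spec.contraction_times),
        contraction_amplitude_au=spec.contraction_amplitude,
        modulation_depth_pct=spec.modulation_depth_pct,
        waveform_au=waveform,
        frame_interval_s=proto.frame_interval_s,
        vessel_rois=vessels,
        background_roi=background,
    )
    return stack, truth


# --------------------------------------------------------------------------
# flow-cytometry EV event tables
# --------------------------------------------------------------------------

EVENT_COLUMNS = ["event_id", "FSC_H", "V_SSC_H", "CFSE_H", "CD31_H", "VEGFR3_H"]

#: EV gate on the violet side-scatter height channel, spanning the event
#: region the ~100-1000 nm silica bead ladder delimits (instrument units).
DEFAULT_EV_GATE = Gate("EV", {"V_SSC_H": (100.0, 1000.0)})
#: Count beads are bright, monodisperse and larger than the EV gate ceiling.
DEFAULT_BEAD_GATE = Gate("beads", {"FSC_H": (5000.0, 20000.0)})


@dataclass(frozen=True)
class EvSimSpec:
    """Ground truth and acquisition model for EV counting.

    ``acquired_fraction`` is the fraction of the tube the cytometer
    interrogates during the run; it links the true concentration to the
    expected number of recorded events and cancels out of the count-bead
    formula. All counts are Poisson, matching cytometer counting
    statistics.
    """

    true_ev_per_ml: float = 1.0e6
    bead_stock_count: int = 10_000
    sample_volume_ml: float = 0.1
    dilution_factor: float = 2.0
    background_events: float = 50.0
    triton_resistant_fraction: float = 0.2
    acquired_fraction: float = 0.2
    debris_events: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if min(self.true_ev_per_ml, self.bead_stock_count, self.background_events,
               self.debris_events) < 0:
            raise ValueError("counts and concentrations must be >= 0")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample_volume_ml must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not 0 <= self.triton_resistant_fraction <= 1:
            raise ValueError("triton_resistant_fraction must be in [0, 1]")
        if not 0 < self.acquired_fraction <= 1:
            raise ValueError("acquired_fraction must be in (0, 1]")

    @property
    def expected_ev_events(self) -> float:
        """Expected EV events in the gate, from the inverted formula."""
        return (self.true_ev_per_ml * self.sample_volume_ml
                / self.dilution_factor * self.acquired_fraction)

    @property
    def expected_bead_events(self) -> float:
        return self.bead_stock_count * self.acquired_fraction


@dataclass
class EvTruth:
    spec: EvSimSpec
    n_ev_sample: int
    n_background_sample: int
    n_beads_sample: int
    n_ev_triton: int
    ev_gate: Gate
    bead_gate: Gate


@dataclass
class EvSimResult:
    sample_table: pd.DataFrame
    background_table: pd.DataFrame
    triton_table: pd.DataFrame
    truth: EvTruth


def _event_rows(rng, n_ev, n_bg, n_debris, n_beads) -> pd.DataFrame:
    blocks = []
    if n_ev:
        blocks.append(pd.DataFrame({
            "FSC_H": rng.uniform(50, 450, n_ev),
            "V_SSC_H": rng.uniform(120, 950, n_ev),
            "CFSE_H": rng.uniform(300, 3000, n_ev),
            "CD31_H": rng.uniform(100, 1500, n_ev),
            "VEGFR3_H": rng.uniform(100, 1500, n_ev),
        }))
    if n_bg:  # reagent/antibody aggregates falling inside the EV gate
        blocks.append(pd.DataFrame({
            "FSC_H": rng.uniform(20, 200, n_bg),
            "V_SSC_H": rng.uniform(100, 1000, n_bg),
            "CFSE_H": rng.uniform(5, 80, n_bg),
            "CD31_H": rng.uniform(5, 120, n_bg),
            "VEGFR3_H": rng.uniform(5, 120, n_bg),
        }))
    if n_debris:  # sub-gate electronic noise / small debris
        blocks.append(pd.DataFrame({
            "FSC_H": rng.uniform(10, 120, n_debris),
            "V_SSC_H": rng.uniform(5, 95, n_debris),
            "CFSE_H": rng.uniform(1, 50, n_debris),
            "CD31_H": rng.uniform(1, 50, n_debris),
            "VEGFR3_H": rng.uniform(1, 50, n_debris),
        }))
    if n_beads:
        blocks.append(pd.DataFrame({
            "FSC_H": rng.uniform(6000, 15000, n_beads),
            "V_SSC_H": rng.uniform(1500, 4000, n_beads),
            "CFSE_H": rng.uniform(2000, 8000, n_beads),
            "CD31_H": rng.uniform(1, 50, n_beads),
            "VEGFR3_H": rng.uniform(1, 50, n_beads),
        }))
    if not blocks:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    table = pd.concat(blocks, ignore_index=True)
    table = table.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31))).reset_index(drop=True)
    table.insert(0, "event_id", np.arange(len(table)))
    return table[EVENT_COLUMNS]


def generate_ev_events(spec: EvSimSpec) -> EvSimResult:
    """Sample, reagent-only and detergent-lysed event tables + truth."""
    rng = np.random.default_rng(spec.seed)
    n_ev = int(rng.poisson(spec.expected_ev_events))
    n_bg_s = int(rng.poisson(spec.background_events))
    n_debris_s = int(rng.poisson(spec.debris_events))
    n_beads_s = int(rng.poisson(spec.expected_bead_events))
    sample = _event_rows(rng, n_ev, n_bg_s, n_debris_s, n_beads_s)

    n_bg_b = int(rng.poisson(spec.background_events))
    n_debris_b = int(rng.poisson(spec.debris_events))
    background = _event_rows(rng, 0, n_bg_b, n_debris_b, 0)

    n_ev_t = int(rng.poisson(
        spec.expected_ev_events * spec.triton_resistant_fraction))
    n_bg_t = int(rng.poisson(spec.background_events))
    n_debris_t = int(rng.poisson(spec.debris_events))
    n_beads_t = int(rng.poisson(spec.expected_bead_events))
    triton = _event_rows(rng, n_ev_t, n_bg_t, n_debris_t, n_beads_t)

    truth = EvTruth(spec=spec, n_ev_sample=n_ev, n_background_sample=n_bg_s,
                    n_beads_sample=n_beads_s, n_ev_triton=n_ev_t,
                    ev_gate=DEFAULT_EV_GATE, bead_gate=DEFAULT_BEAD_GATE)
    return EvSimResult(sample_table=sample, background_table=background,
                       triton_table=triton, truth=truth)


# --------------------------------------------------------------------------
# correlated two-channel volumes
# --------------------------------------------------------------------------


def generate_coloc_image(correlation: float, shape=(32, 64, 64), seed: int = 0):
    """Two same-shape channels whose sample Pearson coefficient tracks
    ``correlation`` (to ~1/sqrt(n_voxels)).

    With ``|correlation| == 1`` the second channel is an exact affine image
    of the first. Channels are floats on a realistic positive intensity
    scale; Pearson is affine-invariant so the scaling is free.
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(shape)
    ch1 = 1000.0 + 250.0 * z1
    if abs(correlation) == 1.0:
        ch2 = 1200.0 + np.copysign(300.0, correlation) * z1
        return ch1, ch2
    z2 = correlation * z1 + np.sqrt(1.0 - correlation ** 2) \
        * rng.standard_normal(shape)
    return ch1, 1200.0 + 300.0 * z2


# --------------------------------------------------------------------------
# feature matrices with planted fold changes
# --------------------------------------------------------------------------


@dataclass
class FeatureMatrixSim:
    intensities: pd.DataFrame   # features x samples, positive
    groups: pd.Series           # sample -> "control" | "treated"
    is_da: np.ndarray           # per-feature truth: planted fold change?
    fc_true: float


def generate_feature_matrix(
    n_features: int = 2139,
    n_da: int = 18,
    fc_true: float = 2.0,
    n_per_group: int = 3,
    sigma: float = 0.25,
    seed: int = 0,
) -> FeatureMatrixSim:
    """Log-normal feature intensities with ``n_da`` planted group changes.

    Per feature, log2 intensity is Gaussian with scale ``sigma`` around a
    feature-specific base level; planted features have their treated-group
    mean shifted by log2(fc_true), so the expected treated/control ratio of
    arithmetic means is exactly ``fc_true``. Defaults mirror an untargeted
    MS lipidomics matrix: 2139 features, 18 changed, triplicates.
    """
    if n_da > n_features:
        raise ValueError("n_da cannot exceed n_features")
    if fc_true <= 0 or sigma < 0 or n_per_group < 2:
        raise ValueError("fc_true > 0, sigma >= 0 and n_per_group >= 2 required")
    rng = np.random.default_rng(seed)
    base = rng.uniform(10.0, 20.0, size=n_features)
    is_da = np.zeros(n_features, dtype=bool)
    if n_da:
        is_da[rng.choice(n_features, size=n_da, replace=False)] = True
    effect = np.where(is_da, np.log2(fc_true), 0.0)

    cols, labels, data = [], [], []
    for grp, shift in (("control", 0.0), ("treated", 1.0)):
        for i in range(n_per_group):
            cols.append(f"{grp}_{i + 1}")
            labels.append(grp)
            log2_int = base + shift * effect \
                + rng.normal(0.0, sigma, size=n_features)
            data.append(2.0 ** log2_int)
    intensities = pd.DataFrame(
        np.column_stack(data), columns=cols,
        index=[f"feat_{i + 1:04d}" for i in range(n_features)])
    groups = pd.Series(labels, index=cols, name="group")
    return FeatureMatrixSim(intensities=intensities, groups=groups,
                            is_da=is_da, fc_true=fc_true)
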