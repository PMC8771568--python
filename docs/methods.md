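# Methods

`pulsekit` quantifies the phasic contractions of collecting lymphatic
vessels from intravital fluorescence time-lapse recordings, and implements
the companion quantifications such a study needs: absolute extracellular-
vesicle (EV) concentration from flow-cytometry events, whole-volume Pearson
colocalization, 2^-ddCT relative expression, MFI normalization, and
volcano-style discriminant-feature selection. This note records the models,
the defaults and why, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Contraction quantification

### Acquisition model

A recording is a single-channel stack (T x Y x X, 16-bit) with a uniform
frame interval. The default protocol is 326 frames over a 10-minute session
at 1 s exposure; frame count and session length are treated as independent
protocol constants, so the derived frame interval is 600/326 ≈ 1.84 s.
Exposure is metadata only — it does not enter any computation.

### Stabilization (`registration`)

Frames are aligned to the first frame by maximizing the zero-normalized
cross-correlation (ZNCC) between a template cut from the reference frame
(default: the central 50% crop) and a search window in each frame. ZNCC is
invariant to intensity offset and gain, which matters under fluorescence
drift and bleaching. Only integer-pixel translations within
`search_radius` are scored; ties are broken toward the smaller displacement
magnitude, then row-major (dy, dx) order, making results deterministic.
Stabilized frames are translated by the negative displacement with
zero-filled borders, and a per-frame validity mask marks the filled pixels
so ROI statistics exclude them. A zero-variance template makes the
correlation undefined and is rejected; frames whose best score falls below
0.5 are logged as probable out-of-range motion. Rotation, scaling and
subpixel optimization are out of scope; with the generator's opt-in
continuous jitter the integer result is tested to stay within one pixel of
the rounded truth.

### ROI traces (`trace_extraction`)

ROIs are polygons in 0-based pixel coordinates (x right, y down); pixel
(i, j) has its center at (x=j, y=i) and belongs to a polygon iff that
center is inside under the even-odd (ray crossing) rule. This one fixed
rasterization rule keeps masks exactly reproducible; it is implemented
directly (vectorized crossing test) and verified against a scalar
point-in-polygon scan. The trace is mean(vessel ROI) − mean(background
ROI) per frame, in arbitrary units (AU). One shared background ROI per
recording is the default (per-vessel backgrounds can be passed explicitly);
negative values are kept unclamped so detection sees true excursions.

### Peak/valley detection (`pulse_analysis`)

Detection is a hysteresis turning-point automaton. A running candidate
extremum is tracked; when the signal departs from it by at least the
threshold (default 40 AU) in the opposite direction, the candidate is
committed and the search direction reverses. The threshold is therefore a
**hysteresis magnitude**, not an absolute intensity level — an absolute
level could not serve peak-and-valley counting on traces with baseline
drift. Plateaus commit their first sample.

Boundary semantics, which dominate exact-count behavior:

* the initial extremum (the candidate the signal first departs from when
  the direction is established) is never committed — it belongs to the
  truncated segment before the first observed turning point, and under
  noise it does not sit exactly on sample 0;
* samples 0 and n−1 are never committed;
* a pending interior candidate when the trace ends **is** committed: the
  counter-excursion that established the current direction already exceeds
  the threshold, only the return leg is unobserved;
* the final sample never displaces a pending candidate. It cannot itself
  be confirmed, and with independent noise the running extremum of a flat
  tail would land on the last sample with probability 1/(tail length),
  randomly disqualifying an otherwise-confirmed event. A truncated
  excursion therefore commits at its best interior sample. This rule is
  threshold-free, which preserves the monotonicity of event counts in the
  threshold.

A recording with k complete contractions (dip and recovery) then yields
exactly k valleys and k peaks regardless of noise below the threshold,
which is what makes the frequency identity testable end-to-end.

Frequency is (Np + Nv) / (2·dt) contractions per minute. dt defaults to
the recorded duration (frames × interval) rather than a fixed 10 min, so
truncated recordings stay correct. Amplitude is the mean |peak − valley|
over adjacent committed pairs — both peak→valley and valley→peak orders
count, so the result is symmetric to whether the recording starts
contracted or relaxed — expressed as a percentage of the trace maximum.
With fewer than one pair, or a non-positive trace maximum, amplitude is a
missing value (NaN), never a fabricated 0.

`analyze_recording` chains register → extract → detect → summarize over
≥1 vessel ROIs (five in the standard protocol) plus exactly one background
ROI, and appends a recording-level mean row.

## Synthetic recordings (`synthetic_data`)

The generator renders a straight vessel (tube of half-width 4 px around a
polyline) at baseline 320 AU over a 20 AU background on a 64x64 field.
Each contraction is a raised-cosine dip of the vessel intensity: smooth,
one unambiguous extremum, and exactly one valley/peak pair for the
detector. Defaults: 6 events evenly spaced over the session (0.6/min, in
the physiological range for collecting vessels), 100 AU deep (33.3% of the
300 AU baseline trace) and 15 s wide. At the 1.84 s frame interval the
worst-case sampled dip depth is ~96% of the programmed depth, which bounds
the amplitude recovery error at ~4% before noise — inside the 5% test
band.

Field-of-view motion is an integer random walk (per-frame step up to
`jitter_px`, reflected at ±`max_drift_px` = 5) so registration truth is
exact; an opt-in flag makes the walk continuous. Noise is additive
Gaussian, clipped at zero and quantized to uint16. A static smoothed
random texture (50 AU scale) is placed strictly below the vessel, outside
every default ROI: without landmarks a straight vessel over flat
background is translation-invariant along its own axis and the along-vessel
shift component would be undetermined, exactly as in a real recording
without tissue structure. Every generator emits machine-readable truth
(shifts, event times, programmed waveform, modulation depth, default
ROIs); recovery tests consume only the data and compare to the truth.

What the movie does **not** model: optics (PSF, depth attenuation),
photobleaching, vessel diameter change (contraction is encoded as
intensity modulation only), lymph-flow physics, multi-vessel scenes.
Passing tests therefore demonstrate the correctness of the measurement
chain on its stated signal model, not robustness to every imaging
artifact.

## EV quantification (`ev_quant`)

Gates are rectangular closed intervals on pulse-height (-H) channels — the
EV gate spans the region a ~100–1000 nm silica bead ladder delimits on
violet side scatter. Counts convert to concentration via spiked count
beads:

    EV/mL = (n_EV-gate / n_bead-gate) · (total beads / volume_mL) · dilution

Reagent-only background is subtracted in count space at matched dilution,
clamped at zero (negative concentrations are unphysical; the clamp is
logged for QC). The detergent-lysis check reports the fractional drop of
gated events after Triton X-100, clamped to [0, 1], missing when no events
preceded lysis.

The simulator draws all counts as Poisson, matching cytometer counting
statistics. It adds one field the inversion needs that no published
protocol states: `acquired_fraction`, the fraction of the tube the
instrument interrogates during the run (default 0.2). It links the true
concentration to expected event counts and cancels exactly out of the
bead-ratio formula, so its value only sets counting depth. Defaults
(10^6 EV/mL true, 10^4 beads, 0.1 mL at 2x dilution, 50 expected
background events, 20% Triton-resistant events) give ~10^4 EV and ~2·10^3
bead events per run and a relative counting SD of ~2.5%, so a 3-SD
recovery test is sharp. Swarm/coincidence effects, compensation and
FCS 3.x binary parsing are out of scope (tables are CSV).

## Colocalization (`colocalization`)

One sample Pearson coefficient over all voxels of the volume ("whole
volume": no threshold, no Costes masking, no per-slice averaging), with an
optional boolean mask for, e.g., zero-filled registration borders. A
constant channel is an error (undefined coefficient), not a silent 0. The
generator produces channel pairs with a target coefficient by Gaussian
mixing (exact affine dependence at |r| = 1), calibrated to ±0.02 at
≥10^5 voxels.

## Group statistics (`group_stats`)

* `mfi_normalize`: treated MFI over its own control (control ≡ 1).
* `ddct_fold_change`: dCT = CT_target − CT_reference per condition,
  ddCT = dCT_treated − dCT_control, fold change 2^−ddCT; invariant to any
  constant CT offset.
* `bh_adjust`: Benjamini–Hochberg step-up (monotone, capped at 1), via
  statsmodels, verified against a brute-force step-up oracle.
* `discriminant_features`: per-feature two-sample t-test on log2
  intensities — equal-variance pooling by default ("Student's" rather than
  Welch; Welch via flag) — BH across all features, selection iff p below
  0.05 **and** the ratio of raw group means falls outside [0.8, 1.25].
  The p gate applies to BH-adjusted values by default; a raw-p mode is
  available and recorded in the output metadata, since published
  volcano-plot legends are often ambiguous on this point. Fold change is
  the ratio of arithmetic means of raw intensities, the common convention
  for MS volcano plots. Features with zero variance and zero mean
  difference get p = 1 (no evidence of effect), logged, not an error.

The matrix simulator plants log2-shifted group effects in a log-normal
intensity model (defaults 2139 features, 18 planted, triplicates,
sigma = 0.25 log2 units ≈ 19% CV, realistic for untargeted MS). Under the
global null the t-test p-values are exactly uniform and independent across
features, so BH's P(any rejection) = q exactly; the calibration test runs
1000 replicate matrices and checks the realized rate against 0.05 within
3 Monte-Carlo SDs. High-power recovery tests use sigma = 0.02 so planted
and null features separate by construction.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed gives bit-identical outputs, including CSV/TIFF bytes.
* Floating "exactness" for Pearson identity is asserted at |r − 1| ≤ 1e-12
  (the normalization arithmetic can land one ulp below 1 before clipping).
* The EV 3-SD recovery test runs 100 fixed seeds and requires ≥97 inside
  the 3-SD band plus a <1% mean relative error, since even a perfectly
  calibrated estimator leaves each seed outside 3 SDs with p ≈ 0.003.
* Problem sizes in the test suite (64x64 movies, 16x16 oracle stacks,
  10^5–10^6-voxel volumes, 1000 null matrices) were chosen so every
  stochastic check has sharp expected behavior while the whole suite runs
  in well under a minute on one CPU.

## Known limitations

* Detection counts a truncated-but-confirmed trailing excursion as an
  event; software that requires a full return leg will report one fewer
  peak on such traces (frequency lower by 1/(2·dt)).
* Registration is translation-only; rotation or focus drift will surface
  as low match scores rather than being corrected.
* The EV size gate is taken as given (bead-ladder calibration table);
  no scatter-to-size modeling is attempted.
* Colocalization offers no statistical significance (no Costes
  randomization) — the coefficient is descriptive, as in the motivating
  use.
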