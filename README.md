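# pulsekit

Quantification of collecting lymphatic-vessel contraction from intravital
fluorescence time-lapse recordings, with the companion analyses such a
study needs: absolute extracellular-vesicle (EV) counting from
flow-cytometry events, whole-volume Pearson colocalization, 2^-ΔΔCT
relative expression, MFI normalization, and t-test/Benjamini–Hochberg/
fold-change discriminant-feature selection.

Collecting lymphatic vessels pump lymph by phasic contractions. After a
fluorescent tracer is injected into the dermis, the vessel's fluorescence
trace oscillates with each contraction; counting the peaks (Np) and
valleys (Nv) of that trace gives the contraction frequency

    f = (Np + Nv) / (2 · dt)      [contractions per minute]

where dt is the analysis time in minutes, while the mean peak-to-valley
intensity change, expressed as a percentage of the maximum intensity of
the region of interest (ROI), gives the contraction amplitude. `pulsekit`
implements the full measurement chain:

1. **registration** — stabilize the stack by zero-normalized
   cross-correlation template matching (integer shifts, deterministic
   tie-breaks, validity mask for exposed borders);
2. **trace_extraction** — rasterize polygonal vessel/background ROIs
   (pixel-center even-odd rule) and compute background-subtracted mean
   intensity traces;
3. **pulse_analysis** — hysteresis peak/valley detection (default
   threshold 40 AU), frequency and amplitude per ROI;
4. **ev_quant** — rectangular gating of event tables, reagent-background
   subtraction, count-bead concentration formula, detergent-lysis check;
5. **colocalization** — whole-volume Pearson coefficient of two channels;
6. **group_stats** — MFI normalization, 2^-ΔΔCT, BH adjustment and
   volcano-style feature selection;
7. **synthetic_data** — generators for every input above with exact,
   machine-readable ground truth, so the whole pipeline is testable
   without any external data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate a standard 10-minute session (326 frames, ~1.84 s frame
interval) with six programmed contractions, field-of-view jitter and
noise, then analyze it:

```sh
pulsekit simulate --seed 1 --out-dir demo
pulsekit analyze --stack demo/movie.tif --rois demo/rois.json \
    --threshold 40 --out demo/metrics.csv
```

which prints

```
  roi  Np  Nv  dt_min  freq_per_min  amplitude_pct     max_au
roi_1 6.0 6.0    10.0           0.6      33.349768 302.604202
roi_2 6.0 6.0    10.0           0.6      33.262284 302.756723
roi_3 6.0 6.0    10.0           0.6      33.290289 302.376681
roi_4 6.0 6.0    10.0           0.6      33.259164 302.439496
roi_5 6.0 6.0    10.0           0.6      33.130195 303.021849
 mean 6.0 6.0    10.0           0.6      33.258340 302.639790
```

Each of the five vessel ROIs recovers the six programmed contraction
events exactly (Np = Nv = 6), hence a frequency of 0.6 contractions per
minute over the 10-minute analysis window, and an amplitude of ~33.3% —
the generator's programmed modulation depth (100 AU dip on a 300 AU
baseline trace). The same chain is available from Python:

```python
from pulsekit import (VesselSimSpec, generate_vessel_movie,
                      analyze_recording, PulseConfig)

spec = VesselSimSpec(jitter_px=2, noise_sigma=5.0, seed=1)
stack, truth = generate_vessel_movie(spec)
table = analyze_recording(stack, [*truth.vessel_rois, truth.background_roi],
                          PulseConfig(threshold_au=40.0),
                          frame_interval_s=truth.frame_interval_s)
```

Other subcommands: `pulsekit register` (stabilization only),
`pulsekit evquant` (EV/mL from event CSVs and gate JSONs),
`pulsekit coloc` (Pearson coefficient of two TIFFs), `pulsekit ddct`
(relative expression from a CT table) and `pulsekit volcano`
(discriminant-feature selection from a feature matrix). Every output
carries a metadata block with the tool version, a configuration hash and
the seed.

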