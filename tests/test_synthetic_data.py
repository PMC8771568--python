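import numpy as np
import pytest

from pulsekit import (AcquisitionProtocol, EvSimSpec, VesselSimSpec,
                      generate_coloc_image, generate_ev_events,
                      generate_feature_matrix, generate_vessel_movie,
                      pearson_coloc)
from pulsekit.synthetic_data import (DEFAULT_BEAD_GATE, DEFAULT_EV_GATE,
                                     programmed_waveform)
from pulsekit.ev_quant import apply_gate


class TestAcquisitionProtocol:
    def test_default_session(self):
        proto = AcquisitionProtocol()
        assert proto.n_frames == 326
        assert proto.duration_min == 10.0
        assert proto.exposure_s == 1.0
        assert proto.frame_interval_s == pytest.approx(600.0 / 326)

    @pytest.mark.parametrize("kwargs", [
        {"n_frames": 1}, {"duration_min": 0}, {"exposure_s": -1},
    ])
    def test_invalid_protocol_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionProtocol(**kwargs)


class TestVesselMovie:
    def test_static_scene_without_variation_sources(self, quick_protocol):
        spec = VesselSimSpec(protocol=quick_protocol, jitter_px=0,
                             noise_sigma=0.0, contraction_times=(),
                             contraction_amplitude=1.0)
        stack, truth = generate_vessel_movie(spec)
        assert (stack == stack[0]).all()
        assert (truth.shifts == 0).all()

    def test_movie_matches_spec_and_truth_closure(self, clean_movie):
        spec, stack, truth = clean_movie
        assert stack.shape == (326, *spec.image_shape)
        assert stack.dtype == np.uint16
        assert len(truth.waveform_au) == 326
        assert truth.contraction_times_min == spec.contraction_times
        # waveform extremes encode the programmed modulation depth
        depth = (truth.waveform_au.max() - truth.waveform_au.min()) \
            / truth.waveform_au.max() * 100
        assert depth == pytest.approx(spec.modulation_depth_pct, rel=0.05)

    def test_background_region_mean(self, clean_movie):
        spec, stack, truth = clean_movie
        from pulsekit import rasterize_roi
        bg = rasterize_roi(truth.background_roi, stack.shape[1:])
        assert stack[0][bg].mean() == pytest.approx(spec.background_level, abs=1.0)

    def test_seed_determinism(self, quick_protocol):
        spec = VesselSimSpec(protocol=quick_protocol, jitter_px=2,
                             noise_sigma=5.0, seed=42)
        s1, t1 = generate_vessel_movie(spec)
        s2, t2 = generate_vessel_movie(spec)
        assert (s1 == s2).all()
        assert (t1.shifts == t2.shifts).all()

    def test_vessel_path_must_fit_image(self):
        with pytest.raises(ValueError, match="image too small"):
            VesselSimSpec(image_shape=(16, 16))

    def test_contraction_times_within_recording(self):
        with pytest.raises(ValueError):
            VesselSimSpec(contraction_times=(11.0,))

    def test_programmed_waveform_baseline_and_dip(self):
        spec = VesselSimSpec(contraction_times=(5.0,), seed=0)
        wf = programmed_waveform(spec)
        base = spec.baseline_intensity - spec.background_level
        assert wf[0] == pytest.approx(base)
        assert wf.min() == pytest.approx(base - spec.contraction_amplitude,
                                         abs=0.05 * spec.contraction_amplitude)


class TestEvEvents:
    def test_zero_ev_zero_background_gives_empty_gate(self):
        spec = EvSimSpec(true_ev_per_ml=0.0, background_events=0.0, seed=1)
        res = generate_ev_events(spec)
        assert apply_gate(res.sample_table, DEFAULT_EV_GATE) == 0

    def test_seed_determinism(self):
        r1 = generate_ev_events(EvSimSpec(seed=5))
        r2 = generate_ev_events(EvSimSpec(seed=5))
        for a, b in ((r1.sample_table, r2.sample_table),
                     (r1.triton_table, r2.triton_table)):
            assert a.equals(b)

    def test_gate_counts_match_truth(self):
        res = generate_ev_events(EvSimSpec(seed=9))
        truth = res.truth
        n_gate = apply_gate(res.sample_table, DEFAULT_EV_GATE)
        assert n_gate == truth.n_ev_sample + truth.n_background_sample
        assert apply_gate(res.sample_table, DEFAULT_BEAD_GATE) == truth.n_beads_sample

    def test_triton_table_scales_with_resistant_fraction(self):
        spec = EvSimSpec(triton_resistant_fraction=0.2, seed=13)
        res = generate_ev_events(spec)
        expected = spec.expected_ev_events * 0.2
        assert res.truth.n_ev_triton == pytest.approx(
            expected, abs=4 * np.sqrt(expected))

    @pytest.mark.parametrize("kwargs", [
        {"dilution_factor": 0.5}, {"triton_resistant_fraction": 1.5},
        {"sample_volume_ml": 0.0}, {"acquired_fraction": 0.0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvSimSpec(**kwargs)


class TestColocImage:
    def test_perfect_correlation_is_affine(self):
        ch1, ch2 = generate_coloc_image(1.0, shape=(50, 50), seed=2)
        fit = np.polyfit(ch1.ravel(), ch2.ravel(), 1)
        assert np.allclose(np.polyval(fit, ch1), ch2)

    @pytest.mark.parametrize("target", [0.0, 0.5, 0.8])
    def test_generator_calibration(self, target):
        ch1, ch2 = generate_coloc_image(target, shape=(48, 64, 64), seed=3)
        r = pearson_coloc(ch1, ch2).pearson_r
        assert r == pytest.approx(target, abs=0.02)

    def test_independent_channels_decorrelated_at_scale(self):
        ch1, ch2 = generate_coloc_image(0.0, shape=(100, 100, 100), seed=4)
        assert abs(pearson_coloc(ch1, ch2).pearson_r) < 0.01

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            generate_coloc_image(1.5, shape=(8, 8))


class TestFeatureMatrix:
    def test_no_planted_changes_means_all_negative_truth(self):
        sim = generate_feature_matrix(n_features=50, n_da=0, seed=1)
        assert not sim.is_da.any()

    def test_planted_ratio_of_means(self):
        sim = generate_feature_matrix(n_features=400, n_da=200, fc_true=2.0,
                                      n_per_group=40, sigma=0.1, seed=6)
        ratio = (sim.intensities.loc[sim.is_da, sim.groups == "treated"]
                 .mean(axis=1)
                 / sim.intensities.loc[sim.is_da, sim.groups == "control"]
                 .mean(axis=1))
        assert ratio.mean() == pytest.approx(2.0, rel=0.05)

    def test_seed_determinism(self):
        a = generate_feature_matrix(n_features=30, n_da=5, seed=7)
        b = generate_feature_matrix(n_features=30, n_da=5, seed=7)
        assert a.intensities.equals(b.intensities)
        assert (a.is_da == b.is_da).all()

    def test_matrix_shape_and_positivity(self):
        sim = generate_feature_matrix(n_features=100, n_da=10, n_per_group=4,
                                      seed=8)
        assert sim.intensities.shape == (100, 8)
        assert (sim.intensities.to_numpy() > 0).all()
        assert sim.groups.value_counts().to_dict() == {"control": 4, "treated": 4}
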