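"""Synthetic dataset generation and x-t rendering."""

import numpy as np
import pytest

from spikefit.fitting import FitSettings, fit_spike
from spikefit.model import SpikeParams, evaluate_spike
from spikefit.scantime import ScanConfig, build_pixel_time_map
from spikefit.simulate import (
    FLUO3,
    OG5N,
    DatasetSpec,
    IndicatorPreset,
    draw_spike_params,
    make_dataset,
    noise_sd_for_snr,
    render_xt_image,
)


class TestPresets:
    def test_snr_grids(self):
        assert OG5N.snr_grid_type3 == (1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0)
        assert FLUO3.snr_grid_type3 == (1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0)

    def test_og5n_population_snr_matches_published_aggregates(self):
        # calibration check: mean amplitude / 0.15-RMS noise ~ 5.39 +/- 2.11
        from spikefit.model import compute_descriptors
        ps = draw_spike_params(OG5N, 2000, seed=11)
        snr = np.array([compute_descriptors(p).A for p in ps]) / OG5N.noise_rms_type1
        assert snr.mean() == pytest.approx(5.39, abs=0.25)
        assert snr.std() == pytest.approx(2.11, abs=0.30)


class TestDrawParams:
    def test_zero_sds_reproduce_means(self):
        preset = IndicatorPreset(
            name="degenerate", param_means=OG5N.param_means,
            param_sds=dict.fromkeys(("t0", "FM", "alpha", "tauA", "tauT"), 0.0),
            noise_rms_type1=0.15, snr_grid_type3=(1.0,),
        )
        for p in draw_spike_params(preset, 5, seed=1):
            assert p == OG5N.param_means

    def test_sample_means_within_clt_bounds(self):
        ps = draw_spike_params(OG5N, 10_000, seed=3)
        fm = np.array([p.FM for p in ps])
        se = OG5N.param_sds["FM"] / np.sqrt(len(fm))
        # slight upward shift from rejection of negative draws is << 3 SE here
        assert fm.mean() == pytest.approx(OG5N.param_means.FM, abs=3 * se + 1e-3)

    def test_same_seed_identical(self):
        assert draw_spike_params(OG5N, 20, seed=7) == draw_spike_params(OG5N, 20, seed=7)

    def test_draws_respect_invariants(self):
        for p in draw_spike_params(FLUO3, 500, seed=9):
            p.validate()


class TestNoiseForSnr:
    def test_arithmetic(self):
        assert noise_sd_for_snr(0.8, 4.0) == pytest.approx(0.2)

    def test_limit(self):
        assert noise_sd_for_snr(0.8, 1e9) < 1e-9

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            noise_sd_for_snr(0.8, 0.0)

    def test_og5n_type1_implies_mean_amplitude(self):
        # sigma = 0.15 with mean SNR 5.39 inverts to A ~ 0.81
        assert noise_sd_for_snr(OG5N.mean_amplitude(), OG5N.mean_amplitude() / 0.15) == pytest.approx(0.15)
        assert OG5N.mean_amplitude() == pytest.approx(0.81, abs=0.02)


class TestMakeDataset:
    def test_dataset_is_pure_function_of_spec(self):
        spec = DatasetSpec(dataset_type=1, preset=OG5N, n_traces=4, seed=5)
        a, b = make_dataset(spec), make_dataset(spec)
        for (ta, pa), (tb, pb) in zip(a, b):
            assert np.array_equal(ta.values, tb.values) and pa == pb

    def test_type2_noise_sd_centered_on_nominal(self):
        ds = make_dataset(DatasetSpec(dataset_type=2, preset=OG5N, n_traces=50, seed=6))
        sds = np.array([tr.values.std() for tr, truth in ds])
        assert all(truth is None for _, truth in ds)
        assert sds.mean() == pytest.approx(0.15, rel=0.02)

    def test_type3_empirical_snr_matches_request(self):
        snr = 5.0
        ds = make_dataset(DatasetSpec(dataset_type=3, preset=OG5N, n_traces=50, seed=8, snr=snr))
        sigma = noise_sd_for_snr(OG5N.mean_amplitude(), snr)
        empirical = np.array([tr.baseline_sd for tr, _ in ds])
        assert empirical.mean() == pytest.approx(sigma, rel=0.05)
        assert all(t == OG5N.param_means for _, t in ds)

    def test_noise_sd_accurate_over_many_samples(self):
        ds = make_dataset(DatasetSpec(dataset_type=2, preset=OG5N, n_traces=2000, seed=17))
        pooled = np.concatenate([tr.values for tr, _ in ds])  # ~1e6 samples
        assert pooled.std() == pytest.approx(0.15, rel=0.005)

    def test_type1_zero_noise_fits_recover_truth(self):
        quiet = IndicatorPreset(name="quiet", param_means=OG5N.param_means,
                                param_sds=OG5N.param_sds, noise_rms_type1=0.0,
                                snr_grid_type3=OG5N.snr_grid_type3)
        ds = make_dataset(DatasetSpec(dataset_type=1, preset=quiet, n_traces=3, seed=12))
        for trace, truth in ds:
            fit = fit_spike(trace, FitSettings(init=truth))
            assert np.allclose(fit.params.as_array(), truth.as_array(), rtol=1e-6)

    def test_type3_requires_snr(self):
        with pytest.raises(ValueError):
            DatasetSpec(dataset_type=3, preset=OG5N, n_traces=10, seed=1)


class TestRenderImage:
    def test_no_spikes_no_noise_is_flat(self):
        cfg = ScanConfig(mode="unidirectional", f=1000, n=32, m=40, tp=0.5)
        img = render_xt_image([], cfg, baseline=100.0, background=7.0)
        assert np.all(img.pixels == 107.0)

    def test_flat_profile_copies_time_course_to_every_column(self):
        cfg = ScanConfig(mode="unidirectional", f=1000, n=32, m=60, tp=0.5)
        p = SpikeParams(t0=5.0, FM=2.0, alpha=0.05, tauA=2.0, tauT=4.0)
        img = render_xt_image([(p, 16)], cfg, baseline=100.0, background=0.0,
                              spatial_sd=np.inf)
        tm = build_pixel_time_map(cfg)
        for j in (0, 10, 31):
            expected = 100.0 * (1.0 + evaluate_spike(p, tm.times[:, j]))
            assert np.allclose(img.pixels[:, j], expected, atol=1e-9)

    def test_spike_column_must_be_inside_image(self):
        cfg = ScanConfig(mode="unidirectional", f=1000, n=32, m=40, tp=0.5)
        p = SpikeParams(t0=5.0, FM=2.0, alpha=0.05, tauA=2.0, tauT=4.0)
        with pytest.raises(ValueError):
            render_xt_image([(p, 40)], cfg)
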