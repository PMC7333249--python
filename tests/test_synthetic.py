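"""Synthetic canopy generator: leaf N distribution, spectral structure,
noise model, and the calibration/validation split."""

import numpy as np
import pytest

from nspec import (
    ConfigurationError,
    SimulationConfig,
    SizeError,
    SpectralDataset,
    clean_spectra,
    simulate_dataset,
    simulate_leaf_n,
    simulate_spectra,
    split_dataset,
    truncated_normal_moments,
)


class TestLeafN:
    def test_values_respect_truncation_bounds(self):
        cfg = SimulationConfig(n_samples=315, seed=3)
        values = simulate_leaf_n(cfg)
        assert values.size == 315
        assert values.min() >= cfg.n_min
        assert values.max() <= cfg.n_max

    def test_moments_match_truncated_normal_quadrature(self):
        # Monte-Carlo draw against the numerically integrated truncated
        # density; note truncation shrinks the SD below the parent 1.24.
        cfg = SimulationConfig(n_samples=10_000, seed=5)
        values = simulate_leaf_n(cfg)
        mean_o, sd_o = truncated_normal_moments(
            cfg.n_mean, cfg.n_sd, cfg.n_min, cfg.n_max
        )
        assert abs(values.mean() - mean_o) < 0.05
        assert abs(values.std(ddof=1) - sd_o) < 0.08

    def test_zero_sd_degenerates_to_constant(self):
        cfg = SimulationConfig(n_samples=50, n_sd=0.0, seed=0)
        assert np.all(simulate_leaf_n(cfg) == cfg.n_mean)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_min=6.0, n_max=2.0)


class TestSpectra:
    def test_deterministic_construction_orders_two_samples(self):
        # visible reflectance higher at low N; NIR higher at high N
        cfg = SimulationConfig(
            n_samples=2, noise_sd=0.0, drift_amplitude=0.0,
            structure_jitter_sd=0.0, seed=0,
        )
        ds = simulate_spectra(np.array([2.0, 5.0]), cfg)
        i550 = int(np.searchsorted(ds.wavelengths, 550.0))
        i850 = int(np.searchsorted(ds.wavelengths, 850.0))
        assert ds.reflectance[0, i550] > ds.reflectance[1, i550]
        assert ds.reflectance[1, i850] > ds.reflectance[0, i850]

    def test_clean_spectra_monotone_in_leaf_n(self):
        # non-increasing at every visible band, non-decreasing at every NIR band
        cfg = SimulationConfig(seed=0)
        n_grid = np.linspace(cfg.n_min, cfg.n_max, 40)
        clean = clean_spectra(n_grid, cfg)
        wl = cfg.wavelength_grid()
        diffs = np.diff(clean, axis=0)
        assert (diffs[:, wl <= 700] <= 1e-12).all()
        assert (diffs[:, wl >= 750] >= -1e-12).all()

    def test_default_grid_has_551_bands_in_unit_interval(self, default_dataset):
        assert default_dataset.n_bands == 551
        assert default_dataset.wavelengths[0] == 400
        assert default_dataset.wavelengths[-1] == 950
        assert default_dataset.reflectance.min() > 0
        assert default_dataset.reflectance.max() < 1

    def test_scan_averaging_shrinks_noise_by_sqrt_n_scans(self):
        # identical seed shares the underlying standard-normal field, so the
        # residual SD ratio between 1 and 60 scans is sqrt(60) band-wise
        base = dict(n_samples=40, drift_amplitude=0.0, structure_jitter_sd=0.0, seed=9)
        leaf = simulate_leaf_n(SimulationConfig(**base))
        noise_free = simulate_spectra(
            leaf, SimulationConfig(**base, noise_sd=0.0)
        ).reflectance
        one = simulate_spectra(
            leaf, SimulationConfig(**base, noise_sd=0.004, scans_per_sample=1)
        ).reflectance
        sixty = simulate_spectra(
            leaf, SimulationConfig(**base, noise_sd=0.004, scans_per_sample=60)
        ).reflectance
        # avoid bands touched by clipping
        interior = ((one > 1e-3) & (one < 1 - 1e-3)).all(axis=0)
        sd1 = (one - noise_free)[:, interior].std(axis=0)
        sd60 = (sixty - noise_free)[:, interior].std(axis=0)
        assert np.allclose(sd1 / sd60, np.sqrt(60), rtol=1e-9)

    def test_bit_identical_under_same_config(self):
        cfg = SimulationConfig(n_samples=30, seed=21)
        a = simulate_dataset(cfg)
        b = simulate_dataset(SimulationConfig(n_samples=30, seed=21))
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.leaf_n, b.leaf_n)

    def test_rejects_nonpositive_leaf_n(self):
        cfg = SimulationConfig(n_samples=2, seed=0)
        with pytest.raises(Exception):
            simulate_spectra(np.array([2.0, -1.0]), cfg)


class TestSplit:
    def test_study_partition_is_disjoint(self, default_dataset):
        cal, val = split_dataset(default_dataset, 165, 150, seed=4)
        assert cal.n_samples == 165 and val.n_samples == 150
        assert not set(cal.sample_ids) & set(val.sample_ids)
        assert set(cal.sample_ids) | set(val.sample_ids) == set(
            default_dataset.sample_ids
        )

    def test_empty_calibration_allowed(self, default_dataset):
        cal, val = split_dataset(default_dataset, 0, 10, seed=0)
        assert cal.n_samples == 0 and val.n_samples == 10

    def test_same_seed_reproduces_partition(self, default_dataset):
        a = split_dataset(default_dataset, 100, 100, seed=8)
        b = split_dataset(default_dataset, 100, 100, seed=8)
        assert a[0].sample_ids == b[0].sample_ids
        assert a[1].sample_ids == b[1].sample_ids

    def test_oversized_request_rejected(self, default_dataset):
        with pytest.raises(SizeError):
            split_dataset(default_dataset, 300, 100, seed=0)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_samples=5, seed=2)
        ds = simulate_dataset(cfg)
        path = tmp_path / "spectra.csv"
        ds.to_csv(path)
        back = SpectralDataset.from_csv(path)
        assert back.domain_tag == "reflectance"
        assert np.allclose(back.reflectance, ds.reflectance)
        assert np.allclose(back.leaf_n, ds.leaf_n)
        assert back.sample_ids == ds.sample_ids

    def test_csv_preserves_domain_tag_comment(self, tmp_path):
        from nspec import first_derivative

        ds = simulate_dataset(SimulationConfig(n_samples=3, seed=2))
        fdr = first_derivative(ds)
        path = tmp_path / "fdr.csv"
        fdr.to_csv(path)
        assert path.read_text(encoding="utf-8").startswith("# domain_tag: fdr")
        back = SpectralDataset.from_csv(path)
        assert back.domain_tag == "fdr"
        assert np.allclose(back.reflectance, fdr.reflectance)

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_samples: 12\nseed: 99\nnoise_sd: 0.002\n", encoding="utf-8")
        cfg = SimulationConfig.from_yaml(path)
        assert (cfg.n_samples, cfg.seed, cfg.noise_sd) == (12, 99, 0.002)
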