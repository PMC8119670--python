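"""Synthetic paired-image generator: determinism, mixture structure, geometry."""

import numpy as np
import pytest

import livedead as ld
from livedead import labeling
from livedead.synthetic import is_bimodal


def _patch_means(pair, stride=224):
    return [labeling.mean_fluorescence(p.fluorescence)
            for p in ld.crop_patches(pair, stride=stride)]


class TestGenerateRawPair:
    def test_no_dead_cells_no_noise_gives_background_only_fluorescence(self):
        cfg = ld.SyntheticConfig(n_raw_images=1, image_width=448,
                                 image_height=448, frac_dead_cells=0.0,
                                 frac_empty_regions=0.0, noise_sd=0.0,
                                 cells_per_image=(4, 8), rng_seed=1)
        pair, records = ld.generate_raw_pair(cfg, 0)
        # no PI signal: each region is flat at its low-component background
        for r in records:
            tile = pair.fluorescence[r.y0:r.y1, r.x0:r.x1]
            assert tile.max() - tile.min() <= 1  # only rounding jitter

    def test_all_dead_patch_means_land_in_high_component_territory(self):
        # well-separated mixture: dead-region means stay far above the
        # live-side cut-off mu_live + sigma_live
        mix = ld.FluorMixture(mu_live=200.0, sigma_live=20.0,
                              mu_dead=900.0, sigma_dead=40.0)
        cfg = ld.SyntheticConfig(n_raw_images=1, image_width=672,
                                 image_height=448, frac_dead_cells=1.0,
                                 frac_empty_regions=0.0, fluor_mixture=mix,
                                 cells_per_image=(12, 24), rng_seed=2)
        pair, _ = ld.generate_raw_pair(cfg, 0)
        live_max = mix.mu_live + mix.sigma_live
        # brute-force pixel-average oracle over every cropped patch
        for p in ld.crop_patches(pair, stride=112):
            oracle_mean = float(np.asarray(p.fluorescence, dtype=float).sum()
                                / p.fluorescence.size)
            assert oracle_mean > live_max

    def test_same_seed_and_index_is_bit_identical(self):
        cfg = ld.SyntheticConfig(n_raw_images=1, image_width=448,
                                 image_height=224, rng_seed=5)
        a, _ = ld.generate_raw_pair(cfg, 3)
        b, _ = ld.generate_raw_pair(cfg, 3)
        assert np.array_equal(a.bright_field, b.bright_field)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        c, _ = ld.generate_raw_pair(cfg, 4)
        assert not np.array_equal(a.fluorescence, c.fluorescence)

    def test_too_small_dimensions_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            ld.SyntheticConfig(image_width=128, image_height=448)

    def test_every_region_has_exactly_one_record(self):
        cfg = ld.SyntheticConfig(n_raw_images=1, image_width=672,
                                 image_height=672, rng_seed=0)
        pair, records = ld.generate_raw_pair(cfg, 0)
        covered = np.zeros(pair.shape, dtype=int)
        for r in records:
            covered[r.y0:r.y1, r.x0:r.x1] += 1
        assert (covered == 1).all()


class TestSampleFluorescenceMeans:
    def test_reference_parameters_give_bimodal_histogram(self, reference_mixture):
        draws = ld.sample_fluorescence_means(reference_mixture, 5000, seed=0)
        assert is_bimodal(draws)

    def test_zero_sigma_draws_equal_the_means(self):
        mix = ld.FluorMixture(mu_live=100.0, sigma_live=0.0,
                              mu_dead=500.0, sigma_dead=0.0)
        draws = ld.sample_fluorescence_means(mix, 200, seed=1)
        assert set(np.round(draws, 9)) <= {100.0, 500.0}

    def test_sample_mean_matches_analytic_mixture_mean(self, reference_mixture):
        n = 10_000
        draws = ld.sample_fluorescence_means(reference_mixture, n, seed=2)
        mix = reference_mixture
        # closed-form mixture moments
        analytic_mean = mix.mean
        second = (mix.weight_live * (mix.sigma_live**2 + mix.mu_live**2)
                  + (1 - mix.weight_live) * (mix.sigma_dead**2 + mix.mu_dead**2))
        analytic_sd = np.sqrt(second - analytic_mean**2)
        se = analytic_sd / np.sqrt(n)
        assert abs(draws.mean() - analytic_mean) < 3 * se

    def test_n_must_be_positive(self, reference_mixture):
        with pytest.raises(ValueError):
            ld.sample_fluorescence_means(reference_mixture, 0, seed=0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ld.FluorMixture(sigma_live=-1.0)


class TestDatasetProperties:
    def test_identical_config_gives_identical_dataset(self, tmp_path):
        cfg = ld.SyntheticConfig(n_raw_images=2, image_width=448,
                                 image_height=224, rng_seed=9)
        pairs_a, gt_a = ld.generate_dataset(cfg, tmp_path / "a")
        pairs_b, gt_b = ld.generate_dataset(cfg, tmp_path / "b")
        for pa, pb in zip(pairs_a, pairs_b):
            assert np.array_equal(pa.bright_field, pb.bright_field)
            assert np.array_equal(pa.fluorescence, pb.fluorescence)
        assert gt_a.drop(columns=[]).equals(gt_b)

    def test_config_round_trips_through_json(self, tmp_path):
        cfg = ld.SyntheticConfig(n_raw_images=2, image_width=448,
                                 image_height=224, rng_seed=9)
        ld.generate_dataset(cfg, tmp_path / "d")
        text = (tmp_path / "d" / "config.json").read_text()
        assert ld.SyntheticConfig.from_json(text) == cfg

    def test_nonempty_patch_means_are_bimodal_when_separated(self):
        mix = ld.FluorMixture(mu_live=200.0, sigma_live=30.0,
                              mu_dead=800.0, sigma_dead=60.0)
        cfg = ld.SyntheticConfig(n_raw_images=12, image_width=672,
                                 image_height=448, frac_dead_cells=0.5,
                                 frac_empty_regions=0.0, fluor_mixture=mix,
                                 cells_per_image=(12, 24), rng_seed=13)
        assert mix.mu_dead - mix.mu_live > 3 * max(mix.sigma_live, mix.sigma_dead)
        means = []
        for i in range(cfg.n_raw_images):
            pair, _ = ld.generate_raw_pair(cfg, i)
            means.extend(_patch_means(pair))
        assert is_bimodal(np.array(means))

    def test_empty_region_fraction_within_binomial_3_sigma(self):
        frac = 0.2
        cfg = ld.SyntheticConfig(n_raw_images=30, image_width=672,
                                 image_height=448, frac_empty_regions=frac,
                                 rng_seed=17)
        n_empty = 0
        n_total = 0
        for i in range(cfg.n_raw_images):
            _, records = ld.generate_raw_pair(cfg, i)
            n_total += len(records)
            n_empty += sum(r.empty for r in records)
        sd = np.sqrt(frac * (1 - frac) * n_total)
        assert abs(n_empty - frac * n_total) < 3 * sd
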