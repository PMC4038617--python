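import numpy as np
import pytest

from ricenest.grids import DEFAULT_SCHEME, Grid
from ricenest.refine import fit_base_classifier, predict_rule_stack, relabel_max_posterior
from ricenest.synth import (
    SuitabilityRules,
    default_class_spectra,
    default_suitability_rules,
    generate_band_stack,
    generate_dem,
    generate_nest_pattern,
    generate_sample_plots,
    generate_true_landcover,
    patchy_habitat,
)
from ricenest.terrain import classify_terrain_position


class TestGenerateDem:
    def test_infinite_smoothness_gives_constant_midpoint(self):
        dem = generate_dem(16, 16, 30.0, (370.0, 2400.0), smoothness=np.inf)
        assert np.all(dem.values == 0.5 * (370.0 + 2400.0))

    def test_same_seed_bit_identical(self):
        a = generate_dem(32, 32, 30.0, seed=7)
        b = generate_dem(32, 32, 30.0, seed=7)
        assert np.array_equal(a.values, b.values)
        c = generate_dem(32, 32, 30.0, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_relief_confined_to_range(self):
        dem = generate_dem(64, 64, 30.0, (370.0, 2400.0), seed=1)
        assert dem.values.min() >= 370.0 and dem.values.max() <= 2400.0

    @pytest.mark.parametrize("kwargs", [
        {"nrows": 0, "ncols": 4}, {"nrows": 4, "ncols": -1},
    ])
    def test_nonpositive_dimensions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_dem(cell_size=30.0, **kwargs)

    def test_bad_relief_range_rejected(self):
        with pytest.raises(ValueError):
            generate_dem(4, 4, 30.0, relief_range=(500.0, 500.0))


class TestGenerateLandcover:
    def _grids(self, seed=0):
        dem = generate_dem(50, 50, 100.0, seed=seed)
        terr = classify_terrain_position(dem, 5)
        return dem, terr

    def test_point_mass_on_forest_everywhere(self):
        dem, terr = self._grids()
        forest = np.zeros(7)
        forest[DEFAULT_SCHEME.code("forest")] = 1.0
        rules = SuitabilityRules((700.0, 1400.0),
                                 {(b, t): forest for b in range(3) for t in range(5)})
        truth = generate_true_landcover(dem, terr.grid, suitability_rules=rules, seed=1)
        assert np.all(truth.values == DEFAULT_SCHEME.code("forest"))

    def test_point_mass_rice_exactly_on_gully_cells(self):
        dem, terr = self._grids()
        rice = np.zeros(7)
        rice[0] = 1.0
        forest = np.zeros(7)
        forest[4] = 1.0
        rules = SuitabilityRules(
            (700.0, 1400.0),
            {(b, t): (rice if t == 0 else forest) for b in range(3) for t in range(5)},
        )
        truth = generate_true_landcover(dem, terr.grid, suitability_rules=rules, seed=1)
        assert np.array_equal(truth.values == 0, terr.grid.values == 0)

    def test_rule_distributions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SuitabilityRules((700.0,), {(0, 0): np.full(7, 0.1)})

    def test_empirical_frequencies_match_rules_within_3_binomial_se(self):
        dem, terr = self._grids(seed=3)
        rules = default_suitability_rules()
        truth = generate_true_landcover(dem, terr.grid, suitability_rules=rules, seed=9)
        elev_band = np.searchsorted(np.asarray(rules.elevation_breaks_m), dem.values, side="right")
        checked = 0
        for (b, t), p in rules.table.items():
            mask = (elev_band == b) & (terr.grid.values == t)
            n = int(mask.sum())
            if n < 200:
                continue
            freq = np.bincount(truth.values[mask].astype(int), minlength=7) / n
            se = np.sqrt(p * (1 - p) / n)
            assert np.all(np.abs(freq - p) <= 3 * se + 1e-12)
            checked += 1
        assert checked >= 3  # enough populous strata actually exercised

    def test_shape_mismatch_rejected(self):
        dem, terr = self._grids()
        small = Grid(np.zeros((5, 5), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError):
            generate_true_landcover(dem, small, seed=0)


class TestBandStack:
    def test_zero_noise_reproduces_class_means_exactly(self):
        dem = generate_dem(20, 20, 100.0, seed=0)
        terr = classify_terrain_position(dem, 3)
        truth = generate_true_landcover(dem, terr.grid, seed=0)
        spectra = default_class_spectra()
        bands = generate_band_stack(truth, noise_sd=0.0, seed=0)
        means = np.stack([spectra[n] for n in DEFAULT_SCHEME.names])
        for b, band in enumerate(bands):
            assert np.array_equal(band.values, means[truth.values.astype(int), b])

    def test_missing_class_spectrum_rejected(self):
        truth = Grid(np.zeros((4, 4), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError):
            generate_band_stack(truth, class_spectra={"forest": np.ones(4)})

    def test_identical_spectra_classes_are_inseparable(self):
        # two classes share a mean vector: the classifier cannot do better
        # than their prior frequencies on the confused pair
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 2, size=(40, 40)).astype(np.uint8)
        truth = Grid(codes, 100.0)
        same = {n: np.array([0.2, 0.3, 0.4, 0.5]) for n in DEFAULT_SCHEME.names}
        bands = generate_band_stack(truth, class_spectra=same, noise_sd=0.05, seed=6)
        plots = generate_sample_plots(truth, 200, seed=7)
        model = fit_base_classifier(plots, bands, seed=0)
        pred = relabel_max_posterior(predict_rule_stack(model, bands))
        acc = float(np.mean(pred.values == truth.values))
        assert 0.35 <= acc <= 0.65  # chance level for two balanced classes

    def test_well_separated_low_noise_recovers_truth(self):
        dem = generate_dem(40, 40, 100.0, seed=2)
        terr = classify_terrain_position(dem, 5)
        truth = generate_true_landcover(dem, terr.grid, seed=2)
        bands = generate_band_stack(truth, noise_sd=0.01, seed=3)
        plots = generate_sample_plots(truth, 400, seed=4)
        model = fit_base_classifier(plots, bands, seed=0)
        pred = relabel_max_posterior(predict_rule_stack(model, bands))
        assert np.mean(pred.values == truth.values) > 0.99


class TestSamplePlots:
    def test_768_plots_split_384_384(self, small_landscape):
        plots = small_landscape["plots"]
        assert plots.n == 768
        assert plots.half("train").n == 384
        assert plots.half("test").n == 384

    def test_equal_strata_map_gets_two_per_stratum_one_per_half(self):
        codes = np.repeat(np.arange(7, dtype=np.uint8), 7).reshape(7, 7)
        truth = Grid(codes, 100.0)
        plots = generate_sample_plots(truth, 14, seed=0)
        for c in range(7):
            m = plots.true_class == c
            assert m.sum() == 2
            assert set(plots.split[m]) == {"train", "test"}

    def test_odd_n_plots_rejected(self, small_landscape):
        with pytest.raises(ValueError):
            generate_sample_plots(small_landscape["truth"], 767, seed=0)

    def test_fixed_seed_reproduces_split(self, small_landscape):
        truth = small_landscape["truth"]
        a = generate_sample_plots(truth, 100, seed=5)
        b = generate_sample_plots(truth, 100, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.split, b.split)

    def test_plot_label_matches_truth_at_centre_cell(self, small_landscape):
        truth = small_landscape["truth"]
        plots = generate_sample_plots(truth, 50, seed=6)
        for x, y, c in zip(plots.x, plots.y, plots.true_class):
            r, col = truth.cell_index(x, y)
            assert truth.values[r, col] == c


class TestNestPattern:
    def test_zero_dispersal_keeps_nests_in_parent_habitat_cell(self):
        hab = patchy_habitat(64, 64, 100.0, n_patches=3, seed=1)
        nests = generate_nest_pattern(hab, 6, 10.0, sigma_m=1e-6, association=1.0, seed=2)
        for x, y in nests.points:
            r, c = hab.cell_index(x, y)
            assert hab.values[r, c] == 1

    def test_empty_habitat_with_positive_association_rejected(self):
        empty = Grid(np.zeros((8, 8), dtype=np.uint8), 100.0)
        with pytest.raises(ValueError):
            generate_nest_pattern(empty, 3, 5.0, 100.0, association=0.5, seed=0)
        # association = 0 never consults the mask
        assert generate_nest_pattern(empty, 3, 5.0, 100.0, association=0.0, seed=0).n >= 0

    def test_points_inside_window_and_deterministic(self):
        hab = patchy_habitat(seed=3)
        a = generate_nest_pattern(hab, 8, 13.0, 500.0, 1.0, seed=4)
        b = generate_nest_pattern(hab, 8, 13.0, 500.0, 1.0, seed=4)
        assert np.array_equal(a.points, b.points)
        xmin, ymin, xmax, ymax = a.window
        assert np.all((a.points[:, 0] > xmin) & (a.points[:, 0] < xmax))
        assert np.all((a.points[:, 1] > ymin) & (a.points[:, 1] < ymax))

    def test_invalid_association_rejected(self):
        hab = patchy_habitat(seed=0)
        with pytest.raises(ValueError):
            generate_nest_pattern(hab, 3, 5.0, 100.0, association=1.5, seed=0)
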