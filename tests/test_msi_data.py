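"""Grid container, imzML round trips, ppm-window extraction, region stats."""

import numpy as np
import pytest

from vcqmsi.msi_data import (IonImage, LabelMap, SpectrumGrid, build_feature_table,
                             extract_ion_image, read_imzml, region_stats,
                             tissue_mask, write_imzml)


def make_grid(pixels, shape=(2, 2)):
    return SpectrumGrid(shape=shape,
                        pixels={k: (np.array(mz, float), np.array(ii, float))
                                for k, (mz, ii) in pixels.items()})


class TestSpectrumGrid:
    def test_rejects_descending_mz(self):
        with pytest.raises(ValueError, match="ascending"):
            make_grid({(0, 0): ([200.0, 100.0], [1.0, 1.0])})

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="negative"):
            make_grid({(0, 0): ([100.0], [-1.0])})

    def test_rejects_out_of_bounds_pixel(self):
        with pytest.raises(ValueError, match="outside"):
            make_grid({(5, 0): ([100.0], [1.0])})

    def test_pixel_area(self):
        g = make_grid({})
        assert g.pixel_area_mm2 == pytest.approx(0.150 * 0.500)


class TestImzmlRoundTrip:
    def test_round_trip_preserves_peaks(self, tmp_path, rng):
        pixels = {}
        for r in range(3):
            for c in range(4):
                mz = np.sort(rng.uniform(100, 1000, 5))
                pixels[(r, c)] = (mz, rng.uniform(0, 1e4, 5))
        grid = make_grid(pixels, shape=(3, 4))
        path = tmp_path / "grid.imzML"
        write_imzml(grid, path)
        back = read_imzml(path)
        assert back.shape == grid.shape
        assert set(back.pixels) == set(grid.pixels)
        for key in grid.pixels:
            mz0, i0 = grid.pixels[key]
            mz1, i1 = back.pixels[key]
            np.testing.assert_allclose(mz1, mz0, atol=1e-6)
            np.testing.assert_allclose(i1, i0, rtol=1e-6)

    def test_single_pixel_file(self, tmp_path):
        grid = make_grid({(0, 0): ([100.0], [5.0])}, shape=(1, 1))
        write_imzml(grid, tmp_path / "one.imzML")
        back = read_imzml(tmp_path / "one.imzML")
        assert back.shape == (1, 1)
        np.testing.assert_allclose(back.pixels[(0, 0)][0], [100.0])
        np.testing.assert_allclose(back.pixels[(0, 0)][1], [5.0])

    def test_empty_grid_round_trip(self, tmp_path):
        grid = make_grid({}, shape=(2, 2))
        write_imzml(grid, tmp_path / "empty.imzML")
        back = read_imzml(tmp_path / "empty.imzML")
        assert len(back.pixels) == 0

    def test_peak_count_conserved(self, tmp_path):
        pixels = {(r, c): ([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
                  for r in range(2) for c in range(2)}
        write_imzml(make_grid(pixels), tmp_path / "g.imzML")
        back = read_imzml(tmp_path / "g.imzML")
        assert sum(len(mz) for mz, _ in back.pixels.values()) == 12

    def test_generator_occupancy_survives_io(self, tmp_path, phantom_spec):
        from vcqmsi.synthetic_data import generate_phantom
        grid, _ = generate_phantom(phantom_spec, {"tumor": 5.0}, seed=7)
        write_imzml(grid, tmp_path / "phantom.imzML")
        back = read_imzml(tmp_path / "phantom.imzML")
        assert len(back.pixels) == len(grid.pixels)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError, match="nowhere"):
            read_imzml(tmp_path / "nowhere.imzML")


class TestExtractIonImage:
    def test_ppm_window_excludes_outside_peak(self):
        # second peak is 11.1 ppm away from the PTX sodium adduct: excluded
        grid = make_grid({(0, 0): ([876.3200, 876.3300], [500.0, 100.0])},
                         shape=(1, 1))
        img = extract_ion_image(grid, 876.3203, tol_ppm=10, aggregation="sum")
        assert img.values[0, 0] == pytest.approx(500.0)

    def test_empty_pixel_gives_zero(self):
        grid = make_grid({(0, 0): ([100.0], [1.0])}, shape=(1, 2))
        img = extract_ion_image(grid, 500.0, tol_ppm=10)
        assert img.values[0, 1] == 0.0

    @pytest.mark.parametrize("aggregation,expected", [("sum", 500.0), ("max", 300.0)])
    def test_aggregation_modes(self, aggregation, expected):
        grid = make_grid({(0, 0): ([500.000, 500.001], [300.0, 200.0])},
                         shape=(1, 1))
        img = extract_ion_image(grid, 500.0005, tol_ppm=10, aggregation=aggregation)
        assert img.values[0, 0] == pytest.approx(expected)

    def test_window_matches_brute_force(self, rng):
        """Extraction equals a per-peak |dmz|/mz <= tol*1e-6 filter."""
        for _ in range(20):
            mz = np.sort(rng.uniform(400, 600, 30))
            inten = rng.uniform(0, 100, 30)
            grid = make_grid({(0, 0): (mz, inten)}, shape=(1, 1))
            target = float(rng.uniform(400, 600))
            tol = float(rng.uniform(5, 5000))
            img = extract_ion_image(grid, target, tol_ppm=tol)
            expect = inten[np.abs(mz - target) / target <= tol * 1e-6].sum()
            assert img.values[0, 0] == pytest.approx(expect, abs=1e-9)

    def test_linear_in_intensities(self, rng):
        mz = np.sort(rng.uniform(100, 900, 20))
        inten = rng.uniform(0, 100, 20)
        g1 = make_grid({(0, 0): (mz, inten)}, shape=(1, 1))
        g2 = make_grid({(0, 0): (mz, 2 * inten)}, shape=(1, 1))
        i1 = extract_ion_image(g1, 500.0, tol_ppm=2e5)
        i2 = extract_ion_image(g2, 500.0, tol_ppm=2e5)
        np.testing.assert_allclose(i2.values, 2 * i1.values)

    def test_invalid_args(self):
        grid = make_grid({(0, 0): ([100.0], [1.0])}, shape=(1, 1))
        with pytest.raises(ValueError):
            extract_ion_image(grid, -1.0, 10)
        with pytest.raises(ValueError):
            extract_ion_image(grid, 100.0, 0)


class TestFeatureTable:
    def test_single_feature_matches_ion_image(self):
        grid = make_grid({(0, 0): ([100.0], [3.0]), (1, 1): ([100.0], [7.0])})
        mask = np.ones((2, 2), dtype=bool)
        ft = build_feature_table(grid, [100.0], tol_ppm=10, mask=mask)
        img = extract_ion_image(grid, 100.0, tol_ppm=10, mask=mask)
        np.testing.assert_allclose(ft.matrix[:, 0], img.values[mask])

    def test_all_masked_out_gives_zero_rows(self):
        grid = make_grid({(0, 0): ([100.0], [3.0])})
        ft = build_feature_table(grid, [100.0], mask=np.zeros((2, 2), dtype=bool))
        assert ft.n_pixels == 0

    def test_column_means_match_image_means(self, dosed_phantom):
        grid, truth = dosed_phantom
        mask = truth.tissue_mask()
        from vcqmsi.synthetic_data import default_panel
        mzs = [f.mz for f in default_panel()[:3]]
        ft = build_feature_table(grid, mzs, tol_ppm=10, mask=mask)
        for j, mz in enumerate(mzs):
            img = extract_ion_image(grid, mz, tol_ppm=10, mask=mask)
            assert ft.matrix[:, j].mean() == pytest.approx(img.values[mask].mean())

    def test_empty_feature_list_rejected(self):
        grid = make_grid({(0, 0): ([100.0], [3.0])})
        with pytest.raises(ValueError, match="non-empty"):
            build_feature_table(grid, [])


class TestRegionStats:
    def labelmap(self, arr, names):
        return LabelMap(labels=np.array(arr), names=names)

    def test_constant_region(self):
        img = np.full((1, 3), 5.0)
        lm = self.labelmap([[1, 1, 1]], {1: "a"})
        out = region_stats(img, lm)
        assert out.loc["a", "mean"] == pytest.approx(5.0)
        assert out.loc["a", "sem"] == pytest.approx(0.0)

    def test_sem_of_small_region(self):
        img = np.array([[1.0, 2.0, 3.0]])
        out = region_stats(img, self.labelmap([[1, 1, 1]], {1: "a"}))
        assert out.loc["a", "mean"] == pytest.approx(2.0)
        assert out.loc["a", "sem"] == pytest.approx(0.57735, abs=1e-4)

    def test_two_regions_and_empty_label_flagged(self):
        img = np.array([[1.0, 2.0]])
        lm = self.labelmap([[1, 2]], {1: "a", 2: "b", 3: "ghost"})
        out = region_stats(img, lm)
        assert list(out.index) == ["a", "b", "ghost"]
        assert out.loc["ghost", "n"] == 0
        assert np.isnan(out.loc["ghost", "mean"])


def test_tissue_mask_drops_low_tic_background(phantom_spec, dosed_phantom):
    grid, truth = dosed_phantom
    mask = tissue_mask(grid, tic_quantile=0.05)
    tissue = truth.tissue_mask()
    # every true tissue pixel is far above the background noise floor
    assert (mask & tissue).sum() / tissue.sum() > 0.99


def test_ion_image_outside_mask_forced_zero():
    vals = np.array([[1.0, 2.0]])
    mask = np.array([[True, False]])
    img = IonImage(target_mz=100.0, tol_ppm=10, values=vals, mask=mask)
    assert img.values[0, 1] == 0.0
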