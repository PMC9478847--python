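"""Compound totals, region partitions, mean-spectrum extraction, splits."""

import numpy as np
import pandas as pd
import pytest

import phenomap as pm
from phenomap.errors import InvalidTableError, PartitionError, SplitError

GRID8 = np.linspace(1000.0, 1700.0, 8)

# printed group totals of the packaged reference table (mg/g DW)
PRINTED_TOTALS = {
    "White+Non-drought": 2.194,
    "White+Drought": 1.859,
    "Blue+Non-drought": 1.371,
    "Blue+Drought": 1.300,
    "Red+Non-drought": 1.311,
    "Red+Drought": 1.582,
    "RedBlue+Non-drought": 0.977,
    "RedBlue+Drought": 1.309,
}
EXACT_COLUMNS = [
    "White+Non-drought",
    "Blue+Non-drought",
    "Blue+Drought",
    "RedBlue+Non-drought",
    "RedBlue+Drought",
]


class TestTotals:
    def test_exact_columns_reproduce_printed_totals(self):
        totals = pm.total_phenolics(pm.load_compound_table())
        for cond in EXACT_COLUMNS:
            assert totals[cond] == pytest.approx(PRINTED_TOTALS[cond], abs=1e-12)

    def test_remaining_columns_differ_only_by_input_rounding(self):
        totals = pm.total_phenolics(pm.load_compound_table())
        for cond, printed in PRINTED_TOTALS.items():
            assert abs(totals[cond] - printed) <= 0.002

    def test_all_nd_column_totals_zero(self):
        df = pd.DataFrame({"c1": [np.nan, np.nan, np.nan]}, index=["a", "b", "c"])
        assert pm.total_phenolics(df)["c1"] == 0.0

    def test_negative_entry_rejected(self):
        df = pd.DataFrame({"c1": [0.2, -0.1]}, index=["a", "b"])
        with pytest.raises(InvalidTableError):
            pm.total_phenolics(df)

    def test_permutation_invariance_and_additivity(self):
        table = pm.load_compound_table()
        shuffled = table.sample(frac=1.0, random_state=3)
        pd.testing.assert_series_equal(
            pm.total_phenolics(table), pm.total_phenolics(shuffled)
        )
        top, bottom = table.iloc[:5], table.iloc[5:]
        combined = pm.total_phenolics(top) + pm.total_phenolics(bottom)
        pd.testing.assert_series_equal(pm.total_phenolics(table), combined)


class TestPartition:
    def disk_mask(self, n=500):
        m = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        m[(yy - 20) ** 2 + (xx - 20) ** 2 <= 160] = True
        assert m.sum() >= n
        return m

    def test_k1_region_equals_mask(self):
        m = self.disk_mask()
        labels = pm.partition_regions(m, k=1, seed=0)
        np.testing.assert_array_equal(labels > 0, m)
        assert set(np.unique(labels)) == {0, 1}

    @pytest.mark.parametrize("method", ["kmeans", "random"])
    def test_k10_is_a_partition(self, method):
        m = self.disk_mask()
        labels = pm.partition_regions(m, k=10, seed=1, method=method)
        np.testing.assert_array_equal(labels > 0, m)  # union = mask, disjoint by construction
        present = np.unique(labels[m])
        assert present.size == 10 and present.min() == 1 and present.max() == 10

    def test_seeded_determinism_and_seed_sensitivity(self):
        m = self.disk_mask()
        a = pm.partition_regions(m, k=10, seed=5)
        b = pm.partition_regions(m, k=10, seed=5)
        np.testing.assert_array_equal(a, b)
        c = pm.partition_regions(m, k=10, seed=6)
        np.testing.assert_array_equal(c > 0, m)  # still a partition even if different

    def test_fewer_pixels_than_regions_rejected(self):
        m = np.zeros((5, 5), dtype=bool)
        m[0, :3] = True
        with pytest.raises(PartitionError):
            pm.partition_regions(m, k=10, seed=0)


class TestExtraction:
    def constant_cube(self, value=0.4):
        return pm.Hypercube(
            np.full((6, 6, 8), value), GRID8, "SWIR", calibrated=True
        )

    def test_constant_cube_gives_constant_means(self):
        cube = self.constant_cube()
        labels = np.zeros((6, 6), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        table = pm.extract_mean_spectra(cube, labels, "p1", "c")
        assert table.n_rows == 2
        np.testing.assert_allclose(table.spectra, 0.4, atol=1e-15)

    def test_two_pixel_region_mean_is_exact(self):
        rng = np.random.default_rng(8)
        data = rng.random((2, 1, 8))
        cube = pm.Hypercube(data, GRID8, "SWIR", calibrated=True)
        labels = np.ones((2, 1), dtype=int)
        table = pm.extract_mean_spectra(cube, labels, "p", "c")
        np.testing.assert_allclose(
            table.spectra[0], (data[0, 0] + data[1, 0]) / 2, atol=1e-15
        )

    def test_region_means_conserve_plant_mean(self, calibrated_cube):
        cube, truth = calibrated_cube
        mask = pm.segment_plant(cube)
        labels = pm.partition_regions(mask, k=10, seed=2)
        table = pm.extract_mean_spectra(cube, labels, "p", "c")
        counts = np.array([(labels == r).sum() for r in np.unique(labels[labels > 0])])
        weighted = (table.spectra * counts[:, None]).sum(axis=0) / counts.sum()
        whole = cube.data[mask.mask].mean(axis=0)
        np.testing.assert_allclose(weighted, whole, atol=1e-12)


class TestReferenceAndSplit:
    def make_table(self, n_plants=12, k=10):
        rng = np.random.default_rng(0)
        n = n_plants * k
        return pm.SpectraTable(
            spectra=rng.random((n, 8)),
            wavelengths_nm=GRID8,
            plant_id=np.repeat([f"p{i}" for i in range(n_plants)], k),
            region_id=np.tile(np.arange(1, k + 1), n_plants),
            condition=np.repeat(["White+Non-drought", "RedBlue+Non-drought"], n // 2),
        )

    def test_reference_assignment_from_totals(self):
        table = self.make_table()
        totals = pm.total_phenolics(pm.load_compound_table())
        out = pm.assign_reference(table, totals)
        np.testing.assert_allclose(out.y[out.condition == "White+Non-drought"], 2.194)
        np.testing.assert_allclose(out.y[out.condition == "RedBlue+Non-drought"], 0.977)

    def test_single_condition_constant_y(self):
        table = self.make_table()
        table = pm.SpectraTable(
            spectra=table.spectra, wavelengths_nm=table.wavelengths_nm,
            plant_id=table.plant_id, region_id=table.region_id,
            condition=np.repeat("only", table.n_rows),
        )
        out = pm.assign_reference(table, {"only": 1.25})
        assert np.all(out.y == 1.25)

    def test_label_renaming_invariance(self):
        table = self.make_table()
        out1 = pm.assign_reference(table, {"White+Non-drought": 2.0, "RedBlue+Non-drought": 1.0})
        renamed = pm.SpectraTable(
            spectra=table.spectra, wavelengths_nm=table.wavelengths_nm,
            plant_id=table.plant_id, region_id=table.region_id,
            condition=np.char.replace(table.condition.astype(str), "drought", "DRY"),
        )
        out2 = pm.assign_reference(renamed, {"White+Non-DRY": 2.0, "RedBlue+Non-DRY": 1.0})
        np.testing.assert_array_equal(out1.y, out2.y)

    def test_unmatched_condition_raises(self):
        with pytest.raises(KeyError):
            pm.assign_reference(self.make_table(), {"White+Non-drought": 2.0})

    def test_spectrum_level_split_sizes(self):
        table = self.make_table(n_plants=120)  # 1,200 rows
        out = pm.split_calibration_validation(table, ratio=0.7, seed=0)
        assert (out.split_tag == "cal").sum() == 840
        assert (out.split_tag == "val").sum() == 360

    def test_plant_level_split_has_no_plant_leakage(self):
        table = self.make_table(n_plants=20)
        out = pm.split_calibration_validation(table, ratio=0.7, seed=1, level="plant")
        cal_plants = set(out.plant_id[out.split_tag == "cal"])
        val_plants = set(out.plant_id[out.split_tag == "val"])
        assert cal_plants.isdisjoint(val_plants)

    def test_split_seeded_determinism(self):
        table = self.make_table()
        a = pm.split_calibration_validation(table, seed=9)
        b = pm.split_calibration_validation(table, seed=9)
        np.testing.assert_array_equal(a.split_tag, b.split_tag)

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(SplitError):
            pm.split_calibration_validation(self.make_table(), ratio=1.5)

    def test_duplicate_plant_region_pair_rejected(self):
        with pytest.raises(ValueError):
            pm.SpectraTable(
                spectra=np.zeros((2, 8)), wavelengths_nm=GRID8,
                plant_id=np.array(["p", "p"]), region_id=np.array([1, 1]),
                condition=np.array(["c", "c"]),
            )
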