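"""Cell-channel normalization, thresholding, size filter, radial mapping."""

import math

import numpy as np
import pytest

from cordmorph.cell_mapping import (
    DetectedCell,
    canal_centers_from_fits,
    classify_zones,
    detect_cells,
    distance_ecdf,
    label_and_filter,
    locate_cells,
    normalize_stack,
    threshold_stack,
)
from cordmorph.cc_geometry import analyze_stack
from cordmorph.synthetic import (
    CanalImageSpec,
    CellFieldSpec,
    CellSpec,
    generate_cell_stack,
)


class TestNormalize:
    def test_min_max_rescale(self):
        stack = np.array([[[0.0, 50.0], [100.0, 100.0]]])
        out = normalize_stack(stack)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_slice_becomes_zeros(self, caplog):
        import logging

        stack = np.stack([np.full((8, 8), 3.0), np.eye(8)])
        with caplog.at_level(logging.WARNING, logger="cordmorph.cell_mapping"):
            out = normalize_stack(stack)
        assert np.all(out[0] == 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_uniform_histogram_equalizes_to_identity(self):
        # oracle: explicit CDF mapping; a uniform slice has linear CDF so
        # equalization is the identity within one histogram bin
        rng = np.random.default_rng(1)
        sl = rng.uniform(0, 1, size=(1, 200, 200))
        out = normalize_stack(sl)
        ranks = (np.argsort(np.argsort(sl.ravel())) + 1) / sl.size
        assert np.abs(out.ravel() - ranks).max() < 2.5 / 256

    def test_slices_processed_independently(self):
        stack = np.stack([np.linspace(0, 1, 64).reshape(8, 8),
                          np.linspace(0, 0.1, 64).reshape(8, 8)])
        out = normalize_stack(stack)
        assert out[0].max() == out[1].max() == 1.0


class TestThreshold:
    def test_voxel_exactly_at_threshold_is_foreground(self):
        stack = np.zeros((1, 2, 2))
        stack[0, 0, 0] = 1.0
        stack[0, 0, 1] = 0.95  # exactly fraction * max
        stack[0, 1, 0] = 0.9499
        mask = threshold_stack(stack, 0.95)
        assert mask[0, 0, 0] and mask[0, 0, 1] and not mask[0, 1, 0]

    def test_all_zero_stack_gives_empty_mask(self):
        assert not threshold_stack(np.zeros((2, 4, 4))).any()


def block_mask(shape, blocks):
    """Binary grid with rectangular blocks of given voxel counts."""
    mask = np.zeros(shape, dtype=bool)
    col = 0
    for n in blocks:
        width = math.ceil(n / (shape[0] * 10))
        flat = np.zeros(shape[0] * 10 * width, dtype=bool)
        flat[:n] = True
        mask[:, :10, col : col + width] = flat.reshape(shape[0], 10, width)
        col += width + 2
    return mask


class TestLabelAndFilter:
    def test_strict_inequality_at_6000(self):
        shape = (60, 20, 300)
        for n, expected in ((5999, 0), (6000, 1)):
            labels, kept, counts = label_and_filter(block_mask(shape, [n]))
            assert kept == expected
            assert counts["objects_in"] == 1

    def test_mixed_sizes(self):
        labels, kept, counts = label_and_filter(block_mask((60, 20, 300), [7000, 100]))
        assert kept == 1
        assert counts == {"objects_in": 2, "kept": 1, "removed": 1}
        assert set(np.unique(labels)) == {0, 1}  # survivors relabelled from 1

    def test_adding_small_objects_never_changes_retained_set(self):
        shape = (60, 20, 400)
        base = block_mask(shape, [7000])
        labels_base, _, _ = label_and_filter(base)
        with_clutter = block_mask(shape, [7000, 100, 50, 200, 5999])
        labels_clutter, kept, _ = label_and_filter(with_clutter)
        assert kept == 1
        assert np.array_equal(labels_clutter > 0, labels_base > 0)


class TestLocateCells:
    def centers(self):
        return {z: (50.0, 50.0) for z in range(10)}

    def make_labels(self, voxel_index):
        labels = np.zeros((10, 400, 400), dtype=np.int32)
        labels[voxel_index] = 1
        return labels

    def test_centroid_at_canal_centre_distance_zero(self):
        labels = self.make_labels((5, 100, 100))  # y = 50 um, x = 50 um at 0.5 um/px
        cells = locate_cells(labels, (0.5, 0.5, 1.0), self.centers())
        assert cells[0].distance_um == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five_triangle(self):
        labels = self.make_labels((5, 180, 160))  # offset (30, 40) um at 0.5 um/px
        cells = locate_cells(labels, (0.5, 0.5, 1.0), self.centers())
        assert cells[0].distance_um == pytest.approx(50.0)

    def test_no_reference_flagged_and_excluded(self):
        labels = self.make_labels((9, 100, 100))
        cells = locate_cells(labels, (0.5, 0.5, 1.0), {0: (50.0, 50.0)}, z_window=2)
        assert cells[0].no_reference and math.isnan(cells[0].distance_um)

    def test_volume_conversion_constant(self):
        labels = np.zeros((6, 30, 30), dtype=np.int32)
        labels[2:4, 5:10, 5:12] = 1
        labels[2:5, 20:25, 20:25] = 2
        cells = locate_cells(labels, (0.31, 0.31, 0.85), {2: (5.0, 5.0)})
        for c in cells:
            assert c.volume_um3 / c.volume_voxels == pytest.approx(0.31 * 0.31 * 0.85)


def cell_at(distance, label=1):
    return DetectedCell(
        label=label, x_um=distance, y_um=0, z_um=0, z_slice=0,
        volume_voxels=6000, volume_um3=6000 * 0.0817, distance_um=distance,
    )


class TestZones:
    def test_boundary_distances_map_to_expected_zones(self):
        cells = [cell_at(d, i) for i, d in enumerate([50, 100, 150, 230, 260])]
        summary = classify_zones(cells)
        assert [c.zone for c in cells] == [
            "proximal", "proximal", "distal", "distal", "outside"
        ]
        assert summary.n_proximal == 2 and summary.n_distal == 2 and summary.n_outside == 1

    def test_percentages_exclude_outside_and_sum_to_100(self):
        cells = [cell_at(d, i) for i, d in enumerate([50, 150, 260])]
        s = classify_zones(cells)
        assert s.percent_proximal == pytest.approx(50.0)
        assert s.percent_distal == pytest.approx(50.0)
        assert s.percent_proximal + s.percent_distal == pytest.approx(100.0)

    def test_empty_group_has_undefined_percentages(self):
        s = classify_zones([])
        assert s.n_cells == 0 and math.isnan(s.percent_proximal)

    def test_per_section_counts(self):
        cells = [cell_at(d, i) for i, d in enumerate([10, 20, 30, 40, 50])]
        s = classify_zones(cells, section_ids=["a", "a", "a", "b", "b"])
        assert s.cells_per_section_mean == pytest.approx(2.5)
        assert s.cells_per_section_sd == pytest.approx(np.std([3, 2], ddof=1))


class TestEcdf:
    def test_step_values(self):
        cells = [cell_at(d, i) for i, d in enumerate([10, 20, 30])]
        F = distance_ecdf(cells)
        assert F(20) == pytest.approx(2 / 3)
        assert F(9.999) == 0.0
        assert F(30) == 1.0 and F(100) == 1.0

    def test_dominance_of_stochastically_closer_group(self):
        rng = np.random.default_rng(0)
        near = [cell_at(d, i) for i, d in enumerate(rng.uniform(10, 80, 200))]
        far = [cell_at(d, i) for i, d in enumerate(rng.uniform(40, 200, 200))]
        Fn, Ff = distance_ecdf(near), distance_ecdf(far)
        grid = np.linspace(0, 220, 50)
        assert np.all(Fn(grid) >= Ff(grid))

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            distance_ecdf([])


class TestEndToEnd:
    def test_count_and_centroid_recovery(self, small_cell_field):
        spec, stack, truth = small_cell_field
        fits, _ = analyze_stack(stack[0], 0.31)
        centers = canal_centers_from_fits(fits)
        cells, counts = detect_cells(stack[1], (0.31, 0.31, 0.85), centers)
        supra = [t for t in truth.cells if t["volume_voxels"] >= 6000]
        assert len(cells) == len(supra) == 3
        got = sorted((c.x_um, c.y_um, c.z_um, c.volume_voxels) for c in cells)
        expect = sorted((t["x_um"], t["y_um"], t["z_um"], t["volume_voxels"]) for t in supra)
        for g, e in zip(got, expect):
            assert abs(g[0] - e[0]) < 0.31 and abs(g[1] - e[1]) < 0.31
            assert abs(g[2] - e[2]) < 0.85
            assert g[3] == e[3]  # detected volume is exact

    def test_planted_radii_recovered_within_2_um(self):
        canal = CanalImageSpec(
            image_shape=(1800, 1800), n_slices=14, noise_sd=0.0, seed=8,
            d_min_um=12.0, d_max_um=16.0, ring_thickness_um=2.5,
        )
        planted = (20.0, 120.0, 250.0)
        cells = tuple(
            CellSpec(r, 120.0 * i, 7, 6000) for i, r in enumerate(planted)
        )
        stack, _ = generate_cell_stack(CellFieldSpec(canal=canal, cells=cells))
        fits, _ = analyze_stack(stack[0], 0.31)
        det, _ = detect_cells(stack[1], (0.31, 0.31, 0.85), canal_centers_from_fits(fits))
        got = sorted(c.distance_um for c in det)
        assert np.allclose(got, sorted(planted), atol=2.0)

    def test_touching_cells_merge_into_one_detection(self):
        # documented under-segmentation: no splitting of merged objects
        canal = CanalImageSpec(image_shape=(300, 300), n_slices=16, noise_sd=0.0, seed=9)
        cells = (CellSpec(30, 0, 8, 6000), CellSpec(30, 12, 8, 6000))
        spec = CellFieldSpec(canal=canal, cells=cells, max_overlap_fraction=1.0)
        stack, truth = generate_cell_stack(spec)
        assert len(truth.cells) == 2
        fits, _ = analyze_stack(stack[0], 0.31)
        det, _ = detect_cells(stack[1], (0.31, 0.31, 0.85), canal_centers_from_fits(fits))
        assert len(det) == 1  # one merged component, counted once
        assert det[0].volume_voxels > 6000
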