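import math

import numpy as np
import pandas as pd
import pytest

from regenhubnet.spatialcoloc import (
    annotation_overlap,
    compose,
    dilate,
    positive_cell_fraction,
    threshold_rgb,
)
from regenhubnet.synthdata import (
    ExpressionSection,
    SynthConfig,
    generate_coloc_image,
    generate_sections,
)
from test_synthdata import lens_area


def make_section(expr_matrix, genes, celltypes, xy):
    n = expr_matrix.shape[0]
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "celltype": celltypes,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    return ExpressionSection(
        values=np.asarray(expr_matrix, float), genes=tuple(genes), cells=cells, condition="2dpi"
    )


class TestPositiveCellFraction:
    def test_configured_course_fraction_realized(self):
        cfg = SynthConfig(n_celltypes=4, cells_per_type=250, seed=0)  # 1000 cells
        sections, truth = generate_sections(cfg)
        two_dpi = next(s for s in sections if s.condition == "2dpi")
        assert positive_cell_fraction(two_dpi, truth.marker_gene) == pytest.approx(0.37)

    def test_gene_expressed_nowhere_gives_zero(self):
        section = make_section(np.zeros((10, 1)), ["g"], ["A"] * 10, np.zeros((10, 2)))
        assert positive_cell_fraction(section, "g") == 0.0

    def test_gene_expressed_everywhere_gives_one(self):
        section = make_section(np.ones((10, 1)), ["g"], ["A"] * 10, np.zeros((10, 2)))
        assert positive_cell_fraction(section, "g") == 1.0

    def test_unknown_gene_rejected(self):
        section = make_section(np.ones((4, 1)), ["g"], ["A"] * 4, np.zeros((4, 2)))
        with pytest.raises(KeyError):
            positive_cell_fraction(section, "nope")

    def test_denominator_is_all_cells_not_annotation_subset(self):
        expr = np.zeros((10, 1))
        expr[:2, 0] = 1.0  # both positives in celltype A (5 cells of 10)
        section = make_section(expr, ["g"], ["A"] * 5 + ["B"] * 5, np.zeros((10, 2)))
        assert positive_cell_fraction(section, "g") == pytest.approx(0.2)


class TestAnnotationOverlap:
    def test_positive_cells_themselves_annotated_colocalize_at_zero_radius(self):
        expr = np.ones((6, 1))
        xy = np.arange(12, dtype=float).reshape(6, 2)
        section = make_section(expr, ["g"], ["MSN"] * 6, xy)
        result = annotation_overlap(section, "g", "MSN", radius=0.0)
        assert result.overlap_fraction_of_marker == 1.0

    def test_separated_populations_do_not_colocalize(self):
        expr = np.zeros((4, 1))
        expr[:2, 0] = 1.0
        xy = np.array([[0, 0], [1, 0], [100, 100], [101, 100]], float)
        section = make_section(expr, ["g"], ["pos", "pos", "MSN", "MSN"], xy)
        result = annotation_overlap(section, "g", "MSN", radius=5.0)
        assert result.overlap_fraction_of_marker == 0.0

    def test_matches_all_pairs_distance_oracle(self, rng):
        n = 60
        xy = rng.uniform(0, 50, size=(n, 2))
        expr = (rng.uniform(size=(n, 1)) < 0.4).astype(float)
        celltypes = np.where(rng.uniform(size=n) < 0.3, "MSN", "other")
        section = make_section(expr, ["g"], celltypes, xy)
        radius = 7.5
        result = annotation_overlap(section, "g", "MSN", radius=radius)
        # O(n^2) oracle
        pos = np.flatnonzero(expr[:, 0] > 0)
        ann = np.flatnonzero(celltypes == "MSN")
        count = 0
        for i in pos:
            if any(math.dist(xy[i], xy[j]) <= radius for j in ann):
                count += 1
        assert result.overlap_pixels == count
        assert result.overlap_fraction_of_marker == pytest.approx(count / len(pos))

    def test_negative_radius_rejected(self):
        section = make_section(np.ones((3, 1)), ["g"], ["A"] * 3, np.zeros((3, 2)))
        with pytest.raises(ValueError):
            annotation_overlap(section, "g", "A", radius=-1.0)


class TestThresholdRGB:
    def test_all_black_image_gives_empty_mask(self):
        img = np.zeros((10, 10, 4), dtype=np.uint8)
        assert threshold_rgb(img, "R>=10").sum() == 0

    def test_red_disk_recovered_exactly(self):
        marker, _, _ = generate_coloc_image(60, 60, [((30.0, 30.0), 10.0, 1.0)], [], seed=0)
        mask = threshold_rgb(marker, "R>=128,G<=50,B<=50")
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (xx - 30.0) ** 2 + (yy - 30.0) ** 2 <= 100.0
        np.testing.assert_array_equal(mask, disk)

    def test_contradictory_rule_rejected(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="contradictory"):
            threshold_rgb(img, "R>=200,R<=100")

    def test_alpha_ignored_unless_named(self):
        img = np.zeros((4, 4, 4), dtype=np.uint8)
        img[..., 0] = 200
        img[..., 3] = 0
        assert threshold_rgb(img, "R>=100").all()
        assert not threshold_rgb(img, "R>=100,A>=1").any()

    def test_unparseable_rule_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            threshold_rgb(img, "X>5")


class TestDilate:
    def test_radius_zero_is_identity(self, rng):
        mask = rng.uniform(size=(20, 20)) < 0.2
        np.testing.assert_array_equal(dilate(mask, 0), mask)

    def test_single_pixel_square_element_gives_nine_pixels(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        out = dilate(mask, 1, element="square")
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_single_pixel_disk_element_gives_cross(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert dilate(mask, 1, element="disk").sum() == 5

    def test_matches_neighborhood_max_oracle(self, rng):
        mask = rng.uniform(size=(25, 30)) < 0.1
        radius = 2
        out = dilate(mask, radius)
        # naive per-pixel Euclidean-disk max oracle
        oracle = np.zeros_like(mask)
        h, w = mask.shape
        for y in range(h):
            for x in range(w):
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        if dy * dy + dx * dx <= radius * radius:
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                                oracle[y, x] = True
        np.testing.assert_array_equal(out, oracle)

    def test_extensive_and_monotone_in_radius(self, rng):
        mask = rng.uniform(size=(30, 30)) < 0.05
        previous = mask
        for radius in range(0, 4):
            out = dilate(mask, radius)
            assert (out | previous == out).all()  # superset of smaller radius
            previous = out

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate(np.zeros((3, 3), bool), -1)


class TestCompose:
    def test_disjoint_masks_have_zero_overlap_and_yellow_count(self):
        img = np.zeros((20, 20, 4), dtype=np.uint8)
        m1 = np.zeros((20, 20), bool)
        m2 = np.zeros((20, 20), bool)
        m1[:5, :5] = True
        m2[10:, 10:] = True
        composite, result = compose(img, m1, m2)
        assert result.overlap_pixels == 0
        assert result.population_pixels == m2.sum()
        yellow = (composite[..., 0] == 255) & (composite[..., 1] == 255) & (composite[..., 2] == 0)
        assert yellow.sum() == m2.sum()

    def test_identical_masks_overlap_equals_marker(self):
        img = np.zeros((10, 10, 4), dtype=np.uint8)
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        _, result = compose(img, m, m.copy())
        assert result.overlap_pixels == result.marker_pixels == m.sum()

    def test_overlap_encoded_red_over_yellow(self):
        img = np.full((8, 8, 4), 255, dtype=np.uint8)
        m = np.ones((8, 8), bool)
        composite, _ = compose(img, m, m.copy())
        assert (composite[..., 0] > 0).all()
        assert (composite[..., 1] == 0).all()  # red wins over yellow

    def test_shape_mismatch_rejected(self):
        img = np.zeros((5, 5, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            compose(img, np.zeros((4, 5), bool), np.zeros((5, 5), bool))

    def test_conservation_against_pixel_set_operations(self, rng):
        img = np.zeros((30, 30, 4), dtype=np.uint8)
        m1 = rng.uniform(size=(30, 30)) < 0.3
        m2 = rng.uniform(size=(30, 30)) < 0.3
        _, result = compose(img, m1, m2)
        set1 = {(y, x) for y, x in zip(*np.nonzero(m1))}
        set2 = {(y, x) for y, x in zip(*np.nonzero(m2))}
        assert result.marker_pixels == len(set1)
        assert result.population_pixels == len(set2)
        assert result.overlap_pixels == len(set1 & set2)

    def test_alpha_transparent_outside_tissue_and_masks(self):
        img = np.zeros((6, 6, 4), dtype=np.uint8)
        img[0, 0, 0] = 100  # lone tissue pixel
        m = np.zeros((6, 6), bool)
        m[3, 3] = True
        composite, _ = compose(img, m, np.zeros((6, 6), bool))
        assert composite[0, 0, 3] == 255
        assert composite[3, 3, 3] == 255
        assert composite[5, 5, 3] == 0


class TestPipelineGeometry:
    def test_threshold_dilate_compose_recovers_lens_area(self):
        r, d = 12.0, 10.0
        marker, pop, truth_overlap = generate_coloc_image(
            120, 80, [((50.0, 40.0), r, 1.0)], [((60.0, 40.0), r)], seed=0
        )
        marker_mask = threshold_rgb(marker, "R>=128,G<=50,B<=50")
        pop_mask = threshold_rgb(pop, "R>=200,G>=200,B<=60")
        _, result = compose(marker, marker_mask, pop_mask)
        assert result.overlap_pixels == truth_overlap.sum()
        expected = lens_area(r, r, d)
        perimeter = 2 * 2 * math.pi * r
        assert abs(result.overlap_pixels - expected) <= perimeter

    def test_time_course_recovered_exactly_and_unimodal(self):
        cfg = SynthConfig(seed=4)
        sections, truth = generate_sections(cfg)
        measured = [
            positive_cell_fraction(s, truth.marker_gene) for s in sections
        ]
        np.testing.assert_allclose(measured, cfg.marker_fraction_course)
        control, peak, last = measured[0], max(measured[1:]), measured[-1]
        assert peak == measured[1]  # rise at 2 DPI
        assert last <= control + 0.01  # decay back to control by 60 DPI
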