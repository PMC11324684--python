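"""Mask-stack segmentation: thresholds, spots, range filter, nucleus, CFM."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ismn.segmentation import (
    SegmentationConfig,
    SpotParams,
    boolean_subtract,
    build_cfm,
    nucleus_mask,
    range_filter,
    spot_count,
    spot_mask,
    threshold_lower_percent,
)
from ismn.synthgen import CellSpec, generate_cell

from conftest import easy_spec


def disc_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestThresholdLowerPercent:
    def test_removes_ten_percent_of_distinct_values(self):
        # brute-force oracle: percentile of 1..100 -> 90 values retained
        image = np.arange(1, 101, dtype=float).reshape(10, 10)
        cut = sorted(image.ravel())[9]  # independently derived 10th pct region
        expected = int((image > cut).sum())
        mask = threshold_lower_percent(image, 10)
        assert mask.sum() == expected == 90

    def test_constant_image_retains_all(self):
        mask = threshold_lower_percent(np.full((5, 5), 7.0), 10)
        assert mask.all()

    @pytest.mark.parametrize("percent", [0, 100, -5, 120])
    def test_invalid_percent(self, percent):
        with pytest.raises(ValueError):
            threshold_lower_percent(np.ones((3, 3)), percent)


class TestBooleanSubtract:
    def test_self_subtraction_empty(self):
        a = disc_mask((32, 32), (16, 16), 8)
        assert not boolean_subtract(a, a).any()

    def test_empty_b_is_identity(self):
        a = disc_mask((32, 32), (16, 16), 8)
        assert np.array_equal(boolean_subtract(a, np.zeros_like(a)), a)

    def test_overlap_pixel_count_brute_force(self):
        a = disc_mask((32, 32), (16, 12), 8)
        b = disc_mask((32, 32), (16, 20), 8)
        out = boolean_subtract(a, b)
        assert out.sum() == a.sum() - (a & b).sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            boolean_subtract(np.ones((4, 4), bool), np.ones((5, 5), bool))


class TestSpotMask:
    def test_single_small_disc_detected(self):
        image = np.full((40, 40), 10.0)
        image[disc_mask((40, 40), (20, 20), 1.5)] = 50.0  # 3-px disc at 5x bg
        base = np.ones_like(image, dtype=bool)
        out = spot_mask(image, base, SpotParams())
        _, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 1
        assert out[20, 20]

    def test_oversized_blob_excluded(self):
        image = np.full((40, 40), 10.0)
        image[disc_mask((40, 40), (20, 20), 5)] = 50.0  # 10-px disc
        out = spot_mask(image, np.ones_like(image, bool), SpotParams())
        assert not out.any()

    def test_uniform_image_empty(self):
        image = np.full((40, 40), 10.0)
        out = spot_mask(image, np.ones_like(image, bool), SpotParams())
        assert not out.any()

    def test_empty_base_empty(self):
        image = np.zeros((20, 20))
        out = spot_mask(image, np.zeros_like(image, bool), SpotParams())
        assert not out.any()


class TestRangeFilter:
    def test_boundary_area_inclusive(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = mask[9, 10] = mask[11, 10] = mask[10, 9] = mask[10, 11] = True
        out = range_filter(mask, (1.25, 25.0), (0.4, 1.0), 0.5)  # 5 px = 1.25 um^2
        assert np.array_equal(out, mask)

    def test_single_pixel_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5] = True  # 0.25 um^2
        assert not range_filter(mask, (1.25, 25.0), (0.4, 1.0), 0.5).any()

    def test_elongated_bar_removed_by_aspect(self):
        mask = np.zeros((40, 40), bool)
        mask[10:13, 5:25] = True  # 3x20 bar, 15 um^2
        # brute-force covariance oracle for the axis ratio
        rows, cols = np.nonzero(mask)
        cov = np.cov(np.stack([rows, cols]).astype(float), bias=True)
        lo, hi = np.linalg.eigvalsh(cov)
        assert np.sqrt(lo / hi) < 0.4
        assert not range_filter(mask, (1.25, 25.0), (0.4, 1.0), 0.5).any()

    def test_widening_bounds_is_monotone(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.8
        tight = range_filter(mask, (1.25, 10.0), (0.4, 1.0), 0.5)
        wide = range_filter(mask, (0.25, 50.0), (0.2, 1.0), 0.5)
        assert not (tight & ~wide).any()  # tight kept => wide kept


class TestNucleusMask:
    def test_disc_area_recovered(self):
        image = np.full((64, 64), 5.0)
        image[disc_mask((64, 64), (32, 32), 20)] = 1000.0
        image = ndi.gaussian_filter(image, 1.0)
        res = nucleus_mask(image)
        assert res.found
        true_area = np.pi * 20**2
        assert abs(res.mask.sum() - true_area) / true_area < 0.10

    def test_small_discs_excluded(self):
        image = np.full((64, 64), 5.0)
        image[disc_mask((64, 64), (32, 32), 12)] = 1000.0
        for c in ((10, 10), (52, 50)):
            image[disc_mask((64, 64), c, 2)] = 1000.0
        res = nucleus_mask(image)
        assert res.found
        assert not res.mask[10, 10] and not res.mask[52, 50]

    def test_empty_image_flagged(self):
        res = nucleus_mask(np.zeros((64, 64)))
        assert not res.found
        assert not res.mask.any()


class TestSpotCount:
    def test_empty_and_disjoint(self):
        assert spot_count(np.zeros((10, 10), bool)) == 0
        mask = np.zeros((30, 30), bool)
        for c in ((5, 5), (15, 15), (25, 25)):
            mask[disc_mask((30, 30), c, 2)] = True
        assert spot_count(mask) == 3

    def test_corner_touching_is_one_component(self):
        # brute-force 8-connected flood fill oracle
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches at corner (3,3)-(4,4)

        def flood_count(m):
            seen = np.zeros_like(m)
            count = 0
            for r, c in zip(*np.nonzero(m)):
                if seen[r, c]:
                    continue
                count += 1
                stack = [(r, c)]
                while stack:
                    y, x = stack.pop()
                    if not (0 <= y < m.shape[0] and 0 <= x < m.shape[1]):
                        continue
                    if seen[y, x] or not m[y, x]:
                        continue
                    seen[y, x] = True
                    stack += [
                        (y + dy, x + dx)
                        for dy in (-1, 0, 1)
                        for dx in (-1, 0, 1)
                    ]
            return count

        assert flood_count(mask) == 1
        assert spot_count(mask) == 1


class TestBuildCfm:
    def test_two_mn_cell_yields_two_components(self, mn_cell, seg_cfg):
        cell, truth = mn_cell
        res = build_cfm(cell, seg_cfg)
        assert spot_count(res.cfm) == truth.spec.mn_count == 2

    def test_mn_free_cell_empty_cfm(self, seg_cfg):
        cell, _ = generate_cell(CellSpec(noise_sd=0.0, seed=11))
        res = build_cfm(cell, seg_cfg)
        assert spot_count(res.cfm) == 0

    def test_cfm_never_overlaps_nucleus(self, seg_cfg):
        rng = np.random.default_rng(42)
        for _ in range(15):
            cell, _ = generate_cell(easy_spec(rng))
            res = build_cfm(cell, seg_cfg)
            assert not (res.cfm & res.nucleus).any()
            combined = res.mn_masks[0] | res.mn_masks[1] | res.mn_masks[2]
            for m in res.mn_masks:
                # per-iteration subtraction guarantee and OR-subset property
                assert not (m & res.nucleus).any()
                assert not (m & ~combined).any()

    def test_growing_nucleus_cannot_increase_count(self, seg_cfg):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cell, _ = generate_cell(easy_spec(rng))
            res = build_cfm(cell, seg_cfg)
            grown = ndi.binary_dilation(res.nucleus, iterations=2)
            shrunk_cfm = res.cfm & ~grown
            assert spot_count(shrunk_cfm) <= spot_count(res.cfm)

    def test_bright_spot_inside_nucleus_absent(self, seg_cfg):
        cell, truth = generate_cell(CellSpec(noise_sd=0.0, seed=13))
        cy, cx = (int(round(v)) for v in truth.nucleus_center_px)
        dna = cell.dna.copy()
        dna[cy - 1 : cy + 2, cx - 1 : cx + 2] *= 1.5  # bright intra-nuclear spot
        cell.dna = dna
        res = build_cfm(cell, seg_cfg)
        assert spot_count(res.cfm) == 0

    def test_no_nucleus_propagates(self, seg_cfg):
        cell, _ = generate_cell(CellSpec(noise_sd=0.0, seed=17))
        cell.dna = np.zeros_like(cell.dna)
        res = build_cfm(cell, seg_cfg)
        assert res.no_nucleus
        assert not res.cfm.any()
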