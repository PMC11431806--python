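import numpy as np
import pytest
import tifffile

from pleoscore import regions
from pleoscore.regions import LabelMask


def flood_fill_hollow_oracle(nucleus, chromatin):
    """Independent hollow counter: BFS over non-chromatin pixels seeded
    from everywhere outside the nucleus (the image border counts as
    outside); non-chromatin pixels inside the nucleus that stay
    unreachable are enclosed hollows."""
    h, w = nucleus.shape
    passable = ~chromatin.astype(bool)  # outside the nucleus is non-chromatin
    seen = np.zeros_like(passable)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not nucleus[r, c]
        or ((r in (0, h - 1) or c in (0, w - 1)) and passable[r, c])
    ]
    for r, c in stack:
        seen[r, c] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and passable[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                stack.append((rr, cc))
    return int((passable & nucleus & ~seen).sum())


def disk_mask(radius, pad=5):
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2).astype(np.int64)


class TestReadLabelMask:
    def test_reads_16bit_tiff(self, tmp_path):
        arr = np.zeros((8, 8), dtype=np.uint16)
        arr[1:3, 1:3] = 1
        arr[5:7, 5:7] = 2
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, arr)
        mask = regions.read_label_mask(path)
        assert mask.nucleus_ids() == [1, 2]

    def test_rejects_rgb(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "m.png"
        iio.imwrite(path, np.zeros((8, 8, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-channel"):
            regions.read_label_mask(path)

    def test_rejects_float(self, tmp_path):
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="integer"):
            regions.read_label_mask(path)

    def test_empty_mask_is_valid(self, tmp_path):
        path = tmp_path / "m.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        assert regions.read_label_mask(path).nucleus_ids() == []

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            LabelMask(labels=np.array([[-1, 0]], dtype=np.int64))


class TestRegionGeometry:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.int64)
        m[2, 2] = 1
        geom = regions.region_geometry(LabelMask(m), 1)
        assert geom.ar == 1

    def test_square_regression(self):
        """10x10 solid square: area 100, frozen Crofton perimeter."""
        m = np.zeros((14, 14), dtype=np.int64)
        m[2:12, 2:12] = 1
        geom = regions.region_geometry(LabelMask(m), 1)
        assert geom.ar == 100
        assert geom.peri == pytest.approx(36.8116572242, abs=1e-6)

    def test_disk_isoperimetric_ratio_near_unity(self):
        geom = regions.region_geometry(LabelMask(disk_mask(50)), 1)
        ratio = 4 * np.pi * geom.ar / geom.peri**2
        assert 0.95 <= ratio <= 1.05

    def test_translation_and_rotation_invariance(self):
        base = np.zeros((40, 40), dtype=np.int64)
        base[5:15, 5:12] = 1
        base[8:11, 12:20] = 1
        g0 = regions.region_geometry(LabelMask(base), 1)
        shifted = np.roll(np.roll(base, 7, axis=0), 9, axis=1)
        g1 = regions.region_geometry(LabelMask(shifted), 1)
        rotated = np.rot90(base)
        g2 = regions.region_geometry(LabelMask(rotated.copy()), 1)
        assert g0.ar == g1.ar == g2.ar
        assert g0.peri == pytest.approx(g1.peri)
        assert g0.peri == pytest.approx(g2.peri)

    def test_absent_id_raises(self):
        m = np.zeros((5, 5), dtype=np.int64)
        m[2, 2] = 1
        with pytest.raises(KeyError):
            regions.region_geometry(LabelMask(m), 7)

    def test_multi_fragment_keeps_largest_with_warning(self):
        m = np.zeros((12, 12), dtype=np.int64)
        m[1:5, 1:5] = 1  # 16 px
        m[8:10, 8:10] = 1  # 4 px, disjoint
        with pytest.warns(UserWarning, match="fragments"):
            geom = regions.region_geometry(LabelMask(m), 1)
        assert geom.ar == 16


class TestChromatinMap:
    def test_bright_interior_pixels_are_non_chromatin(self):
        m = np.zeros((12, 12), dtype=np.int64)
        m[1:11, 1:11] = 1
        h = np.zeros((12, 12))
        h[1:11, 1:11] = 0.9  # high hematoxylin = chromatin
        low = [(3, 3), (3, 8), (6, 5), (8, 3), (8, 8)]
        for r, c in low:
            h[r, c] = 0.1
        chrom = regions.chromatin_map(h, LabelMask(m), 1)
        assert chrom.sum() == 100 - 5
        assert all(not chrom[r, c] for r, c in low)

    def test_constant_nucleus_all_foreground(self):
        m = np.zeros((6, 6), dtype=np.int64)
        m[1:5, 1:5] = 1
        chrom = regions.chromatin_map(np.full((6, 6), 0.5), LabelMask(m), 1)
        assert chrom.sum() == 16

    def test_binary_image_foreground_is_high_value(self):
        m = np.zeros((8, 8), dtype=np.int64)
        m[1:7, 1:7] = 1
        h = np.zeros((8, 8))
        h[1:7, 1:7] = 1.0
        h[3, 3] = 0.0  # a hole pixel
        chrom = regions.chromatin_map(h, LabelMask(m), 1)
        assert chrom[2, 2] and not chrom[3, 3]

    def test_shape_mismatch_raises(self):
        m = np.zeros((6, 6), dtype=np.int64)
        m[1, 1] = 1
        with pytest.raises(ValueError, match="shape"):
            regions.chromatin_map(np.zeros((5, 5)), LabelMask(m), 1)

    def test_empty_nucleus_raises(self):
        with pytest.raises(KeyError):
            regions.chromatin_map(np.zeros((5, 5)), LabelMask(np.zeros((5, 5), dtype=np.int64)), 1)


class TestCountHollow:
    def test_solid_nucleus_zero(self):
        m = disk_mask(5)
        chrom = m.astype(bool)
        assert regions.count_hollow(LabelMask(m), 1, chrom) == 0

    def test_single_enclosed_pixel(self):
        m = np.zeros((9, 9), dtype=np.int64)
        m[1:8, 1:8] = 1
        chrom = m.astype(bool)
        chrom[4, 4] = False
        assert regions.count_hollow(LabelMask(m), 1, chrom) == 1

    def test_boundary_touching_pale_pixels_not_hollow(self):
        m = np.zeros((9, 9), dtype=np.int64)
        m[1:8, 1:8] = 1
        chrom = m.astype(bool)
        chrom[1, 3] = False  # on the nucleus edge: not enclosed
        chrom[4, 4] = False
        assert regions.count_hollow(LabelMask(m), 1, chrom) == 1

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(200):
            nucleus = rng.random((12, 12)) < 0.75
            chrom = nucleus & (rng.random((12, 12)) < 0.8)
            m = nucleus.astype(np.int64)
            # restrict to the largest 8-connected fragment, as the measurer does
            from skimage.measure import label as cc_label

            comps = cc_label(nucleus, connectivity=2)
            if comps.max() > 1:
                sizes = np.bincount(comps.ravel())[1:]
                keep = comps == (int(np.argmax(sizes)) + 1)
                m = keep.astype(np.int64)
                chrom = chrom & keep
                nucleus = keep
            got = regions.count_hollow(LabelMask(m), 1, chrom)
            assert got == flood_fill_hollow_oracle(nucleus, chrom)

    def test_hol_bounded_by_area(self, rng):
        m = disk_mask(6)
        chrom = m.astype(bool) & (rng.random(m.shape) < 0.5)
        hol = regions.count_hollow(LabelMask(m), 1, chrom)
        assert 0 <= hol <= m.sum()
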