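import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.measure import find_contours, regionprops
from skimage.morphology import disk

from gliamorph import morphometry as mm
from gliamorph.datatypes import CalibratedImage, ChannelSet, GliaComponent
from conftest import random_blob


# ---------------------------------------------------------------------------
# independent brute-force oracles


def endpoints_oracle(skel):
    skel = np.asarray(skel, bool)
    count = 0
    for r, c in np.argwhere(skel):
        nb = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                    nb += 1
        if nb <= 1:
            count += 1
    return count


def branchpoints_oracle(skel):
    skel = np.asarray(skel, bool)
    cands = []
    for r, c in np.argwhere(skel):
        nb = sum(
            1
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if not (dr == dc == 0)
            and 0 <= r + dr < skel.shape[0]
            and 0 <= c + dc < skel.shape[1]
            and skel[r + dr, c + dc]
        )
        if nb >= 3:
            cands.append((r, c))
    # merge 8-adjacent candidates by union-find
    parent = {p: p for p in cands}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in cands:
        for b in cands:
            if a < b and max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1:
                parent[find(a)] = find(b)
    return len({find(p) for p in cands})


def contour_length_oracle(mask):
    total = max(
        (
            np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum()
            for c in find_contours(np.pad(mask, 1).astype(float), 0.5)
        ),
        default=0.0,
    )
    return total


class TestCounts:
    def test_straight_line_endpoints(self):
        s = np.zeros((3, 7), bool)
        s[1, 1:6] = True
        assert mm.count_endpoints(s) == 2
        assert mm.count_branchpoints(s) == 0

    def test_plus_sign(self):
        s = np.zeros((7, 7), bool)
        s[3, 1:6] = True
        s[1:6, 3] = True
        assert mm.count_endpoints(s) == 4
        assert mm.count_branchpoints(s) == 1

    def test_single_pixel_is_one_endpoint(self):
        s = np.zeros((3, 3), bool)
        s[1, 1] = True
        assert mm.count_endpoints(s) == 1

    def test_empty(self):
        s = np.zeros((4, 4), bool)
        assert mm.count_endpoints(s) == 0
        assert mm.count_branchpoints(s) == 0

    def test_matches_oracles_on_random_skeletons(self, rng):
        from skimage.morphology import skeletonize

        for _ in range(40):
            blob = random_blob(rng, (40, 40), sigma=rng.uniform(1.5, 3.0))
            s = skeletonize(blob)
            assert mm.count_endpoints(s) == endpoints_oracle(s)
            assert mm.count_branchpoints(s) == branchpoints_oracle(s)


class TestProcessLength:
    def test_horizontal_line(self):
        s = np.zeros((3, 13), bool)
        s[1, 1:12] = True  # 11 px -> 10 unit links
        assert mm.process_length(s, 1.0) == pytest.approx(10.0)

    def test_empty(self):
        assert mm.process_length(np.zeros((5, 5), bool)) == 0.0

    def test_l_shaped_mixed_links(self):
        s = np.zeros((12, 12), bool)
        for i in range(6):
            s[1, 1 + i] = True  # 5 orthogonal links
        for i in range(1, 6):
            s[1 + i, 6 + i] = True  # diagonal run from (1,6)
        # link enumeration oracle: count adjacent pairs
        pts = set(map(tuple, np.argwhere(s)))
        orth = dia = 0
        for r, c in pts:
            if (r, c + 1) in pts:
                orth += 1
            if (r + 1, c) in pts:
                orth += 1
            if (r + 1, c + 1) in pts:
                dia += 1
            if (r + 1, c - 1) in pts:
                dia += 1
        assert mm.process_length(s, 1.0) == pytest.approx(orth + dia * np.sqrt(2))
        assert orth == 5 and dia == 5

    def test_pixel_size_scales_linearly(self):
        s = np.zeros((3, 10), bool)
        s[1, 1:9] = True
        assert mm.process_length(s, 2.0) == pytest.approx(2 * mm.process_length(s, 1.0))


class TestPercentFill:
    def test_solid_rectangle(self):
        m = np.zeros((10, 12), bool)
        m[2:8, 3:11] = True
        assert mm.percent_fill(m) == pytest.approx(1.0)

    def test_diagonal_of_box(self):
        n = 9
        m = np.eye(n, dtype=bool)
        assert mm.percent_fill(m) == pytest.approx(1.0 / n)

    def test_disk_approaches_pi_over_4(self):
        # radius-50 disk centred between pixels so the bounding box is 100 px
        rr, cc = np.mgrid[0:104, 0:104]
        m = (rr - 51.5) ** 2 + (cc - 51.5) ** 2 <= 50.0**2
        assert mm.percent_fill(m) == pytest.approx(np.pi / 4, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mm.percent_fill(np.zeros((4, 4), bool))

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(30):
            m = random_blob(rng, (40, 40))
            rows = np.argwhere(m)
            r0, c0 = rows.min(axis=0)
            r1, c1 = rows.max(axis=0)
            oracle = m.sum() / ((r1 - r0 + 1) * (c1 - c0 + 1))
            assert mm.percent_fill(m) == pytest.approx(oracle)


class TestSpanRatio:
    def test_disk_is_isotropic(self):
        assert mm.span_ratio(disk(30).astype(bool)) == pytest.approx(1.0, abs=0.02)

    def test_rectangle_4_to_1(self):
        m = np.zeros((44, 14), bool)
        m[2:42, 2:12] = True
        assert mm.span_ratio(m) == pytest.approx(4.0, abs=0.05)

    def test_square_is_isotropic(self):
        m = np.ones((15, 15), bool)
        assert mm.span_ratio(m) == pytest.approx(1.0, abs=0.02)

    def test_collinear_returns_cap(self):
        m = np.zeros((1, 10), bool)
        m[0, :] = True
        assert mm.span_ratio(m, degenerate_cap=123.0) == 123.0

    def test_single_pixel_rejected(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        with pytest.raises(ValueError):
            mm.span_ratio(m)

    def test_matches_regionprops_oracle(self, rng):
        for _ in range(30):
            m = random_blob(rng, (40, 40))
            props = regionprops(m.astype(int))[0]
            if props.axis_minor_length < 1e-6:
                continue
            oracle = props.axis_major_length / props.axis_minor_length
            assert mm.span_ratio(m) == pytest.approx(oracle, rel=1e-6)


class TestPerimeter:
    def test_square_10x10(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        # boundary cycle of a 10x10 square: 36 orthogonal steps
        assert mm.perimeter(m, 1.0) == pytest.approx(36.0)

    def test_single_row(self):
        m = np.zeros((3, 12), bool)
        m[1, 1:11] = True
        # out-and-back walk over a 10x1 box: 18 unit steps
        assert mm.perimeter(m, 1.0) == pytest.approx(18.0)

    def test_pixel_size_linearity(self):
        m = disk(7).astype(bool)
        assert mm.perimeter(m, 2.0) == pytest.approx(2 * mm.perimeter(m, 1.0))

    def test_tracks_marching_squares_oracle(self, rng):
        checked = 0
        while checked < 30:
            m = random_blob(rng, (40, 40), min_px=12)
            if (ndi.binary_fill_holes(m) != m).any():
                continue  # outer contour comparison needs hole-free masks
            got = mm.perimeter(m, 1.0)
            oracle = contour_length_oracle(m)
            assert got == pytest.approx(oracle, rel=0.15)
            checked += 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.perimeter(np.zeros((3, 3), bool))


class TestMarkerSum:
    def test_uniform(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 0:5] = True
        marker = np.full((5, 5), 3.0)
        assert mm.marker_sum_intensity(m, marker) == pytest.approx(30.0)

    def test_empty_mask(self):
        assert mm.marker_sum_intensity(np.zeros((4, 4), bool), np.ones((4, 4))) == 0.0

    def test_random_16bit_matches_elementwise_oracle(self, rng):
        arr = rng.integers(0, 2**16, (30, 30)).astype(np.uint16)
        m = rng.random((30, 30)) > 0.5
        oracle = sum(int(arr[r, c]) for r, c in np.argwhere(m))
        assert mm.marker_sum_intensity(m, arr.astype(float)) == pytest.approx(oracle)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.marker_sum_intensity(np.zeros((3, 3), bool), np.ones((4, 4)))


def _component_from_mask(mask, soma, cid=1, n_nuclei=1):
    return GliaComponent(
        id=cid,
        bbox=(0, mask.shape[0], 0, mask.shape[1]),
        mask=mask,
        soma_mask=soma,
        nucleus_count=n_nuclei,
    )


class TestMeasure:
    def test_amoeboid_terminal_case(self):
        m = np.zeros((30, 30), bool)
        m[5:26, 5:26] = disk(10)
        comp = _component_from_mask(m, m.copy())
        rec = mm.measure(comp, None, 0.5)
        assert rec.process_length_um == 0.0
        assert rec.morphology_ratio == 0.0
        assert rec.n_endpoints == 0
        assert rec.cd68_sum_intensity is None
        assert not rec.degenerate_soma

    def test_ratio_arithmetic(self, small_result):
        result, _ = small_result
        for rec in result.records:
            if rec.morphology_ratio is not None and rec.soma_area_um2 > 0:
                assert rec.morphology_ratio * rec.soma_area_um2 == pytest.approx(
                    rec.process_length_um
                )

    def test_degenerate_soma_flag(self):
        m = np.zeros((20, 20), bool)
        m[10, 2:18] = True
        m[9:12, 2:18] = True
        comp = _component_from_mask(m, np.zeros_like(m))
        rec = mm.measure(comp, None, 1.0)
        assert rec.degenerate_soma
        assert rec.morphology_ratio is None

    def test_cd68_present_when_channel_given(self):
        m = np.zeros((12, 12), bool)
        m[3:9, 3:9] = True
        comp = _component_from_mask(m, m.copy())
        glia = CalibratedImage(m.astype(float) * 10, 1.0)
        cd68 = CalibratedImage(np.full((12, 12), 2.0), 1.0, role="activation_marker")
        channels = ChannelSet(glia, None, cd68)
        rec = mm.measure(comp, channels, 1.0)
        assert rec.cd68_sum_intensity == pytest.approx(2.0 * m.sum())

    def test_rotation_invariance_90deg(self, small_result):
        result, _ = small_result
        comp = next(c for c in result.components if c.skeleton.sum() > 20)
        rec = mm.measure(comp, None, 1.0)
        rot = GliaComponent(
            id=comp.id,
            bbox=(0, comp.mask.shape[1], 0, comp.mask.shape[0]),
            mask=np.rot90(comp.mask).copy(),
            soma_mask=np.rot90(comp.soma_mask).copy(),
            nucleus_count=comp.nucleus_count,
        )
        rec_r = mm.measure(rot, None, 1.0)
        assert rec_r.cell_area_px == rec.cell_area_px
        assert rec_r.soma_area_px == rec.soma_area_px
        assert rec_r.n_endpoints == rec.n_endpoints
        assert rec_r.n_branchpoints == rec.n_branchpoints
        assert rec_r.percent_fill == pytest.approx(rec.percent_fill)
        assert rec_r.perimeter_px == pytest.approx(rec.perimeter_px, rel=0.02)
        assert rec_r.span_ratio == pytest.approx(rec.span_ratio, rel=0.02)


class TestSkeletonize:
    def test_amoeboid_disk_empty_skeleton(self):
        m = disk(10).astype(bool)
        comp = _component_from_mask(m, m.copy())
        assert not mm.skeletonize_processes(comp).any()

    def test_thin_line_survives(self):
        m = np.zeros((5, 30), bool)
        m[2, 2:28] = True
        comp = _component_from_mask(m, np.zeros_like(m))
        skel = mm.skeletonize_processes(comp, min_fragment_px=2)
        assert skel.sum() >= 24

    def test_thick_bar_centerline_length(self):
        m = np.zeros((9, 40), bool)
        m[3:6, 2:38] = True  # 3-px-wide bar, 36 long
        comp = _component_from_mask(m, np.zeros_like(m))
        skel = mm.skeletonize_processes(comp)
        # medial-axis oracle: centerline length within 10% of bar length
        assert mm.process_length(skel, 1.0) == pytest.approx(35.0, rel=0.10)
        assert skel[4, 10]
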