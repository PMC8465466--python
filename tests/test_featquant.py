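import numpy as np
import pytest
from scipy import ndimage

from facequant import featquant
from facequant.faceregions import REGION_NAMES
from facequant.featquant import (
    RegionHits,
    aggregate,
    binarize_heatmap,
    extract_contours,
    filter_contours,
    quantify_heatmap,
    smooth_threshold,
)


def _flood_fill_components(binary):
    """Independent 8-connected component labeling by BFS."""
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    H, W = binary.shape
    for r0 in range(H):
        for c0 in range(W):
            if not binary[r0, c0] or visited[r0, c0]:
                continue
            queue = [(r0, c0)]
            visited[r0, c0] = True
            comp = []
            while queue:
                r, c = queue.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] \
                                and not visited[rr, cc]:
                            visited[rr, cc] = True
                            queue.append((rr, cc))
            comps.append(sorted(comp))
    return comps


class TestBinarize:
    def test_all_zero_and_all_one(self):
        assert not binarize_heatmap(np.zeros((8, 8))).any()
        assert binarize_heatmap(np.ones((8, 8))).all()

    def test_matches_bruteforce_pixel_scan(self):
        rng = np.random.default_rng(0)
        heat = np.clip(rng.random((32, 32)), 0, 1)
        out = binarize_heatmap(heat, 0.5)
        expect = np.array([[heat[i, j] >= 0.5 for j in range(32)] for i in range(32)])
        assert np.array_equal(out, expect)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            binarize_heatmap(np.zeros((4, 4)), 1.5)
        with pytest.raises(ValueError, match="median"):
            binarize_heatmap(np.zeros((4, 4)), "median")

    def test_otsu_mode_splits_bimodal_map(self):
        heat = np.zeros((10, 10))
        heat[:5] = 0.9
        out = binarize_heatmap(heat, "otsu")
        assert out[:5].all() and not out[5:].any()


class TestSmoothThreshold:
    def test_isolated_pixel_removed(self):
        # hand convolution: the binomial kernel leaves 4/16 = 0.25 < 0.5
        b = np.zeros((7, 7), dtype=bool)
        b[3, 3] = True
        assert not smooth_threshold(b).any()

    def test_solid_square_interior_survives(self):
        # kernel sums to 1.0 at the center of a solid 5x5 block
        b = np.zeros((9, 9), dtype=bool)
        b[2:7, 2:7] = True
        out = smooth_threshold(b)
        assert out[3:6, 3:6].all()
        assert out.any()

    def test_all_false_stays_false(self):
        assert not smooth_threshold(np.zeros((5, 5), dtype=bool)).any()


class TestContours:
    def test_two_disjoint_squares(self):
        b = np.zeros((16, 16), dtype=bool)
        b[1:5, 1:5] = True
        b[9:13, 10:14] = True
        cs = extract_contours(b)
        assert len(cs) == 2
        assert sorted(c.filled_area for c in cs) == [16, 16]
        assert {c.bbox[2:] for c in cs} == {(4, 4)}

    def test_empty_raster_gives_no_contours(self):
        assert extract_contours(np.zeros((8, 8), dtype=bool)) == []

    def test_matches_flood_fill_oracle_on_random_rasters(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            b = rng.random((32, 32)) < 0.35
            got = extract_contours(b)
            expect = _flood_fill_components(b)
            assert len(got) == len(expect)
            got_sets = sorted(sorted(map(tuple, c.pixels)) for c in got)
            assert got_sets == sorted(expect)

    def test_boundary_is_closed_loop_of_component_pixels(self):
        b = np.zeros((10, 10), dtype=bool)
        b[2:7, 3:8] = True
        (c,) = extract_contours(b)
        bset = set(map(tuple, c.boundary))
        # boundary pixels all belong to the component and cover its border
        assert bset <= set(map(tuple, c.pixels))
        border = {(r, cc) for r, cc in map(tuple, c.pixels)
                  if r in (2, 6) or cc in (3, 7)}
        assert bset == border
        # consecutive trace steps are 8-neighbors (closed loop)
        loop = np.vstack([c.boundary, c.boundary[:1]])
        steps = np.abs(np.diff(loop, axis=0)).max(axis=1)
        assert (steps == 1).all()


class TestFilter:
    @pytest.mark.parametrize("w,h,kept", [
        (5, 30, False),   # too narrow, even though long
        (30, 5, False),
        (10, 10, True),   # boundary: exactly 10 survives
        (9, 10, False),
        (12, 15, True),
    ])
    def test_bbox_size_rule(self, w, h, kept):
        b = np.zeros((40, 40), dtype=bool)
        b[5:5 + h, 5:5 + w] = True
        (c,) = extract_contours(b)
        assert (len(filter_contours([c])) == 1) is kept


class TestHitsAndAggregate:
    def test_no_contours_no_flags(self, partition64):
        hits = quantify_heatmap(np.zeros((64, 64)), partition64, min_size=3)
        assert not any(hits.flags.values())

    def test_nose_blob_flags_nose_only(self, landmarks64, partition64, masks64):
        from facequant.synthgen import generate_heatmap

        heat = generate_heatmap(landmarks64, {"nose": 1.0}, blob_scale=2.0)
        hits = quantify_heatmap(heat, partition64, min_size=3, masks=masks64)
        assert hits.flags["nose"]
        assert sum(hits.flags.values()) == 1

    def test_region_hits_requires_all_six_flags(self):
        with pytest.raises(ValueError):
            RegionHits(image_id="x", flags={"nose": True})

    def test_presence_monotone_in_saliency_support(self, partition64, masks64):
        rng = np.random.default_rng(2)
        heat = np.zeros((64, 64))
        heat[20:26, 28:36] = 1.0
        base = quantify_heatmap(heat, partition64, min_size=3, masks=masks64)
        heat2 = heat.copy()
        heat2[40:47, 20:28] = 1.0  # add saliency elsewhere
        more = quantify_heatmap(heat2, partition64, min_size=3, masks=masks64)
        for r in REGION_NAMES:
            assert more.flags[r] >= base.flags[r]

    def test_aggregate_reference_study_proportions(self):
        """Counts with the reference group sizes must reproduce the
        published two-decimal percentages."""
        def hits(region, n, N, group):
            out = []
            for i in range(N):
                out.append(RegionHits(
                    image_id=f"{group}{i}",
                    flags={r: (r == region and i < n) for r in REGION_NAMES}))
            return out

        table = aggregate(hits("nose", 1289, 2999, "case"),
                          hits("nose", 1693, 5833, "ctl"), chi_square=False)
        row = table.set_index("region").loc["nose"]
        assert row["p_case"] == 42.98
        assert row["p_control"] == 29.02

        table = aggregate(hits("left-eye", 661, 2999, "case"),
                          hits("left-eye", 2095, 5833, "ctl"), chi_square=False)
        row = table.set_index("region").loc["left-eye"]
        assert row["p_case"] == 22.04
        assert row["p_control"] == 35.92

    def test_zero_count_zero_percent(self):
        case = [RegionHits(image_id="a", flags={r: False for r in REGION_NAMES})]
        ctl = [RegionHits(image_id="b", flags={r: False for r in REGION_NAMES})]
        table = aggregate(case, ctl, chi_square=False)
        assert (table["p_case"] == 0.0).all()

    def test_empty_group_rejected(self):
        ctl = [RegionHits(image_id="b", flags={r: False for r in REGION_NAMES})]
        with pytest.raises(ValueError, match="non-empty"):
            aggregate([], ctl)
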