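import numpy as np
import pytest
from scipy import ndimage

import spotcall as sc
from spotcall.segmentation import SegmentationParams, boundary_length, peel_iteration

from conftest import single_spot_scene
from reference import ref_segment, random_test_tile


def make_dumbbell(seed, size=49):
    """Two fused center-bright Gaussian nuclei with distinct cores.

    Geometry drawn so the pair is 8-connected at the start threshold (one
    region) but the bright cores separate at a higher threshold before the
    fused boundary ever fits within the perimeter limit.
    """
    rng = np.random.default_rng(seed)
    sigma = rng.uniform(4.0, 4.6)
    d = sigma * rng.uniform(2.6, 3.2)
    peak = int(rng.integers(205, 241))
    ang = rng.uniform(0, np.pi)
    c = size // 2
    dx, dy = d / 2 * np.cos(ang), d / 2 * np.sin(ang)
    yy, xx = np.mgrid[0:size, 0:size]
    g1 = peak * np.exp(-(((xx - (c - dx)) ** 2 + (yy - (c - dy)) ** 2)) / (2 * sigma**2))
    g2 = peak * np.exp(-(((xx - (c + dx)) ** 2 + (yy - (c + dy)) ** 2)) / (2 * sigma**2))
    return np.clip(np.rint(np.maximum(g1, g2)), 0, 255).astype(np.uint8)


DUMBBELL_PARAMS = SegmentationParams(
    dapi_start_threshold=40, range_increment=10, perimeter_max=40, min_area_px=20
)


class TestBoundaryLength:
    def test_single_pixel(self):
        assert boundary_length({(3, 3)}) == 1

    def test_filled_square_excludes_center(self):
        square = {(x, y) for x in range(3) for y in range(3)}
        assert boundary_length(square) == 8

    def test_line_is_all_boundary(self):
        assert boundary_length({(x, 0) for x in range(5)}) == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boundary_length(set())


class TestPeelIteration:
    def test_blank_tile(self):
        accepted, remaining = peel_iteration(np.zeros((10, 10), dtype=np.int32), 40, SegmentationParams())
        assert accepted == [] and not remaining.any()

    def test_single_isolated_blob_accepted(self):
        tile = np.zeros((20, 20), dtype=np.int32)
        yy, xx = np.mgrid[0:20, 0:20]
        tile[(xx - 10) ** 2 + (yy - 10) ** 2 <= 16] = 200
        accepted, remaining = peel_iteration(tile, 100, SegmentationParams(min_area_px=5))
        assert len(accepted) == 1
        assert not remaining.any()
        assert accepted[0].accept_threshold == 100

    def test_dumbbell_rejected_then_split(self):
        """Fused pair: first iteration accepts nothing, later one accepts 2."""
        tile = make_dumbbell(seed=1)
        accepted, remaining = peel_iteration(
            tile.astype(np.int32), DUMBBELL_PARAMS.dapi_start_threshold, DUMBBELL_PARAMS
        )
        assert accepted == []  # fused boundary exceeds the perimeter limit
        assert remaining.any()
        nuclei = sc.segment_nuclei(tile, DUMBBELL_PARAMS)
        assert len(nuclei) == 2

    def test_below_threshold_pixels_deleted(self):
        tile = np.full((5, 5), 30, dtype=np.int32)
        accepted, remaining = peel_iteration(tile, 40, SegmentationParams())
        assert accepted == [] and not remaining.any()

    def test_ties_kept(self):
        # "deletes below the threshold": a pixel exactly at T survives
        tile = np.zeros((8, 8), dtype=np.int32)
        tile[2:7, 2:7] = 40
        accepted, _ = peel_iteration(tile, 40, SegmentationParams(min_area_px=5, perimeter_max=30))
        assert len(accepted) == 1 and accepted[0].area_px == 25


class TestSegmentNuclei:
    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_recovers_well_separated_nuclei(self, k):
        spec = single_spot_scene(k, seed=k)
        image, grid, truth = sc.render_slide(spec)
        tile = sc.extract_spot_tile(image, grid.spots[0])
        nuclei = sc.segment_nuclei(tile, spec.suggested_segmentation_params())
        assert len(nuclei) == k
        found = np.array([[n.centroid[0] + tile.origin_x, n.centroid[1] + tile.origin_y] for n in nuclei])
        for _, row in truth.nuclei.iterrows():
            dist = np.min(np.hypot(found[:, 0] - row.x, found[:, 1] - row.y))
            assert dist < 2.0

    def test_all_below_start_threshold_gives_nothing(self):
        tile = np.full((30, 30), 25, dtype=np.uint8)
        assert sc.segment_nuclei(tile, SegmentationParams(dapi_start_threshold=40)) == []

    def test_range_increment_on_fused_pairs(self):
        """Both a fine and a coarse increment resolve a fused pair whose
        boundary never fits the perimeter limit while fused; counts on
        heavy-overlap tiles stay close across increments."""
        import dataclasses

        for seed in range(5):
            tile = make_dumbbell(seed)
            fine = sc.segment_nuclei(tile, dataclasses.replace(DUMBBELL_PARAMS, range_increment=5))
            coarse = sc.segment_nuclei(tile, dataclasses.replace(DUMBBELL_PARAMS, range_increment=50))
            assert len(fine) == len(coarse) == 2
        for seed in range(5):
            spec = single_spot_scene(20, seed=seed, separation_factor=1.25)
            image, grid, _ = sc.render_slide(spec)
            stile = sc.extract_spot_tile(image, grid.spots[0])
            base = spec.suggested_segmentation_params()
            counts = [
                len(sc.segment_nuclei(stile, dataclasses.replace(base, range_increment=inc)))
                for inc in (5, 50)
            ]
            assert abs(counts[0] - counts[1]) <= 2

    def test_range_increment_irrelevant_when_well_separated(self):
        spec = single_spot_scene(10, seed=2)
        image, grid, _ = sc.render_slide(spec)
        tile = sc.extract_spot_tile(image, grid.spots[0])
        base = spec.suggested_segmentation_params()
        counts = {
            inc: len(sc.segment_nuclei(tile, SegmentationParams(
                dapi_start_threshold=40, range_increment=inc,
                perimeter_max=base.perimeter_max, min_area_px=base.min_area_px)))
            for inc in (5, 50)
        }
        assert counts[5] == counts[50] == 10


class TestInvariants:
    def _segmented_fixture(self, seed=4):
        spec = single_spot_scene(15, seed=seed, separation_factor=1.4)
        image, grid, _ = sc.render_slide(spec)
        tile = sc.extract_spot_tile(image, grid.spots[0])
        params = spec.suggested_segmentation_params()
        return tile, params, sc.segment_nuclei(tile, params)

    def test_pixel_conservation(self):
        tile, params, nuclei = self._segmented_fixture()
        available = int((tile.masked_channel(2) >= params.dapi_start_threshold).sum())
        assert sum(n.area_px for n in nuclei) <= available

    def test_disjoint_pixel_sets(self):
        _, _, nuclei = self._segmented_fixture()
        seen = set()
        for n in nuclei:
            assert not (n.pixel_set & seen)
            seen |= n.pixel_set

    def test_acceptance_is_idempotent(self):
        """Every accepted region re-passes the criteria it was accepted under."""
        _, params, nuclei = self._segmented_fixture()
        assert nuclei
        for n in nuclei:
            assert n.area_px >= params.min_area_px
            assert boundary_length(n.pixel_set) == n.boundary_px <= params.perimeter_max

    def test_iteration_bound(self):
        params = SegmentationParams(dapi_start_threshold=40, range_increment=10, dapi_upper_limit=255)
        assert params.max_iterations() == 23  # ceil(215/10) + 1; guaranteed halt

    def test_matches_brute_force_oracle(self, rng):
        """Spot-check against the naive flood-fill reference (full sweep in
        the acceptance suite)."""
        for _ in range(25):
            tile = random_test_tile(rng)
            params = SegmentationParams(
                dapi_start_threshold=int(rng.integers(20, 70)),
                range_increment=int(rng.integers(5, 35)),
                perimeter_max=int(rng.integers(10, 60)),
                min_area_px=int(rng.integers(1, 10)),
            )
            mine = [(n.pixel_set, n.accept_threshold) for n in sc.segment_nuclei(tile, params)]
            ref = ref_segment(
                tile.tolist(),
                params.dapi_start_threshold,
                params.range_increment,
                params.dapi_upper_limit,
                params.perimeter_max,
                params.min_area_px,
            )
            assert mine == ref

    def test_overlap_resolution_beats_single_threshold(self):
        """The method's purpose: peeling splits what one threshold cannot."""
        tile = make_dumbbell(seed=7)
        nuclei = sc.segment_nuclei(tile, DUMBBELL_PARAMS)
        _, n_single = ndimage.label(tile >= DUMBBELL_PARAMS.dapi_start_threshold, structure=np.ones((3, 3)))
        assert len(nuclei) == 2 and n_single == 1


class TestDilation:
    def test_dilate_back_grows_within_initial_footprint(self):
        spec = single_spot_scene(5, seed=9)
        image, grid, _ = sc.render_slide(spec)
        tile = sc.extract_spot_tile(image, grid.spots[0])
        base = spec.suggested_segmentation_params()
        core = sc.segment_nuclei(tile, base)
        import dataclasses

        grown = sc.segment_nuclei(tile, dataclasses.replace(base, dilate_px=2))
        assert len(core) == len(grown) == 5
        initial = tile.masked_channel(2) >= base.dapi_start_threshold
        for c, g in zip(core, grown):
            assert c.pixel_set <= g.pixel_set
            assert all(initial[y, x] for x, y in g.pixel_set)
        # still pairwise disjoint after growth
        seen = set()
        for g in grown:
            assert not (g.pixel_set & seen)
            seen |= g.pixel_set
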