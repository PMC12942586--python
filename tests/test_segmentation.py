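"""The embeddedness criterion, the BFS region growing, and morphology.

The primary correctness surface is exact agreement between the BFS
implementation and the independent exhaustive route (embeddedness evaluated
at every voxel, 6-connected components via scipy) on random volumes.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungembed import reference
from lungembed.errors import ParameterError
from lungembed.segmentation import (
    EmbeddednessParams,
    embedded_region_growing,
    is_embedded,
    morphological_closing,
    ray_hits_range,
)
from lungembed.volume import CTVolume, LabeledVolume

from conftest import random_hu_volume, random_params

DEFAULTS = EmbeddednessParams()


def grow_quiet(volume, seed, params=None):
    """Run the segmenter ignoring seed-placement warnings (random seeds)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return embedded_region_growing(volume, seed, params)


class TestRayCasting:
    def test_self_witness_at_offset_zero(self):
        vol = np.full((9, 9, 9), -900, dtype=np.int16)
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            assert ray_hits_range(vol, (4, 4, 4), d, 5, -1500, -200)

    def test_witness_at_exact_probe_limit(self):
        # witness exactly R steps away counts; one step further does not
        vol = np.full((12, 3, 3), 100, dtype=np.int16)
        vol[5, 1, 1] = -900
        assert ray_hits_range(vol, (0, 1, 1), (1, 0, 0), 5, -1500, -200)
        vol2 = np.full((12, 3, 3), 100, dtype=np.int16)
        vol2[6, 1, 1] = -900
        assert not ray_hits_range(vol2, (0, 1, 1), (1, 0, 0), 5, -1500, -200)

    def test_out_of_bounds_never_witnesses(self):
        vol = np.full((6, 6, 6), 100, dtype=np.int16)
        assert not ray_hits_range(vol, (5, 3, 3), (1, 0, 0), 5, -1500, -200)

    def test_include_self_false_skips_offset_zero(self):
        vol = np.full((7, 7, 7), 100, dtype=np.int16)
        vol[3, 3, 3] = -900
        assert ray_hits_range(vol, (3, 3, 3), (1, 0, 0), 5, -1500, -200, include_self=True)
        assert not ray_hits_range(vol, (3, 3, 3), (1, 0, 0), 5, -1500, -200, include_self=False)

    @settings(derandomize=True, max_examples=60)
    @given(offset=st.integers(0, 13), max_steps=st.integers(1, 8))
    def test_hit_iff_witness_within_probe_distance(self, offset, max_steps):
        vol = np.full((14, 3, 3), 100, dtype=np.int16)
        vol[offset, 1, 1] = -900
        hit = ray_hits_range(vol, (0, 1, 1), (1, 0, 0), max_steps, -1500, -200)
        assert hit == (offset <= max_steps)

    def test_non_axis_direction_rejected(self):
        vol = np.zeros((4, 4, 4), dtype=np.int16)
        with pytest.raises(ParameterError):
            ray_hits_range(vol, (1, 1, 1), (1, 1, 0), 5, -1500, -200)


class TestEmbeddedness:
    def test_witness_range_voxel_is_trivially_embedded(self):
        vol = np.full((9, 9, 9), 40, dtype=np.int16)
        vol[4, 4, 4] = -900
        assert is_embedded(vol, (4, 4, 4))

    def test_four_satisfied_directions_meet_the_miss_budget(self):
        # witnesses 3 steps away along ±x and ±y only: misses = {±z} = 2 <= M
        vol = np.full((13, 13, 13), 40, dtype=np.int16)
        vol[6, 6, 6] = 100
        for dx, dy in [(3, 0), (-3, 0), (0, 3), (0, -3)]:
            vol[6 + dx, 6 + dy, 6] = -900
        assert is_embedded(vol, (6, 6, 6))
        vol[3, 6, 6] = 40  # remove the -x witness: 3 misses > M=2
        assert not is_embedded(vol, (6, 6, 6))

    def test_uniform_soft_tissue_voxel_is_not_embedded(self):
        vol = np.full((9, 9, 9), 40, dtype=np.int16)
        vol[4, 4, 4] = 100
        assert not is_embedded(vol, (4, 4, 4))


class TestRegionGrowing:
    def test_uniform_lung_block_fully_accepted(self):
        vol = CTVolume(np.full((16, 16, 16), -900, dtype=np.int16))
        res = embedded_region_growing(vol, (8, 8, 8))
        assert res.voxel_count == 16**3
        assert res.histogram.counts == {-900: 16**3}
        assert res.visited_count == 16**3

    def test_disconnected_blob_excluded_by_connectivity(self):
        # two lung-HU blobs separated by soft tissue: only the seeded one is kept
        vol = np.full((24, 12, 12), 40, dtype=np.int16)
        vol[2:8, 3:9, 3:9] = -900
        vol[16:22, 3:9, 3:9] = -900
        res = embedded_region_growing(CTVolume(vol), (4, 5, 5))
        expected = reference.embedded_component(vol, (4, 5, 5))
        assert np.array_equal(res.labeled.foreground, expected)
        assert res.labeled.foreground[18, 5, 5] == False  # noqa: E712
        assert res.voxel_count == int(expected.sum())
        # every voxel of the other blob is individually embedded, yet excluded
        assert is_embedded(vol, (18, 5, 5))

    def test_non_embedded_seed_yields_empty_result_with_warning(self):
        vol = CTVolume(np.full((8, 8, 8), 40, dtype=np.int16))
        with pytest.warns(UserWarning):
            res = embedded_region_growing(vol, (4, 4, 4))
        assert res.voxel_count == 0
        assert res.histogram.total == 0
        assert not res.labeled.foreground.any()

    def test_seed_outside_witness_interval_warns_but_runs(self):
        vol = np.full((10, 10, 10), -900, dtype=np.int16)
        vol[5, 5, 5] = 100  # embedded vessel-like voxel as seed
        with pytest.warns(UserWarning, match="witness interval"):
            res = embedded_region_growing(CTVolume(vol), (5, 5, 5))
        assert res.voxel_count == 1000

    def test_seed_out_of_bounds_is_error(self):
        vol = CTVolume(np.full((4, 4, 4), -900, dtype=np.int16))
        with pytest.raises(ParameterError):
            embedded_region_growing(vol, (4, 0, 0))

    def test_accepted_voxels_keep_hu_and_background_is_fill(self):
        rng = np.random.default_rng(5)
        data = random_hu_volume(rng, (20, 18, 16))
        res = grow_quiet(CTVolume(data), (10, 9, 8))
        fg = res.labeled.foreground
        assert np.array_equal(res.labeled.data[fg], data[fg])
        assert np.all(res.labeled.data[~fg] == DEFAULTS.fill_value)
        assert res.histogram.total == res.voxel_count == int(fg.sum())

    def test_matches_exhaustive_oracle_on_random_volumes(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            dims = tuple(rng.integers(6, 25, size=3))
            data = random_hu_volume(rng, dims)
            params = random_params(rng)
            seed = tuple(rng.integers(0, d) for d in dims)
            res = grow_quiet(CTVolume(data.astype(np.int16)), seed, params)
            expected = reference.embedded_component(data, seed, params)
            assert np.array_equal(res.labeled.foreground, expected)

    def test_monotone_in_miss_budget_and_probe_distance(self):
        rng = np.random.default_rng(23)
        data = random_hu_volume(rng, (18, 18, 18))
        data[9, 9, 9] = -900  # embedded seed under every setting
        seed = (9, 9, 9)
        prev = None
        for m in range(0, 7):
            p = EmbeddednessParams(max_misses=m)
            fg = grow_quiet(CTVolume(data), seed, p).labeled.foreground
            if prev is not None:
                assert np.all(fg | ~prev == True)  # noqa: E712  prev subset of fg
                assert not (prev & ~fg).any()
            prev = fg
        prev = None
        for r in range(1, 9):
            p = EmbeddednessParams(max_ray_steps=r)
            fg = grow_quiet(CTVolume(data), seed, p).labeled.foreground
            if prev is not None:
                assert not (prev & ~fg).any()
            prev = fg

    def test_rerun_is_bit_identical(self):
        rng = np.random.default_rng(7)
        data = random_hu_volume(rng, (16, 16, 16))
        a = grow_quiet(CTVolume(data), (8, 8, 8))
        b = grow_quiet(CTVolume(data), (8, 8, 8))
        assert np.array_equal(a.labeled.data, b.labeled.data)
        assert a.histogram == b.histogram
        assert a.visited_count == b.visited_count

    def test_visited_count_bounded_by_volume(self):
        rng = np.random.default_rng(9)
        data = random_hu_volume(rng, (14, 14, 14))
        res = grow_quiet(CTVolume(data), (7, 7, 7))
        assert res.voxel_count <= res.visited_count <= 14**3


class TestMorphologicalClosing:
    def test_single_interior_hole_filled_from_source(self):
        source = CTVolume(np.full((9, 9, 9), -900, dtype=np.int16))
        lab_data = np.full((9, 9, 9), -5000, dtype=np.int16)
        lab_data[2:7, 2:7, 2:7] = -900
        lab_data[4, 4, 4] = -5000  # the hole
        lab = LabeledVolume(lab_data)
        out = morphological_closing(lab, 1, source)
        assert out.data[4, 4, 4] == -900
        assert out.foreground_count == lab.foreground_count + 1

    def test_full_foreground_unchanged(self):
        lab = LabeledVolume(np.full((6, 6, 6), -900, dtype=np.int16))
        out = morphological_closing(lab, 1)
        assert np.array_equal(out.data, lab.data)

    def test_matches_dilate_then_erode_brute_force(self):
        from scipy import ndimage

        rng = np.random.default_rng(13)
        mask = rng.random((9, 9, 9)) < 0.5
        lab_data = np.where(mask, np.int16(-900), np.int16(-5000))
        source = CTVolume(np.full((9, 9, 9), -900, dtype=np.int16))
        out = morphological_closing(LabeledVolume(lab_data), 1, source)
        cross = ndimage.generate_binary_structure(3, 1)
        padded = np.pad(mask, 1)
        expected = ndimage.binary_erosion(ndimage.binary_dilation(padded, cross), cross)
        expected = expected[1:-1, 1:-1, 1:-1]
        assert np.array_equal(out.foreground, expected)

    def test_missing_source_is_error_when_holes_filled(self):
        lab_data = np.full((7, 7, 7), -5000, dtype=np.int16)
        lab_data[1:6, 1:6, 1:6] = -900
        lab_data[3, 3, 3] = -5000
        with pytest.raises(ParameterError):
            morphological_closing(LabeledVolume(lab_data), 1)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lung_min": -100, "lung_max": -200},
            {"max_ray_steps": 0},
            {"max_misses": 7},
            {"fill_value": -1000},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            EmbeddednessParams(**kwargs)

    def test_published_defaults(self):
        p = EmbeddednessParams()
        assert (p.lung_min, p.lung_max, p.max_ray_steps, p.max_misses, p.fill_value) == (
            -1500, -200, 5, 2, -5000,
        )
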