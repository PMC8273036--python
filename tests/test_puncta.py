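"""Puncta segmentation, size filtering and IN/ring-OUT mask geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroquant.core import Channel, InvalidParameterError, LabeledObjects, Mask
from neuroquant.puncta import (
    build_in_out,
    remove_somas,
    segment_les,
    size_filter,
    somas_from_map2,
)


def brute_force_ring(objects: np.ndarray, gap: float, width: float) -> np.ndarray:
    """Per-pixel nearest-object Euclidean distance ring, by direct search."""
    obj_pix = np.argwhere(objects)
    ring = np.zeros(objects.shape, dtype=bool)
    for i in range(objects.shape[0]):
        for j in range(objects.shape[1]):
            if objects[i, j]:
                continue
            d = np.sqrt(((obj_pix - (i, j)) ** 2).sum(axis=1)).min()
            ring[i, j] = gap < d <= gap + width
    return ring


def disk(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def labels_of(binary):
    from scipy import ndimage as ndi

    lab, _ = ndi.label(binary, structure=np.ones((3, 3), int))
    return LabeledObjects(lab)


class TestSegmentLes:
    def test_blank_channel_no_objects(self):
        les = segment_les(Channel(np.zeros((64, 64))))
        assert les.n_objects == 0

    def test_size_filter_is_strictly_above(self):
        """25-px objects are rejected, 26-px retained (strict 'above 25')."""
        vals = np.zeros((64, 64))
        vals[5:10, 5:10] = 100.0  # 25 px
        vals[30:43, 30:32] = 100.0  # 26 px
        les = segment_les(Channel(vals), min_area=25)
        assert les.n_objects == 1
        assert les.table()["area"].iloc[0] == 26

    def test_two_disks_one_survives(self):
        vals = np.zeros((64, 64))
        vals[disk((64, 64), (15, 15), 2.5)] = 100.0  # area 21 < 25
        vals[disk((64, 64), (45, 45), 3.2)] = 100.0  # area 29 > 25
        les = segment_les(Channel(vals), min_area=25)
        assert les.n_objects == 1

    def test_recovers_ground_truth_objects(self, clean_render):
        """Noise-free render: every truth LE above the size floor is found
        with its centroid within 1 px."""
        image, truth, _ = clean_render
        les = segment_les(image["LAMP1"], min_area=25)
        truth_table = truth.le_labels.table()
        big = truth_table[truth_table["area"] > 25]
        assert les.n_objects == len(big)
        found = les.table()
        for _, trow in big.iterrows():
            d = np.hypot(
                found["centroid_row"] - trow["centroid_row"],
                found["centroid_col"] - trow["centroid_col"],
            ).min()
            assert d < 1.0

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 100))
    def test_survivor_count_non_increasing_in_min_area(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.zeros((96, 96))
        for _ in range(8):
            c = rng.uniform(8, 88, 2)
            vals[disk((96, 96), c, rng.uniform(1.5, 5))] = 100.0
        counts = [
            segment_les(Channel(vals), min_area=m).n_objects
            for m in (0, 10, 25, 40, 80)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_min_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            segment_les(Channel(np.ones((8, 8))), min_area=-1)


class TestBuildInOut:
    def test_single_pixel_ring_matches_enumeration(self):
        """Ring around one pixel equals the exhaustive count of lattice
        points with 6 < d <= 10."""
        objects = np.zeros((41, 41), dtype=bool)
        objects[20, 20] = True
        les = labels_of(objects)
        dend = Mask(np.ones((41, 41), dtype=bool))
        masks = build_in_out(les, dend, gap=6, width=4)
        expected = brute_force_ring(objects, 6, 4)
        np.testing.assert_array_equal(masks.out_mask.values, expected)
        # independent closed-form count of lattice points in the annulus
        dr, dc = np.mgrid[-12:13, -12:13]
        d = np.hypot(dr, dc)
        assert masks.out_mask.area == int(((d > 6) & (d <= 10)).sum())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_multi_object_ring_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        objects = np.zeros((64, 64), dtype=bool)
        for _ in range(4):
            c = rng.uniform(5, 59, 2)
            objects |= disk((64, 64), c, rng.uniform(1, 4))
        les = labels_of(objects)
        dend = Mask(np.ones((64, 64), dtype=bool))
        masks = build_in_out(les, dend, gap=6, width=4)
        np.testing.assert_array_equal(
            masks.out_mask.values, brute_force_ring(objects, 6, 4)
        )

    def test_nearby_objects_rings_merge_and_stay_outside(self):
        objects = np.zeros((64, 64), dtype=bool)
        objects[30, 20] = True
        objects[30, 28] = True  # 8 px apart: rings overlap
        les = labels_of(objects)
        masks = build_in_out(les, Mask(np.ones((64, 64), bool)), gap=6, width=4)
        assert not (masks.out_mask.values & objects).any()
        assert not (masks.in_mask.values & masks.out_mask.values).any()
        # merged ring is smaller than two disjoint rings would be
        single = brute_force_ring(
            np.eye(64, dtype=bool) * False
            | (np.arange(64)[:, None] == 30) & (np.arange(64)[None, :] == 20),
            6, 4,
        ).sum()
        assert masks.out_mask.area < 2 * single

    def test_empty_dendrite_mask_empties_both(self):
        objects = np.zeros((32, 32), dtype=bool)
        objects[10:14, 10:14] = True
        masks = build_in_out(labels_of(objects), Mask(np.zeros((32, 32), bool)))
        assert masks.in_mask.area == 0 and masks.out_mask.area == 0

    def test_invalid_geometry_params(self):
        les = labels_of(np.zeros((8, 8), dtype=bool))
        dend = Mask(np.ones((8, 8), bool))
        with pytest.raises(InvalidParameterError):
            build_in_out(les, dend, gap=-1)
        with pytest.raises(InvalidParameterError):
            build_in_out(les, dend, width=0)

    def test_equivariant_under_translation_and_rot90(self):
        objects = np.zeros((64, 64), dtype=bool)
        objects |= disk((64, 64), (26, 24), 3)
        objects[36, 38] = True  # rings stay >= 10 px from every border
        dend = Mask(np.ones((64, 64), bool))
        base = build_in_out(labels_of(objects), dend).out_mask.values
        shifted = build_in_out(
            labels_of(np.roll(objects, (3, 5), axis=(0, 1))), dend
        ).out_mask.values
        np.testing.assert_array_equal(shifted, np.roll(base, (3, 5), axis=(0, 1)))
        rotated = build_in_out(
            labels_of(np.rot90(objects).copy()), dend
        ).out_mask.values
        np.testing.assert_array_equal(rotated, np.rot90(base))

    def test_per_object_ring_partition(self):
        objects = np.zeros((48, 48), dtype=np.int32)
        objects[disk((48, 48), (20, 15), 3)] = 1
        objects[disk((48, 48), (20, 30), 3)] = 2
        les = LabeledObjects(objects)
        masks = build_in_out(les, Mask(np.ones((48, 48), bool)), per_object=True)
        union = np.zeros((48, 48), dtype=bool)
        for ring in masks.per_object_rings.values():
            assert not (union & ring).any()  # disjoint ownership
            union |= ring
        np.testing.assert_array_equal(union, masks.out_mask.values)


class TestRemoveSomas:
    def test_soma_covering_everything(self):
        soma = LabeledObjects(np.ones((16, 16), dtype=np.int32))
        out = remove_somas(Mask(np.ones((16, 16), bool)), soma)
        assert out.area == 0

    def test_empty_soma_set_is_identity(self):
        m = Mask(np.eye(16, dtype=bool))
        out = remove_somas(m, LabeledObjects(np.zeros((16, 16), dtype=np.int32)))
        np.testing.assert_array_equal(out.values, m.values)

    def test_truth_dendrite_area_recovered(self, small_truth):
        dend = remove_somas(small_truth.map2_mask, small_truth.soma_labels)
        expected = small_truth.map2_mask.area - (
            small_truth.soma_labels.labels > 0
        ).sum()
        assert abs(dend.area - expected) / expected < 0.02


def test_somas_from_map2_finds_each_truth_soma(small_truth):
    somas = somas_from_map2(small_truth.map2_mask)
    assert somas.n_objects == small_truth.soma_labels.n_objects
    truth_tab = small_truth.soma_labels.table()
    found_tab = somas.table()
    for _, trow in truth_tab.iterrows():
        d = np.hypot(
            found_tab["centroid_row"] - trow["centroid_row"],
            found_tab["centroid_col"] - trow["centroid_col"],
        ).min()
        assert d < 5.0


def test_size_filter_relabels_consecutively():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[1:3, 1:9] = 1  # 16 px
    labels[6:7, 1:3] = 2  # 2 px
    labels[10:14, 10:16] = 3  # 24 px
    out = size_filter(labels, 10)
    assert sorted(np.unique(out)) == [0, 1, 2]
    assert (out == 2).sum() == 24
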