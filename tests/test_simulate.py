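"""Synthetic field generator: determinism, ground-truth invariants,
photon statistics and fixture round-trips."""

import dataclasses

import numpy as np
import pytest
import tifffile

from neuroquant.core import InvalidParameterError
from neuroquant.io import read_fixture
from neuroquant.simulate import (
    GeometryParams,
    PhotophysicsParams,
    expected_mtor_total,
    make_geometry,
    noise_free_render,
    render,
    write_fixture,
)

SMALL = GeometryParams(image_shape=(192, 192), n_neurons=2, seed=3)


def flood_fill_count(binary):
    """Independent component count: breadth-first flood fill, 8-connected."""
    visited = np.zeros_like(binary, dtype=bool)
    count = 0
    n_rows, n_cols = binary.shape
    for i in range(n_rows):
        for j in range(n_cols):
            if binary[i, j] and not visited[i, j]:
                count += 1
                stack = [(i, j)]
                visited[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < n_rows
                                and 0 <= cc < n_cols
                                and binary[rr, cc]
                                and not visited[rr, cc]
                            ):
                                visited[rr, cc] = True
                                stack.append((rr, cc))
    return count


class TestMakeGeometry:
    def test_empty_field(self):
        truth = make_geometry(dataclasses.replace(SMALL, n_neurons=0))
        assert truth.map2_mask.area == 0
        assert truth.le_labels.n_objects == 0
        assert truth.soma_labels.n_objects == 0

    def test_deterministic_for_fixed_seed(self):
        t1 = make_geometry(SMALL)
        t2 = make_geometry(SMALL)
        np.testing.assert_array_equal(t1.map2_mask.values, t2.map2_mask.values)
        np.testing.assert_array_equal(t1.le_labels.labels, t2.le_labels.labels)
        np.testing.assert_array_equal(
            t1.soma_labels.labels, t2.soma_labels.labels
        )
        assert t1.per_le_enrichment == t2.per_le_enrichment
        for d in t1.dendrite_centerlines:
            np.testing.assert_array_equal(
                t1.dendrite_centerlines[d], t2.dendrite_centerlines[d]
            )

    def test_soma_count_verified_by_flood_fill(self):
        params = GeometryParams(
            image_shape=(400, 400), n_neurons=12, dendrites_per_neuron=4,
            seed=9, n_les_per_100um_dendrite=0.0,
        )
        truth = make_geometry(params)
        assert truth.soma_labels.n_objects == 12
        assert flood_fill_count(truth.soma_labels.labels > 0) == 12

    def test_truth_invariants(self, small_truth):
        truth = small_truth
        # soma support is inside the MAP2 mask
        assert not (
            (truth.soma_labels.labels > 0) & ~truth.map2_mask.values
        ).any()
        # every LE id appears exactly once in the enrichment map
        assert sorted(truth.per_le_enrichment) == truth.le_labels.ids
        # LE centroids lie inside the MAP2-positive region
        for _, row in truth.le_labels.table().iterrows():
            r, c = int(round(row["centroid_row"])), int(round(row["centroid_col"]))
            assert truth.map2_mask.values[r, c]
        # LEs do not overlap (disjoint labels by construction) and are
        # dendritic: none sits inside a soma footprint
        assert not (
            (truth.le_labels.labels > 0) & (truth.soma_labels.labels > 0)
        ).any()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            GeometryParams(soma_radius_range=(10, 5))
        with pytest.raises(InvalidParameterError):
            GeometryParams(pixel_size=0)
        with pytest.raises(InvalidParameterError):
            GeometryParams(image_shape=(20, 20), soma_radius_range=(10, 16))
        with pytest.raises(InvalidParameterError):
            GeometryParams(n_neurons=-1)


class TestRender:
    def test_no_recruitment_uniform_mtor(self, small_truth):
        phys = PhotophysicsParams(mtor_enrichment=1.0, background_level=0.0)
        signal = noise_free_render(small_truth, phys)
        on = signal["mTOR"][small_truth.map2_mask.values]
        assert np.all(on == phys.mtor_cytoplasm_intensity)
        inside = signal["mTOR"][
            (small_truth.le_labels.labels > 0) & small_truth.map2_mask.values
        ]
        outside = signal["mTOR"][
            (small_truth.le_labels.labels == 0) & small_truth.map2_mask.values
        ]
        assert inside.mean() == outside.mean()

    def test_enrichment_two_exact_by_construction(self):
        truth = make_geometry(SMALL)
        phys = PhotophysicsParams(mtor_enrichment=2.0, background_level=0.0)
        image = render(truth, phys)
        inside = image["mTOR"].values[
            (truth.le_labels.labels > 0) & truth.map2_mask.values
        ]
        ring_free_cyto = image["mTOR"].values[
            (truth.le_labels.labels == 0) & truth.map2_mask.values
        ]
        assert inside.mean() / ring_free_cyto.mean() == pytest.approx(2.0)

    def test_total_intensity_conservation_closed_form(self):
        truth = make_geometry(SMALL)
        phys = PhotophysicsParams(mtor_enrichment=1.7)
        image = render(truth, phys)
        assert image["mTOR"].values.sum() == pytest.approx(
            expected_mtor_total(truth, phys), rel=1e-12
        )

    def test_poisson_variance_matches_mean_in_le_interiors(self):
        """Across seed replicates the per-pixel variance inside LEs tracks
        the Poisson mean."""
        truth = make_geometry(SMALL)
        stack = []
        for seed in range(20):
            phys = PhotophysicsParams(
                mtor_enrichment=1.0, poisson_noise=True, seed=seed
            )
            stack.append(render(truth, phys)["mTOR"].values)
        stack = np.stack(stack)
        interior = (truth.le_labels.labels > 0) & truth.map2_mask.values
        means = stack[:, interior].mean(axis=0)
        variances = stack[:, interior].var(axis=0, ddof=1)
        # ratio of pooled variance to pooled mean ~ 1 for Poisson
        assert variances.mean() / means.mean() == pytest.approx(1.0, abs=0.15)

    def test_render_is_deterministic_given_seed(self):
        truth = make_geometry(SMALL)
        phys = PhotophysicsParams(
            poisson_noise=True, gaussian_read_noise_sd=2.0, seed=42
        )
        img1 = render(truth, phys)
        img2 = render(make_geometry(SMALL), dataclasses.replace(phys))
        for name in img1.channels:
            np.testing.assert_array_equal(
                img1[name].values, img2[name].values
            )

    def test_hotspot_truth_recorded(self):
        truth = make_geometry(SMALL)
        dend = next(iter(truth.dendrite_centerlines))
        phys = PhotophysicsParams(hotspot_positions=[(dend, 0.5)])
        render(truth, phys)
        assert len(truth.hotspot_truth) == 1
        assert truth.hotspot_truth[0][0] == dend

    def test_per_neuron_activity_heterogeneity(self):
        """With a nonzero P-pS6 CV, somata differ from each other but each
        soma stays internally uniform and its dendrites share its factor."""
        truth = make_geometry(dataclasses.replace(SMALL, n_neurons=2))
        phys = PhotophysicsParams(
            background_level=0.0, pps6_soma_cv=0.4, seed=2,
            pps6_dendrite_decay_length=1e9,
        )
        signal = noise_free_render(truth, phys)["P-pS6"]
        soma_means = [
            signal[truth.soma_labels.labels == i].mean() for i in (1, 2)
        ]
        assert soma_means[0] != pytest.approx(soma_means[1], rel=1e-6)
        for i in (1, 2):
            vals = signal[truth.soma_labels.labels == i]
            assert vals.std() == pytest.approx(0.0, abs=1e-9)
        # a dendrite carries its neuron's factor (no decay configured)
        dend, neuron = next(iter(truth.dendrite_neuron.items()))
        on_dend = (
            (truth.dendrite_id_map == dend)
            & (truth.soma_labels.labels == 0)
            & ~np.isnan(truth.dendrite_arclength)
        )
        assert signal[on_dend].mean() == pytest.approx(
            soma_means[neuron - 1], rel=1e-6
        )

    def test_unknown_hotspot_dendrite_raises(self):
        truth = make_geometry(SMALL)
        with pytest.raises(InvalidParameterError):
            render(truth, PhotophysicsParams(hotspot_positions=[(9999, 0.5)]))


class TestFixtureIO:
    def test_roundtrip_bit_for_bit(self, tmp_path):
        truth = make_geometry(SMALL)
        phys = PhotophysicsParams(poisson_noise=True, seed=5)
        image = render(truth, phys)
        files = write_fixture(image, truth, tmp_path, "f0")
        image2, truth2 = read_fixture(files["sidecar"])
        # reading back the quantized data is stable under a second cycle
        files2 = write_fixture(image2, truth2, tmp_path / "again", "f0")
        image3, truth3 = read_fixture(files2["sidecar"])
        for name in image2.channels:
            np.testing.assert_array_equal(
                image2[name].values, image3[name].values
            )
        # and equals the documented quantization of the original
        for name in image.channels:
            expected = np.clip(np.round(image[name].values), 0, 65535)
            np.testing.assert_array_equal(image2[name].values, expected)

    def test_truth_sidecar_roundtrip(self, tmp_path):
        truth = make_geometry(SMALL)
        phys = PhotophysicsParams(mtor_enrichment=2.18)
        image = render(truth, phys)
        files = write_fixture(image, truth, tmp_path, "f1")
        _, truth2 = read_fixture(files["sidecar"])
        assert truth2.per_le_enrichment == truth.per_le_enrichment
        np.testing.assert_array_equal(
            truth2.le_labels.labels, truth.le_labels.labels
        )
        np.testing.assert_array_equal(
            truth2.soma_labels.labels, truth.soma_labels.labels
        )

    def test_16bit_saturation_clips_with_warning(self, tmp_path):
        truth = make_geometry(dataclasses.replace(SMALL, n_neurons=1))
        phys = PhotophysicsParams(map2_intensity=80000.0)
        image = render(truth, phys)
        with pytest.warns(UserWarning, match="clip"):
            files = write_fixture(image, None, tmp_path, "sat")
        arr = tifffile.imread(files["image"])
        assert arr.max() == 65535

    def test_per_channel_file_layout(self, tmp_path):
        truth = make_geometry(dataclasses.replace(SMALL, n_neurons=1))
        image = render(truth, PhotophysicsParams())
        files = write_fixture(image, truth, tmp_path, "f2", multipage=False)
        image2, _ = read_fixture(files["sidecar"])
        assert set(image2.channels) == set(image.channels)
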