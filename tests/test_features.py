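"""Scattering features: invariance, stability, path counts, centering."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from trajfuse.datasets.study import render_frame
from trajfuse.features import (FeatureVector, ScatterConfig, center_by_dataset,
                               feature_matrix, n_scattering_paths,
                               pixel_features, scatter_image)

CFG32 = ScatterConfig(averaging_scale=32)


@pytest.fixture(scope="module")
def frame64():
    return render_frame(0.5, 64)["nuclei"]


def brute_force_path_count(J, L, order):
    """Independent enumeration of admissible scattering paths."""
    paths = [()]                                    # S0
    paths += [(j, l) for j in range(J) for l in range(L)]
    if order == 2:
        paths += [
            (j1, l1, j2, l2)
            for j1 in range(J) for l1 in range(L)
            for j2 in range(J) for l2 in range(L)
            if j2 > j1
        ]
    return len(paths)


class TestTransform:
    def test_zero_image_gives_zero_vector(self):
        fv = scatter_image(np.zeros((64, 64)), CFG32)
        assert np.all(fv.values == 0)

    @pytest.mark.parametrize("J,L,order", [(3, 4, 1), (3, 4, 2), (5, 8, 2)])
    def test_dimension_matches_path_enumeration(self, J, L, order):
        assert n_scattering_paths(J, L, order) == brute_force_path_count(J, L, order)
        cfg = ScatterConfig(averaging_scale=2 ** J, order=order, n_orientations=L)
        img = render_frame(0.3, 64)["nuclei"]
        fv = scatter_image(img, cfg)
        n_pos = int(np.ceil(64 / 2 ** J)) ** 2
        assert fv.dim == n_scattering_paths(J, L, order) * n_pos

    def test_translation_stability(self, frame64):
        fv = scatter_image(frame64, CFG32)
        shifted = np.roll(frame64, 2, axis=1)
        fv2 = scatter_image(shifted, CFG32)
        rel = np.linalg.norm(fv.values - fv2.values) / np.linalg.norm(fv.values)
        rel_pix = np.linalg.norm(frame64 - shifted) / np.linalg.norm(frame64)
        assert rel < 0.05
        assert rel < 0.2 * rel_pix

    def test_deformation_stability_grows_boundedly(self, frame64):
        """Relative feature distance grows at most ~linearly with the
        deformation amplitude."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 8, 8))
        rows, cols = np.mgrid[0:64, 0:64].astype(float)
        fv0 = scatter_image(frame64, CFG32).values
        rels = []
        for delta in (1, 2, 4):
            disp = np.stack([
                map_coordinates(b, np.stack([rows, cols]) / 9.0, order=3)
                for b in base
            ])
            disp *= delta / np.abs(disp).max()
            warped = map_coordinates(
                frame64, [rows + disp[0], cols + disp[1]], order=1)
            fv = scatter_image(warped, CFG32).values
            rels.append(np.linalg.norm(fv - fv0) / np.linalg.norm(fv0))
        assert rels[0] < rels[1] < rels[2]
        # bounded slope: quadrupling the displacement does not blow up the
        # distance by much more than the proportional factor
        assert rels[2] / rels[0] < 8.0

    def test_deterministic(self, frame64):
        a = scatter_image(frame64, CFG32).values
        b = scatter_image(frame64, CFG32).values
        assert np.array_equal(a, b)

    def test_oversized_averaging_scale_rejected(self):
        with pytest.raises(ValueError):
            scatter_image(np.zeros((32, 32)), ScatterConfig(averaging_scale=64))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ScatterConfig(averaging_scale=48)
        with pytest.raises(ValueError):
            ScatterConfig(order=3)


class TestCentering:
    def _toy(self):
        rng = np.random.default_rng(2)
        return [FeatureVector(rng.normal(size=6), f"im{i}", f"ds{i % 3}")
                for i in range(12)]

    def test_per_dataset_mean_is_zero(self):
        out = center_by_dataset(self._toy())
        for ds in ("ds0", "ds1", "ds2"):
            mean = np.mean([f.values for f in out if f.dataset_id == ds], axis=0)
            assert np.linalg.norm(mean) < 1e-10

    def test_idempotent(self):
        once = center_by_dataset(self._toy())
        twice = center_by_dataset(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_single_dataset_equals_global_mean_subtraction(self):
        feats = [FeatureVector(f.values, f.image_id, "all") for f in self._toy()]
        out = center_by_dataset(feats)
        gmean = np.mean([f.values for f in feats], axis=0)
        for a, f in zip(out, feats):
            np.testing.assert_allclose(a.values, f.values - gmean, atol=1e-12)

    def test_singleton_dataset_warns_and_zeroes(self):
        feats = [FeatureVector(np.ones(3), "a", "solo")]
        with pytest.warns(RuntimeWarning):
            out = center_by_dataset(feats)
        assert np.all(out[0].values == 0)


def test_feature_matrix_rejects_mixed_dimensions():
    with pytest.raises(ValueError):
        feature_matrix([FeatureVector(np.zeros(3)), FeatureVector(np.zeros(4))])


def test_pixel_feature_alternative_has_right_shape(frame64):
    fv = pixel_features(frame64, out_size=10)
    assert fv.dim == 100
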