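"""Geometry oracles: moments, meshes, sphericity, normalization, distances."""

import numpy as np
import pytest
from scipy import ndimage

import airwaymorph as am
from airwaymorph.morphometry import object_geometry, sphericity


def _digitized(axes, spacing=(0.5, 0.5, 0.5), center=(30.0, 30.0, 30.0),
               shape=(120, 120, 120)):
    return am.ellipsoid_mask(shape, spacing, center, axes)


class TestComposites:
    def _mask(self, code, values):
        return am.ObjectMask(code, values, spacing=(1, 1, 1))

    def test_union_of_disjoint_components_adds_voxels(self):
        a = np.zeros((10, 10, 4), dtype=bool)
        b = np.zeros_like(a)
        a[:3], b[5:] = True, True
        masks = {"np": self._mask("np", a), "op": self._mask("op", b)}
        out = am.derive_composites({**masks, **_dummy_base(masks)})
        assert out["ph"].voxel_count == a.sum() + b.sum()

    def test_union_is_idempotent_for_identical_components(self):
        a = np.zeros((10, 10, 4), dtype=bool)
        a[2:4] = True
        masks = _dummy_base({})
        masks["tR"] = self._mask("tR", a)
        masks["tL"] = self._mask("tL", a)
        out = am.derive_composites(masks)
        assert out["tn"].voxel_count == a.sum()

    def test_overlapping_union_obeys_inclusion_exclusion(self, phantom):
        cohort, _ = phantom
        masks = am.derive_composites(cohort.subjects[0].masks)
        tn, ad, at = (masks[c].values for c in ("tn", "ad", "at"))
        assert at.sum() == tn.sum() + ad.sum() - (tn & ad).sum()
        np.testing.assert_array_equal(at, tn | ad)


def _dummy_base(overrides):
    """Minimal base-mask dict for composite derivation in isolation."""
    blank = np.zeros((10, 10, 4), dtype=bool)
    blank[0, 0, 0] = True
    masks = {c: am.ObjectMask(c, blank, spacing=(1, 1, 1))
             for c in am.BASE_OBJECTS}
    masks.update(overrides)
    return masks


class TestObjectGeometry:
    def test_single_voxel_has_zero_dispersion_and_centred_centroid(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 3, 1] = True
        g = object_geometry(mask, (0.5, 0.5, 3.3), (0, 0, 0))
        np.testing.assert_allclose(g.principal_dispersions, 0.0, atol=1e-12)
        np.testing.assert_allclose(g.centroid, [(2.5) * 0.5, 3.5 * 0.5, 1.5 * 3.3])
        assert g.raw_volume > 0 and g.raw_area > 0

    def test_sphere_moments_match_uniform_ball_closed_form(self):
        """Uniform ball: per-axis variance r^2/5, so the dispersion sum is
        3r/sqrt(5); mesh volume approaches 4/3*pi*r^3."""
        r = 10.0
        mask = _digitized((r, r, r))
        g = object_geometry(mask, (0.5, 0.5, 0.5), (0, 0, 0))
        assert abs(g.dispersion_sum - 3 * r / np.sqrt(5)) / (3 * r / np.sqrt(5)) < 0.02
        assert abs(g.raw_volume - 4188.79) / 4188.79 < 0.02

    def test_dispersions_match_brute_force_voxel_covariance(self):
        mask = _digitized((8.0, 6.0, 5.0))
        spacing = np.array([0.5, 0.5, 0.5])
        g = object_geometry(mask, spacing, (0, 0, 0))
        pts = (np.argwhere(mask) + 0.5) * spacing  # independent oracle
        lam = np.sqrt(np.sort(np.linalg.eigvalsh(np.cov(pts.T, ddof=0)))[::-1])
        np.testing.assert_allclose(g.principal_dispersions, lam, rtol=1e-10)

    def test_ellipsoid_dispersion_sum_closed_form(self):
        a, b, c = 20.0, 15.0, 9.0
        mask = _digitized((a, b, c))
        g = object_geometry(mask, (0.5, 0.5, 0.5), (0, 0, 0))
        expected = (a + b + c) / np.sqrt(5)
        assert abs(g.dispersion_sum - expected) / expected < 0.02

    def test_mesh_volume_close_to_voxel_volume(self):
        mask = _digitized((10.0, 8.0, 6.0))
        voxel_volume = 0.125
        g = object_geometry(mask, (0.5, 0.5, 0.5), (0, 0, 0))
        surface = mask & ~ndimage.binary_erosion(mask)
        assert (abs(g.raw_volume - mask.sum() * voxel_volume) / voxel_volume
                <= surface.sum())

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            object_geometry(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1), (0, 0, 0))

    def test_anisotropic_grid_agrees_with_isotropic_within_5pc(self):
        """A sphere sampled at 0.5 x 0.5 x 3.3 mm reproduces the isotropic
        features within the slice-thickness tolerance, for an object that
        spans a reasonable number of slices."""
        r = 28.0
        iso = object_geometry(
            am.ellipsoid_mask((124, 124, 124), (0.5, 0.5, 0.5),
                              (31.0, 31.0, 31.0), (r, r, r)),
            (0.5, 0.5, 0.5), (0, 0, 0))
        aniso = object_geometry(
            am.ellipsoid_mask((124, 124, 44), (0.5, 0.5, 3.3),
                              (31.0, 31.0, 72.6), (r, r, r)),
            (0.5, 0.5, 3.3), (0, 0, 0))
        for attr in ("dispersion_sum", "raw_volume", "raw_area"):
            a, b = getattr(iso, attr), getattr(aniso, attr)
            assert abs(a - b) / a < 0.05
        sp_iso = sphericity(iso.raw_volume, iso.raw_area)
        sp_aniso = sphericity(aniso.raw_volume, aniso.raw_area)
        assert abs(sp_iso - sp_aniso) / sp_iso < 0.05


class TestNormalizationLength:
    def test_single_voxel_mandible_gives_spacing_norm(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 2, 3] = True
        L = am.normalization_length(mask, (0.5, 0.5, 3.3)).L
        np.testing.assert_allclose(L, np.linalg.norm([0.5, 0.5, 3.3]))

    def test_box_diagonal_closed_form(self):
        mask = np.zeros((220, 180, 40), dtype=bool)
        mask[10:210, 10:170, 10:28] = True  # 100 x 80 x 59.4 mm box
        L = am.normalization_length(mask, (0.5, 0.5, 3.3)).L
        expected = np.linalg.norm([100.0, 80.0, 59.4])
        assert abs(L - expected) <= np.linalg.norm([0.5, 0.5, 3.3])

    def test_in_plane_rotation_preserves_L(self):
        mask = _digitized((12.0, 7.0, 5.0), spacing=(0.5, 0.5, 3.3),
                          center=(30.0, 30.0, 30.0), shape=(120, 120, 18))
        L1 = am.normalization_length(mask, (0.5, 0.5, 3.3)).L
        L2 = am.normalization_length(np.rot90(mask, axes=(0, 1)),
                                     (0.5, 0.5, 3.3)).L
        np.testing.assert_allclose(L1, L2, rtol=1e-12)

    def test_empty_mandible_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            am.normalization_length(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestSphericity:
    def test_analytic_sphere_is_exactly_one(self):
        for r in (1.0, 5.0, 10.0):
            V, A = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2
            assert abs(sphericity(V, A) - 1.0) < 1e-12

    def test_cube_closed_form(self):
        s = 3.7
        assert abs(sphericity(s**3, 6 * s**2) - np.cbrt(36 * np.pi) / 6) < 1e-12

    def test_scale_invariance(self):
        assert sphericity(5.0, 9.0) == pytest.approx(
            sphericity(5.0 / 150.0**3, 9.0 / 150.0**2), rel=1e-12)

    def test_meshed_sphere_within_discretization_tolerance(self):
        mask = _digitized((10.0, 10.0, 10.0))
        g = object_geometry(mask, (0.5, 0.5, 0.5), (0, 0, 0))
        assert abs(sphericity(g.raw_volume, g.raw_area) - 1.0) < 0.03

    def test_sphere_maximizes_sphericity_over_shape_library(self):
        spacing = (0.5, 0.5, 0.5)
        shapes = {
            "sphere": _digitized((10.0, 10.0, 10.0)),
            "ellipsoid_2to1": _digitized((14.0, 7.0, 7.0)),
            "ellipsoid_4to1": _digitized((20.0, 5.0, 5.0)),
        }
        cube = np.zeros((60, 60, 60), dtype=bool)
        cube[10:50, 10:50, 10:50] = True
        shapes["cube"] = cube
        ell = np.zeros((80, 80, 80), dtype=bool)
        ell[10:70, 10:26, 10:26] = True
        ell[10:26, 10:70, 10:26] = True
        shapes["L_solid"] = ell
        sp = {}
        for name, mask in shapes.items():
            g = object_geometry(mask, spacing, (0, 0, 0))
            sp[name] = sphericity(g.raw_volume, g.raw_area)
        assert max(sp, key=sp.get) == "sphere"
        assert all(v <= 1.0 + 0.03 for v in sp.values())

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)


class TestIntensityAndDistance:
    def test_mean_intensity_of_constant_and_mixed_regions(self):
        shape = (4, 4, 2)
        mask = np.ones(shape, dtype=bool)
        vol = am.IntensityVolume(np.full(shape, 2000.0), spacing=(1, 1, 1))
        assert am.mean_standardized_intensity(vol, mask) == 2000.0
        half = np.full(shape, 1000.0)
        half[2:] = 3000.0
        vol = am.IntensityVolume(half, spacing=(1, 1, 1))
        assert am.mean_standardized_intensity(vol, mask) == 2000.0

    def test_noisy_region_mean_obeys_clt_bound(self):
        rng = np.random.default_rng(0)
        shape = (20, 20, 10)
        sigma, mu = 60.0, 1500.0
        vol = am.IntensityVolume(mu + rng.normal(0, sigma, shape), spacing=(1, 1, 1))
        mask = np.ones(shape, dtype=bool)
        n = mask.sum()
        assert abs(am.mean_standardized_intensity(vol, mask) - mu) < 4 * sigma / np.sqrt(n)

    def test_out_of_range_values_warn(self):
        shape = (2, 2, 2)
        vol = am.IntensityVolume(np.full(shape, 5000.0), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="standardized"):
            am.mean_standardized_intensity(vol, np.ones(shape, dtype=bool))

    def test_distance_arithmetic_symmetry_and_identity(self):
        class G:  # minimal stand-in carrying only a centroid
            def __init__(self, c):
                self.centroid = np.asarray(c, dtype=float)

        a, b = G([0, 0, 0]), G([30.0, 0, 0])
        assert am.inter_object_distance(a, b, 150.0) == pytest.approx(0.2)
        assert am.inter_object_distance(b, a, 150.0) == pytest.approx(0.2)
        assert am.inter_object_distance(a, a, 150.0) == 0.0


class TestExtraction:
    def test_full_vector_has_159_features_in_catalog_order(
            self, phantom, standardizer):
        cohort, _ = phantom
        feats = am.extract_features(cohort.subjects[0], standardizer)
        assert len(feats) == 159
        assert list(feats.index) == list(am.CATALOG)
        assert np.isfinite(feats.to_numpy()).all()

    def test_extraction_is_deterministic(self, phantom, standardizer):
        cohort, _ = phantom
        a = am.extract_features(cohort.subjects[3], standardizer)
        b = am.extract_features(cohort.subjects[3], standardizer)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_table_matches_per_subject_extraction(self, phantom, standardizer,
                                                  phantom_table):
        cohort, _ = phantom
        row = am.extract_features(cohort.subjects[5], standardizer)
        np.testing.assert_allclose(
            phantom_table.data.iloc[5].to_numpy(), row.to_numpy(), rtol=1e-12)
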