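"""Phantom generators: seeded determinism, exact truth, failure injection."""

import numpy as np
import pytest

from epifat.eat import compute_volume_ml
from epifat.errors import InvalidGeometryError, ParameterError, PlacementError
from epifat.phantom import (
    AbdominalShapeParams,
    CardiacShapeParams,
    FailureSpec,
    generate_abdominal_phantom,
    generate_cardiac_phantom,
    inject_segmentation_failure,
)
from .conftest import SMALL_CARDIAC


def test_seeded_determinism_cardiac():
    v1, t1 = generate_cardiac_phantom(SMALL_CARDIAC, noise_sd_hu=8.0, seed=42)
    v2, t2 = generate_cardiac_phantom(SMALL_CARDIAC, noise_sd_hu=8.0, seed=42)
    assert np.array_equal(v1.data, v2.data)
    assert np.array_equal(t1.pericardium_mask, t2.pericardium_mask)
    assert t1.true_eatv_ml == t2.true_eatv_ml
    assert t1.true_eata_hu == t2.true_eata_hu


def test_seeded_determinism_abdominal():
    v1, t1 = generate_abdominal_phantom(noise_sd_hu=5.0, seed=9)
    v2, t2 = generate_abdominal_phantom(noise_sd_hu=5.0, seed=9)
    assert np.array_equal(v1.data, v2.data)
    assert t1.true_vat_cm2 == t2.true_vat_cm2


def test_truth_conservation_brute_force(small_phantom):
    """Stored EATV equals an exhaustive voxel count on the fat label."""
    vol, truth = small_phantom
    fat = truth.pericardium_mask & ~truth.chamber_mask
    count = 0
    for flag in fat.reshape(-1):
        count += bool(flag)
    assert truth.true_eatv_ml == count * np.prod(vol.spacing) / 1000.0


def test_chamber_subset_of_pericardium(small_phantom):
    _, truth = small_phantom
    assert not (truth.chamber_mask & ~truth.pericardium_mask).any()


def test_noiseless_eata_equals_center(small_phantom):
    _, truth = small_phantom
    assert truth.true_eata_hu == truth.fat_center_hu == -70.0


def test_resolution_refinement_toward_analytic_shell():
    """Finer grids drive the discrete shell volume toward 4/3 pi (abc_o - abc_i)."""
    outer, inner = (24.0, 21.0, 18.0), (18.0, 15.0, 12.0)
    analytic = 4.0 / 3.0 * np.pi * (np.prod(outer) - np.prod(inner)) / 1000.0
    errors = []
    for spacing in (3.0, 1.5, 0.75):
        n = int(np.ceil(2 * 26.0 / spacing)) + 4
        params = CardiacShapeParams(
            shape=(n, n, n),
            spacing=(spacing,) * 3,
            pericardium_axes_mm=outer,
            chamber_axes_mm=inner,
            chest_wall=False,
        )
        _, truth = generate_cardiac_phantom(params, noise_sd_hu=0.0, seed=0)
        errors.append(abs(truth.true_eatv_ml - analytic))
    assert errors[0] > errors[-1]
    assert errors[-1] / analytic < 0.02


def test_geometry_exceeding_grid_raises():
    bad = CardiacShapeParams(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))
    with pytest.raises(InvalidGeometryError):
        generate_cardiac_phantom(bad, seed=0)


def test_chamber_larger_than_pericardium_raises():
    bad = CardiacShapeParams(
        pericardium_axes_mm=(30.0, 30.0, 30.0), chamber_axes_mm=(31.0, 20.0, 20.0)
    )
    with pytest.raises(InvalidGeometryError):
        generate_cardiac_phantom(bad, seed=0)


class TestFailureInjection:
    @pytest.mark.parametrize("magnitude_ml", [2.0, 4.0])
    def test_add_blob_volume_within_one_voxel(self, small_phantom, magnitude_ml):
        vol, truth = small_phantom
        spec = FailureSpec("add_blob", magnitude_ml, offset_mm=12.0, seed=5,
                           direction=(0.0, 0.0, 1.0))
        bad = inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)
        diff = compute_volume_ml(bad, vol.spacing) - compute_volume_ml(
            truth.pericardium_mask, vol.spacing
        )
        assert abs(diff - magnitude_ml) <= vol.voxel_volume_mm3 / 1000.0

    def test_original_mask_unmodified(self, small_phantom):
        vol, truth = small_phantom
        before = truth.pericardium_mask.copy()
        spec = FailureSpec("delete_wedge", 3.0, seed=1)
        inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)
        assert np.array_equal(before, truth.pericardium_mask)

    def test_delete_wedge_removes_magnitude(self, small_phantom):
        vol, truth = small_phantom
        spec = FailureSpec("delete_wedge", 4.0, seed=3)
        bad = inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)
        diff = compute_volume_ml(truth.pericardium_mask, vol.spacing) - compute_volume_ml(
            bad, vol.spacing
        )
        assert abs(diff - 4.0) <= vol.voxel_volume_mm3 / 1000.0
        assert not (bad & ~truth.pericardium_mask).any()

    def test_delete_more_than_exists_raises(self, small_phantom):
        vol, truth = small_phantom
        total = compute_volume_ml(truth.pericardium_mask, vol.spacing)
        with pytest.raises(ParameterError):
            inject_segmentation_failure(
                truth.pericardium_mask,
                FailureSpec("delete_wedge", total + 1.0, seed=0),
                vol.spacing,
            )

    def test_blob_outside_grid_raises(self, small_phantom):
        vol, truth = small_phantom
        spec = FailureSpec("add_blob", 5.0, offset_mm=500.0, seed=0)
        with pytest.raises(PlacementError):
            inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)

    def test_touching_blob_is_valid(self, small_phantom):
        """offset 0 places the blob at the surface: still a legal corruption."""
        vol, truth = small_phantom
        spec = FailureSpec("add_blob", 0.5, offset_mm=0.0, seed=2,
                           direction=(0.0, 0.0, -1.0))
        bad = inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)
        assert bad.sum() > truth.pericardium_mask.sum()

    def test_leak_adds_connected_finger(self, small_phantom):
        from scipy import ndimage

        vol, truth = small_phantom
        spec = FailureSpec("leak_to_chest_wall", 3.0, offset_mm=15.0, seed=4,
                           direction=(1.0, 0.0, 0.0))
        bad = inject_segmentation_failure(truth.pericardium_mask, spec, vol.spacing)
        diff = compute_volume_ml(bad, vol.spacing) - compute_volume_ml(
            truth.pericardium_mask, vol.spacing
        )
        assert abs(diff - 3.0) <= vol.voxel_volume_mm3 / 1000.0
        _, n = ndimage.label(bad, structure=np.ones((3, 3, 3)))
        assert n == 1  # the finger stays attached

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            FailureSpec("swap", 1.0)


class TestAbdominalPhantom:
    def test_areas_match_pixel_enumeration(self, abdominal_phantom):
        vol, truth = abdominal_phantom
        vat_px = truth.fat_mask & ~truth.lean_wall_mask
        # reconstruct the VAT subset: fat pixels painted at the VAT HU
        vat_like = truth.fat_mask & (np.abs(vol.data - (-88.0)) < 1.0)
        assert truth.true_vat_cm2 == int(vat_like.sum()) * np.prod(vol.spacing) / 100.0
        assert truth.true_vat_cm2 + truth.true_sat_cm2 == pytest.approx(
            int(truth.fat_mask.sum()) * np.prod(vol.spacing) / 100.0
        )
        assert vat_px.sum() == truth.fat_mask.sum()  # wall and fat disjoint

    def test_zero_width_sat_annulus(self):
        params = AbdominalShapeParams(
            vat_axes_mm=(40.0, 36.0),
            wall_thickness_mm=6.0,
            sat_outer_axes_mm=(46.0, 42.0),  # equals the wall outer ellipse
            shape=(128, 128),
        )
        _, truth = generate_abdominal_phantom(params, noise_sd_hu=0.0, seed=0)
        assert truth.true_sat_cm2 == 0.0
        assert truth.true_sat_hu is None
        assert truth.true_vat_cm2 > 0

    def test_open_ring_with_vat_raises(self):
        with pytest.raises(InvalidGeometryError):
            generate_abdominal_phantom(
                AbdominalShapeParams(wall_gap_deg=30.0), seed=0
            )

    def test_outer_ellipse_must_fit(self):
        with pytest.raises(InvalidGeometryError):
            generate_abdominal_phantom(
                AbdominalShapeParams(shape=(64, 64)), seed=0
            )
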