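"""Synthetic phantom rasterization, ground truth and DECT simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from wetspr import (
    CouchSpec,
    EllipseShape,
    HardeningModel,
    PhantomSpec,
    cylinder_phantom,
    ellipse_phantom,
    ground_truth_wet,
    phantom_sweep,
    rasterize,
    simulate_dect,
)
from wetspr.surrogates import PMMA, default_surrogates


def attenuation_area(img):
    return img.pixels.sum() * img.spacing_x * img.spacing_y


class TestRasterize:
    @pytest.mark.parametrize(
        "a, b, rot",
        [(100, 100, 0), (100, 50, 0), (100, 50, 30), (80, 40, 45)],
    )
    def test_uniform_ellipse_area_within_pct(self, a, b, rot):
        spec = ellipse_phantom(a, b, 1.0, rot)
        area = attenuation_area(rasterize(spec))
        assert area == pytest.approx(math.pi * a * b, rel=2e-3)

    def test_empty_shape_list_gives_zero_image(self):
        img = rasterize(PhantomSpec(16, 16))
        assert np.all(img.pixels == 0)

    def test_disjoint_disks_areas_add(self):
        one = PhantomSpec(100, 200, shapes=(EllipseShape(-50, 0, 20, 20, 0, 1.0),))
        other = PhantomSpec(100, 200, shapes=(EllipseShape(50, 0, 20, 20, 0, 0.5),))
        both = PhantomSpec(100, 200, shapes=one.shapes + other.shapes)
        total = attenuation_area(rasterize(both))
        assert total == pytest.approx(
            attenuation_area(rasterize(one)) + attenuation_area(rasterize(other)), rel=1e-12
        )

    def test_overlapping_shape_overwrites(self):
        spec = PhantomSpec(
            80, 80,
            shapes=(EllipseShape(0, 0, 30, 30, 0, 1.0), EllipseShape(0, 0, 10, 10, 0, 2.0)),
        )
        img = rasterize(spec)
        n_rows, n_cols = img.shape
        assert img.pixels[n_rows // 2, n_cols // 2] == pytest.approx(2.0)
        assert img.pixels[n_rows // 2, n_cols // 2 + 20] == pytest.approx(1.0)

    def test_shape_exceeding_grid_rejected(self):
        spec = PhantomSpec(50, 50, shapes=(EllipseShape(0, 0, 40, 40, 0, 1.0),))
        with pytest.raises(ValueError, match="exceeds"):
            rasterize(spec)

    def test_deterministic_for_fixed_spec(self):
        spec = ellipse_phantom(60, 30, 1.1, 17)
        np.testing.assert_array_equal(rasterize(spec).pixels, rasterize(spec).pixels)


class TestGroundTruth:
    def test_ellipse_closed_form(self):
        spec = ellipse_phantom(100, 50, 1.0)
        assert ground_truth_wet(spec) == pytest.approx(2 * math.sqrt(100 * 50), abs=1e-4)

    def test_uniform_cylinder_is_diameter_times_mu(self):
        spec = ellipse_phantom(50, 50, 1.1)
        assert ground_truth_wet(spec) == pytest.approx(110.0)

    def test_rotation_free(self):
        assert ground_truth_wet(ellipse_phantom(100, 50, 1.0, 45)) == pytest.approx(
            ground_truth_wet(ellipse_phantom(100, 50, 1.0, 0))
        )

    def test_inhomogeneity_shifts_mean_attenuation(self):
        inh = EllipseShape(40, 40, 10, 10, 0, 1.5)
        spec = ellipse_phantom(100, 100, 1.0, inhomogeneities=[inh])
        expected = 200.0 * (1.0 + 0.5 * (10 * 10) / (100 * 100))
        assert ground_truth_wet(spec) == pytest.approx(expected)

    def test_second_primary_ellipse_rejected(self):
        outside = EllipseShape(150, 0, 20, 20, 0, 1.0)
        spec = PhantomSpec(400, 400, shapes=(EllipseShape(0, 0, 50, 50, 0, 1.0), outside))
        with pytest.raises(ValueError, match="primary"):
            ground_truth_wet(spec)


class TestHardeningModel:
    def test_bias_arithmetic(self):
        model = HardeningModel(w0=200.0, g_low=-5e-5)
        # mu 1.2 at W = W0 + 200 -> 1.2 * (1 - 0.01) = 1.188
        assert 1.2 * model.bias_factor(400.0, "low") == pytest.approx(1.188)

    def test_zero_bias_at_reference_wet(self):
        model = HardeningModel()
        for energy in ("low", "high"):
            assert model.bias_factor(model.w0, energy, is_bone=True) == 1.0

    def test_bone_gets_extra_slope(self):
        model = HardeningModel()
        soft = model.bias_factor(400.0, "low", is_bone=False)
        bone = model.bias_factor(400.0, "low", is_bone=True)
        assert bone == pytest.approx(soft * (1 + model.b_low * 200.0))


class TestSimulateDect:
    def test_zero_noise_zero_slopes_reproduces_nominal_hu(self):
        flat = HardeningModel(g_low=0, g_high=0, b_low=0, b_high=0)
        spec = cylinder_phantom(150, hardening=flat)
        de, table = simulate_dect(spec)
        for row, mat in zip(table.itertuples(), default_surrogates()):
            assert row.H_low == pytest.approx((mat.mu_low - 1) * 1000, abs=1e-9)
            assert row.H_high == pytest.approx((mat.mu_high - 1) * 1000, abs=1e-9)

    def test_roi_mean_equals_biased_hu_exactly(self):
        spec = cylinder_phantom(300)
        de, table = simulate_dect(spec)
        wet = ground_truth_wet(spec)
        model = spec.hardening
        for row, ins in zip(table.itertuples(), spec.inserts):
            mu = ins.mu_low * model.bias_factor(wet, "low", is_bone=ins.is_bone)
            assert row.H_low == pytest.approx((mu - 1) * 1000, abs=1e-9)

    def test_same_seed_identical_noisy_images(self):
        a = simulate_dect(cylinder_phantom(100, noise_sigma_hu=10, seed=5))[0]
        b = simulate_dect(cylinder_phantom(100, noise_sigma_hu=10, seed=5))[0]
        np.testing.assert_array_equal(a.low.pixels, b.low.pixels)
        np.testing.assert_array_equal(a.high.pixels, b.high.pixels)

    def test_missing_hardening_model_rejected(self):
        spec = ellipse_phantom(50, 50, 1.0)
        with pytest.raises(ValueError, match="HardeningModel"):
            simulate_dect(spec)

    def test_wet_column_is_ground_truth(self):
        spec = cylinder_phantom(200)
        _, table = simulate_dect(spec)
        assert table["wet_mm"].unique() == pytest.approx([200 * PMMA.mu_low])


class TestPhantomSweep:
    def test_ground_truth_wets_scale_with_diameter(self):
        sweep = phantom_sweep([75, 400], seed=0)
        wets = [t["wet_mm"].iloc[0] for _, _, t in sweep]
        assert wets[0] == pytest.approx(75 * PMMA.mu_low)
        assert wets[1] == pytest.approx(400 * PMMA.mu_low)

    def test_single_diameter(self):
        assert len(phantom_sweep([200])) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            phantom_sweep([])

    def test_duplicate_diameters_get_independent_noise(self):
        a, b = phantom_sweep([100, 100], seed=3, noise_sigma_hu=15)
        assert not np.array_equal(a[1].low.pixels, b[1].low.pixels)


class TestCouchGeometry:
    def test_couch_rendered_below_object(self):
        spec = cylinder_phantom(100, materials=(), couch=CouchSpec())
        img = rasterize(spec)
        xs_mid = img.shape[1] // 2
        col = img.pixels[:, xs_mid]
        body_rows = np.where(np.isclose(col, PMMA.mu_low, atol=1e-6))[0]
        couch_rows = np.where(np.isclose(col, 0.3, atol=1e-6))[0]
        assert couch_rows.min() > body_rows.max()  # row index grows downward

    def test_couch_parameters_validated(self):
        with pytest.raises(ValueError):
            CouchSpec(width=-1)
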