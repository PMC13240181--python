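"""Thickness estimation methods: closed-form oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wetspr import (
    AttenuationImage,
    CouchSpec,
    EllipseShape,
    cylinder_phantom,
    ellipse_phantom,
    estimate,
    estimate_profile,
    ground_truth_wet,
    max_pairwise_deviation,
    rasterize,
    tem_a,
    tem_b1,
    tem_b2,
)
from wetspr.tem import WetEstimate, WetProfile

METHODS = {"tem-a": tem_a, "tem-b1": tem_b1, "tem-b2": tem_b2}


def brute_force(method, pixels, sx, sy):
    """Independent double-loop implementation of each estimator."""
    mu = [[max(v, 0.0) for v in row] for row in pixels.tolist()]
    m, n = len(mu), len(mu[0])
    if method == "tem-a":
        best_row = max(sum(mu[i][j] * sx for j in range(n)) for i in range(m))
        best_col = max(sum(mu[i][j] * sy for i in range(m)) for j in range(n))
        return math.sqrt(best_row * best_col)
    total = 0.0
    for i in range(m):
        for j in range(n):
            w = mu[i][j] if method == "tem-b1" else mu[i][j] ** 2
            total += w * sx * sy
    return 2.0 * math.sqrt(total / math.pi)


def directional_chord(a, b, theta_deg):
    """Longest chord of an ellipse along a fixed direction (through the centre)."""
    t = math.radians(theta_deg)
    return 2.0 / math.sqrt(math.cos(t) ** 2 / a**2 + math.sin(t) ** 2 / b**2)


class TestClosedForms:
    def test_uniform_circle(self):
        img = rasterize(ellipse_phantom(100, 100, 1.0))
        assert tem_a(img) == pytest.approx(200.0, rel=0.01)
        assert tem_b1(img) == pytest.approx(200.0, rel=0.002)
        assert tem_b2(img) == pytest.approx(200.0, rel=0.002)

    def test_axis_aligned_ellipse(self):
        img = rasterize(ellipse_phantom(100, 50, 1.0))
        expected = 2 * math.sqrt(100 * 50)
        assert tem_a(img) == pytest.approx(expected, rel=0.01)
        assert tem_b1(img) == pytest.approx(expected, rel=0.002)

    def test_tem_a_rotated_ellipse_follows_directional_chords(self):
        img = rasterize(ellipse_phantom(100, 50, 1.0, 45))
        # at 45 deg both directional chords coincide
        expected = directional_chord(100, 50, 45)
        assert expected == pytest.approx(126.491, abs=1e-3)
        assert tem_a(img) == pytest.approx(expected, rel=0.01)

    def test_tem_b1_attenuation_scaled_circle(self):
        # D=100, mu=1.1: equal-area circle of the attenuation area -> 100*sqrt(1.1)
        img = rasterize(ellipse_phantom(50, 50, 1.1, spacing=0.25))
        assert tem_b1(img) == pytest.approx(100 * math.sqrt(1.1), rel=0.002)

    def test_tem_b2_attenuation_weighted_circle(self):
        # quadratic weighting recovers D*mu for a uniform object
        img = rasterize(ellipse_phantom(50, 50, 1.1, spacing=0.25))
        assert tem_b2(img) == pytest.approx(110.0, rel=0.002)

    @pytest.mark.parametrize("fn", [tem_a, tem_b1, tem_b2])
    def test_all_zero_image(self, fn):
        img = AttenuationImage(np.zeros((10, 10)), 1.0, 1.0)
        assert fn(img) == 0.0


class TestInvariants:
    def test_b2_equals_b1_on_binary_images(self):
        rng = np.random.default_rng(7)
        pixels = (rng.random((40, 40)) > 0.6).astype(float)
        img = AttenuationImage(pixels, 0.8, 1.2)
        assert tem_b2(img) == pytest.approx(tem_b1(img), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        hnp.arrays(np.float64, (9, 7), elements=st.floats(0, 3, width=64)),
        st.floats(0.0, 4.0),
    )
    def test_scaling_laws(self, pixels, k):
        img = AttenuationImage(pixels, 1.0, 1.0)
        scaled = AttenuationImage(pixels * k, 1.0, 1.0)
        assert tem_a(scaled) == pytest.approx(k * tem_a(img), rel=1e-9, abs=1e-9)
        assert tem_b2(scaled) == pytest.approx(k * tem_b2(img), rel=1e-9, abs=1e-9)
        assert tem_b1(scaled) == pytest.approx(math.sqrt(k) * tem_b1(img), rel=1e-9, abs=1e-9)

    def test_negative_attenuation_clipped_before_sums(self):
        with_noise = AttenuationImage(np.array([[1.0, -0.5], [0.0, 1.0]]), 1.0, 1.0)
        clean = AttenuationImage(np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0, 1.0)
        for fn in (tem_a, tem_b1, tem_b2):
            assert fn(with_noise) == fn(clean)

    @pytest.mark.parametrize("method", list(METHODS))
    def test_brute_force_oracle_equivalence(self, method):
        rng = np.random.default_rng(42)
        for _ in range(50):
            shape = rng.integers(1, 33, size=2)
            pixels = rng.random(shape) * rng.choice([0.1, 1.0, 3.0])
            img = AttenuationImage(pixels, 0.7, 1.9)
            fast = METHODS[method](img)
            slow = brute_force(method, pixels, 0.7, 1.9)
            assert fast == pytest.approx(slow, rel=1e-12)


class TestRotationRobustness:
    def test_b_methods_rotation_invariant_a_is_not(self):
        angles = range(0, 91, 15)
        wets = {m: [] for m in METHODS}
        for theta in angles:
            img = rasterize(ellipse_phantom(100, 50, 1.0, theta))
            for m, fn in METHODS.items():
                wets[m].append(fn(img))
        gt = 2 * math.sqrt(100 * 50)
        for m in ("tem-b1", "tem-b2"):
            v = np.array(wets[m])
            assert 100 * (v.max() - v.min()) / v.mean() < 0.2
        dev_45 = 100 * (wets["tem-a"][3] / gt - 1)
        assert dev_45 == pytest.approx(100 * (directional_chord(100, 50, 45) / gt - 1), abs=0.5)


class TestOffCenterInhomogeneity:
    def test_a_blind_b1_sees_equal_area_amount(self):
        base = ellipse_phantom(100, 100, 1.0)
        inh = EllipseShape(50, 50, 10, 10, 0, 1.5)  # away from central row/column
        spec = ellipse_phantom(100, 100, 1.0, inhomogeneities=[inh])
        img0, img1 = rasterize(base), rasterize(spec)
        assert abs(tem_a(img1) / tem_a(img0) - 1) < 1e-3
        expected_b1 = 2 * math.sqrt(100**2 + 0.5 * 10**2)  # 200.50 mm
        assert tem_b1(img1) == pytest.approx(expected_b1, rel=0.002)


class TestCouchEffect:
    @pytest.mark.parametrize("diameter", [75, 100, 150])
    def test_couch_inflates_every_method(self, diameter):
        bare = rasterize(cylinder_phantom(diameter, materials=()))
        couched = rasterize(cylinder_phantom(diameter, materials=(), couch=CouchSpec()))
        for fn in METHODS.values():
            assert fn(couched) > fn(bare)

    @pytest.mark.parametrize("diameter", [75, 100])
    def test_tem_a_most_affected_when_couch_dominates_projections(self, diameter):
        # the couch's horizontal projection (width*mu = 150 mm) exceeds the
        # body's maximum chord for these diameters, shifting TEM-A's maximum
        # x-projection onto the couch surface
        bare = rasterize(cylinder_phantom(diameter, materials=()))
        couched = rasterize(cylinder_phantom(diameter, materials=(), couch=CouchSpec()))
        inflation = {m: fn(couched) - fn(bare) for m, fn in METHODS.items()}
        assert inflation["tem-a"] >= inflation["tem-b1"]


class TestProfiles:
    def test_identical_slices_identical_estimates(self):
        img = rasterize(ellipse_phantom(50, 50, 1.0))
        profile = estimate_profile("tem-b1", [img, img, img])
        wets = profile.wet_mm
        assert len(profile) == 3
        assert np.all(wets == wets[0])
        assert profile.summary == wets[0]

    def test_single_slice_profile(self):
        img = rasterize(ellipse_phantom(30, 30, 1.0))
        assert len(estimate_profile("tem-a", [img])) == 1

    def test_empty_slice_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_profile("tem-a", [])

    def test_mixed_methods_in_profile_rejected(self):
        e1 = WetEstimate("tem-a", 0, 100.0)
        e2 = WetEstimate("tem-b1", 1, 100.0)
        with pytest.raises(ValueError, match="method"):
            WetProfile("tem-a", (e1, e2))

    def test_unknown_method_rejected(self):
        img = rasterize(ellipse_phantom(30, 30, 1.0))
        with pytest.raises(ValueError, match="unknown"):
            estimate("tem-c", img)


class TestMaxPairwiseDeviation:
    def _profile(self, method, values):
        return WetProfile(method, tuple(WetEstimate(method, i, v) for i, v in enumerate(values)))

    def test_identical_profiles_zero(self):
        p = self._profile("tem-a", [100, 200])
        q = self._profile("tem-b1", [100, 200])
        assert max_pairwise_deviation([p, q])["max_mm"] == 0.0

    def test_two_profiles_mm_and_percent(self):
        p = self._profile("tem-a", [200.0])
        q = self._profile("tem-b1", [210.0])
        out = max_pairwise_deviation([p, q])
        assert out["max_mm"] == pytest.approx(10.0)
        assert out["max_pct"] == pytest.approx(100 * 10 / 205, abs=1e-3)

    def test_three_profiles_pairwise_max(self):
        ps = [self._profile(m, [v]) for m, v in zip(METHODS, (200.0, 205.0, 210.0))]
        assert max_pairwise_deviation(ps)["max_mm"] == pytest.approx(10.0)

    def test_length_mismatch_rejected(self):
        p = self._profile("tem-a", [100, 200])
        q = self._profile("tem-b1", [100])
        with pytest.raises(ValueError, match="length"):
            max_pairwise_deviation([p, q])
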