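"""Semi-quantitative comparator: MPR, axis measurement, volume, ROI, rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calcnet import (CalcMask, CalcnetError, CTStack, ellipsoid_volume,
                     make_5mm_mpr, mean_attenuation_roi, measure_axes,
                     semiquant_classify)
from calcnet.semiquant import SemiQuantMeasurement, measure_stack


def digitized_ellipsoid(axes_mm, shape=(40, 40, 40), rotation=None):
    """Boolean mask of an ellipsoid with full axis lengths `axes_mm`."""
    g = np.indices(shape).astype(float)
    c = (np.array(shape) - 1) / 2.0
    rel = np.stack([g[i] - c[i] for i in range(3)], axis=-1)
    if rotation is not None:
        rel = rel @ rotation
    semi = np.asarray(axes_mm) / 2.0
    return (np.square(rel / semi).sum(axis=-1) <= 1.0)


class TestMPR:
    def test_uniform_stays_uniform(self, uniform_stack):
        out = make_5mm_mpr(uniform_stack(300.0, shape=(10, 10, 50)))
        assert np.allclose(out.values, 300.0)
        assert out.spacing[2] == 5.0

    def test_fifty_slices_become_ten(self, uniform_stack):
        out = make_5mm_mpr(uniform_stack(0.0, shape=(10, 10, 50)))
        assert out.shape == (10, 10, 10)

    def test_alternating_slices_average_by_phase(self):
        """z-profile 0,100,0,100,... -> 5-slice means 40 and 60 alternating."""
        v = np.zeros((4, 4, 50), dtype=np.float32)
        v[:, :, 1::2] = 100.0
        out = make_5mm_mpr(CTStack(v, (1, 1, 1)))
        # slabs starting at even z hold 3 zeros + 2 hundreds -> 40
        expected = [40.0, 60.0] * 5
        assert np.allclose(out.values[0, 0, :], expected)

    def test_non_multiple_of_five_pads_by_replication(self, uniform_stack):
        out = make_5mm_mpr(uniform_stack(120.0, shape=(6, 6, 48)))
        assert out.shape[2] == 10
        assert np.allclose(out.values, 120.0)

    def test_requires_1mm_slices(self, uniform_stack):
        with pytest.raises(CalcnetError):
            make_5mm_mpr(uniform_stack(0.0, spacing=(1.0, 1.0, 2.0)))


class TestMeasureAxes:
    def test_axis_aligned_ellipsoid(self):
        mask = CalcMask(digitized_ellipsoid((8, 6, 4)), "e")
        W, L, H = measure_axes(mask)
        assert abs(W - 8) <= 1 and abs(L - 6) <= 1 and abs(H - 4) <= 1
        assert W >= L >= H

    def test_single_voxel(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        assert measure_axes(CalcMask(m, "v")) == (1.0, 1.0, 1.0)

    def test_rotation_invariance(self):
        theta = math.pi / 4
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1]])
        straight = measure_axes(CalcMask(digitized_ellipsoid((8, 6, 4)), "a"))
        rotated = measure_axes(
            CalcMask(digitized_ellipsoid((8, 6, 4), rotation=rot), "b"))
        for s, r in zip(straight, rotated):
            assert abs(s - r) <= 1.0

    def test_anisotropic_spacing_honoured(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[2:7, 4, 4] = True  # 5 voxels along x
        W, L, H = measure_axes(CalcMask(m, "s", spacing=(2.0, 1.0, 1.0)))
        assert abs(W - 10.0) <= 2.0  # 5 voxels at 2 mm

    def test_empty_mask_rejected(self):
        with pytest.raises(CalcnetError):
            measure_axes(CalcMask(np.zeros((5, 5, 5), dtype=bool), "e"))


class TestEllipsoidVolume:
    def test_analytic_values(self):
        assert abs(ellipsoid_volume(2, 2, 2) - 4.18879) < 1e-5
        assert math.isclose(ellipsoid_volume(1, 1, 1), math.pi / 6,
                            rel_tol=1e-12)
        assert abs(ellipsoid_volume(8, 6, 4) - 100.53096) < 1e-4

    def test_non_positive_axis_rejected(self):
        with pytest.raises(CalcnetError):
            ellipsoid_volume(0, 1, 1)

    @given(st.floats(0.5, 20), st.floats(0.5, 20), st.floats(0.5, 20),
           st.floats(0.1, 3))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_degree_three_homogeneous(self, w, l, h, k):
        v = ellipsoid_volume(w, l, h)
        assert math.isclose(v, ellipsoid_volume(h, w, l), rel_tol=1e-12)
        assert math.isclose(ellipsoid_volume(k * w, k * l, k * h), k ** 3 * v,
                            rel_tol=1e-9)


class TestMeanAttenuationROI:
    def _stack_with_sphere(self, inner_hu, outer_hu=700.0, d=10.0):
        shape = (40, 40, 50)
        g = np.indices(shape).astype(float)
        c = np.array([19.5, 19.5, 24.5])
        r = np.sqrt(((g - c[:, None, None, None]) ** 2).sum(axis=0))
        v = np.full(shape, -100.0, dtype=np.float32)
        v[r <= d / 2] = outer_hu
        v[r <= d / 6] = inner_hu
        mask = CalcMask(v >= 250.0, "roi")
        return CTStack(v, (1, 1, 1), id="roi"), mask

    def test_uniform_calcification(self):
        # large enough that the central ROI sits fully inside the plateau
        # across the whole 5-mm slab
        stack, mask = self._stack_with_sphere(700.0, 700.0, d=16.0)
        assert abs(mean_attenuation_roi(make_5mm_mpr(stack), mask) - 700.0) < 1.0

    def test_partial_volume_lowers_small_body_mean(self):
        # a 10-mm sphere does not fill the 5-mm slab, so slab averaging
        # mixes in fat: the measured mean drops below the true 700 HU
        stack, mask = self._stack_with_sphere(700.0, 700.0, d=10.0)
        roi = mean_attenuation_roi(make_5mm_mpr(stack), mask)
        assert 250.0 < roi < 700.0

    def test_central_lucency_pulls_mean_down(self):
        stack, mask = self._stack_with_sphere(100.0, 700.0)
        hollow = mean_attenuation_roi(make_5mm_mpr(stack), mask)
        solid = mean_attenuation_roi(make_5mm_mpr(
            self._stack_with_sphere(700.0, 700.0)[0]), mask)
        assert hollow < solid

    def test_constant_region_is_exact(self):
        stack, mask = self._stack_with_sphere(643.0, 643.0, d=16.0)
        roi = mean_attenuation_roi(make_5mm_mpr(stack), mask)
        # central ROI on a 16 mm body stays fully inside the 643 HU plateau
        assert abs(roi - 643.0) < 1.0

    def test_empty_mask_rejected(self, uniform_stack):
        with pytest.raises(CalcnetError):
            mean_attenuation_roi(make_5mm_mpr(uniform_stack(0., shape=(10, 10, 50))),
                                 CalcMask(np.zeros((10, 10, 50), dtype=bool), "e"))


class TestClassify:
    @pytest.mark.parametrize("hu,vol,expected", [
        (650.0, 100.0, "stone"),        # attenuation above cutoff
        (600.0, 200.0, "stone"),        # volume above cutoff
        (600.0, 100.0, "phlebolith"),   # both at or below cutoffs
    ])
    def test_published_rule(self, hu, vol, expected):
        assert semiquant_classify(hu, vol) == expected

    def test_cutoffs_configurable(self):
        assert semiquant_classify(600.0, 172.0, vol_cutoff=173.0) == "phlebolith"
        assert semiquant_classify(600.0, 172.0, vol_cutoff=171.0) == "stone"

    @given(st.floats(0, 2000), st.floats(0, 500),
           st.floats(0, 500), st.floats(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_inputs(self, hu, vol, dhu, dvol):
        base = semiquant_classify(hu, vol)
        if base == "stone":
            assert semiquant_classify(hu + dhu, vol + dvol) == "stone"

    def test_non_finite_rejected(self):
        with pytest.raises(CalcnetError):
            semiquant_classify(float("nan"), 100.0)


class TestMeasurementRecord:
    def test_volume_consistency_enforced(self):
        with pytest.raises(CalcnetError):
            SemiQuantMeasurement(W=2, L=2, H=2, volume=5.0, mean_hu=300.0)

    def test_full_chain_on_phantom(self, stone_stack, stone_mask):
        m = measure_stack(stone_stack, stone_mask)
        assert m.W >= m.L >= m.H > 0
        assert math.isclose(m.volume, ellipsoid_volume(m.W, m.L, m.H),
                            rel_tol=1e-12)
        assert m.mean_hu > 250.0  # ROI sits on the calcification
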