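"""MSR integration, threshold profiles and critical-threshold detection."""

import numpy as np
import pytest

from msrelevance import (MSRProfile, RRCurve, RRPoint, critical_thresholds,
                         default_a_grid, gradient_msr, msr, msr_profile,
                         scale_set, segment, rr_curve)


def curve_from_normalized(points, N=16):
    hmax = np.log2(N)
    return RRCurve(points=[(i + 1, RRPoint(x * hmax, y * hmax))
                           for i, (x, y) in enumerate(points)], N=N)


class TestMSRIntegral:
    def test_triangle_area(self):
        c = curve_from_normalized([(0.0, 0.0), (0.5, 0.5), (1.0, 0.0)])
        assert msr(c) == pytest.approx(0.25, abs=1e-12)

    def test_flat_zero_curve(self):
        c = curve_from_normalized([(0.0, 0.0), (1.0, 0.0)])
        assert msr(c) == 0.0

    def test_origin_anchor_prepended(self):
        # curve that starts away from the origin: the segment to (0,0) counts
        c = curve_from_normalized([(0.5, 0.5), (1.0, 0.5)])
        assert msr(c) == pytest.approx(0.5 * 0.5 * 0.5 + 0.5 * 0.5, abs=1e-12)

    def test_duplicate_resolutions_averaged(self):
        c = curve_from_normalized([(0.5, 0.2), (0.5, 0.4), (1.0, 0.0)])
        expected = 0.5 * 0.5 * 0.3 + 0.5 * (0.3 + 0.0) / 2
        assert msr(c) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_curve_warns_and_returns_zero(self):
        c = curve_from_normalized([(0.7, 0.3), (0.7, 0.1)])
        with pytest.warns(UserWarning):
            assert msr(c) == 0.0

    def test_unit_interval_bound(self, field_h0_128):
        for a in (0.2, 0.5, 0.8):
            b = segment(field_h0_128.values, a)
            val = msr(rr_curve(b, scale_set(128, "geometric")))
            assert 0.0 <= val <= 1.0

    def test_trapezoid_close_to_refined_riemann(self, field_h0_128):
        """Geometric-scale trapezoid integral within 1% of the full
        integer-scale evaluation (dense Riemann reference)."""
        b = segment(field_h0_128.values, 0.5)
        coarse = msr(rr_curve(b, scale_set(128, "geometric")))
        fine = msr(rr_curve(b, scale_set(128, "full")))
        assert coarse == pytest.approx(fine, rel=0.01)


class TestCriticalThresholds:
    def _profile(self, values):
        a = np.linspace(0.02, 0.98, len(values))
        return MSRProfile(a_grid=a, msr_values=np.asarray(values, dtype=float))

    def test_unimodal(self):
        a = np.linspace(0.02, 0.98, 49)
        prof = self._profile(np.exp(-((a - 0.5) ** 2) / 0.02))
        found = critical_thresholds(prof)
        assert len(found) == 1
        assert found[0] == pytest.approx(0.5, abs=0.03)

    def test_symmetric_bimodal(self):
        a = np.linspace(0.02, 0.98, 49)
        prof = self._profile(np.exp(-((a - 0.35) ** 2) / 0.005)
                             + np.exp(-((a - 0.65) ** 2) / 0.005))
        found = critical_thresholds(prof)
        assert len(found) == 2
        assert found[0] + found[1] == pytest.approx(1.0, abs=0.05)

    def test_flat_profile_flagged(self):
        prof = self._profile(np.full(49, 0.3))
        assert critical_thresholds(prof) == []
        assert prof.flat

    def test_close_peaks_merged(self):
        a = np.linspace(0.02, 0.98, 49)
        y = np.exp(-((a - 0.50) ** 2) / 0.005)
        y[24] += 0.002  # sub-separation wiggle on the flank
        prof = self._profile(y)
        assert len(critical_thresholds(prof, min_separation=0.06)) == 1

    def test_single_point_dip_ignored(self):
        # the exact-symmetry artifact: a one-grid-point dip must not
        # split a unimodal profile into two maxima
        a = np.linspace(0.02, 0.98, 49)
        y = np.exp(-((a - 0.5) ** 2) / 0.05)
        y[24] -= 0.03
        prof = self._profile(y)
        found = critical_thresholds(prof)
        assert len(found) == 1


class TestMSRProfile:
    def test_constant_image_zero_and_flat(self):
        prof = msr_profile(np.full((32, 32), 9))
        assert prof.flat
        assert np.all(prof.msr_values == 0.0)

    def test_a_grid_validation(self, field_h0_128):
        with pytest.raises(ValueError):
            msr_profile(field_h0_128.values, a_grid=[0.0, 0.5])

    def test_deterministic_given_seed(self, field_hneg_128):
        p1 = msr_profile(field_hneg_128.values, tie_seed=3)
        p2 = msr_profile(field_hneg_128.values, tie_seed=3)
        assert np.array_equal(p1.msr_values, p2.msr_values)

    def test_sign_flip_reverses_profile(self, field_hneg_128):
        p1 = msr_profile(field_hneg_128.values)
        p2 = msr_profile(-field_hneg_128.values)
        np.testing.assert_allclose(p1.msr_values, p2.msr_values[::-1], atol=1e-12)

    def test_anticorrelated_field_bimodal(self, field_hneg_128):
        prof = msr_profile(field_hneg_128.values)
        assert len(prof.maxima) == 2
        assert prof.maxima[0] < 0.5 < prof.maxima[1]

    def test_values_in_unit_interval(self, field_hneg_128):
        prof = msr_profile(field_hneg_128.values)
        assert np.all(prof.msr_values >= 0) and np.all(prof.msr_values <= 1)


class TestGradientMSR:
    def test_constant_image_zero(self):
        assert gradient_msr(np.full((64, 64), 3.0)) == 0.0

    def test_bounded(self, field_h0_128):
        val = gradient_msr(field_h0_128.values)
        assert 0.0 < val < 1.0

    def test_larger_wavelet_reduces_gradient_msr(self, field_h0_128):
        v0 = gradient_msr(field_h0_128.values, j=0)
        v2 = gradient_msr(field_h0_128.values, j=2)
        assert v2 < v0


def test_default_a_grid_open_interval():
    g = default_a_grid()
    assert g[0] == pytest.approx(0.02) and g[-1] == pytest.approx(0.98)
    assert len(g) == 49


def test_scale_set_presets():
    assert scale_set(8, "full").tolist() == list(range(1, 9))
    assert scale_set(64, "dyadic").tolist() == [1, 2, 4, 8, 16, 32, 64]
    geo = scale_set(256, "geometric")
    assert geo[0] == 1 and geo[-1] == 256
    assert np.all(np.diff(geo) > 0)
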