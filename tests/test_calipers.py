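"""Chord measurement, contour-profile fitting, valve cutoff, ratio."""

import numpy as np
import pytest

from rvlvcad import calipers as cal
from rvlvcad.core import Caliper, SeptumPlane
from rvlvcad.phantom import PhantomSpec, generate_phantom


def _plane(nx=1.0, ny=0.0):
    return SeptumPlane(point=(0, 0, 0), normal=(nx, ny, 0.0), score=5.0,
                       scale_mm=3.0)


def _ellipse_mask(a_mm, b_mm, shape=(120, 120), spacing=(1.0, 1.0),
                  angle_deg=0.0):
    xs = (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(shape[1]) + 0.5) * spacing[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cx = shape[0] * spacing[0] / 2
    cy = shape[1] * spacing[1] / 2
    th = np.radians(angle_deg)
    u = (X - cx) * np.cos(th) + (Y - cy) * np.sin(th)
    v = -(X - cx) * np.sin(th) + (Y - cy) * np.cos(th)
    return (u / a_mm) ** 2 + (v / b_mm) ** 2 <= 1.0


def max_ellipse_chord(a, b, direction_angle_deg):
    """Closed form: the maximal chord of an ellipse along a direction is
    2 / sqrt(u' A u) with A = diag(1/a^2, 1/b^2)."""
    th = np.radians(direction_angle_deg)
    u = np.array([np.cos(th), np.sin(th)])
    A = np.diag([1.0 / a**2, 1.0 / b**2])
    return 2.0 / np.sqrt(u @ A @ u)


class TestSliceCaliper:
    def test_rectangle_chord(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 20:40] = True  # 40 x 20 voxels at 1 mm
        c = cal.slice_caliper(mask, _plane(1, 0), (1.0, 1.0), 5.0, "RV")
        assert c.length_mm == pytest.approx(40.0, abs=0.5)

    def test_ellipse_chord_matches_closed_form(self):
        # direction at 30 degrees to the major axis of a 25/15 mm ellipse
        a, b, ang = 25.0, 15.0, 30.0
        mask = _ellipse_mask(a, b)
        plane = _plane(np.cos(np.radians(ang)), np.sin(np.radians(ang)))
        c = cal.slice_caliper(mask, plane, (1.0, 1.0), 0.0, "LV")
        assert c.length_mm == pytest.approx(max_ellipse_chord(a, b, ang),
                                            abs=0.5)

    def test_caliper_direction_is_inplane_septum_normal(self):
        mask = _ellipse_mask(25.0, 15.0)
        ang = 30.0
        plane = _plane(np.cos(np.radians(ang)), np.sin(np.radians(ang)))
        c = cal.slice_caliper(mask, plane, (1.0, 1.0), 0.0, "LV")
        p0, p1 = np.asarray(c.endpoints[0]), np.asarray(c.endpoints[1])
        d = (p1 - p0)[:2] / np.linalg.norm((p1 - p0)[:2])
        u = plane.inplane_direction()[:2]
        assert abs(abs(d @ u) - 1.0) < 1e-6

    def test_empty_slice_returns_none(self):
        mask = np.zeros((30, 30), dtype=bool)
        assert cal.slice_caliper(mask, _plane(), (1.0, 1.0), 0.0, "RV") is None

    def test_craniocaudal_normal_rejected(self):
        mask = np.ones((10, 10), dtype=bool)
        plane = SeptumPlane(point=(0, 0, 0), normal=(0, 0, 1.0), score=1.0,
                            scale_mm=3.0)
        with pytest.raises(ValueError, match="craniocaudal"):
            cal.slice_caliper(mask, plane, (1.0, 1.0), 0.0, "RV")

    def test_anisotropic_spacing(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[20:60, 30:50] = True  # 40 vox * 0.5 mm = 20 mm along x
        c = cal.slice_caliper(mask, _plane(1, 0), (0.5, 1.0), 0.0, "RV")
        assert c.length_mm == pytest.approx(20.0, abs=0.5)


class TestContourProfile:
    def test_disk_profile_is_constant(self):
        mask = _ellipse_mask(20.0, 20.0)
        prof = cal.fit_contour_profile(mask, (59.5, 59.5), (1.0, 1.0))
        assert prof.radii_mm == pytest.approx(20.0, abs=0.6)
        fitted = prof.evaluate(prof.angles)
        assert np.std(fitted) < 0.5
        assert prof.residual_rms_mm < 0.5

    def test_ellipse_profile_matches_analytic(self):
        a, b = 25.0, 15.0
        mask = _ellipse_mask(a, b)
        prof = cal.fit_contour_profile(mask, (59.5, 59.5), (1.0, 1.0),
                                       n_angles=128)
        analytic = a * b / np.sqrt((b * np.cos(prof.angles)) ** 2
                                   + (a * np.sin(prof.angles)) ** 2)
        rms = np.sqrt(np.mean((prof.radii_mm - analytic) ** 2))
        assert rms <= 0.02 * np.mean(analytic)

    def test_fit_matches_independent_least_squares(self):
        """The stored coefficients equal an independent lstsq solution of the
        same Vandermonde system to 1e-6."""
        from scipy.linalg import lstsq as scipy_lstsq

        mask = _ellipse_mask(22.0, 14.0, angle_deg=20.0)
        prof = cal.fit_contour_profile(mask, (59.5, 59.5), (1.0, 1.0))
        x = prof.angles / np.pi - 1.0
        V = np.vander(x, 11, increasing=True)
        coeffs, *_ = scipy_lstsq(V, prof.radii_mm)
        assert np.max(np.abs(coeffs - prof.coeffs)) < 1e-6
        resid = np.sqrt(np.mean((V @ coeffs - prof.radii_mm) ** 2))
        assert prof.residual_rms_mm == pytest.approx(resid, abs=1e-9)

    def test_empty_mask_rejected(self):
        mask = np.zeros((30, 30), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            cal.fit_contour_profile(mask, (15, 15), (1.0, 1.0))

    def test_too_few_boundary_samples_rejected(self):
        # a tiny blob far from the sampling centroid: almost no ray hits it
        mask = np.zeros((60, 60), dtype=bool)
        mask[50:52, 50:52] = True
        with pytest.raises(ValueError, match="boundary samples"):
            cal.fit_contour_profile(mask, (5.0, 5.0), (1.0, 1.0))


class TestValveCutoff:
    def _profiles_and_lengths(self, mask3d, septum, spacing):
        profiles, lengths = [], {}
        for k in range(mask3d.shape[2]):
            sl = mask3d[:, :, k]
            if not sl.any():
                continue
            c = cal.slice_caliper(sl, septum, spacing[:2], float(k), "RV")
            if c is None:
                continue
            c.slice_index = k
            lengths[k] = c.length_mm
            xs, ys = np.nonzero(sl)
            try:
                profiles.append(cal.fit_contour_profile(
                    sl, (xs.mean(), ys.mean()), spacing[:2], slice_index=k))
            except ValueError:
                pass
        return profiles, lengths

    def test_no_atrium_retains_full_range(self):
        spec = PhantomSpec(noise_sigma=0.0, atrium_scale=0.0, rng_seed=4)
        vol, truth = generate_phantom(spec)
        septum = SeptumPlane(point=tuple(truth.septum_point),
                             normal=tuple(truth.septum_normal), score=10.0,
                             scale_mm=3.0)
        profiles, lengths = self._profiles_and_lengths(truth.rv_mask, septum,
                                                       vol.spacing)
        out = cal.find_valve_cutoff(profiles, lengths)
        assert out.slice_index == min(lengths)
        assert out.atrial_slices == set()

    def test_atrium_excluded_max_in_ventricular_range(self, detector_model):
        """With atria attached the selected maximal caliper must fall within
        the true ventricular slice range."""
        from rvlvcad.pipeline import PipelineConfig, run_case

        spec = PhantomSpec(noise_sigma=0.0, atrium_scale=1.0, rng_seed=4)
        vol, truth = generate_phantom(spec)
        report, inter = run_case(vol, PipelineConfig(), model=detector_model,
                                 return_intermediates=True)
        ks = np.nonzero(truth.rv_mask.any(axis=(0, 1)))[0]
        assert ks.min() <= report.rv_caliper.slice_index <= ks.max()
        lv_ks = np.nonzero(truth.lv_mask.any(axis=(0, 1)))[0]
        assert lv_ks.min() <= report.lv_caliper.slice_index <= lv_ks.max()

    def test_single_slice_outlier_excluded_by_trend(self):
        spec = PhantomSpec(noise_sigma=0.0, atrium_scale=0.0, rng_seed=4)
        vol, truth = generate_phantom(spec)
        septum = SeptumPlane(point=tuple(truth.septum_point),
                             normal=tuple(truth.septum_normal), score=10.0,
                             scale_mm=3.0)
        profiles, lengths = self._profiles_and_lengths(truth.rv_mask, septum,
                                                       vol.spacing)
        ks = sorted(lengths)
        mid = ks[len(ks) // 3]
        lengths[mid] *= 2.0  # inject a 2x outlier
        out = cal.find_valve_cutoff(profiles, lengths)
        assert mid in out.atrial_slices

    def test_fewer_than_five_slices_retains_all(self):
        out = cal.find_valve_cutoff([], {3: 10.0, 4: 11.0})
        assert out.slice_index == 3
        assert out.atrial_slices == set()


def _cal(slice_index, length, chamber="RV"):
    return Caliper(slice_index, ((0.0, 0.0, float(slice_index)),
                                 (length, 0.0, float(slice_index))),
                   float(length), chamber)


class TestSelectMaxAndRatio:
    def test_equal_maxima_give_unit_ratio(self):
        res = cal.select_max_and_ratio([_cal(5, 50.0)],
                                       [_cal(7, 50.0, "LV")])
        assert res.ratio == pytest.approx(1.0, abs=1e-9)

    def test_cohort_mean_diameters_worked_division(self):
        """47.9 mm / 44.6 mm, the cohort-mean diameters, divide to 1.0740."""
        res = cal.select_max_and_ratio([_cal(5, 47.9)],
                                       [_cal(9, 44.6, "LV")])
        assert res.ratio == pytest.approx(1.0740, abs=1e-4)

    def test_maxima_may_come_from_different_slices(self):
        rv = [_cal(5, 30.0), _cal(8, 45.0)]
        lv = [_cal(3, 40.0, "LV"), _cal(9, 35.0, "LV")]
        res = cal.select_max_and_ratio(rv, lv)
        assert res.rv.slice_index == 8
        assert res.lv.slice_index == 3

    def test_valve_cutoff_excludes_cranial_calipers(self):
        rv = [_cal(2, 60.0), _cal(6, 45.0)]
        res = cal.select_max_and_ratio(rv, [_cal(6, 40.0, "LV")],
                                       rv_valve=cal.ValveCutoff(4, {2}))
        assert res.rv.slice_index == 6
        assert res.ratio == pytest.approx(45.0 / 40.0)

    def test_all_excluded_chamber_flags_no_ratio(self):
        res = cal.select_max_and_ratio([_cal(5, 50.0)], [],
                                       rv_valve=None, lv_valve=None)
        assert res.ratio is None
        assert "detection_failed_lv" in res.flags

    def test_ratio_definition(self):
        res = cal.select_max_and_ratio([_cal(5, 42.0)], [_cal(5, 28.0, "LV")])
        assert res.ratio == pytest.approx(42.0 / 28.0, abs=1e-9)
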