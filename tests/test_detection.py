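import numpy as np
import pytest

from citruslines import detection, spline
from citruslines.detection import (
    CrossSection, RegionHit, DeviationProfile, slice_cross_sections,
    fit_ideal_section, pca_normal, deviation_profile, detect_feature_regions,
    assemble_separation_lines, calibrate_threshold)
from citruslines.reconstruction import PointCloud


def circle_section(radius=10.0, n=200, z0=12.0):
    """Upper half-circle cross-section centred at (0, z0 - radius)."""
    t = np.linspace(0.15, np.pi - 0.15, n)
    x = radius * np.cos(t)[::-1]
    z = z0 - radius + radius * np.sin(t)[::-1]
    return CrossSection(y_value=0.0, points=np.stack([x, z], axis=1))


class TestSlicing:
    def test_single_profile_single_section(self):
        pts = np.stack([np.linspace(-5, 5, 40), np.zeros(40),
                        np.linspace(1, 3, 40)], axis=1)
        sections = slice_cross_sections(PointCloud(pts), bin_width=1.0)
        assert len(sections) == 1
        assert len(sections[0].points) == 40

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(300, 3))
        pts[:, 2] += 1.0
        a = slice_cross_sections(PointCloud(pts), bin_width=2.0)
        perm = rng.permutation(len(pts))
        b = slice_cross_sections(PointCloud(pts[perm]), bin_width=2.0)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.allclose(np.sort(sa.points, axis=0),
                               np.sort(sb.points, axis=0))

    def test_small_bins_dropped(self):
        pts = np.zeros((5, 3))
        pts[:, 2] = 1.0
        with pytest.raises(ValueError, match="no usable sections"):
            slice_cross_sections(PointCloud(pts), bin_width=1.0)


class TestIdealFit:
    def test_clean_section_trim_is_noop(self):
        sec = circle_section()
        c_plain = fit_ideal_section(sec, trim_frac=0.0)
        c_trim = fit_ideal_section(sec, trim_frac=0.3)
        u = np.linspace(0, 1, 100)
        d = np.linalg.norm(spline.evaluate_curve(c_plain, u)
                           - spline.evaluate_curve(c_trim, u), axis=1)
        assert d.max() < 0.05

    def test_groove_excluded_from_ideal(self):
        sec = circle_section(n=400)
        pts = sec.points.copy()
        groove = np.exp(-(pts[:, 0] ** 2) / (2 * 0.6 ** 2)) * 2.0
        pts[:, 1] -= groove
        grooved = CrossSection(y_value=0.0, points=pts)
        ideal = fit_ideal_section(grooved, trim_frac=0.3)
        u = np.linspace(0.1, 0.9, 200)
        fitted = spline.evaluate_curve(ideal, u)
        clean = fit_ideal_section(sec, trim_frac=0.0)
        reference = spline.evaluate_curve(clean, u)
        away = np.abs(fitted[:, 0]) > 3.0
        assert np.abs(fitted[away, 1] - reference[away, 1]).max() < 0.1


class TestPcaNormal:
    def test_collinear_window(self):
        pts = np.stack([np.linspace(0, 1, 9), np.zeros(9)], axis=1)
        n = pca_normal(pts, orient_away_from=np.array([0.5, -5.0]))
        assert np.allclose(np.abs(n), [0.0, 1.0], atol=1e-12)
        assert n[1] > 0  # away from the centroid below

    def test_circle_normals_radial(self):
        radius, z0 = 10.0, 12.0
        center = np.array([0.0, z0 - radius])
        sec = circle_section(radius, n=400, z0=z0)
        errs = []
        for i in range(20, 380, 20):
            win = sec.points[i - 4:i + 5]
            n = pca_normal(win, orient_away_from=center)
            radial = (win[4] - center) / np.linalg.norm(win[4] - center)
            errs.append(np.degrees(np.arccos(np.clip(np.dot(n, radial), -1, 1))))
        assert max(errs) < 1.0

    def test_flip_invariance_up_to_sign(self):
        rng = np.random.default_rng(1)
        pts = np.stack([np.linspace(0, 2, 9),
                        0.3 * np.linspace(0, 2, 9) ** 2], axis=1)
        anchor = np.array([1.0, -3.0])
        n1 = pca_normal(pts, orient_away_from=anchor)
        n2 = pca_normal(pts[::-1], orient_away_from=anchor)
        assert np.allclose(n1, n2, atol=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            pca_normal(np.zeros((5, 2)))


class TestDeviationProfile:
    def test_self_deviation_zero(self):
        sec = circle_section(n=300)
        ideal = fit_ideal_section(sec, trim_frac=0.0)
        prof = deviation_profile(ideal, sec)
        assert np.nanmax(np.abs(prof.deviations[prof.hits])) < 0.02
        assert np.allclose(np.linalg.norm(prof.normals, axis=1), 1.0,
                           atol=1e-9)

    def test_concentric_circles_offset(self):
        outer = circle_section(radius=10.0, n=300, z0=12.0)
        inner = circle_section(radius=9.0, n=300, z0=11.0)  # same centre
        ideal = fit_ideal_section(outer, trim_frac=0.0)
        prof = deviation_profile(ideal, inner, edge_margin=0.1)
        dev = prof.deviations[prof.hits]
        assert np.abs(dev + 1.0).max() < 0.05

    def test_groove_depth_recovered(self):
        # groove at the section apex: tangent horizontal there, so the
        # normal-direction deviation should equal the carved depth
        sec = circle_section(n=500)
        pts = sec.points.copy()
        depth = 1.5
        pts[:, 1] -= depth * np.exp(-(pts[:, 0] ** 2) / (2 * 0.6 ** 2))
        grooved = CrossSection(y_value=0.0, points=pts)
        ideal = fit_ideal_section(grooved, trim_frac=0.3)
        prof = deviation_profile(ideal, grooved)
        peak = -np.nanmin(prof.deviations)
        assert abs(peak - depth) < 0.05 * depth


class TestRegions:
    def _profile(self, deviations):
        k = len(deviations)
        samples = np.stack([np.linspace(0, 10, k), np.zeros(k)], axis=1)
        normals = np.tile([0.0, 1.0], (k, 1))
        dev = np.asarray(deviations, dtype=float)
        return DeviationProfile(samples=samples, normals=normals,
                                deviations=dev, hits=np.isfinite(dev),
                                y_value=1.0)

    def test_zero_profile_no_regions(self):
        prof = self._profile(np.zeros(50))
        assert detect_feature_regions(prof, tau=0.1) == []

    def test_single_deep_sample(self):
        dev = np.zeros(30)
        dev[12] = -3.0
        prof = self._profile(dev)
        regions = detect_feature_regions(prof, tau=1.0, min_run=1)
        assert len(regions) == 1
        assert regions[0].deviation == pytest.approx(-3.0)

    def test_min_run_filters_short_runs(self):
        dev = np.zeros(30)
        dev[12] = -3.0
        prof = self._profile(dev)
        assert detect_feature_regions(prof, tau=1.0, min_run=2) == []

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(2)
        prof = self._profile(-np.abs(rng.normal(1.0, 0.8, size=200)))
        counts = []
        for tau in (0.2, 0.6, 1.0, 1.5, 2.5):
            regs = detect_feature_regions(prof, tau=tau, min_run=1)
            counts.append(sum(r.run_length for r in regs))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            detect_feature_regions(self._profile(np.zeros(5)), tau=0.0)


class TestAssemble:
    def _hit(self, x, y, z=5.0, dev=-2.0):
        return RegionHit(x=x, z=z, y=y, deviation=dev, run_length=3)

    def test_single_track_full_support(self):
        sections = [[self._hit(1.0 + 0.05 * i, float(i))] for i in range(10)]
        lines = assemble_separation_lines(sections, min_support=5)
        assert len(lines) == 1
        assert lines[0].support == 10
        assert np.all(np.diff(lines[0].points[:, 1]) > 0)

    def test_two_tracks_no_switch(self):
        sections = [[self._hit(-5.0, float(i)), self._hit(5.0, float(i))]
                    for i in range(8)]
        lines = assemble_separation_lines(sections, gate=3.0, min_support=5)
        assert len(lines) == 2
        for line in lines:
            assert np.ptp(line.points[:, 0]) < 1e-9

    def test_isolated_region_discarded(self):
        sections = [[self._hit(1.0, float(i))] for i in range(8)]
        sections[3].append(self._hit(30.0, 3.0))  # spurious, one section
        lines = assemble_separation_lines(sections, min_support=5)
        assert len(lines) == 1


class TestCalibration:
    def _grooved_profiles(self, depth=2.0, noise=0.0, n_sections=8, seed=0):
        rng = np.random.default_rng(seed)
        profiles = []
        truth_pts = []
        for i in range(n_sections):
            sec = circle_section(n=400)
            pts = sec.points.copy()
            pts[:, 1] -= depth * np.exp(-((pts[:, 0] - 2.0) ** 2) / (2 * 1.2 ** 2))
            if noise:
                pts[:, 1] += rng.normal(0, noise, len(pts))
            grooved = CrossSection(y_value=float(i), points=pts)
            ideal = fit_ideal_section(grooved, trim_frac=0.3)
            profiles.append(deviation_profile(ideal, grooved))
            bottom = pts[np.argmin(np.abs(pts[:, 0] - 2.0))]
            truth_pts.append([2.0, float(i), bottom[1]])
        return profiles, [np.array(truth_pts)]

    def test_noiseless_flat_bottom_returns_smallest_tau(self):
        profiles, truth = self._grooved_profiles()
        taus = np.array([0.4, 0.8, 1.2])
        tau_star, errors = calibrate_threshold(profiles, truth, taus=taus,
                                               min_support=5)
        assert tau_star == pytest.approx(0.4)
        assert errors[0] == pytest.approx(errors[1], abs=0.2)

    def test_threshold_above_depth_is_miss(self):
        profiles, truth = self._grooved_profiles(depth=1.0)
        taus = np.array([0.5, 2.0])
        tau_star, errors = calibrate_threshold(profiles, truth, taus=taus,
                                               miss_penalty=10.0,
                                               min_support=5)
        assert tau_star == pytest.approx(0.5)
        assert errors[1] == pytest.approx(10.0)

    def test_noisy_groove_calibrates_inside_basin(self):
        profiles, truth = self._grooved_profiles(depth=2.0, noise=0.2, seed=3)
        taus = np.linspace(0.3, 2.5, 9)
        tau_star, errors = calibrate_threshold(profiles, truth, taus=taus,
                                               min_support=5)
        assert 0.3 <= tau_star < 2.0
        assert errors.min() < 0.5
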