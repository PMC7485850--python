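"""Cubing: section formulas, interpolation, and whole-stem volumes."""

import math

import numpy as np
import pytest

import multivol as mv
from multivol.scaling import sectional_area, smalian_volume, tip_volume, diameter_without_bark

from conftest import cylinder_stem, paraboloid_stem, conic_frustum_volume, linear_taper_profile


class TestSectionFormulas:
    @pytest.mark.parametrize("d, expected", [
        (0.0, 0.0),
        (20.0, 0.031415926535897934),
        (5.0, 0.001963495408493621),
    ])
    def test_sectional_area(self, d, expected):
        assert sectional_area(d) == pytest.approx(expected, abs=1e-12)

    def test_sectional_area_rejects_negative(self):
        with pytest.raises(ValueError):
            sectional_area(-1.0)

    def test_smalian_values(self):
        assert smalian_volume(0, 0, 2.0) == 0.0
        assert smalian_volume(20, 18, 2.0) == pytest.approx(0.056862827029975256, rel=1e-12)
        # cylinder: Smalian is exact
        assert smalian_volume(14, 14, 3.5) == pytest.approx(sectional_area(14) * 3.5, rel=1e-14)

    def test_smalian_rejects_bad_length(self):
        with pytest.raises(ValueError):
            smalian_volume(10, 10, 0.0)

    def test_tip_volume(self):
        assert tip_volume(5.0, 0.0) == 0.0
        assert tip_volume(5.0, 3.0) == pytest.approx(0.0029452431127404313, rel=1e-12)
        with pytest.raises(ValueError):
            tip_volume(5.0, -1.0)

    def test_diameter_without_bark(self):
        assert diameter_without_bark(10.0, 0.0) == 10.0
        assert diameter_without_bark(20.0, 0.5) == 19.0
        with pytest.raises(ValueError):
            diameter_without_bark(6.0, 3.1)


class TestHeightAtDiameter:
    def _stem(self):
        return mv.TreeStem(
            stem_id="s", clone="", rotation=1, dbh_cm=14, total_height_m=15,
            measurements=[(0.15, 14, 0.5), (1.3, 14, 0.5), (10.0, 12, 0.4), (12.0, 9, 0.3)],
            ref_heights={})

    def test_interpolates_between_bracketing_measurements(self):
        h = mv.height_at_diameter(self._stem(), 10.0)
        assert h == pytest.approx(10.0 + 2.0 * (12 - 10) / (12 - 9), rel=1e-12)

    def test_exact_at_measured_diameter(self):
        assert mv.height_at_diameter(self._stem(), 12.0) == pytest.approx(10.0)

    def test_absent_beyond_largest_diameter(self):
        assert mv.height_at_diameter(self._stem(), 40.0) is None

    def test_field_recorded_height_returned_verbatim(self):
        stem = self._stem()
        stem.ref_heights[10] = 11.111
        assert mv.height_at_diameter(stem, 10.0) == 11.111

    def test_without_bark_uses_inside_bark_diameters(self):
        # inside-bark diameters: 13, 13, 11.2, 8.4
        h = mv.height_at_diameter(self._stem(), 10.0, bark=False)
        assert h == pytest.approx(10.0 + 2.0 * (11.2 - 10) / (11.2 - 8.4), rel=1e-9)


class TestCubeStem:
    def test_cylinder_sections_exact(self):
        stem = cylinder_stem(d=20.0, heights=[0.15, 2.0, 4.0, 6.0, 8.0])
        vol = mv.cube_stem(stem)
        span = 8.0 - 0.15
        assert vol.V5b == pytest.approx(sectional_area(20.0) * span, rel=1e-14)

    def test_paraboloid_exact_at_any_section_length(self):
        for n_points in (3, 6, 17):
            stem, exact = paraboloid_stem(n_points=n_points)
            assert mv.cube_stem(stem).V5b == pytest.approx(exact, rel=1e-12)

    def test_cone_within_two_percent_at_2m_sections(self):
        profile = linear_taper_profile(30.0, 20.0)
        stem = mv.measure_stem(profile, noise_cv=0.0)
        vol = mv.cube_stem(stem)
        h = stem.heights
        exact = sum(conic_frustum_volume(profile.diameter_with_bark(h[i]),
                                         profile.diameter_with_bark(h[i + 1]),
                                         h[i + 1] - h[i])
                    for i in range(len(h) - 1))
        assert vol.V5b >= exact  # Smalian overestimates convex tapers
        assert (vol.V5b - exact) / exact < 0.02

    def test_cone_converges_to_integral_with_section_length(self):
        profile = linear_taper_profile(30.0, 20.0)
        errors = []
        for step in (4.0, 2.0, 0.5, 0.1):
            hs = list(np.arange(0.15, 16.6667, step)) + [16.666666666666668]
            stem = mv.TreeStem("c", "", 1, profile.dbh_cm, 20.0,
                               [(h, profile.diameter_with_bark(h), 0.0) for h in hs], {})
            exact = sum(conic_frustum_volume(profile.diameter_with_bark(hs[i]),
                                             profile.diameter_with_bark(hs[i + 1]),
                                             hs[i + 1] - hs[i]) for i in range(len(hs) - 1))
            errors.append(mv.cube_stem(stem).V5b - exact)
        assert all(e >= 0 for e in errors)
        assert errors[-1] < errors[0] / 100

    def test_total_equals_merchantable_plus_tip(self):
        profile = linear_taper_profile(30.0, 20.0, bark_fraction=0.1)
        stem = mv.measure_stem(profile, noise_cv=0.0)
        vol = mv.cube_stem(stem)
        tip_len = stem.total_height_m - stem.heights[-1]
        assert vol.TVb - vol.V5b == pytest.approx(
            tip_volume(stem.diameters_bark[-1], tip_len), abs=1e-12)
        assert vol.TVw - vol.V5w == pytest.approx(
            tip_volume(stem.diameters_wood[-1], tip_len), abs=1e-12)

    def test_small_stem_lacks_20cm_volumes(self):
        profile = linear_taper_profile(19.0, 20.0, bark_fraction=0.08)
        stem = mv.measure_stem(profile, noise_cv=0.0)
        assert stem.dbh_cm < 20
        vol = mv.cube_stem(stem)
        assert vol.V20b is None and vol.V20w is None
        assert len(vol.available()) == 8

    def test_min_log_length_rule(self):
        # 20 cm occurs 0.65 m above the cut height: shorter than the 1 m minimum
        profile = linear_taper_profile(21.0, 20.0)
        stem = mv.measure_stem(profile, noise_cv=0.0)
        h20 = stem.ref_heights[20]
        assert h20 - 0.15 < 1.0
        vol = mv.cube_stem(stem, min_log_length=1.0)
        assert vol.V20b is None
        # relaxing the rule makes the volume appear
        vol2 = mv.cube_stem(stem, min_log_length=0.3)
        assert vol2.V20b is not None

    def test_volume_ordering_and_bark_direction(self, small_stems):
        for stem in small_stems:
            vol = mv.cube_stem(stem)
            assert vol.TVb >= vol.TVw > 0
            for bark in "bw":
                seq = [getattr(vol, f"V{d}{bark}") for d in (5, 10, 15, 20)]
                present = [v for v in seq if v is not None]
                assert all(a >= b for a, b in zip(present, present[1:]))
            assert vol.TVb >= (vol.V5b or 0.0)

    def test_rejects_unordered_measurements(self):
        stem = cylinder_stem()
        stem.measurements[1], stem.measurements[2] = stem.measurements[2], stem.measurements[1]
        with pytest.raises(ValueError, match="increasing"):
            mv.cube_stem(stem)

    def test_rejects_single_measurement(self):
        stem = cylinder_stem(heights=[0.15])
        with pytest.raises(ValueError):
            mv.cube_stem(stem)
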