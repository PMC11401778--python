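import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from octffr import (LumenProfile, apply_lumen_correction, crop_roi, ellipse_area,
                    fit_reference_taper, lesion_metrics, merge_pullbacks,
                    read_lumen_csv, suggest_references)
from octffr.errors import (CorrectionError, FormatError, InvalidParameterError,
                           MergeError)


def profile_from(areas, spacing=0.2):
    areas = np.asarray(areas, dtype=float)
    return LumenProfile(np.arange(areas.size) * spacing, areas, spacing)


class TestReadLumenCsv:
    def test_toy_csv_parses_positions_and_areas(self, tmp_path):
        p = tmp_path / "lumen.csv"
        p.write_text("frame,area_mm2\n0,10\n1,5\n2,10\n")
        prof = read_lumen_csv(p)
        assert prof.position.size == 3
        assert prof.spacing == pytest.approx(0.2)
        assert prof.area.tolist() == [10.0, 5.0, 10.0]

    def test_blank_area_row_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "lumen.csv"
        p.write_text("frame,area_mm2\n0,10\n1,\n2,10\n3,9\n")
        with caplog.at_level("WARNING"):
            prof = read_lumen_csv(p)
        assert prof.area.size == 3
        assert "dropping 1 rows" in caplog.text

    def test_write_read_round_trip(self, tmp_path):
        prof = profile_from([9.8, 7.2, 3.3, 6.1, 8.8])
        path = tmp_path / "rt.csv"
        prof.write_csv(path)
        back = read_lumen_csv(path)
        np.testing.assert_allclose(back.area, prof.area, rtol=1e-12)
        np.testing.assert_allclose(back.position, prof.position, atol=1e-12)

    def test_missing_area_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,diameter\n0,3\n")
        with pytest.raises(FormatError, match="area_mm2"):
            read_lumen_csv(p)

    def test_non_numeric_cell_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,area_mm2\n0,10\n1,oops\n")
        with pytest.raises(FormatError, match="line 3"):
            read_lumen_csv(p)


class TestMergeCrop:
    def test_merging_identical_profiles_at_same_landmark_is_identity(self):
        prof = profile_from(np.linspace(10, 6, 51))
        merged = merge_pullbacks(prof, prof, 10, 10)
        np.testing.assert_allclose(merged.area, prof.area)
        np.testing.assert_allclose(merged.position, prof.position)

    def test_two_75mm_pullbacks_with_25mm_overlap_give_125mm(self):
        # distal pullback starts 50 mm into the proximal one
        n = 376  # 75 mm at 0.2 mm pitch
        prox = profile_from(np.linspace(12, 8, n))
        dist = profile_from(np.linspace(9, 5, n))
        # landmark at 60 mm on prox (frame 300) == 10 mm on dist (frame 50)
        merged = merge_pullbacks(prox, dist, 300, 50)
        assert merged.length == pytest.approx(125.0, abs=0.2)
        # proximal values kept over the overlap
        assert merged.area[275] == pytest.approx(prox.area[275])

    def test_landmark_mismatch_raises_merge_error(self):
        prox = profile_from(np.linspace(12, 8, 51))
        dist = profile_from(np.linspace(9, 5, 51))
        # swapped landmarks place the distal pullback inside the proximal one
        with pytest.raises(MergeError, match="landmark"):
            merge_pullbacks(prox, dist, 5, 45)

    def test_crop_full_extent_is_identity(self):
        prof = profile_from(np.linspace(10, 6, 51))
        out = crop_roi(prof, 0.0, prof.length)
        np.testing.assert_allclose(out.area, prof.area)

    def test_crop_50mm_window_from_75mm_profile(self):
        prof = profile_from(np.linspace(12, 6, 376))
        out = crop_roi(prof, 10.0, 60.0)
        assert out.length == pytest.approx(50.0, abs=0.2)
        assert out.position[0] == 0.0

    def test_reversed_bounds_rejected(self):
        prof = profile_from(np.linspace(10, 6, 51))
        with pytest.raises(InvalidParameterError):
            crop_roi(prof, 30.0, 10.0)


class TestEllipseArea:
    def test_closed_form(self):
        assert ellipse_area(3.0, 4.0) == pytest.approx(9.42478, abs=1e-5)

    def test_equal_diameters_give_circle(self):
        d = 3.7
        assert ellipse_area(d, d) == pytest.approx(math.pi * d * d / 4)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            ellipse_area(0.0, 4.0)


class TestLumenCorrection:
    def test_closed_form_at_unit_radius(self):
        prof = profile_from([math.pi] * 5)
        out = apply_lumen_correction(prof, -0.075)
        assert out.area[0] == pytest.approx(math.pi * 0.925 ** 2, rel=1e-12)
        assert out.corrected

    def test_zero_correction_is_identity(self):
        prof = profile_from([8.0, 2.5, 7.0])
        out = apply_lumen_correction(prof, 0.0)
        np.testing.assert_allclose(out.area, prof.area, rtol=1e-14)

    def test_degenerate_lumen_guarded(self):
        prof = profile_from([8.0, 0.01, 7.0])
        with pytest.raises(CorrectionError, match="0.20 mm"):
            apply_lumen_correction(prof, -0.075)

    def test_double_correction_rejected(self):
        prof = apply_lumen_correction(profile_from([8.0, 7.0]), -0.05)
        with pytest.raises(InvalidParameterError):
            apply_lumen_correction(prof, -0.05)

    @given(st.lists(st.floats(1.0, 20.0), min_size=2, max_size=30),
           st.floats(-0.2, 0.2))
    @hsettings(max_examples=50, deadline=None)
    def test_round_trip_in_radius_space(self, areas, k):
        prof = profile_from(areas)
        corrected = apply_lumen_correction(prof, k)
        back = apply_lumen_correction(
            LumenProfile(corrected.position, corrected.area, corrected.spacing),
            -k)
        np.testing.assert_allclose(back.area, prof.area, atol=1e-9)


class TestReferenceTaper:
    def test_cohort_mean_taper_midpoint(self):
        prof = profile_from(np.linspace(10.57, 5.69, 251))
        taper = fit_reference_taper(prof, 10.57, 5.69)
        assert taper.a_ref(25.0) == pytest.approx(8.13, abs=0.005)

    def test_endpoints_are_exact(self):
        prof = profile_from(np.linspace(9, 6, 101))
        taper = fit_reference_taper(prof, 9.0, 6.0)
        assert taper.a_ref(0.0) == 9.0
        assert taper.a_ref(prof.length) == 6.0

    def test_equal_references_give_constant_taper(self):
        prof = profile_from(np.full(51, 8.0))
        taper = fit_reference_taper(prof, 8.0, 8.0)
        assert taper.a_ref(3.7) == 8.0

    def test_reversed_ordering_rejected(self):
        prof = profile_from(np.linspace(9, 6, 51))
        with pytest.raises(InvalidParameterError):
            fit_reference_taper(prof, 6.0, 9.0)

    def test_automatic_suggestion_tracks_least_diseased_edges(self):
        areas = np.linspace(10.0, 6.0, 251)
        areas[100:150] *= 0.4  # focal lesion mid-vessel
        prof = profile_from(areas)
        a_p, a_d = suggest_references(prof)
        assert a_p == pytest.approx(10.0, abs=0.5)
        assert a_d == pytest.approx(6.5, abs=0.5)  # 90th pct of distal 10 mm


class TestLesionMetrics:
    def test_cohort_mean_plaque_burden(self):
        areas = np.linspace(10.57, 5.69, 251)
        i = 125
        areas[i] = 2.62
        prof = profile_from(areas)
        taper = fit_reference_taper(prof, 10.57, 5.69)
        m = lesion_metrics(prof, taper, rva=10.8)
        assert m.mla == pytest.approx(2.62)
        assert m.plaque_burden == pytest.approx(0.757, abs=5e-4)

    def test_area_stenosis_against_local_reference(self):
        # MLA 2.62 where the taper reads 5.14 -> area stenosis 49%
        prof = profile_from(np.concatenate([np.linspace(10.57, 2.62, 100),
                                            np.linspace(2.7, 5.2, 151)]))
        taper = fit_reference_taper(prof, 10.57, 5.69)
        x_mla = prof.position[int(np.argmin(prof.area))]
        a_local = taper.a_ref(x_mla)
        m = lesion_metrics(prof, taper, rva=10.8)
        assert m.area_stenosis == pytest.approx(1 - 2.62 / a_local, rel=1e-9)
        assert m.diameter_stenosis == pytest.approx(
            1 - math.sqrt(2.62 / a_local), rel=1e-9)

    def test_mla_equal_rva_gives_zero_burden(self):
        prof = profile_from(np.full(51, 7.0))
        taper = fit_reference_taper(prof, 7.0, 7.0)
        m = lesion_metrics(prof, taper, rva=7.0)
        assert m.plaque_burden == 0.0

    def test_burden_invariant_under_fine_resampling(self):
        areas = 9.0 - 5.0 * np.exp(-0.5 * ((np.arange(251) * 0.2 - 25) / 3) ** 2)
        prof = profile_from(areas)
        taper = fit_reference_taper(prof, 9.0, 9.0)
        coarse = lesion_metrics(prof, taper, rva=10.0)
        fine = lesion_metrics(prof.resample(0.05), taper, rva=10.0)
        assert fine.plaque_burden == pytest.approx(coarse.plaque_burden, abs=1e-4)
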