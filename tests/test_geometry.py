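"""Slice geometry: closed-form oracles, symmetries, and the profile layout."""

import numpy as np
import pytest

from osteophylo.geometry import (BoneStack, EmptySectionError, SectionImage,
                                 bone_stress, extract_profile,
                                 normalize_dimensionless, otsu_threshold,
                                 read_stack, section_traits, slice_indices,
                                 write_stack)
from osteophylo.synth import (StackParams, annulus_closed_form,
                              make_annulus_stack, rasterize_annulus)


def _round_half_away(v):
    import math
    return math.floor(v + 0.5) if v >= 0 else math.ceil(v - 0.5)


class TestSliceIndices:
    def test_exact_division_gives_even_steps(self):
        idx = slice_indices(0, 1000)
        assert idx == list(range(0, 1001, 50))
        assert len(idx) == 21

    def test_shift_invariance(self):
        assert slice_indices(100, 1100) == [i + 100 for i in slice_indices(0, 1000)]

    @pytest.mark.parametrize("span", [20, 25, 33, 47, 101])
    def test_rounding_matches_independent_enumeration(self, span):
        idx = slice_indices(0, span)
        expected = [_round_half_away(k * span / 20) for k in range(21)]
        assert idx == expected
        assert idx[0] == 0 and idx[-1] == span
        assert all(b >= a for a, b in zip(idx, idx[1:]))

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            slice_indices(0, 19)


class TestSectionTraits:
    def test_single_pixel_is_point_area(self):
        img = SectionImage(np.array([[0, 0], [0, 255]]), 1.0, 128)
        t = section_traits(img)
        assert t.csa == 1.0
        assert t.sma_ml == 0.0 and t.sma_cc == 0.0
        assert t.mod_ml == 0.0 and t.mod_cc == 0.0

    def test_filled_circle_matches_closed_form(self):
        r = 5.0
        img = rasterize_annulus(r, r, 0, 0, 0.02)
        t = section_traits(SectionImage(img, 0.02, 128))
        assert t.csa == pytest.approx(np.pi * r**2, rel=0.01)
        exact = np.pi * r**4 / 4
        assert t.sma_ml == pytest.approx(exact, rel=0.01)
        assert t.sma_cc == pytest.approx(exact, rel=0.01)

    def test_elliptical_annulus_matches_closed_form(self):
        img = rasterize_annulus(4, 3, 2.5, 1.8, 0.02)
        t = section_traits(SectionImage(img, 0.02, 128))
        cf = annulus_closed_form(4, 3, 2.5, 1.8)
        assert t.csa == pytest.approx(cf["csa_mm2"], rel=0.01)
        assert t.sma_ml == pytest.approx(cf["sma_ml_mm4"], rel=0.01)
        assert t.sma_cc == pytest.approx(cf["sma_cc_mm4"], rel=0.01)
        assert t.mod_ml == pytest.approx(cf["mod_ml_mm3"], rel=0.01)

    def test_quarter_rotation_swaps_axes_exactly(self, rng):
        pix = (rng.random((40, 60)) > 0.6).astype(float) * 255
        t = section_traits(SectionImage(pix, 0.1, 128))
        tr = section_traits(SectionImage(np.rot90(pix), 0.1, 128))
        assert tr.sma_ml == pytest.approx(t.sma_cc, abs=1e-12)
        assert tr.sma_cc == pytest.approx(t.sma_ml, abs=1e-12)

    def test_polar_moment_conserved_under_rotation(self):
        base = rasterize_annulus(4, 3, 2.5, 1.8, 0.05)
        rot = rasterize_annulus(4, 3, 2.5, 1.8, 0.05, angle_deg=30)
        t0 = section_traits(SectionImage(base, 0.05, 128))
        t1 = section_traits(SectionImage(rot, 0.05, 128))
        j0 = t0.sma_ml + t0.sma_cc
        j1 = t1.sma_ml + t1.sma_cc
        assert j1 == pytest.approx(j0, rel=0.005)

    def test_scale_equivariance(self, rng):
        pix = (rng.random((30, 30)) > 0.5).astype(float) * 255
        t1 = section_traits(SectionImage(pix, 0.1, 128))
        t2 = section_traits(SectionImage(pix, 0.2, 128))
        assert t2.csa == pytest.approx(t1.csa * 4, rel=1e-12)
        assert t2.sma_ml == pytest.approx(t1.sma_ml * 16, rel=1e-12)
        assert t2.mod_ml == pytest.approx(t1.mod_ml * 8, rel=1e-12)

    def test_mod_times_c_recovers_sma(self, rng):
        pix = (rng.random((25, 35)) > 0.4).astype(float) * 255
        t = section_traits(SectionImage(pix, 0.07, 128))
        assert t.mod_ml * t.c_ml == pytest.approx(t.sma_ml, rel=1e-12)
        assert t.mod_cc * t.c_cc == pytest.approx(t.sma_cc, rel=1e-12)

    def test_empty_section_raises(self):
        with pytest.raises(EmptySectionError):
            section_traits(SectionImage(np.zeros((5, 5)), 1.0, 128))


class TestNormalization:
    def test_root_scaling(self):
        from osteophylo.geometry import SectionTraits
        t = SectionTraits(csa=4.0, sma_ml=16.0, sma_cc=16.0, mod_ml=8.0,
                          mod_cc=8.0, centroid_row=0, centroid_col=0,
                          c_ml=2.0, c_cc=2.0)
        d = normalize_dimensionless(t, 10.0)
        assert d.csa_d == pytest.approx(0.2)
        assert d.sma_ml_d == pytest.approx(0.2)
        assert d.mod_ml_d == pytest.approx(0.2)
        assert d.r_ml == pytest.approx(1.0)

    def test_dimensionless_invariant_to_similarity(self):
        """A geometrically similar bone (all lengths x s) has equal traits."""
        img1 = rasterize_annulus(4, 3, 2.5, 1.8, 0.05)
        img2 = rasterize_annulus(4, 3, 2.5, 1.8, 0.05)  # same raster, scaled spacing
        t1 = section_traits(SectionImage(img1, 0.05, 128))
        t2 = section_traits(SectionImage(img2, 0.10, 128))
        d1 = normalize_dimensionless(t1, 30.0)
        d2 = normalize_dimensionless(t2, 60.0)
        assert d2.csa_d == pytest.approx(d1.csa_d, rel=1e-12)
        assert d2.sma_ml_d == pytest.approx(d1.sma_ml_d, rel=1e-12)
        assert d2.r_cc == pytest.approx(d1.r_cc, rel=1e-12)

    def test_invalid_length_rejected(self):
        from osteophylo.geometry import SectionTraits
        t = SectionTraits(1, 1, 1, 1, 1, 0, 0)
        with pytest.raises(ValueError):
            normalize_dimensionless(t, 0.0)


class TestBoneStress:
    def test_compression_and_bending(self):
        from osteophylo.geometry import SectionTraits
        t = SectionTraits(csa=50.0, sma_ml=500.0, sma_cc=500.0, mod_ml=1,
                          mod_cc=1, centroid_row=0, centroid_col=0)
        sc, sb = bone_stress(100.0, 1000.0, 5.0, t)
        assert sc == pytest.approx(2.0)
        assert sb == pytest.approx(10.0)
        assert bone_stress(0.0, 1000.0, 5.0, t)[0] == 0.0

    def test_zero_area_rejected(self):
        from osteophylo.geometry import SectionTraits
        t = SectionTraits(0.0, 0.0, 0.0, 0.0, 0.0, 0, 0)
        with pytest.raises(ValueError):
            bone_stress(1.0, 1.0, 1.0, t)


class TestExtractProfile:
    def test_constant_stack_gives_identical_increments(self):
        stack, _ = make_annulus_stack(StackParams(n_slices=21, pixel_spacing=0.1))
        prof = extract_profile(stack)
        assert prof.increments == list(range(0, 101, 5))
        csa = [t.csa for t in prof.raw]
        assert all(c == pytest.approx(csa[0]) for c in csa)

    def test_tapering_stack_monotone_csa(self):
        params = StackParams(n_slices=41, pixel_spacing=0.1,
                             outer_a=(4.0, 2.0), outer_b=(3.0, 1.5),
                             inner_a=(0.0, 0.0), inner_b=(0.0, 0.0))
        stack, _ = make_annulus_stack(params)
        prof = extract_profile(stack)
        csa_d = [t.csa_d for t in prof.traits]
        assert all(b < a for a, b in zip(csa_d, csa_d[1:]))

    def test_21_slice_stack_is_identity_downsampling(self):
        stack, oracle = make_annulus_stack(StackParams(n_slices=21, pixel_spacing=0.05))
        prof = extract_profile(stack)
        assert len(prof.raw) == 21
        for row, t in zip(oracle.itertuples(), prof.raw):
            assert t.csa == pytest.approx(row.csa_mm2, rel=0.01)


class TestStackIO:
    def test_round_trip_preserves_traits(self, tmp_path):
        stack, _ = make_annulus_stack(StackParams(n_slices=21, pixel_spacing=0.1))
        write_stack(stack, tmp_path / "s")
        back = read_stack(tmp_path / "s")
        assert back.bone_length_mm == stack.bone_length_mm
        t0 = section_traits(stack.slices[3])
        t1 = section_traits(back.slices[3])
        assert t1.csa == pytest.approx(t0.csa, rel=1e-12)
        assert t1.sma_ml == pytest.approx(t0.sma_ml, rel=1e-12)

    def test_rotate_flag_swaps_axes(self, tmp_path):
        stack, _ = make_annulus_stack(StackParams(n_slices=21, pixel_spacing=0.1))
        write_stack(stack, tmp_path / "s")
        rot = read_stack(tmp_path / "s", rotate=1)
        t0 = section_traits(stack.slices[0])
        t1 = section_traits(rot.slices[0])
        assert t1.sma_ml == pytest.approx(t0.sma_cc, rel=1e-12)


def test_otsu_separates_bimodal_image(rng):
    lo = rng.normal(30, 5, 500)
    hi = rng.normal(200, 10, 500)
    t = otsu_threshold(np.concatenate([lo, hi]))
    assert np.all(lo < t) and np.all(hi >= t)
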