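"""Raytraced tip transmission and planar dose computation."""

import numpy as np
import pytest

import leafcal as lc
from leafcal.engine import tip_path_length, transmission

from _oracles import brute_force_path


class TestTipPathLength:
    def test_ray_misses_leaf_in_open_field(self, model):
        for e in (-10.0, 0.0, 18.0):
            assert tip_path_length(model, e, e + 3.0, opening_side=1) == 0.0
            assert tip_path_length(model, e, e - 3.0, opening_side=-1) == 0.0

    def test_deep_block_equals_oblique_slab_traversal(self, model):
        # beyond the tip-face taper (~7 cm at isocenter for this tip) the
        # ray crosses the full slab
        for e, u in [(0.0, -9.0), (18.0, 9.0), (-10.0, -19.0)]:
            obliquity = np.sqrt(1.0 + (u / model.source_to_iso_distance) ** 2)
            expected = model.leaf_thickness * obliquity
            got = tip_path_length(model, e, u, opening_side=1)
            assert got == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("e_axis", [-10.7, -3.0, 0.0, 5.0, 12.0, 18.72])
    @pytest.mark.parametrize("opening_side", [1, -1])
    def test_agrees_with_brute_force_ray_sampling(self, model, e_axis, opening_side):
        us = e_axis + np.linspace(-2.5, 2.5, 21)
        analytic = tip_path_length(model, e_axis, us, opening_side)
        for u, a in zip(us, analytic):
            bf = brute_force_path(model, e_axis, u, opening_side)
            assert a == pytest.approx(bf, rel=0.01, abs=2e-3)

    def test_vectorized_matches_scalar(self, model):
        us = np.linspace(-2.0, 2.0, 7)
        vec = tip_path_length(model, 0.0, us)
        for u, v in zip(us, vec):
            assert tip_path_length(model, 0.0, float(u)) == pytest.approx(v)


class TestTransmission:
    def test_closed_forms(self, model):
        assert transmission(model, 0.0) == 1.0
        assert transmission(model, 1.0) == pytest.approx(np.exp(-0.9), abs=1e-12)
        assert transmission(model, 1e6) == model.transmission_floor

    def test_negative_path_rejected(self, model):
        with pytest.raises(ValueError):
            transmission(model, -0.1)


class TestComputePlanarDose:
    def test_open_field_center_is_100(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        dose = lc.compute_planar_dose(model, beam, zero_table, setup)
        assert dose.value_at(0.0, 14.0) == pytest.approx(100.0, abs=1e-9)
        # plateau is flat near the center
        assert dose.value_at(1.0, 14.5) == pytest.approx(100.0, abs=1e-6)

    def test_blocked_region_sits_at_leakage_floor(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        dose = lc.compute_planar_dose(model, beam, zero_table, setup)
        # inside the Y1-blocked region, 2 cm (many blur widths) from the edge
        assert dose.value_at(0.0, 8.0) <= 100.0 * model.transmission_floor * 1.05

    def test_margin_extension_leaves_interior_unchanged(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        a = lc.compute_planar_dose(model, beam, zero_table, setup, margin=2.5)
        b = lc.compute_planar_dose(model, beam, zero_table, setup, margin=3.5)
        # compare shared grid nodes well inside the smaller grid (more than
        # the blur kernel reach from its boundary)
        pad = 0.5
        xs = a.xs[(a.xs >= a.xs[0] + pad) & (a.xs <= a.xs[-1] - pad)][::5]
        us = a.us[(a.us >= a.us[0] + pad) & (a.us <= a.us[-1] - pad)][::5]
        for x in xs:
            for u in us:
                assert a.value_at(x, u) == pytest.approx(b.value_at(x, u), abs=1e-9)

    def test_fully_closed_aperture_cannot_normalize(self, model, setup):
        # a closed pair driven past each other by a positive offset blocks
        # the whole plane; there is no open center to normalize against
        beam = lc.BeamDefinition.uniform(model.layout, y2=5.0, y1=-5.0)
        overtravel = lc.RLOTable.from_arrays([-12.0, 19.0], [0.6, 0.6])
        with pytest.raises(lc.NormalizationError):
            lc.compute_planar_dose(model, beam, overtravel, setup)

    def test_mirror_symmetry_of_mirrored_beam(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        d1 = lc.compute_planar_dose(model, beam, zero_table, setup)
        d2 = lc.compute_planar_dose(model, beam.mirrored(), zero_table, setup)
        p1 = lc.extract_line_profile(d1, -1.5)
        p2 = lc.extract_line_profile(d2, -1.5)
        np.testing.assert_allclose(p1.values, p2.values[::-1], atol=1e-9)

    def test_shift_equivariance_under_constant_rlo(self, model, setup):
        # with a constant offset r the engine sees only e = d - r
        def y2_edge(d, r):
            table = lc.RLOTable.from_arrays([-12.0, 19.0], [r, r])
            beam = lc.BeamDefinition.uniform(model.layout, y2=d, y1=8.0 - d)
            dose = lc.compute_planar_dose(model, beam, table, setup)
            prof = lc.normalize_profile(
                lc.extract_line_profile(dose, -1.5), d - 4.0
            )
            return lc.find_half_intensity_edges(prof, d, 8.0 - d).y2_edge

        for d, r in [(18.0, -0.3), (10.0, 0.2), (0.0, -0.5)]:
            assert abs(y2_edge(d, r) - y2_edge(d - r, 0.0)) < setup.grid_spacing

    def test_monotone_penumbra_between_20_and_80(self, beam1_profile):
        u, v = beam1_profile.u, beam1_profile.values
        for lo, hi, sign in [(9.0, 11.0, +1), (17.0, 19.0, -1)]:
            seg = v[(u >= lo) & (u <= hi)]
            band = (seg >= 20.0) & (seg <= 80.0)
            dv = sign * np.diff(seg)[band[:-1]]
            assert np.all(dv > 0)


class TestExtractLineProfile:
    def test_nearest_column_and_extent(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        dose = lc.compute_planar_dose(model, beam, zero_table, setup)
        prof = lc.extract_line_profile(dose, -1.49)
        assert prof.x_line == pytest.approx(-1.5)
        assert len(prof.u) == dose.nu
        assert prof.u[-1] - prof.u[0] == pytest.approx(
            (dose.nu - 1) * dose.spacing
        )
        np.testing.assert_array_equal(
            prof.values, dose.values[:, int(round((-1.5 - dose.x0) / dose.spacing))]
        )

    def test_symmetric_beam_gives_symmetric_profile(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=10.0, y1=10.0)
        dose = lc.compute_planar_dose(model, beam, zero_table, setup)
        prof = lc.extract_line_profile(dose, -1.5)
        np.testing.assert_allclose(prof.values, prof.values[::-1], atol=1e-9)

    def test_outside_grid_rejected(self, model, setup, zero_table):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        dose = lc.compute_planar_dose(model, beam, zero_table, setup)
        with pytest.raises(ValueError):
            lc.extract_line_profile(dose, 99.0)
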