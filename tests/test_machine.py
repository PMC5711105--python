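"""Domain types, coordinate conventions and RLO table semantics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leafcal as lc
from leafcal.exceptions import ConfigurationError, InvalidBeamError


class TestRLOLookup:
    def test_node_value_exact(self):
        table = lc.datasets.default_rlo_table()
        assert lc.rlo_lookup(table, 10.0) == pytest.approx(-0.2234, abs=1e-12)

    def test_zero_table_identity(self):
        table = lc.RLOTable.zero((-10.0, 18.0))
        for d in (-10.0, -3.3, 0.0, 7.12, 18.0):
            assert lc.rlo_lookup(table, d) == 0.0
            assert lc.effective_edge(d, table) == d

    def test_linear_interpolation_between_nodes(self):
        table = lc.RLOTable.from_arrays([0.0, 2.0], [0.0, -0.0090])
        assert lc.rlo_lookup(table, 1.0) == pytest.approx(-0.0045, abs=1e-12)

    def test_clamps_outside_tabulated_range(self):
        table = lc.RLOTable.from_arrays([0.0, 2.0], [0.1, -0.3])
        assert lc.rlo_lookup(table, -50.0) == pytest.approx(0.1)
        assert lc.rlo_lookup(table, 50.0) == pytest.approx(-0.3)

    @given(st.floats(-12.0, 19.0))
    def test_continuous_and_exact_at_nodes(self, d):
        table = lc.datasets.default_rlo_table()
        eps = 1e-7
        v = lc.rlo_lookup(table, d)
        assert abs(lc.rlo_lookup(table, d + eps) - v) < 1e-5
        for p, o in zip(table.positions, table.offsets):
            assert lc.rlo_lookup(table, p) == pytest.approx(o, abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ConfigurationError):
            lc.RLOTable((), ())
        with pytest.raises(ConfigurationError):
            lc.RLOTable.from_arrays([0.0, 0.0], [0.1, 0.2])
        with pytest.raises(ConfigurationError):
            lc.RLOTable.from_arrays([2.0, 0.0], [0.1, 0.2])
        with pytest.raises(ConfigurationError):
            lc.RLOTable.from_arrays([0.0, 1.0], [0.1])


class TestEffectiveEdge:
    def test_negative_offset_retracts_leaf(self):
        # r = -0.2234 at displayed 10 moves the leaf ~2.2 mm away from the
        # opposing bank before the dose is calculated.
        table = lc.RLOTable.from_arrays([10.0], [-0.2234])
        assert lc.effective_edge(10.0, table) == pytest.approx(10.2234, abs=1e-12)

    def test_strongly_negative_offset_at_full_retraction(self):
        table = lc.RLOTable.from_arrays([18.0], [-0.7198])
        assert lc.effective_edge(18.0, table) == pytest.approx(18.7198, abs=1e-12)


class TestApertureWidth:
    @pytest.mark.parametrize(
        "y2, y1, width",
        [(12.1, -9.9, 2.2), (18.0, -10.0, 8.0), (5.0, -5.0, 0.0)],
    )
    def test_printed_geometries(self, y2, y1, width):
        assert lc.aperture_width(y2, y1) == pytest.approx(width, abs=1e-12)

    def test_negative_width_rejected(self):
        with pytest.raises(InvalidBeamError):
            lc.aperture_width(3.0, -5.0)

    @given(st.floats(-10.0, 18.0), st.floats(-10.0, 18.0))
    def test_invariant_under_bank_exchange(self, a, b):
        # The mirrored beam swaps the banks; the aperture width cannot change.
        if a + b < 0:
            a, b = -a, -b
            if a + b < 0:
                return
        assert lc.aperture_width(a, b) == pytest.approx(lc.aperture_width(b, a))


class TestLayoutAndPresets:
    def test_elekta80_layout(self, model):
        layout = model.layout
        assert layout.leaf_count_per_bank == 40
        assert layout.leaf_span(19) == (-2.0, -1.0)
        assert layout.leaf_center(19) == pytest.approx(-1.5)
        assert layout.leaf_span(8) == (-13.0, -12.0)
        assert layout.leaf_edges_x[0] == pytest.approx(-20.0)
        assert layout.leaf_edges_x[-1] == pytest.approx(20.0)

    def test_varian120_layout(self):
        model, _ = lc.load_preset("varian120")
        widths = model.layout.leaf_widths
        assert model.layout.leaf_count_per_bank == 60
        assert widths[:10] == (1.0,) * 10
        assert widths[10:50] == (0.5,) * 40
        assert widths[50:] == (1.0,) * 10

    def test_unknown_preset_lists_alternatives(self):
        with pytest.raises(ConfigurationError, match="elekta80"):
            lc.load_preset("badname")

    def test_leaf_index_at(self, model):
        assert model.layout.leaf_index_at(-1.5) == 19
        assert model.layout.leaf_index_at(-12.5) == 8
        assert model.layout.leaf_index_at(25.0) is None


class TestBeamDefinition:
    def test_uniform_beam_geometry(self, model):
        beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
        assert beam.n_leaf_pairs == 40
        assert beam.pair_aperture(19) == (10.0, 18.0)
        assert beam.backup_y2 == pytest.approx(20.0)
        assert beam.backup_y1 == pytest.approx(-8.0)

    def test_backup_jaw_must_trail_leaves(self, model):
        with pytest.raises(InvalidBeamError):
            lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0, backup_gap=-1.0)

    def test_negative_pair_aperture_rejected(self, model):
        with pytest.raises(InvalidBeamError):
            lc.BeamDefinition.uniform(model.layout, y2=3.0, y1=-5.0)

    def test_mirrored_roundtrip(self, model):
        beam = lc.BeamDefinition.uniform(model.layout, y2=12.1, y1=-9.9, x1=20, x2=2)
        assert beam.mirrored().mirrored() == beam


class TestMachineModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"source_to_leaf_plane": 120.0},
            {"tip_radius": -1.0},
            {"mu": 0.0},
            {"transmission_floor": 1.0},
            {"blur_sigma": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            lc.MachineModel(**kwargs)

    def test_travel_range_enforced(self, model):
        with pytest.raises(InvalidBeamError):
            model.check_travel([21.0])

    def test_phantom_setup_places_plane_at_iso(self, model, setup):
        assert setup.ssd + setup.calc_depth == pytest.approx(
            model.source_to_iso_distance
        )
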