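"""Disease substrates: validation, purity, scaling semantics, directions."""

import numpy as np
import pytest

from mrla.echo import compute_echo_indices
from mrla.model import ModelError
from mrla.presets import PRESETS
from mrla.substrates import SubstrateSpec, apply_substrates


@pytest.mark.parametrize("field,value", [
    ("eroa", -0.1),
    ("la_hypertrophy", 90.0),
    ("la_hypertrophy", 310.0),
    ("la_stiffness", 50.0),
    ("la_stiffness", 700.0),
    ("lbbb_delay", -5.0),
    ("lv_hypertrophy", 80.0),
    ("flow_target", 0.0),
])
def test_spec_invariants_name_the_offending_field(field, value):
    spec = SubstrateSpec(**{field: value})
    with pytest.raises(ModelError, match=field.split("_")[0]):
        spec.validate()


def test_apply_is_pure(reference_model):
    before = reference_model.to_param_vector().copy()
    apply_substrates(reference_model, PRESETS["week20"], recalibrate=False)
    assert np.array_equal(reference_model.to_param_vector(), before)


def test_structural_scaling_semantics(reference_model):
    spec = SubstrateSpec(eroa=0.4, la_hypertrophy=250.0, la_stiffness=530.0,
                         lbbb_delay=60.0, lv_hypertrophy=125.0,
                         flow_target=3.6, map_target=75.0)
    m = apply_substrates(reference_model, spec, recalibrate=False)
    la0 = reference_model.chambers["LA"].patches[0]
    la1 = m.chambers["LA"].patches[0]
    assert la1.wall_volume == pytest.approx(2.5 * la0.wall_volume)
    assert la1.reference_midwall_area == pytest.approx(
        2.5 * la0.reference_midwall_area)
    assert la1.passive_stress_scale == pytest.approx(
        5.3 * la0.passive_stress_scale)
    assert m.valves["mitral"].leak_area == 0.4
    fw0 = reference_model.chambers["LV"].patches[0]
    fw1 = m.chambers["LV"].patches[0]
    sw1 = m.chambers["LV"].patches[1]
    assert fw1.activation_onset == pytest.approx(fw0.activation_onset + 60.0)
    assert sw1.activation_onset == pytest.approx(fw0.activation_onset)
    assert fw1.wall_volume == pytest.approx(1.25 * fw0.wall_volume)


def test_eccentric_hypertrophy_preserves_reference_thickness(reference_model):
    """Wall volume / reference area ratio (thickness at reference geometry)
    is unchanged by the hypertrophy substrate."""
    spec = SubstrateSpec(la_hypertrophy=200.0)
    m = apply_substrates(reference_model, spec, recalibrate=False)
    la0 = reference_model.chambers["LA"].patches[0]
    la1 = m.chambers["LA"].patches[0]
    assert (la1.wall_volume / la1.reference_midwall_area ==
            pytest.approx(la0.wall_volume / la0.reference_midwall_area))


def test_identity_substrate_reproduces_reference(reference):
    model, ref_beat = reference
    spec = SubstrateSpec(eroa=0.0, flow_target=model.flow_target,
                         map_target=model.map_target)
    _, beat = apply_substrates(model, spec,
                               init_state=ref_beat.states[-1].copy())
    a = compute_echo_indices(ref_beat)
    b = compute_echo_indices(beat, ref_beat)
    for field in ("lvedv", "lvef", "las_r", "las_ct_mag", "lafac"):
        assert getattr(b, field) == pytest.approx(getattr(a, field), rel=1e-3)
    assert b.la_es_area_ratio == pytest.approx(1.0, abs=1e-3)


def test_field_order_does_not_matter(reference_model):
    a = SubstrateSpec(eroa=0.4, la_hypertrophy=180.0, la_stiffness=220.0,
                      flow_target=3.6, map_target=75.0)
    b = SubstrateSpec(map_target=75.0, flow_target=3.6, la_stiffness=220.0,
                      la_hypertrophy=180.0, eroa=0.4)
    ma = apply_substrates(reference_model, a, recalibrate=False)
    mb = apply_substrates(reference_model, b, recalibrate=False)
    assert np.array_equal(ma.to_param_vector(), mb.to_param_vector())


def test_hypertrophy_dilates_and_depresses_reservoir_strain(coarse_grid):
    """Along the normal-stiffness row, growing the atrium raises its
    end-systolic area and lowers reservoir strain."""
    row = [coarse_grid.cells[(h, 100.0)] for h in coarse_grid.hyp_values]
    areas = [c.la_es_area_ratio for c in row]
    strains = [c.las_r for c in row]
    assert all(b > a for a, b in zip(areas, areas[1:]))
    assert all(b < a for a, b in zip(strains, strains[1:]))


def test_stiffening_shrinks_area_and_depresses_strain(coarse_grid):
    """Along the normal-size column, stiffening lowers both the
    end-systolic area and the strain indices."""
    col = [coarse_grid.cells[(100.0, s)] for s in coarse_grid.stiff_values]
    areas = [c.la_es_area_ratio for c in col]
    strains = [c.las_r for c in col]
    cts = [c.las_ct_mag for c in col]
    assert all(b < a for a, b in zip(areas, areas[1:]))
    assert all(b < a for a, b in zip(strains, strains[1:]))
    assert all(b < a for a, b in zip(cts, cts[1:]))


def test_lbbb_delay_on_remodeled_substrate(phase_indices):
    """Adding free-wall activation delay to the 20-week substrate raises
    reservoir strain and lowers contractile strain magnitude."""
    sync = phase_indices["week20"]
    d30 = phase_indices["week20_lbbb30"]
    d60 = phase_indices["week20_lbbb60"]
    assert d30.las_r > sync.las_r
    assert d60.las_r > sync.las_r
    assert d30.las_ct_mag < sync.las_ct_mag
    assert d60.las_ct_mag < sync.las_ct_mag


def test_lbbb_dilates_and_depresses_lv(phase_indices):
    sync = phase_indices["week20"]
    d30 = phase_indices["week20_lbbb30"]
    d60 = phase_indices["week20_lbbb60"]
    assert sync.lvedv < d30.lvedv < d60.lvedv
    assert sync.lvef > d30.lvef > d60.lvef
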