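"""Grid-search substrate inference: recovery, ties, invariances."""

import copy

import numpy as np
import pytest

from mrla.echo import EchoIndices
from mrla.inference import (IndexGrid, InferenceError, best_match,
                            sweep_grid)
from mrla.substrates import SubstrateSpec


def _targets(idx: EchoIndices) -> dict:
    return {"las_r": idx.las_r, "las_ct": idx.las_ct,
            "la_es_area_ratio": idx.la_es_area_ratio}


def _toy_grid() -> IndexGrid:
    """Small synthetic grid with smoothly varying indices (no simulation)."""
    cells = {}
    hyps = (100.0, 150.0, 200.0)
    stiffs = (100.0, 200.0, 300.0)
    for h in hyps:
        for s in stiffs:
            las_r = 52.0 - 0.1 * (h - 100) - 0.02 * (s - 100)
            ct = 20.0 - 0.04 * (h - 100) - 0.015 * (s - 100)
            ratio = 1.2 + 0.004 * (h - 100) - 0.0006 * (s - 100)
            cells[(h, s)] = EchoIndices(
                las_r=las_r, las_ct=-ct, las_ct_mag=ct, lafac=60.0,
                la_es_area=10.0, la_ed_area=5.0, la_es_area_ratio=ratio,
                lvedv=150.0, lvesv=42.0, lvef=72.0, rf=52.0)
    return IndexGrid(hyp_values=hyps, stiff_values=stiffs, cells=cells,
                     failed={}, template=SubstrateSpec())


def test_grid_dimensions_match_requested_axes(coarse_grid):
    assert len(coarse_grid.hyp_values) == 5
    assert len(coarse_grid.stiff_values) == 6
    assert len(coarse_grid.cells) + len(coarse_grid.failed) == 30
    assert not coarse_grid.failed


def test_full_study_grid_shape():
    from mrla.inference import FULL_HYPERTROPHY_GRID, FULL_STIFFNESS_GRID

    assert len(FULL_HYPERTROPHY_GRID) == 21
    assert len(FULL_STIFFNESS_GRID) == 51


def test_grid_corner_equals_acute_simulation(coarse_grid, phase_indices):
    corner = coarse_grid.cells[(100.0, 100.0)]
    acute = phase_indices["acute_mr"]
    assert corner.las_r == pytest.approx(acute.las_r, rel=5e-3)
    assert corner.la_es_area_ratio == pytest.approx(acute.la_es_area_ratio,
                                                    rel=5e-3)


def test_exact_recovery_from_self_targets(coarse_grid):
    for point, idx in coarse_grid.cells.items():
        res = best_match(coarse_grid, _targets(idx))
        assert res.best_point == point
        assert res.objective_value == pytest.approx(0.0, abs=1e-20)


def test_acute_targets_recover_no_remodeling(coarse_grid, phase_indices):
    res = best_match(coarse_grid, _targets(phase_indices["acute_mr"]))
    assert res.best_point == (100.0, 100.0)


def test_sign_convention_of_contractile_target_is_normalized(coarse_grid):
    idx = coarse_grid.cells[(200.0, 300.0)]
    t_neg = {"las_r": idx.las_r, "las_ct": -idx.las_ct_mag,
             "la_es_area_ratio": idx.la_es_area_ratio}
    t_pos = {"las_r": idx.las_r, "las_ct": idx.las_ct_mag,
             "la_es_area_ratio": idx.la_es_area_ratio}
    assert best_match(coarse_grid, t_neg).best_point == \
        best_match(coarse_grid, t_pos).best_point == (200.0, 300.0)


def test_objective_invariant_to_common_rescaling():
    grid = _toy_grid()
    targets = {"las_r": 45.0, "las_ct": -16.0, "la_es_area_ratio": 1.35}
    ref = best_match(grid, targets).best_point
    factor = 3.7
    scaled = copy.deepcopy(grid)
    for idx in scaled.cells.values():
        idx.las_r *= factor
        idx.las_ct_mag *= factor
        idx.las_ct *= factor
        idx.la_es_area_ratio *= factor
    scaled_targets = {k: v * factor for k, v in targets.items()}
    assert best_match(scaled, scaled_targets).best_point == ref


def test_ties_break_lexicographically():
    grid = _toy_grid()
    # make two cells identical
    grid.cells[(200.0, 300.0)] = copy.deepcopy(grid.cells[(150.0, 200.0)])
    res = best_match(grid, _targets(grid.cells[(150.0, 200.0)]))
    assert res.best_point == (150.0, 200.0)
    assert res.objective_value == 0.0


def test_runner_ups_are_sorted():
    grid = _toy_grid()
    res = best_match(grid, _targets(grid.cells[(150.0, 200.0)]), top_k=4)
    objs = [o for _, o in res.runner_ups]
    assert objs == sorted(objs)
    assert len(res.runner_ups) == 4


def test_best_match_rejects_empty_and_incomplete_targets():
    grid = _toy_grid()
    with pytest.raises(InferenceError, match="missing"):
        best_match(grid, {"las_r": 40.0})
    empty = IndexGrid(hyp_values=(), stiff_values=(), cells={}, failed={},
                      template=SubstrateSpec())
    with pytest.raises(InferenceError, match="empty"):
        best_match(empty, {"las_r": 40, "las_ct": -10,
                           "la_es_area_ratio": 1.5})


def test_grid_frame_roundtrip(coarse_grid):
    frame = coarse_grid.to_frame()
    clone = IndexGrid.from_frame(frame, template=coarse_grid.template)
    assert clone.hyp_values == coarse_grid.hyp_values
    assert clone.stiff_values == coarse_grid.stiff_values
    for key, idx in coarse_grid.cells.items():
        assert clone.cells[key].las_r == pytest.approx(idx.las_r)
        assert clone.cells[key].la_es_area_ratio == pytest.approx(
            idx.la_es_area_ratio)


def test_noise_robustness_within_one_grid_step(coarse_grid):
    """With +-5% relative perturbation of the targets, the recovered point
    stays within one grid step of the truth in >=90% of seeded trials."""
    rng = np.random.default_rng(2024)
    points = list(coarse_grid.cells)
    hyp_step = np.diff(coarse_grid.hyp_values).max()
    stiff_step = np.diff(coarse_grid.stiff_values).max()
    hits = trials = 0
    for _ in range(100):
        true_pt = points[rng.integers(len(points))]
        idx = coarse_grid.cells[true_pt]
        noisy = {k: v * (1.0 + rng.uniform(-0.05, 0.05))
                 for k, v in _targets(idx).items()}
        got = best_match(coarse_grid, noisy).best_point
        trials += 1
        hits += (abs(got[0] - true_pt[0]) <= hyp_step
                 and abs(got[1] - true_pt[1]) <= stiff_step)
    assert hits / trials >= 0.90
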