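"""Best-match inference of LA remodeling substrates by grid search.

Forward simulations are run over a (LA hypertrophy x LA stiffness) grid on
top of a fixed base substrate (typically acute MR), and the grid point whose
simulated LA reservoir strain, contractile strain and end-systolic area
ratio are closest to measured values -- in normalized squared relative
error -- is selected. The equal weighting of the three indices is a
documented choice and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .echo import EchoIndices, compute_echo_indices
from .model import BeatResult, CirculationModel, ConvergenceError
from .substrates import SubstrateSpec, apply_substrates

log = logging.getLogger(__name__)

# the study's full sweep: hypertrophy 100..300%, stiffness 100..600%, 10-pt steps
FULL_HYPERTROPHY_GRID = tuple(range(100, 301, 10))
FULL_STIFFNESS_GRID = tuple(range(100, 601, 10))

MATCH_INDICES = ("las_r", "las_ct_mag", "la_es_area_ratio")


class InferenceError(RuntimeError):
    pass


@dataclass
class IndexGrid:
    """Echo indices over a substrate grid, plus provenance."""

    hyp_values: tuple[float, ...]
    stiff_values: tuple[float, ...]
    cells: dict[tuple[float, float], EchoIndices]
    failed: dict[tuple[float, float], str]
    template: SubstrateSpec

    def validate(self) -> None:
        for vals, name in ((self.hyp_values, "hyp_values"),
                           (self.stiff_values, "stiff_values")):
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise InferenceError(f"{name} must be strictly increasing")
        for h in self.hyp_values:
            for s in self.stiff_values:
                if (h, s) not in self.cells and (h, s) not in self.failed:
                    raise InferenceError(f"grid cell ({h}, {s}) missing")

    def to_frame(self):
        import pandas as pd

        rows = []
        for (h, s), idx in sorted(self.cells.items()):
            row = {"la_hypertrophy": h, "la_stiffness": s}
            row.update(idx.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame, template: Optional[SubstrateSpec] = None
                   ) -> "IndexGrid":
        cells = {}
        for _, row in frame.iterrows():
            key = (float(row["la_hypertrophy"]), float(row["la_stiffness"]))
            kw = {k: (None if k == "la_es_area_ratio" and np.isnan(row[k])
                      else float(row[k]))
                  for k in EchoIndices.__dataclass_fields__}
            cells[key] = EchoIndices(**kw)
        hyps = tuple(sorted({k[0] for k in cells}))
        stiffs = tuple(sorted({k[1] for k in cells}))
        grid = cls(hyp_values=hyps, stiff_values=stiffs, cells=cells,
                   failed={}, template=template or SubstrateSpec())
        return grid


@dataclass
class MatchResult:
    best_point: tuple[float, float]       # (la_hypertrophy %, la_stiffness %)
    objective_value: float
    residuals: dict[str, float]           # per-index (sim - target)
    runner_ups: list[tuple[tuple[float, float], float]]


def sweep_grid(model: CirculationModel, template: SubstrateSpec,
               hyp_values: Sequence[float] = FULL_HYPERTROPHY_GRID,
               stiff_values: Sequence[float] = FULL_STIFFNESS_GRID,
               reference_beat: Optional[BeatResult] = None,
               max_fail_fraction: float = 0.05) -> IndexGrid:
    """One forward simulation (with homeostatic recalibration) per grid point.

    The template fixes EROA, LBBB delay, LV hypertrophy and hemodynamic
    targets; its LA fields are overridden by the grid coordinates. Each
    cell warm-starts from the previous converged state along the stiffness
    axis. Cell failures are recorded; more than ``max_fail_fraction``
    failures raise.
    """
    hyp_values = tuple(float(h) for h in hyp_values)
    stiff_values = tuple(float(s) for s in stiff_values)
    cells: dict[tuple[float, float], EchoIndices] = {}
    failed: dict[tuple[float, float], str] = {}
    row_state = None
    row_guess = None
    for h in hyp_values:
        state, guess = row_state, row_guess
        row_state = row_guess = None
        for s in stiff_values:
            spec = replace(template, la_hypertrophy=h, la_stiffness=s)
            try:
                m_cell, beat = apply_substrates(model, spec, init_state=state,
                                                hemo_guess=guess)
                state = beat.states[-1].copy()
                guess = (m_cell.vessels["sys_art"].downstream_resistance,
                         m_cell.total_blood_volume)
                if row_state is None:
                    row_state, row_guess = state, guess
                cells[(h, s)] = compute_echo_indices(beat, reference_beat)
            except ConvergenceError as exc:  # pragma: no cover - rare
                failed[(h, s)] = str(exc)
                log.warning("grid cell (%s, %s) failed: %s", h, s, exc)
                state = guess = None
    n_total = len(hyp_values) * len(stiff_values)
    if len(failed) > max_fail_fraction * n_total:
        raise InferenceError(
            f"{len(failed)}/{n_total} grid cells failed to converge")
    grid = IndexGrid(hyp_values=hyp_values, stiff_values=stiff_values,
                     cells=cells, failed=failed, template=template)
    grid.validate()
    return grid


def _normalize_targets(targets: dict) -> dict[str, float]:
    t = dict(targets)
    if "las_ct" in t and "las_ct_mag" not in t:
        t["las_ct_mag"] = abs(t.pop("las_ct"))
    missing = [k for k in MATCH_INDICES if k not in t]
    if missing:
        raise InferenceError(f"targets missing indices: {missing}")
    out = {k: float(t[k]) for k in MATCH_INDICES}
    if any(not np.isfinite(v) for v in out.values()):
        raise InferenceError(f"targets must be finite: {out}")
    return out


def best_match(grid: IndexGrid, targets: dict,
               weights: Optional[dict[str, float]] = None,
               top_k: int = 5) -> MatchResult:
    """Grid point minimizing the normalized squared relative error to the
    measured (las_r, las_ct, la_es_area_ratio) targets.

    Contractile strain is accepted in either sign convention. Ties break
    toward smaller (hypertrophy, stiffness) lexicographically.
    """
    if not grid.cells:
        raise InferenceError("empty grid")
    t = _normalize_targets(targets)
    w = {k: 1.0 for k in MATCH_INDICES}
    if weights:
        w.update(weights)
    scored = []
    for (h, s) in sorted(grid.cells):
        idx = grid.cells[(h, s)]
        obj = 0.0
        for k in MATCH_INDICES:
            sim = getattr(idx, k)
            if sim is None:
                raise InferenceError(
                    f"grid cell ({h}, {s}) lacks index {k} "
                    "(sweep run without a reference beat?)")
            scale = abs(t[k]) if t[k] != 0.0 else 1.0
            obj += w[k] * ((sim - t[k]) / scale) ** 2
        scored.append(((h, s), obj))
    # sorted(grid.cells) gives lexicographic order; stable min breaks ties
    best_pt, best_obj = min(scored, key=lambda e: e[1])
    idx = grid.cells[best_pt]
    residuals = {k: getattr(idx, k) - t[k] for k in MATCH_INDICES}
    runners = sorted(scored, key=lambda e: e[1])[1:1 + top_k]
    return MatchResult(best_point=best_pt, objective_value=best_obj,
                       residuals=residuals, runner_ups=runners)
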