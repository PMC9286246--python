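"""Disease substrates layered on the calibrated reference model.

Five mechanisms, applied as a pure transformation of a calibrated model:

* acute mitral regurgitation -- an effective regurgitant orifice (EROA) of
  the closed mitral valve;
* LA eccentric hypertrophy -- simultaneous scaling of LA wall mass and
  zero-stress wall area (chamber growth at reference geometry);
* LA passive stiffening -- scaling of the LA passive stress-stretch
  relation (fibrosis surrogate);
* left bundle-branch block -- delayed activation of the LV free wall
  relative to septum and right ventricle;
* LV eccentric hypertrophy -- scaling of both LV patches' wall mass/area.

After the structural changes, the hemodynamic homeostasis loop retunes
systemic resistance and circulating volume to the substrate's flow and
pressure targets (reduced flow/pressure represent the compromised state
after severe regurgitation).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .calibrate import homeostatic_calibration
from .model import BeatResult, CirculationModel, ModelError


@dataclass(frozen=True)
class SubstrateSpec:
    """Degrees of the five disease mechanisms plus hemodynamic targets.

    Percent fields use 100 = normal. The study grid covers LA hypertrophy
    100..300% and LA stiffness 100..600% in 10-point steps, LBBB delays
    {0, 30, 60} ms; any value within the invariants is accepted.
    """

    eroa: float = 0.0            # cm2
    la_hypertrophy: float = 100.0  # % of normal wall mass and area
    la_stiffness: float = 100.0    # % of normal passive stress scale
    lbbb_delay: float = 0.0        # ms added to LV free-wall activation
    lv_hypertrophy: float = 100.0  # % of normal LV wall mass and area
    flow_target: float = 5.1       # L/min
    map_target: float = 92.0       # mmHg

    def validate(self) -> None:
        if self.eroa < 0:
            raise ModelError(f"eroa must be >= 0, got {self.eroa}")
        if not 100.0 <= self.la_hypertrophy <= 300.0:
            raise ModelError(
                f"la_hypertrophy must be in [100, 300], got {self.la_hypertrophy}")
        if not 100.0 <= self.la_stiffness <= 600.0:
            raise ModelError(
                f"la_stiffness must be in [100, 600], got {self.la_stiffness}")
        if self.lbbb_delay < 0:
            raise ModelError(f"lbbb_delay must be >= 0, got {self.lbbb_delay}")
        if self.lv_hypertrophy < 100.0:
            raise ModelError(
                f"lv_hypertrophy must be >= 100, got {self.lv_hypertrophy}")
        if self.flow_target <= 0 or self.map_target <= 0:
            raise ModelError("flow_target and map_target must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubstrateSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown substrate keys: {sorted(unknown)}")
        spec = cls(**d)
        spec.validate()
        return spec


def apply_substrates(model: CirculationModel, spec: SubstrateSpec,
                     recalibrate: bool = True,
                     init_state: Optional[np.ndarray] = None,
                     hemo_guess: Optional[tuple[float, float]] = None,
                     ) -> CirculationModel | tuple[CirculationModel, BeatResult]:
    """Apply a substrate spec to a calibrated model (pure transformation).

    With ``recalibrate`` (default) the homeostatic loop is run against the
    spec's flow/MAP targets and the function returns
    ``(model, steady_beat)``; otherwise only the structurally modified
    model is returned. The input model is never modified.

    ``hemo_guess`` optionally seeds the homeostatic loop with a
    (systemic_resistance, total_blood_volume) starting point from a nearby
    already-calibrated simulation (pure speed-up; the converged state is
    set by the targets).
    """
    spec.validate()
    m = model.copy()

    m.valves["mitral"].leak_area = spec.eroa

    f_la = spec.la_hypertrophy / 100.0
    la = m.chambers["LA"].patches[0]
    la.wall_volume *= f_la
    la.reference_midwall_area *= f_la

    # stiffening (fibrosis surrogate) scales the whole passive stress
    # relation, i.e. both the ground-matrix and collagen branches
    la.passive_stress_scale *= spec.la_stiffness / 100.0
    la.collagen_stress_scale *= spec.la_stiffness / 100.0

    fw = m.chambers["LV"].patches[0]
    fw.activation_onset += spec.lbbb_delay

    f_lv = spec.lv_hypertrophy / 100.0
    for p in m.chambers["LV"].patches:
        p.wall_volume *= f_lv
        p.reference_midwall_area *= f_lv

    m.flow_target = spec.flow_target
    m.map_target = spec.map_target

    if not recalibrate:
        return m
    if hemo_guess is not None:
        m.vessels["sys_art"].downstream_resistance = hemo_guess[0]
        m.total_blood_volume = hemo_guess[1]
    m, beat = homeostatic_calibration(m, init_state=init_state)
    return m, beat
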