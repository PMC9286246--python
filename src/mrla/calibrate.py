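"""Deterministic calibration of the healthy reference simulation.

Two nested fixed-point loops:

1. Homeostatic pressure-flow regulation: the systemic peripheral resistance
   is set so that the target mean arterial pressure is reached at the target
   systemic flow, and the circulating blood volume is adjusted by the
   relative mean-pressure error. This loop is reused whenever a disease
   substrate changes the hemodynamic targets.

2. Structural calibration (reference model only): LV size (reference
   midwall area + wall volume at fixed shape), LV contractility and LA size
   are scaled multiplicatively until the baseline beat reproduces the
   target LV end-diastolic volume, ejection fraction and LA reservoir
   strain; the LA fractional area change co-emerges and is verified
   downstream rather than servo-controlled.

Both loops are deterministic: same configuration, same result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .model import (BeatResult, Chamber, CirculationModel, ConvergenceError,
                    Valve, VesselCompartment, WallPatch, run_to_steady_state)


class CalibrationError(ConvergenceError):
    """Calibration loop exceeded its round budget; carries residuals."""

    def __init__(self, msg: str, residuals: dict):
        self.residuals = residuals
        super().__init__(f"{msg}; residuals: {residuals}")


@dataclass(frozen=True)
class ReferenceConfig:
    """Targets and settings for the baseline reference calibration."""

    heart_rate: float = 70.0      # bpm
    flow_target: float = 5.1      # L/min
    map_target: float = 92.0      # mmHg
    lvedv_target: float = 130.0   # mL
    lvef_target: float = 55.0     # %
    las_r_target: float = 41.0    # %
    lafac_target: float = 61.0    # %
    av_delay: float = 150.0       # ms, activation-onset interval
    ventricular_twitch: float = 440.0  # ms
    atrial_twitch: float = 180.0       # ms
    hemo_tol: float = 0.003       # relative, on flow and MAP
    struct_tol: float = 0.015     # relative, on the structural targets
    max_hemo_rounds: int = 50
    max_struct_rounds: int = 30
    dt: float = 1.0e-3            # s
    beat_tol: float = 1.0e-3
    max_beats: int = 200


def initial_reference_model(config: ReferenceConfig = ReferenceConfig()
                            ) -> CirculationModel:
    """Uncalibrated starting point: textbook-scale human parameters."""
    hr = config.heart_rate
    av = config.av_delay
    tw_v = config.ventricular_twitch
    tw_a = config.atrial_twitch
    k_atrial = 3.5  # atria: shallow passive exponent (compliant reservoir)
    chambers = {
        "LA": Chamber("LA", [WallPatch(
            wall_volume=12.0, reference_midwall_area=50.0,
            activation_onset=0.0, twitch_duration=tw_a,
            active_stress_scale=15.0, passive_stress_scale=4.0,
            passive_exponent=k_atrial, collagen_stress_scale=1.5,
            collagen_exponent=25.0, collagen_slack=1.28,
            compression_factor=2.5)]),
        "RA": Chamber("RA", [WallPatch(
            wall_volume=15.0, reference_midwall_area=65.0,
            activation_onset=0.0, twitch_duration=tw_a,
            active_stress_scale=2.5, passive_stress_scale=1.5,
            passive_exponent=k_atrial, collagen_stress_scale=1.5,
            collagen_exponent=25.0, collagen_slack=1.28,
            compression_factor=2.5)]),
        "LV": Chamber("LV", [
            WallPatch(wall_volume=113.0, reference_midwall_area=101.0,
                      activation_onset=av, twitch_duration=tw_v,
                      active_stress_scale=28.0, passive_stress_scale=0.6,
                      starling_slope=10.5, rise_fraction=0.3),
            WallPatch(wall_volume=57.0, reference_midwall_area=50.5,
                      activation_onset=av, twitch_duration=tw_v,
                      active_stress_scale=28.0, passive_stress_scale=0.6,
                      starling_slope=10.5, rise_fraction=0.3),
        ]),
        "RV": Chamber("RV", [WallPatch(
            wall_volume=65.0, reference_midwall_area=130.0,
            activation_onset=av, twitch_duration=tw_v,
            active_stress_scale=14.0, passive_stress_scale=0.6,
            starling_slope=10.5, rise_fraction=0.3)]),
    }
    valves = {
        # the aortic series resistance is the lumped proximal-aortic
        # (characteristic) impedance; it meters ejection in place of the
        # unmodelled arterial wave dynamics
        "mitral": Valve("mitral", open_area=5.0),
        "aortic": Valve("aortic", open_area=3.0, viscous_resistance=0.22),
        "tricuspid": Valve("tricuspid", open_area=6.0),
        "pulmonary": Valve("pulmonary", open_area=3.5,
                           viscous_resistance=0.015),
    }
    vessels = {
        "sys_art": VesselCompartment("sys_art", compliance=1.4,
                                     unstressed_volume=600.0,
                                     downstream_resistance=1.03),
        "sys_ven": VesselCompartment("sys_ven", compliance=60.0,
                                     unstressed_volume=2800.0,
                                     downstream_resistance=0.015),
        "pulm_art": VesselCompartment("pulm_art", compliance=4.0,
                                      unstressed_volume=90.0,
                                      downstream_resistance=0.07),
        "pulm_ven": VesselCompartment("pulm_ven", compliance=10.0,
                                      unstressed_volume=350.0,
                                      downstream_resistance=0.10),
    }
    return CirculationModel(
        heart_rate=hr, av_delay=av, total_blood_volume=4800.0,
        chambers=chambers, valves=valves, vessels=vessels,
        flow_target=config.flow_target, map_target=config.map_target)


# ------------------------------------------------------------ homeostasis
def homeostatic_calibration(model: CirculationModel,
                            init_state: Optional[np.ndarray] = None,
                            tol: float = 0.005,
                            max_rounds: int = 50,
                            dt: float = 1.0e-3,
                            beat_tol: float = 1.0e-3,
                            max_beats: int = 200,
                            ) -> tuple[CirculationModel, BeatResult]:
    """Adjust systemic resistance and blood volume to hit flow/MAP targets.

    Returns the adjusted model (a copy; the input is not modified) together
    with its converged steady-state beat. The steady state of each round
    warm-starts the next.
    """
    m = model.copy()
    co_target = m.flow_target * 1000.0 / 60.0      # mL/s
    state = init_state
    beat = None
    prev: Optional[tuple[float, float]] = None     # (V_total, MAP)
    for rnd in range(max_rounds):
        beat = run_to_steady_state(m, dt=dt, tol=beat_tol,
                                   max_beats=max_beats, init_state=state)
        state = beat.states[-1].copy()
        co = beat.forward_volume("aortic") / m.cycle_time   # mL/s
        mean_map = beat.mean_arterial_pressure()
        err_f = co / co_target - 1.0
        err_p = mean_map / m.map_target - 1.0
        if abs(err_f) < tol and abs(err_p) < tol:
            return m, beat
        p_ven = float(np.mean(beat.p_sysven[:-1]))
        r_new = (m.map_target - p_ven) / co_target
        m.vessels["sys_art"].downstream_resistance = max(r_new, 0.05)
        # volume adjustment by the MAP error: damped secant on MAP(V_total),
        # first round uses the venous compliance as the slope estimate
        dmap = m.map_target - mean_map
        slope = None
        if prev is not None and abs(m.total_blood_volume - prev[0]) > 1.0:
            slope = (mean_map - prev[1]) / (m.total_blood_volume - prev[0])
        if slope is None or slope <= 1e-4:
            slope = 1.0 / m.vessels["sys_ven"].compliance
        prev = (m.total_blood_volume, mean_map)
        dv = float(np.clip(0.7 * dmap / slope, -300.0, 300.0))
        m.total_blood_volume += dv
        # volume enters/leaves through the venous reservoir
        state[5] = max(state[5] + dv,
                       0.3 * m.vessels["sys_ven"].unstressed_volume)
    residuals = {"flow_rel_err": err_f, "map_rel_err": err_p}
    raise CalibrationError(
        f"homeostatic calibration did not converge in {max_rounds} rounds",
        residuals)


def _scale_patch_size(patch: WallPatch, linear: float) -> None:
    """Scale a patch geometrically by a linear factor (area ~ f^2, vol ~ f^3)."""
    patch.reference_midwall_area *= linear ** 2
    patch.wall_volume *= linear ** 3


# ------------------------------------------------------- structural loop
def calibrate_reference(config: ReferenceConfig = ReferenceConfig()
                        ) -> tuple[CirculationModel, BeatResult]:
    """Full deterministic calibration of the healthy reference simulation."""
    from .echo import compute_echo_indices

    m = initial_reference_model(config)
    la_scale = 1.0      # cumulative LA linear scale, guarded against runaway
    state = None
    beat = None
    hist = {}
    for rnd in range(config.max_struct_rounds):
        m, beat = homeostatic_calibration(
            m, init_state=state, tol=config.hemo_tol,
            max_rounds=config.max_hemo_rounds, dt=config.dt,
            beat_tol=config.beat_tol, max_beats=config.max_beats)
        state = beat.states[-1].copy()
        idx = compute_echo_indices(beat)
        # LA fractional area change co-emerges with the strain targets and
        # has no independent strong-leverage knob; it is verified against
        # its target downstream, not servo-controlled here.
        errs = {
            "lvedv": idx.lvedv / config.lvedv_target - 1.0,
            "lvef": idx.lvef / config.lvef_target - 1.0,
            "las_r": idx.las_r / config.las_r_target - 1.0,
        }
        hist = dict(errs, lafac=idx.lafac / config.lafac_target - 1.0)
        if max(abs(e) for e in errs.values()) < config.struct_tol:
            m.validate()
            return m, beat
        # LV size: linear factor from volume mismatch
        f_lv = (config.lvedv_target / idx.lvedv) ** (1.0 / 3.0)
        for p in m.chambers["LV"].patches:
            _scale_patch_size(p, f_lv)
        # LV contractility: stronger contraction raises EF
        f_ef = (config.lvef_target / idx.lvef)
        for p in m.chambers["LV"].patches:
            p.active_stress_scale *= np.clip(f_ef ** 1.2, 0.6, 1.6)
        # LA size: a smaller atrium is stretched more by the same filling
        # volume -> higher reservoir strain (damped update; cumulative range
        # guarded, the strain-size relation is only locally monotone)
        f_la = float(np.clip((idx.las_r / config.las_r_target) ** 0.45,
                             0.75, 1.3))
        f_la = float(np.clip(la_scale * f_la, 0.6, 1.6)) / la_scale
        la_scale *= f_la
        _scale_patch_size(m.chambers["LA"].patches[0], f_la)
    raise CalibrationError(
        f"structural calibration did not converge in "
        f"{config.max_struct_rounds} rounds", hist)


# ----------------------------------------------------------- public API
@lru_cache(maxsize=8)
def _cached_reference(config: ReferenceConfig) -> tuple[CirculationModel, BeatResult]:
    return calibrate_reference(config)


def build_reference_model(config: Optional[ReferenceConfig] = None
                          ) -> CirculationModel:
    """Calibrated healthy reference model meeting the baseline targets.

    Deterministic; results are cached in-process per configuration. The
    returned model is a copy and safe to mutate.
    """
    cfg = config or ReferenceConfig()
    model, _ = _cached_reference(cfg)
    return model.copy()


def reference_beat(config: Optional[ReferenceConfig] = None) -> BeatResult:
    """Steady-state beat of the calibrated reference model (cached)."""
    cfg = config or ReferenceConfig()
    _, beat = _cached_reference(cfg)
    return beat
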