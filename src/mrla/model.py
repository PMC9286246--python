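"""Closed-loop lumped-parameter model of the four-chamber heart and circulation.

The heart chambers are thick-walled spheres following a one-fiber wall model:
the midwall radius follows from cavity volume plus half the wall volume, the
fiber stretch is the square root of the midwall-area ratio to its zero-stress
reference, and the transmural (cavity) pressure follows from total fiber
stress via Laplace's law, p = 2*sigma*h/r. Total stress is an active
rise-plateau-fall twitch with a saturating linear length dependence
(Frank-Starling) plus a biphasic exponential passive stress. The left ventricle carries two patches (free wall
and septum) that share the cavity and split the midwall area by tension
balance, so dyssynchronous activation produces per-wall strain differences.

Valves are inertial Bernoulli orifices with pressure-driven opening dynamics;
a closed mitral valve may retain an effective regurgitant orifice (EROA).
Systemic and pulmonary beds are linear compliance/resistance compartments,
closing the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel as K

CHAMBER_NAMES = ("LA", "RA", "LV", "RV")
PATCH_ORDER = (("LA", 0), ("RA", 0), ("LV", 0), ("LV", 1), ("RV", 0))
VALVE_NAMES = ("mitral", "aortic", "tricuspid", "pulmonary")
VESSEL_NAMES = ("sys_art", "sys_ven", "pulm_art", "pulm_ven")


class ModelError(ValueError):
    """Invalid model construction or parameters."""


class ConvergenceError(RuntimeError):
    """Integration or calibration failed to converge."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelError(msg)


@dataclass
class WallPatch:
    """One myocardial wall patch of the one-fiber model.

    wall_volume            myocardial tissue volume, mL
    reference_midwall_area zero-stress midwall area, cm2
    activation_onset       onset of the active twitch within the cycle, ms
    twitch_duration        active twitch duration, ms
    active_stress_scale    peak isometric active stress, kPa
    passive_stress_scale   passive stress scale, kPa
    passive_exponent       exponent of the passive stress-stretch relation
    starling_slope         linear length dependence of active stress
    """

    wall_volume: float
    reference_midwall_area: float
    activation_onset: float
    twitch_duration: float
    active_stress_scale: float
    passive_stress_scale: float
    passive_exponent: float = 10.0
    starling_slope: float = 5.0
    collagen_stress_scale: float = 0.0   # kPa; steep second passive branch
    collagen_exponent: float = 25.0
    collagen_slack: float = 1.25         # stretch at which collagen engages
    compression_factor: float = 1.0      # compression slope multiplier at lam<1
    rise_fraction: float = 0.5           # twitch flank width / duration; 0.5 = no plateau
    starling_max: float = 3.0            # plateau of the length-dependence factor

    def validate(self, cycle_ms: float) -> None:
        _require(self.wall_volume > 0, "wall_volume must be > 0")
        _require(self.reference_midwall_area > 0,
                 "reference_midwall_area must be > 0")
        _require(self.passive_stress_scale >= 0,
                 "passive_stress_scale must be >= 0")
        _require(self.active_stress_scale >= 0,
                 "active_stress_scale must be >= 0")
        _require(0 <= self.activation_onset < cycle_ms,
                 "activation_onset must lie within the cycle")
        _require(self.twitch_duration > 0, "twitch_duration must be > 0")


@dataclass
class Chamber:
    name: str
    patches: list[WallPatch]

    def validate(self, cycle_ms: float) -> None:
        _require(self.name in CHAMBER_NAMES, f"unknown chamber {self.name!r}")
        want = 2 if self.name == "LV" else 1
        _require(len(self.patches) == want,
                 f"chamber {self.name} must have {want} patch(es)")
        for p in self.patches:
            p.validate(cycle_ms)

    @property
    def wall_volume(self) -> float:
        return sum(p.wall_volume for p in self.patches)


@dataclass
class Valve:
    """Inertial orifice valve; leak_area is the EROA when closed."""

    name: str
    open_area: float
    leak_area: float = 0.0
    inertance: float = 1.0     # effective blood-column length, cm
    rate_constant: float = 50.0  # opening/closing rate per mmHg, 1/(mmHg.s)
    viscous_resistance: float = 0.001  # series resistance, mmHg.s/mL

    def validate(self) -> None:
        _require(self.name in VALVE_NAMES, f"unknown valve {self.name!r}")
        _require(self.open_area > 0, "open_area must be > 0")
        _require(self.leak_area >= 0, "leak_area must be >= 0")


@dataclass
class VesselCompartment:
    name: str
    compliance: float            # mL/mmHg
    unstressed_volume: float     # mL
    downstream_resistance: float  # mmHg.s/mL

    def validate(self) -> None:
        _require(self.name in VESSEL_NAMES, f"unknown vessel {self.name!r}")
        _require(self.compliance > 0, "compliance must be > 0")
        _require(self.downstream_resistance > 0, "resistance must be > 0")


@dataclass
class CirculationModel:
    heart_rate: float                 # bpm
    av_delay: float                   # ms, atrial-to-ventricular activation
    total_blood_volume: float         # mL
    chambers: dict[str, Chamber]
    valves: dict[str, Valve]
    vessels: dict[str, VesselCompartment]
    flow_target: float = 5.1          # L/min
    map_target: float = 92.0          # mmHg
    bernoulli_coefficient: float = K.BERNOULLI


    # ------------------------------------------------------------------
    @property
    def cycle_time(self) -> float:
        return 60.0 / self.heart_rate

    def validate(self) -> None:
        _require(self.heart_rate > 0, "heart_rate must be > 0")
        _require(self.flow_target > 0, "flow_target must be > 0")
        _require(self.map_target > 0, "map_target must be > 0")
        _require(self.total_blood_volume > 0, "total_blood_volume must be > 0")
        cyc = 1000.0 * self.cycle_time
        for name in CHAMBER_NAMES:
            _require(name in self.chambers, f"missing chamber {name}")
            self.chambers[name].validate(cyc)
        for name in VALVE_NAMES:
            _require(name in self.valves, f"missing valve {name}")
            self.valves[name].validate()
        for name in VESSEL_NAMES:
            _require(name in self.vessels, f"missing vessel {name}")
            self.vessels[name].validate()
        for name, v in self.valves.items():
            if name != "mitral":
                _require(v.leak_area == 0.0,
                         "only the mitral valve may have a leak orifice")

    def copy(self) -> "CirculationModel":
        import copy

        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    def to_param_vector(self) -> np.ndarray:
        self.validate()
        P = np.zeros(K.NPARAM)
        P[K.I_TCYC] = self.cycle_time
        for i, (cham, idx) in enumerate(PATCH_ORDER):
            p = self.chambers[cham].patches[idx]
            b = K.PATCH0 + i * K.NPPATCH
            P[b + K.P_VW] = p.wall_volume
            P[b + K.P_AREF] = p.reference_midwall_area
            P[b + K.P_ONSET] = p.activation_onset / 1000.0
            P[b + K.P_TWITCH] = p.twitch_duration / 1000.0
            P[b + K.P_SACT] = p.active_stress_scale
            P[b + K.P_SPAS] = p.passive_stress_scale
            P[b + K.P_KPAS] = p.passive_exponent
            P[b + K.P_FSS] = p.starling_slope
            P[b + K.P_SCOL] = p.collagen_stress_scale
            P[b + K.P_KCOL] = p.collagen_exponent
            P[b + K.P_LCOL] = p.collagen_slack
            P[b + K.P_CCOMP] = p.compression_factor
            P[b + K.P_TRISE] = p.rise_fraction
            P[b + K.P_GMAX] = p.starling_max
        for j, name in enumerate(VALVE_NAMES):
            v = self.valves[name]
            b = K.VALVE0 + j * K.NPVALVE
            P[b + K.V_AOPEN] = v.open_area
            P[b + K.V_ALEAK] = v.leak_area
            P[b + K.V_LLEN] = v.inertance
            P[b + K.V_KV] = v.rate_constant
            P[b + K.V_RLIN] = v.viscous_resistance
        for j, name in enumerate(VESSEL_NAMES):
            ves = self.vessels[name]
            b = K.VESSEL0 + j * K.NPVESSEL
            P[b] = ves.compliance
            P[b + 1] = ves.unstressed_volume
        P[K.I_RSYS] = self.vessels["sys_art"].downstream_resistance
        P[K.I_RPULM] = self.vessels["pulm_art"].downstream_resistance
        P[K.I_RVENRA] = self.vessels["sys_ven"].downstream_resistance
        P[K.I_RVENLA] = self.vessels["pulm_ven"].downstream_resistance
        P[K.I_BERN] = self.bernoulli_coefficient
        return P

    def initial_state(self) -> np.ndarray:
        """A physiologically plausible starting state for the integrator."""
        y = np.zeros(K.NSTATE)
        y[K.IV_LA] = 30.0
        y[K.IV_RA] = 40.0
        y[K.IV_LV] = 120.0
        y[K.IV_RV] = 120.0
        sa = self.vessels["sys_art"]
        pa = self.vessels["pulm_art"]
        pv = self.vessels["pulm_ven"]
        y[K.IV_SA] = sa.unstressed_volume + 85.0 * sa.compliance
        y[K.IV_PA] = pa.unstressed_volume + 14.0 * pa.compliance
        y[K.IV_PV] = pv.unstressed_volume + 8.0 * pv.compliance
        used = (y[K.IV_LA] + y[K.IV_RA] + y[K.IV_LV] + y[K.IV_RV]
                + y[K.IV_SA] + y[K.IV_PA] + y[K.IV_PV])
        rest = self.total_blood_volume - used
        _require(rest > 0, "total_blood_volume too small for initial state")
        y[K.IV_SV] = rest
        y[K.IZ_MV] = 1.0
        y[K.IZ_TV] = 1.0
        vm = y[K.IV_LV] + 0.5 * self.chambers["LV"].wall_volume
        area = (36.0 * np.pi * vm * vm) ** (1.0 / 3.0)
        y[K.IX_FW] = area * 2.0 / 3.0
        return y

    # config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "heart_rate": self.heart_rate,
            "av_delay": self.av_delay,
            "total_blood_volume": self.total_blood_volume,
            "flow_target": self.flow_target,
            "map_target": self.map_target,
            "bernoulli_coefficient": self.bernoulli_coefficient,
            "chambers": {n: {"name": c.name,
                             "patches": [asdict(p) for p in c.patches]}
                         for n, c in self.chambers.items()},
            "valves": {n: asdict(v) for n, v in self.valves.items()},
            "vessels": {n: asdict(v) for n, v in self.vessels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CirculationModel":
        d = dict(d)
        chambers = {n: Chamber(name=c["name"],
                               patches=[WallPatch(**p) for p in c["patches"]])
                    for n, c in d.pop("chambers").items()}
        valves = {n: Valve(**v) for n, v in d.pop("valves").items()}
        vessels = {n: VesselCompartment(**v) for n, v in d.pop("vessels").items()}
        known = {"heart_rate", "av_delay", "total_blood_volume", "flow_target",
                 "map_target", "bernoulli_coefficient"}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown model config keys: {sorted(unknown)}")
        m = cls(chambers=chambers, valves=valves, vessels=vessels, **d)
        m.validate()
        return m


# ======================================================================
@dataclass
class BeatResult:
    """One steady-state cardiac cycle of the closed-loop model."""

    time: np.ndarray                  # s, 0 .. cycle_time
    states: np.ndarray                # (nt, NSTATE)
    aux: np.ndarray                   # (nt, NAUX)
    model: CirculationModel
    beats_run: int
    residual: float
    converged: bool

    def _s(self, i: int) -> np.ndarray:
        return self.states[:, i]

    def _a(self, i: int) -> np.ndarray:
        return self.aux[:, i]

    # volumes
    @property
    def v_la(self): return self._s(K.IV_LA)
    @property
    def v_ra(self): return self._s(K.IV_RA)
    @property
    def v_lv(self): return self._s(K.IV_LV)
    @property
    def v_rv(self): return self._s(K.IV_RV)
    # valve flows
    @property
    def q_mv(self): return self._s(K.IQ_MV)
    @property
    def q_av(self): return self._s(K.IQ_AV)
    @property
    def q_tv(self): return self._s(K.IQ_TV)
    @property
    def q_pv(self): return self._s(K.IQ_PV)
    # pressures
    @property
    def p_la(self): return self._a(K.A_PLA)
    @property
    def p_lv(self): return self._a(K.A_PLV)
    @property
    def p_ra(self): return self._a(K.A_PRA)
    @property
    def p_rv(self): return self._a(K.A_PRV)
    @property
    def p_sysart(self): return self._a(K.A_PSA)
    @property
    def p_sysven(self): return self._a(K.A_PSV)
    @property
    def p_pulmart(self): return self._a(K.A_PPA)
    @property
    def p_pulmven(self): return self._a(K.A_PPV)
    # midwall areas
    @property
    def area_la(self): return self._a(K.A_ALA)
    @property
    def area_ra(self): return self._a(K.A_ARA)
    @property
    def area_lvfw(self): return self._a(K.A_AFW)
    @property
    def area_sw(self): return self._a(K.A_ASW)
    @property
    def area_rv(self): return self._a(K.A_ARV)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def total_volume(self) -> float:
        return float(self.states[0, :8].sum())

    # per-beat volumes ---------------------------------------------------
    def forward_volume(self, valve: str = "aortic") -> float:
        q = {"mitral": self.q_mv, "aortic": self.q_av,
             "tricuspid": self.q_tv, "pulmonary": self.q_pv}[valve]
        return float(np.trapezoid(np.maximum(q, 0.0), self.time))

    def backward_volume(self, valve: str = "mitral") -> float:
        q = {"mitral": self.q_mv, "aortic": self.q_av,
             "tricuspid": self.q_tv, "pulmonary": self.q_pv}[valve]
        return float(np.trapezoid(np.maximum(-q, 0.0), self.time))

    def mean_systemic_flow(self) -> float:
        """Mean systemic (forward aortic) flow in L/min."""
        return self.forward_volume("aortic") / self.model.cycle_time * 60.0 / 1000.0

    def mean_arterial_pressure(self) -> float:
        return float(np.mean(self.p_sysart[:-1]))

    # export -------------------------------------------------------------
    def to_frame(self):
        import pandas as pd

        from .echo import detect_valve_events, la_strain_curve, patch_strain_curve

        events = detect_valve_events(self)
        strain_la = la_strain_curve(self, events).values
        strain_fw = patch_strain_curve(self, "lvfw", events).values
        strain_sw = patch_strain_curve(self, "sw", events).values
        return pd.DataFrame({
            "time_s": self.time,
            "v_la": self.v_la, "v_lv": self.v_lv,
            "v_ra": self.v_ra, "v_rv": self.v_rv,
            "p_sysart": self.p_sysart, "p_pulmven": self.p_pulmven,
            "q_mv": self.q_mv, "q_av": self.q_av,
            "a_la": self.area_la,
            "strain_la": strain_la, "strain_lvfw": strain_fw,
            "strain_sw": strain_sw,
        })

    def export_csv(self, path) -> None:
        """Write the beat as CSV with a JSON sidecar of convergence metadata."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"beats_run": self.beats_run, "residual": self.residual,
                "converged": self.converged,
                "heart_rate": self.model.heart_rate,
                "cycle_time_s": self.model.cycle_time}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


class NegativeVolumeError(ConvergenceError):
    def __init__(self, chamber: str, time: float):
        self.chamber = chamber
        self.time = time
        super().__init__(f"negative cavity volume in {chamber} at t={time:.4f} s")


_STATE_FLOOR = np.array([1.0] * 8 + [10.0] * 4 + [0.05] * 4 + [1.0])


def run_to_steady_state(model: CirculationModel,
                        dt: float = 1.0e-3,
                        tol: float = 1.0e-3,
                        max_beats: int = 200,
                        min_beats: int = 5,
                        init_state: Optional[np.ndarray] = None) -> BeatResult:
    """Run the model to its periodic steady state and return the final beat.

    Convergence: the beat-to-beat relative change of every state variable
    (scaled by a per-state floor) drops below ``tol``. The step count per
    beat is round(cycle/dt), so the recorded beat is exactly one period.
    """
    P = model.to_param_vector()
    tcyc = model.cycle_time
    nst = int(round(tcyc / dt))
    dt_eff = tcyc / nst
    y = model.initial_state() if init_state is None else np.array(init_state, dtype=float)
    if y.shape != (K.NSTATE,):
        raise ModelError("init_state has wrong shape")
    dummy_y = np.empty((1, K.NSTATE))
    dummy_a = np.empty((1, K.NAUX))

    residual = np.inf
    beats = 0
    for beat in range(max_beats):
        y_prev = y.copy()
        status, cham, step = K.integrate_beat(y, P, nst, dt_eff,
                                              dummy_y, dummy_a, False)
        beats += 1
        if status == 1:
            raise NegativeVolumeError(CHAMBER_NAMES[cham], step * dt_eff)
        scale = np.maximum(np.abs(y), _STATE_FLOOR)
        residual = float(np.max(np.abs(y - y_prev) / scale))
        if residual < tol and beats >= min_beats:
            break
    converged = residual < tol
    if not converged:
        raise ConvergenceError(
            f"no periodic steady state after {beats} beats "
            f"(last residual {residual:.3e} > tol {tol:.1e})")

    yout = np.empty((nst + 1, K.NSTATE))
    auxout = np.empty((nst + 1, K.NAUX))
    yrec = y.copy()
    status, cham, step = K.integrate_beat(yrec, P, nst, dt_eff, yout, auxout, True)
    if status == 1:
        raise NegativeVolumeError(CHAMBER_NAMES[cham], step * dt_eff)
    time = np.linspace(0.0, tcyc, nst + 1)
    return BeatResult(time=time, states=yout, aux=auxout, model=model,
                      beats_run=beats, residual=residual, converged=True)


def mitral_regurgitant_fraction(beat: BeatResult) -> float:
    """Regurgitant fraction in % = backward mitral / (backward mitral +
    forward aortic) volume per beat."""
    if not beat.converged:
        raise ConvergenceError("regurgitant fraction requires a converged beat")
    back = beat.backward_volume("mitral")
    fwd = beat.forward_volume("aortic")
    return 100.0 * back / (back + fwd)


def build_reference_model(config=None) -> CirculationModel:
    """Calibrated healthy reference model (see :mod:`mrla.calibrate`)."""
    from .calibrate import build_reference_model as _build

    return _build(config)
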