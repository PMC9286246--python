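"""Echocardiography-style indices computed from a simulated beat.

Strain conventions follow clinical atrial strain analysis: the zero-strain
reference is set at mitral valve closure (LV end-diastole); reservoir strain
LAS(r) is the strain value at mitral valve opening; contractile strain is
the pre-A strain value (at onset of atrial contraction), reported both as a
positive magnitude and in the negative echo convention. The LA "area" of the
spherical model is the midwall disc cross-section pi*r^2 -- only area ratios
and the fractional area change are compared across simulations, so the
choice of cross-section metric cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .model import BeatResult, ConvergenceError


class EchoError(ValueError):
    """Index extraction failed (missing event, inconsistent labels...)."""


@dataclass(frozen=True)
class EventTimes:
    """Valve event times (s) within one cycle starting at atrial activation."""

    mv_closure: float
    av_opening: float
    av_closure: float
    mv_opening: float
    atrial_onset: float

    def validate(self) -> None:
        seq = (self.mv_closure, self.av_opening, self.av_closure,
               self.mv_opening, self.atrial_onset)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise EchoError(f"valve events out of cyclic order: {seq}")


@dataclass
class EchoIndices:
    las_r: float          # LA reservoir strain, %
    las_ct: float         # LA contractile strain, echo convention (<= 0), %
    las_ct_mag: float     # LA contractile strain magnitude, %
    lafac: float          # LA fractional area change, %
    la_es_area: float     # maximal LA area over the cycle, cm2
    la_ed_area: float     # minimal LA area over the cycle, cm2
    la_es_area_ratio: Optional[float]  # vs a reference (baseline) beat
    lvedv: float          # mL
    lvesv: float          # mL
    lvef: float           # %
    rf: float             # mitral regurgitant fraction, %

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------- events
def _up_crossing(t, q, eps, start=0):
    """First index i >= start with q[i-1] <= eps < q[i]."""
    for i in range(max(start, 1), len(q)):
        if q[i - 1] <= eps < q[i]:
            return i
    return None


def _down_crossing_before(t, q, eps, stop):
    """Last index i <= stop with q[i-1] > eps >= q[i]."""
    for i in range(stop, 0, -1):
        if q[i - 1] > eps >= q[i]:
            return i
    return None


def detect_valve_events(beat: BeatResult, eps: float = 0.5) -> EventTimes:
    """Valve events from the simulated flow traces.

    Mitral closure/opening from mitral forward-flow crossings, aortic
    opening/closure from aortic flow crossings; atrial onset is the LA
    activation time (cycle start, reported as the cycle end so that the
    event sequence is ordered within one beat).
    """
    if not beat.converged:
        raise ConvergenceError("event detection requires a converged beat")
    t = beat.time
    q_mv = beat.q_mv
    q_av = beat.q_av
    i_avo = _up_crossing(t, q_av, eps)
    if i_avo is None:
        raise EchoError("no aortic opening found (non-ejecting model?)")
    i_mvc = _down_crossing_before(t, q_mv, eps, i_avo)
    if i_mvc is None:
        raise EchoError("no mitral closure found before aortic opening")
    # aortic closure: last down-crossing of aortic flow
    i_avc = None
    for i in range(len(q_av) - 1, i_avo, -1):
        if q_av[i - 1] > eps >= q_av[i]:
            i_avc = i
            break
    if i_avc is None:
        raise EchoError("no aortic closure found")
    i_mvo = _up_crossing(t, q_mv, eps, start=i_avc)
    if i_mvo is None:
        raise EchoError("no mitral opening found after aortic closure")

    def interp(i, q):
        # linear interpolation of the eps-crossing between samples i-1 and i
        q0, q1 = q[i - 1], q[i]
        if q1 == q0:
            return t[i]
        f = (eps - q0) / (q1 - q0)
        return t[i - 1] + f * (t[i] - t[i - 1])

    ev = EventTimes(
        mv_closure=interp(i_mvc, q_mv),
        av_opening=interp(i_avo, q_av),
        av_closure=interp(i_avc, q_av),
        mv_opening=interp(i_mvo, q_mv),
        atrial_onset=float(t[-1]),
    )
    ev.validate()
    return ev


# ---------------------------------------------------------------- strain
@dataclass
class StrainCurve:
    """A longitudinal strain trace (%) over one cycle."""

    time: np.ndarray
    values: np.ndarray
    reference_time: float

    def at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.values))


def _length_strain(time, area, t_ref) -> StrainCurve:
    length = np.sqrt(area)
    l_ref = float(np.interp(t_ref, time, length))
    return StrainCurve(time=time, values=100.0 * (length / l_ref - 1.0),
                       reference_time=t_ref)


def la_strain_curve(beat: BeatResult, events: EventTimes) -> StrainCurve:
    """LA longitudinal strain with zero reference at mitral valve closure.

    strain(t) = 100*(L(t)/L_ref - 1) with L(t) = sqrt(LA midwall area).
    """
    return _length_strain(beat.time, beat.area_la, events.mv_closure)


def patch_strain_curve(beat: BeatResult, patch: str,
                       events: EventTimes) -> StrainCurve:
    """Strain of an LV patch ('lvfw' or 'sw'), zero at mitral valve closure."""
    area = {"lvfw": beat.area_lvfw, "sw": beat.area_sw}[patch]
    return _length_strain(beat.time, area, events.mv_closure)


def la_strain_indices(curve: StrainCurve,
                      events: EventTimes) -> tuple[float, float, float]:
    """(las_r, las_ct, las_ct_mag): reservoir strain at mitral opening and
    pre-A contractile strain at atrial onset (negated for echo convention)."""
    tmin, tmax = float(curve.time[0]), float(curve.time[-1])
    for name, t in (("mv_opening", events.mv_opening),
                    ("atrial_onset", events.atrial_onset)):
        if not (tmin <= t <= tmax):
            raise EchoError(f"event {name}={t} outside strain trace")
    las_r = curve.at(events.mv_opening)
    las_ct_mag = curve.at(events.atrial_onset)
    return las_r, -las_ct_mag, las_ct_mag


def lafac(la_es_area: float, la_ed_area: float) -> float:
    """LA fractional area change, % = 100*(ES - ED)/ES.

    Atrial end-systole is the maximal area (ventricular systole), atrial
    end-diastole the minimal area.
    """
    if not (la_es_area >= la_ed_area > 0):
        raise EchoError(
            f"need la_es_area >= la_ed_area > 0, got ES={la_es_area}, "
            f"ED={la_ed_area} (area labels swapped?)")
    return 100.0 * (la_es_area - la_ed_area) / la_es_area


def _cavity_disc_area(volume: np.ndarray) -> np.ndarray:
    """Endocardial disc cross-section pi*r^2 from a spherical cavity volume."""
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return np.pi * r * r


def la_area_metrics(beat: BeatResult,
                    reference_beat: Optional[BeatResult] = None
                    ) -> tuple[float, float, Optional[float]]:
    """(la_es_area, la_ed_area, ratio): max/min LA cavity cross-section over
    the cycle; ratio is the ES area relative to the reference beat's.

    The disc area pi*r^2 uses the endocardial (cavity) radius, mirroring the
    clinical practice of tracing the LA endocardium; wall strain, by
    contrast, follows the midwall. Only ratios and the fractional change
    are compared across simulations.
    """
    disc = _cavity_disc_area(beat.v_la)
    es = float(disc.max())
    ed = float(disc.min())
    ratio = None
    if reference_beat is not None:
        es_ref = float(_cavity_disc_area(reference_beat.v_la).max())
        ratio = es / es_ref
    return es, ed, ratio


def lv_metrics(beat: BeatResult) -> tuple[float, float, float]:
    """(lvedv, lvesv, lvef): extreme LV cavity volumes and ejection fraction."""
    lvedv = float(beat.v_lv.max())
    lvesv = float(beat.v_lv.min())
    return lvedv, lvesv, 100.0 * (lvedv - lvesv) / lvedv


def compute_echo_indices(beat: BeatResult,
                         reference_beat: Optional[BeatResult] = None
                         ) -> EchoIndices:
    """All indices of one simulated beat (area ratio vs an optional baseline)."""
    from .model import mitral_regurgitant_fraction

    events = detect_valve_events(beat)
    curve = la_strain_curve(beat, events)
    las_r, las_ct, las_ct_mag = la_strain_indices(curve, events)
    es, ed, ratio = la_area_metrics(beat, reference_beat)
    lvedv, lvesv, lvef = lv_metrics(beat)
    return EchoIndices(
        las_r=las_r, las_ct=las_ct, las_ct_mag=las_ct_mag,
        lafac=lafac(es, ed), la_es_area=es, la_ed_area=ed,
        la_es_area_ratio=ratio, lvedv=lvedv, lvesv=lvesv, lvef=lvef,
        rf=mitral_regurgitant_fraction(beat),
    )
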