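"""Synthetic longitudinal canine cohort generator.

Emulates the experimental design: an MR-LBBB group (n = 12; echo at
baseline, acutely after MR induction, and at 4 and 20 weeks; 4 animals die
of heart failure before the 20-week phase) and an LBBB-only control group
(n = 7; echo at baseline and 16 weeks). Per (group, phase, parameter) the
generator is parameterized by a median and interquartile range; defaults
reproduce the in-vivo summary statistics of the study.

Latent trajectory model: for animal i at phase j,

    value = median[j] + sigma[j] * (rho * z_i + sqrt(1 - rho^2) * z_ij)

with z ~ N(0,1), sigma = IQR/1.349 (normal-theory conversion) and rho the
within-animal correlation across phases. Contractile strain is clipped to
be non-positive (echo sign convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

IQR_TO_SIGMA = 1.0 / 1.349  # normal distribution: IQR = 1.349 sigma

PARAM_UNITS = {
    "la_es_area": "cm2",
    "lafac": "%",
    "las_r": "%",
    "las_ct": "%",
    "lvedv": "mL",
    "lvef": "%",
    "heart_rate": "bpm",
}


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: phases and per-phase (median, q1, q3) cells."""

    n: int
    phases: tuple[str, ...]
    # parameter -> phase -> (median, q1, q3)
    measurements: dict[str, dict[str, tuple[float, float, float]]]
    deaths_before_phase: str | None = None
    n_deaths: int = 0

    def validate(self, name: str) -> None:
        if self.n <= 0:
            raise CohortError(f"group {name}: n must be > 0")
        if not (self.n > self.n_deaths >= 0):
            raise CohortError(f"group {name}: need n > deaths >= 0")
        if self.deaths_before_phase is not None \
                and self.deaths_before_phase not in self.phases:
            raise CohortError(
                f"group {name}: deaths_before_phase "
                f"{self.deaths_before_phase!r} not a phase")
        for param, cells in self.measurements.items():
            if param not in PARAM_UNITS:
                raise CohortError(f"group {name}: unknown parameter {param!r}")
            for phase in self.phases:
                if phase not in cells:
                    raise CohortError(
                        f"group {name}: parameter {param!r} missing phase "
                        f"{phase!r}")
                med, q1, q3 = cells[phase]
                if not q1 <= med <= q3:
                    raise CohortError(
                        f"group {name}: {param}/{phase} IQR bounds not "
                        f"ordered: median={med}, q1={q1}, q3={q3}")


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, GroupSpec]
    rho: float = 0.6          # within-animal correlation across phases
    seed: int = 0
    severity_linked_dropout: bool = False  # drop the worst reservoir strains

    def validate(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise CohortError(f"rho must be in [0, 1), got {self.rho}")
        if not self.groups:
            raise CohortError("at least one group required")
        for name, g in self.groups.items():
            g.validate(name)


def _tbl(*cells: tuple[float, float, float]):
    return cells


# In-vivo summary cells (median, q1, q3) per phase. The heart-rate row is
# printed as mean +/- SD in the source study; it is converted here with
# median = mean and IQR = 1.349*SD.
def _hr(mean: float, sd: float) -> tuple[float, float, float]:
    half = 0.5 * 1.349 * sd
    return (mean, mean - half, mean + half)


_MR_LBBB_PHASES = ("baseline", "acute", "4w", "20w")
_MR_LBBB = {
    "la_es_area": dict(zip(_MR_LBBB_PHASES, _tbl(
        (7.4, 6.3, 7.8), (8.0, 7.1, 8.9), (13.0, 8.6, 15.8),
        (11.6, 10.1, 20.7)))),
    "lafac": dict(zip(_MR_LBBB_PHASES, _tbl(
        (47, 44, 50), (55, 53, 59), (41, 39, 44), (33, 25, 42)))),
    "las_r": dict(zip(_MR_LBBB_PHASES, _tbl(
        (40, 37, 42), (51, 48, 56), (32, 30, 35), (29, 18, 29)))),
    "las_ct": dict(zip(_MR_LBBB_PHASES, _tbl(
        (-10, -12, -8), (-21, -25, -21), (-7, -10, -2), (-2, -5, -1)))),
    "lvedv": dict(zip(_MR_LBBB_PHASES, _tbl(
        (42, 34, 45), (53, 42, 57), (65, 39, 75), (82, 50, 106)))),
    "lvef": dict(zip(_MR_LBBB_PHASES, _tbl(
        (54, 50, 60), (61, 61, 69), (64, 59, 67), (55, 47, 57)))),
    "heart_rate": dict(zip(_MR_LBBB_PHASES, _tbl(
        _hr(82, 26), _hr(101, 37), _hr(86, 25), _hr(73, 24)))),
}

_LBBB_PHASES = ("baseline", "16w")
_LBBB = {
    "la_es_area": dict(zip(_LBBB_PHASES, _tbl((7.9, 5.4, 9.2), (8.5, 7.0, 8.6)))),
    "lafac": dict(zip(_LBBB_PHASES, _tbl((46, 45, 48), (43, 42, 46)))),
    "las_r": dict(zip(_LBBB_PHASES, _tbl((42, 37, 43), (39, 36, 40)))),
    "las_ct": dict(zip(_LBBB_PHASES, _tbl((-8, -12, -7), (-7, -8, -4)))),
    "lvedv": dict(zip(_LBBB_PHASES, _tbl((44, 39, 45), (47, 30, 51)))),
    "lvef": dict(zip(_LBBB_PHASES, _tbl((50, 48, 52), (34, 24, 49)))),
    "heart_rate": dict(zip(_LBBB_PHASES, _tbl(_hr(75, 40), _hr(79, 38)))),
}


def default_cohort_spec(seed: int = 0, rho: float = 0.6,
                        severity_linked_dropout: bool = False) -> CohortSpec:
    """The study's design: MR-LBBB n=12 (4 deaths before 20 weeks), LBBB n=7."""
    groups = {
        "MR-LBBB": GroupSpec(n=12, phases=_MR_LBBB_PHASES,
                             measurements=_MR_LBBB,
                             deaths_before_phase="20w", n_deaths=4),
        "LBBB": GroupSpec(n=7, phases=_LBBB_PHASES, measurements=_LBBB),
    }
    return CohortSpec(groups=groups, rho=rho, seed=seed,
                      severity_linked_dropout=severity_linked_dropout)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a tidy per-animal, per-phase, per-parameter measurement table.

    Columns: animal_id, group, phase, parameter, value, units. Surviving
    animals have every parameter at every phase; animals that die are
    absent from phases at and after ``deaths_before_phase`` only.
    Deterministic for a fixed spec (the seed lives in the spec).
    """
    spec = spec or default_cohort_spec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho = spec.rho
    rows = []
    for gname in sorted(spec.groups):
        g = spec.groups[gname]
        params = sorted(g.measurements)
        n_ph = len(g.phases)
        # latent per-animal and per-observation noise, one draw per parameter
        values: dict[str, np.ndarray] = {}
        for param in params:
            z_animal = rng.standard_normal(g.n)
            z_obs = rng.standard_normal((g.n, n_ph))
            latent = rho * z_animal[:, None] + np.sqrt(1.0 - rho * rho) * z_obs
            med = np.array([g.measurements[param][ph][0] for ph in g.phases])
            iqr = np.array([g.measurements[param][ph][2]
                            - g.measurements[param][ph][1] for ph in g.phases])
            vals = med[None, :] + iqr[None, :] * IQR_TO_SIGMA * latent
            if param == "las_ct":
                vals = np.minimum(vals, 0.0)  # echo convention: <= 0
            values[param] = vals
        # attrition: choose survivors
        dead: set[int] = set()
        if g.n_deaths:
            if spec.severity_linked_dropout and "las_r" in values:
                death_phase_i = g.phases.index(g.deaths_before_phase)
                prior = values["las_r"][:, death_phase_i - 1]
                dead = set(np.argsort(prior, kind="stable")[:g.n_deaths])
            else:
                dead = set(rng.choice(g.n, size=g.n_deaths, replace=False))
        for i in range(g.n):
            for j, phase in enumerate(g.phases):
                if i in dead and g.deaths_before_phase is not None \
                        and j >= g.phases.index(g.deaths_before_phase):
                    continue
                for param in params:
                    rows.append({
                        "animal_id": f"{gname}-{i + 1:02d}",
                        "group": gname,
                        "phase": phase,
                        "parameter": param,
                        "value": float(values[param][i, j]),
                        "units": PARAM_UNITS[param],
                    })
    return pd.DataFrame(rows,
                        columns=["animal_id", "group", "phase", "parameter",
                                 "value", "units"])
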