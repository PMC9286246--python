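"""Substrate presets for the six simulated disease phases.

``baseline`` is the healthy reference; ``acute_mr`` adds a severe mitral
leak (EROA 0.40 cm2) with the compromised hemodynamic targets (3.6 L/min,
75 mmHg); ``week4`` and ``week20`` add the best-match LA remodeling
substrates (hypertrophy/stiffness 180/220% and 250/530%); the two LBBB
presets add 30/60 ms free-wall activation delay with 113/125% LV eccentric
hypertrophy on top of the 20-week substrate.
"""

from __future__ import annotations

from .substrates import SubstrateSpec

BASELINE_TARGETS = dict(flow_target=5.1, map_target=92.0)
MR_TARGETS = dict(flow_target=3.6, map_target=75.0)

PRESETS: dict[str, SubstrateSpec] = {
    "baseline": SubstrateSpec(eroa=0.0, **BASELINE_TARGETS),
    "acute_mr": SubstrateSpec(eroa=0.40, **MR_TARGETS),
    "week4": SubstrateSpec(eroa=0.40, la_hypertrophy=180.0,
                           la_stiffness=220.0, **MR_TARGETS),
    "week20": SubstrateSpec(eroa=0.40, la_hypertrophy=250.0,
                            la_stiffness=530.0, **MR_TARGETS),
    "week20_lbbb30": SubstrateSpec(eroa=0.40, la_hypertrophy=250.0,
                                   la_stiffness=530.0, lbbb_delay=30.0,
                                   lv_hypertrophy=113.0, **MR_TARGETS),
    "week20_lbbb60": SubstrateSpec(eroa=0.40, la_hypertrophy=250.0,
                                   la_stiffness=530.0, lbbb_delay=60.0,
                                   lv_hypertrophy=125.0, **MR_TARGETS),
}

TABLE_PHASES = ("baseline", "acute_mr", "week4", "week20",
                "week20_lbbb30", "week20_lbbb60")
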