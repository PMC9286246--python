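# Methods

`mrla` couples a closed-loop lumped-parameter (0-D) model of the four-chamber
heart and circulation to an inference layer that reads left-atrial (LA)
remodeling out of echocardiography-style indices. This note documents the
model, its numerical choices, the calibration procedure, the synthetic-cohort
generator and the known limitations.

## The wall model

Each chamber is a thick-walled sphere obeying a one-fiber model. With cavity
volume `V` and wall (tissue) volume `V_w`, the midwall radius is
`r = (3(V + V_w/2)/4π)^(1/3)`, the midwall area `A_m = 4πr²`, and the fiber
stretch `λ = sqrt(A_m/A_ref)` with `A_ref` the zero-stress reference area.
The transmural pressure follows Laplace's law for a thick shell approximated
at the midwall, `p = 2 σ h / r`, with `h = V_w/A_m` and `σ` the total fiber
stress.

Total stress is active plus passive:

* **Active**: `σ_a = S_act · g(λ) · s(t − t_on)`. The envelope `s` is a
  rise–plateau–fall twitch: sine-squared flanks of width
  `rise_fraction × twitch_duration` on both sides of a full-activation
  plateau; `rise_fraction = 0.5` recovers a pure raised cosine (used for the
  atria), while the ventricles use 0.3 so that systolic pressure is
  sustained, as in recorded ventricular pressure traces. The length
  dependence `g(λ) = clip(1 + f·(λ−1), 0, g_max)` is a linearized
  Frank–Starling ascending limb with a saturation plateau; the ventricular
  slope (`f = 10.5`) makes ejection self-limit at an end-systolic volume
  floor, the atrial slope (`f = 5`) produces the stretch-induced
  augmentation of atrial contraction under acute volume loading.
* **Passive, extension (λ ≥ 1)**: `σ_p = S_pas(e^{k(λ−1)} − 1)` plus a much
  steeper collagen branch `S_col(e^{k_col(λ−λ_col)} − 1)` recruited beyond a
  slack stretch `λ_col`. The atria use a shallow ground-matrix exponent
  (`k = 3.5`) — a compliant reservoir must span ≈40 % stretch between its
  end-diastolic and v-wave pressures — capped by collagen
  (`k_col = 25`, `λ_col = 1.28`) that limits acute overdistension and
  generates the large v-wave of severe regurgitation. The ventricles use
  `k = 10` (steep end-diastolic pressure–volume relation) and no separate
  collagen term.
* **Passive, compression (λ < 1)**: a linear branch
  `σ_p = S_pas · k · c · (λ−1)` resisting wall buckling; the atrial
  compression factor `c = 2.5` (ventricles 1) keeps strongly contracting
  atria from collapsing and limits the booster-pump excursion of a stiffened
  atrium.

The LV carries two patches — free wall (2/3 of reference area) and septum
(1/3) — mechanically in series on one spherical cavity. At every evaluation
the midwall area is split so that the two patches' wall tensions `σ·h` are
equal; the split is solved by bisection (the tension imbalance is monotone in
the split, so the root is unique). Delayed free-wall activation therefore
stretches the late wall at the expense of the early one, reproducing the
discoordination cost of bundle-branch block at the fidelity a two-patch
sphere allows (no septal bulging — see Limitations).

## Valves and vessels

Valves are Bernoulli orifices with blood-column inertance
(`L = ρℓ/A_eff`), a series viscous resistance, and pressure-driven opening
dynamics `dζ/dt = ±K·|Δp|` (rate-capped, giving 1–3 ms transitions);
`A_eff = A_leak + (A_open − A_leak)·ζ`. A closed mitral valve retains the
effective regurgitant orifice area (EROA) as `A_leak`; valves without a leak
orifice are clamped to non-negative flow, so the zero-leak backward volume is
exactly zero. The aortic series resistance (0.22 mmHg·s/mL) acts as the
lumped proximal-aortic characteristic impedance: it meters ejection over
systole in place of the arterial wave dynamics a 0-D model cannot carry.
Without it the ventricle dumps its stroke in ≈100 ms, end-systole arrives
early, and the sustained systolic LV–LA gradient that drives regurgitation
is lost.

Systemic and pulmonary beds are linear compliance compartments joined by
resistances (`sys_art → sys_ven → RA`, `pulm_art → pulm_ven → LA`). The
venous connections are bidirectional, so a severe v-wave produces systolic
pulmonary-venous flow reversal, which is how the left atrium sheds most of
the regurgitant volume.

## Integration and steady state

Fixed-step classical RK4 with `dt = cycle/round(cycle/1 ms)` (857 steps per
cycle at 70 bpm). The cycle starts at atrial activation onset; ventricular
onset follows after the activation-onset interval (150 ms). State: 8
volumes, 4 valve flows, 4 valve opening states. Volume conservation is exact
by construction (every flow appears with both signs); periodicity is
declared when the beat-to-beat relative change of every state falls below
10⁻³ (floored per state class). Negative cavity volumes abort integration
naming chamber and time. Doubling the beat budget or tightening the
tolerance changes no reported index by more than 0.1 %.

## Calibration

Two deterministic fixed-point loops:

1. **Homeostasis** (reused for every disease configuration): the systemic
   peripheral resistance is set to `(MAP_target − p_ven)/CO_target` and the
   circulating volume is updated by a damped secant iteration on
   MAP(volume), until mean systemic flow and mean arterial pressure are
   within 0.3 % of their targets (baseline 5.1 L/min, 92 mmHg; the
   compromised MR state 3.6 L/min, 75 mmHg).
2. **Structure** (healthy reference only): LV size (reference area and wall
   volume at fixed shape) is scaled to the target end-diastolic volume
   (130 mL), LV contractility to the target ejection fraction (55 %), and LA
   size to the target reservoir strain (41 %), iterating with damped
   multiplicative updates to 1.5 %. The LA fractional area change co-emerges
   (≈60 % against a 61 % target) and is verified rather than
   servo-controlled — it has no independent strong-leverage knob once the
   strain targets are met.

## Echo indices

The zero-strain reference is mitral valve closure (LV end-diastole), located
from the mitral forward-flow crossings; LA strain is
`100·(L/L_ref − 1)` with `L = sqrt(midwall area)`. Reservoir strain LAS(r)
is the value at mitral opening; contractile strain LAS(ct) is the pre-A
value at atrial activation onset, reported as a magnitude and as its
negative in the clinical sign convention. The taken reading of LAS(ct) —
pre-A strain rather than the literal difference LAS(r) minus pre-A —
reproduces the clinical example pair (42 %, −12 %) and keeps simulated
magnitudes on the scale of the published table. LA areas use the
endocardial (cavity) disc cross-section `πr_cav²`, mirroring the clinical
practice of tracing the endocardium, while strain follows the wall; only
area ratios and the fractional area change are ever compared across
simulations, so the choice of cross-section metric cancels. LV volumes are
cavity extremes; the regurgitant fraction is backward mitral volume over
backward mitral plus forward aortic volume.

## Substrates and inference

Disease substrates are pure transformations of the calibrated reference:
EROA on the closed mitral valve; LA eccentric hypertrophy scaling wall mass
and reference area together (thickness at reference geometry preserved); LA
stiffening scaling the whole passive relation (ground matrix and collagen —
the fibrosis surrogate); free-wall activation delay; LV eccentric
hypertrophy. Each configuration is re-homeostated to its flow/pressure
targets.

The best-match inference sweeps the (hypertrophy × stiffness) grid — the
full study grid is 21 × 51 cells in 10-point steps; any sub-grid is
accepted — and minimizes the equally weighted sum of squared relative
errors of LAS(r), LAS(ct) magnitude and the LA end-systolic area ratio
(weights configurable; ties break toward the least-remodeled point).
Recovery from a grid point's own indices is exact; under ±5 % target noise
the recovered point stays within one grid step in ≥90 % of trials on the
coarse verification grid (5 × 6, 50/100-point steps).

## Synthetic cohort

The generator emulates the two-group longitudinal design: an MR-LBBB group
(n = 12; baseline, acute, 4- and 20-week phases; 4 deaths before the final
phase, leaving n = 8) and an LBBB-only control group (n = 7; baseline and 16
weeks). Per (group, phase, parameter) cells are parameterized by median and
interquartile range; the defaults encode the in-vivo summary table. Values
follow a Gaussian latent-trajectory model,
`value = median + σ·(ρ·z_animal + sqrt(1−ρ²)·z_obs)` with `σ = IQR/1.349`
and within-animal correlation ρ = 0.6 (a free, documented parameter — the
true repeat-measure correlation is not identifiable from published
summaries). Contractile strain is clipped non-positive. Attrition drops a
seeded random subset by default; an optional severity-linked mode drops the
four worst 4-week reservoir strains. The generator reproduces medians and
group sizes, not echo physics: passing cohort tests says the statistical
layer behaves correctly on data shaped like the study's, not that the
generator models real atria.

## Statistics

Summaries are median [Q1–Q3] per group/phase/parameter; phase effects use
the paired Wilcoxon signed-rank test against each group's baseline on
animals present in both phases (n < 3 pairs are flagged untested). The
signed-rank p-value is exact and tie-aware up to n = 25 (dynamic program
over the doubled-midrank distribution; two-sided as twice the smaller tail,
capped at 1), with the continuity-corrected normal approximation beyond.
Group comparisons use Student's t (equal variances; zero-variance input is
rejected) or the Mann-Whitney U test, exact for min(n) ≤ 8 on tie-free
data. No multiple-testing correction is applied, and the summary metadata
says so. The comparative threshold-cycle fold change is
`2^(Ct_reference − Ct_target)`.

## Problem sizes used

Default runs integrate 857 steps per cycle and reach steady state in 5–40
beats (warm-started continuations in ≤10). The verification grid for
inference properties is 5 × 6 cells; the full 21 × 51 study grid runs in
roughly a quarter hour on one core via the command line.

## Limitations

* **20-week contractile strain.** With the published 20-week substrate
  (hypertrophy 250 %, stiffness 530 %) the simulated pre-A strain floors
  near 8 %, above the published ≈3 %. In this wall-model class the conduit
  phase drains the dilated stiff atrium to its slack point and the booster
  pump still compresses it several percent below slack; making the fibrotic
  atrium near-akinetic while preserving the healthy atrium's deep booster
  excursion appears to require sarcomere-level activation physiology
  (length-dependent activation duration), which the one-fiber twitch does
  not carry.
* **Acute LBBB and atrial strain.** Adding activation delay to the acute-MR
  state leaves LAS(r) essentially flat here (the acutely loaded atrium sits
  at its collagen knee and cannot stretch further), whereas the delay does
  raise LAS(r) and lower LAS(ct) when added to the 20-week substrate, which
  is the remodeled-state behaviour the acceptance checks exercise.
* **Dyssynchrony fidelity.** Two patches on a sphere carry no septal-bulge
  interaction; the ejection-fraction penalty of a 60 ms free-wall delay is
  ≈10 points here versus ≈14 in the source simulations.
* No pericardium, no baroreflex within a beat, no atrial fibrillation
  electrophysiology, no growth dynamics (remodeling is imposed, not
  evolved).
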