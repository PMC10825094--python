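# Methods

## Scope and model structure

`ventbench` is a deterministic, closed-form replica of a bench experiment:
a test lung ventilated in volume-controlled mode, an inhaled-sedation
device inserted as extra series dead space, and a stepwise
minute-ventilation titration that restores end-tidal CO2. Every quantity
the package reports is derived from five small sub-models — breath
mechanics, steady-state gas exchange, device calibration, the titration
controller, and the lung-stress indices — composed by the experiment
orchestrator.

## Breath mechanics

The lung is a passive linear single compartment: compliance *C*
(mL/cmH2O), separate inspiratory/expiratory resistances *R* (cmH2O/L/s),
ventilated with a square inspiratory flow *V̇*, an end-inspiratory pause,
and passive exhalation against the set PEEP with time constant
τ = *R*<sub>exp</sub>·*C*. The periodic steady state has closed forms:

* trapped end-expiratory volume
  V<sub>trap</sub> = V<sub>T</sub>·e^(−Te/τ) / (1 − e^(−Te/τ)),
  auto-PEEP = V<sub>trap</sub>/C;
* PEEP<sub>tot</sub> = PEEP<sub>set</sub> + auto-PEEP;
* P<sub>plat</sub> = PEEP<sub>tot</sub> + V<sub>T</sub>/C;
* P<sub>peak</sub> = P<sub>plat</sub> + R<sub>insp</sub>·V̇ (V̇ in L/s).

The test suite ties the auto-PEEP closed form to an independent
breath-by-breath fixed-point iteration (steady state declared when
successive end-expiratory volumes differ by < 1e−9 L, or after 200
breaths); agreement is required to 1e−6 cmH2O over randomized parameters.
The waveform (200 Hz by default, configurable) samples the same analytic
solution; it exists for export and inspection, not as a separate solver.
Flow is set in L/min and converted once, in `mechanics.lpm_to_lps`.

Device resistances default to zero: pressures are "measured" downstream of
the device, so the reported indices deliberately exclude the device's
resistive pressure; per-device resistances are hooks, not defaults.

Out of scope by design: nonlinear compliance, inertance, multi-compartment
heterogeneity, spontaneous effort, circuit compressible volume.

## Gas exchange

CO2 enters the alveolar compartment at a constant rate (the bench's CO2
bottle) and leaves by alveolar ventilation
V̇<sub>A</sub> = RR·(V<sub>T</sub> − V<sub>D</sub>) through a series (Bohr)
dead space. The steady state is then an inverse law,
EtCO2 = EtCO2₀ · V̇<sub>A,0</sub>/V̇<sub>A</sub>, anchored at 40 mmHg at
the baseline settings (V<sub>T</sub> 400 mL, RR 20/min, circuit dead space
120 mL ⇒ V̇<sub>A,0</sub> = 5600 mL/min). This is the simplest model
consistent with the bench design; no dissociation-curve chemistry, body CO2
stores, or arterial-to-end-tidal gradients are modelled.

A per-breath washout model supplies dynamics for step changes: each breath
relaxes EtCO2 toward the closed-form target with gain
k = V̇<sub>A,b</sub>/(FRC + V̇<sub>A,b</sub>), where
V̇<sub>A,b</sub> = V̇<sub>A</sub>/RR and FRC defaults to 2500 mL (an adult
functional residual capacity; used only for dwell-time realism). At the
protocol's 2.5-min dwell the step is ≥ 95 % complete, so steady-state and
dynamic titrations reach the same endpoints; the default evaluates closed
forms directly.

## Device calibration

Each device is summarised by one *effective* added dead space, obtained by
inverting the steady-state model at the observed mean EtCO2 ratio:
V<sub>D,total</sub> = V<sub>T</sub> − (V<sub>T</sub> − V<sub>D,circuit</sub>)/ratio.
With the shipped catalog (mean increases +49 %, +78 %, +100 % at the
reference settings) this gives added dead spaces of 92.1, 122.7 and
140.0 mL for ANA-50, MIRUS and ANA-100 — each above the device's geometric
volume (50/100/100 mL), the excess (42.1/22.7/40.0 mL) being the CO2
reflection of the conserving filter. Only printed means anchor the
defaults; the catalog carries the SDs for sensitivity sweeps.

The effective dead space is constant per breath by default. That
assumption is *known* to be imperfect: a brute-force bound
(`feasible_dead_space_interval`, scanning candidates at 0.1 mL resolution
and keeping those for which the titration controller reproduces observed
endpoints) returns a non-empty interval for ANA-50 (≈ 195–216 mL total)
but an *empty* interval for ANA-100 and MIRUS when both titration-arm
endpoints are imposed jointly — evidence that their CO2 reflection varies
with inspiratory pressure/flow. The functional form of that dependence is
unknown, so it is not modelled; the empty interval is the documented
negative control, not an error. Endpoints that are unreachable in whole
15 % steps (one published cell, final V<sub>T</sub> 560 mL from a 400 mL
base) are dropped from the bound with a warning rather than snapped to the
grid.

## Titration controller

Correction raises either V<sub>T</sub> or RR in arithmetic steps of 15 % of
the *baseline* value (60 mL, 3 breaths/min). Because the grid is fixed, the
modelled EtCO2 can jump from above 42 mmHg straight below 38 mmHg; the
controller therefore stops at the first grid value with
EtCO2 ≤ target + band (the only monotone reading of "until 40 ± 2 mmHg is
resumed" that always terminates) and reports band membership separately
(`within_band`). The step budget defaults to 20 (V<sub>T</sub> would reach
1600 mL, RR 80/min — far beyond the clinical range; exhausting it raises an
error carrying the trajectory). Mechanics are re-simulated at the final
settings. A grid-scan oracle in the tests checks the controller is exactly
first-crossing for every device and mode.

## Indices

MP = 0.098 · RR · V<sub>T</sub>[L] · (P<sub>peak</sub> − ΔP/2) (J/min),
ΔP = P<sub>plat</sub> − PEEP<sub>tot</sub>, Costa index = 4·ΔP + RR. A
tidal volume passed in litres above 10 is rejected as a probable
millilitre value (unit-confusion guard). The sevoflurane density
correction V<sub>T</sub>/0.993 (air-calibrated flow sensors at 1.3 %
expired sevoflurane) is opt-in and applied to device arms only; the
orchestrator emits indices both with and without it. All internal
computation is on unrounded values; printed companions round half-up to
integers, matching the published table's precision.

## Synthetic bench records

`bench_synth` is the stand-in for the rig: it runs the deterministic
simulator, optionally adds independent zero-mean Gaussian noise to
pressures and EtCO2, then applies instrument rounding (pressures to whole
cmH2O, EtCO2 to 0.1 mmHg, volumes to 1 mL). The published bench is
deterministic within condition (zero reported SDs), so the noise models
no physical process — it exists to exercise pipeline robustness, and its
magnitude can be chosen to match the published between-condition spread
(e.g. 2.8 mmHg on EtCO2 reproduces a 7 % SD of the percent increase at the
ANA-50 operating point). Records regenerate bit-for-bit from the same
seed; with zero noise they equal the ideal pipeline after rounding. What
passing these tests does **not** show: behaviour under correlated drift,
sensor nonlinearity, or humidity effects — none of which the generator
emulates.

## Experiment grid and reference comparison

The dry-rig (ATPD) defaults are C ∈ {20, 40, 60} mL/cmH2O,
PEEP ∈ {5, 15} cmH2O, R = 5 cmH2O/L/s, circuit dead space 120 mL; the
humidified-rig (BTPS) defaults are a single C = 25, R = 15, dead space
150 mL. Each condition runs a control arm (which anchors EtCO2 at
40 mmHg) and the three device arms in three states (baseline with device,
V<sub>T</sub>-corrected, RR-corrected): 72 rows for the full ATPD grid.
Errors are recorded per row, never fatal to the grid; two runs of the same
config produce byte-identical CSV.

The packaged reference (`ventbench/data/bench_reference.csv`) is a
long-format transcription of the published ventilatory table plus the
BTPS Costa values printed in the results text. Comparison tolerances are
1 cmH2O for pressures, 2 a.u. for the Costa index, exact for final
settings. Eight printed Costa cells are internally inconsistent with their
own printed driving pressure and rate beyond integer rounding (by up to
7 a.u.); they are flagged `excluded` in the fixture and skipped by
tolerance checks, with the inconsistency recorded in the `note` column.

Expected, reported deviations of the ideal model:

* at C = 20 the printed baseline ΔP is 17 cmH2O where the ideal
  compartment gives V<sub>T</sub>/C = 20 — the deviation report flags it
  rather than fitting a correction whose physical cause (circuit gas
  compression? test-lung nonlinearity?) the data cannot identify;
* the constant-dead-space model reproduces four of the six published
  titration endpoints exactly (ANA-100 V<sub>T</sub> 580, ANA-50
  V<sub>T</sub> 520, MIRUS RR 35, ANA-50 RR 29); the other two require a
  pressure-dependent reflection term (see calibration above);
* BTPS cells are deviation-reported only: the devices keep their dry-rig
  calibration because no per-device humid-rig EtCO2 increases are
  published, and with the larger 150 mL circuit dead space the model then
  *over*-predicts the device effect under BTPS, whereas the bench observed
  smaller increases under humidity. The BTPS arm is a structural
  replication, not a calibrated one.

## Statistical non-goals

Inferential statistics (ANOVA and post-hoc tests), sevoflurane
pharmacology and delivery control, humid-gas physics beyond the stated
R/C/dead-space parameters, and figure replication are out of scope; the
comparison surface is descriptive deviations only.
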