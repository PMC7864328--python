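# Methods

## The measurement model

A knee state is a six-channel vector: medial/lateral compartment loads at
10° and 90° of flexion (`m10, l10, m90, l90`, lbf, from an instrumented
tibial trial) and two navigation angles — coronal alignment (`coronal`,
degrees, negative = varus) and the sagittal extension deficit
(`ext_deficit`, degrees, positive = flexion contracture, negative =
hyperextension). Loads are non-negative; |coronal| ≤ 30° and
|ext_deficit| ≤ 40° are treated as hard sanity bounds.

### Classification thresholds

| parameter | default | meaning |
|---|---|---|
| `diff_max` | 15 lbf | mediolateral differential must stay strictly below this at both angles |
| `load_min` / `load_max` | 10 / 40 lbf | per-compartment acceptance window (boundaries acceptable) |
| `coronal_window` | 3° | valgus acceptance bound |
| `varus_allow` | 3° | varus acceptance bound (kept separate: valgus is avoided outright, mild varus is tolerated) |
| `small_deficit_max` | 5° | split between small contractures (soft-tissue range) and large ones (bone-recut range); the underlying clinical convention, exposed in config |
| `hyper_min` | 2° | tolerated hyperextension below which the insert is upsized |

Two fixed tolerances: alignment within 0.5° of zero is *neutral*, and a
contracture up to 0.5° still counts as full extension. Ties at printed
thresholds use strict inequalities (differential < 15 balanced, load > 40
tight, load < 10 loose), so boundary values are acceptable.

## The decision engine

`recommend` evaluates ordered rule blocks, first match wins:

1. **R1 sagittal block** — terminal extension is assured first. Large
   contracture: arcuate release if the lateral compartment is tight in
   extension and the limb is valgus (one release addresses both), femoral
   recut if flexion loads are acceptable, tibial recut if loads exceed the
   ceiling in both flexion and extension. Small contracture: posterior
   capsule release. Hyperextension: thicker insert.
2. **R2 loose block** — any load below the floor → thicker insert.
3. **R3 lateral-tight block** — extension only: arcuate (ITB once the
   arcuate has already been released this case); flexion only: popliteus;
   both: arcuate first, popliteus on a later pass.
4. **R4 medial-tight block** — extension only: MCL pie-crust when varus is
   outside the window, otherwise femoral recut; flexion only: pie-crust;
   both: pie-crust when varus, varus tibial recut when neutral/valgus
   (pie-crusting would push the limb into valgus).
5. **R4e/R4f** — balanced loads but alignment outside the window: pie-crust
   for residual varus, arcuate release for residual valgus.
6. **R5** — accept.

"Tight" combines the absolute criterion (load > 40 lbf) with the relative
one (differential ≥ 15 lbf; the higher side is tight); with both
compartments over the ceiling the higher load wins and an exact tie is
called medial, the medial column being the primary balance target. This
makes the rule set exhaustive: acceptance happens exactly when the knee is
balanced, inside the coronal window and at full extension.

Design choices made where the algorithm statement is open:

* The R4e/R4f alignment-only rules cover balanced knees with out-of-window
  alignment, which the tightness blocks cannot reach; their actions are the
  two releases documented to move coronal alignment in the needed
  direction.
* A large contracture with tight flexion loads but acceptable extension
  loads matches no sagittal rule and falls through to the tightness blocks;
  relieving flexion tightness there is the precondition for a later femoral
  recut. This is the only exception to strict sagittal priority.
* R4a fires the pie-crust only for varus beyond the window (pie-crusting
  adds valgus, so it simultaneously corrects that varus); the direction is
  ambiguous in the source algorithm and is noted as such.
* The engine is single-step: one correction per call, with the simulator
  iterating. The set of corrections already performed is passed as optional
  context and only gates the arcuate→ITB / arcuate→popliteus choices.

`rule_trace` evaluates every rule's predicate on the same state and marks
the single winner, giving an auditable account of each recommendation;
`truth_table` applies the engine over a state grid (used by the
oracle-equivalence tests).

## The correction-effect model

Applying an event (one or several batched corrections) to a state gives

    post = pre + Σ mean_delta(c) + u_i + ε,

with loads clamped at 0 lbf (a sensor cannot read negative load). `u_i` is
a per-patient six-channel offset, constant within a case — the
random-intercept analogue of patient-to-patient variability — drawn
N(0, `sigma_patient`²); `ε` is independent Gaussian residual noise per
channel, N(0, `sigma_resid`²). No cross-channel correlation is modelled.

The *sign ledger* fixes the direction of every statistically established
effect (per channel: m10, l10, m90, l90, coronal, ext):

| correction | significant effects |
|---|---|
| MCL pie-crust | m10−, l10+, m90−, l90+, coronal+ (valgus), ext− |
| arcuate release | l10−, coronal− (varus), ext− |
| popliteus release | l10−, l90−, coronal− |
| ITB release | l10− |
| posterior capsule release | m10−, ext− |
| tibial recut | m10−, m90−, l90−, coronal−, ext− |
| femoral recut | ext− only |
| insert +2 mm | m10+, l10+, ext **+2.5°** |

The +2.5° insert effect on the extension deficit is the one anchored
magnitude; all other magnitudes are model defaults living in
`data/default_calibration.json`, never in code, and a strict loading mode
rejects any calibration whose significant components contradict the
ledger.

Three non-significant components are deliberately non-zero, at small,
physically motivated values: the insert raises the 90° loads by 3 lbf (a
thicker insert tightens both gaps), and the pooled femoral-recut category
lowers extension loads by 5/2 lbf medially/laterally (it contains varus
recuts that open the medial extension compartment). With these at zero the
closed loop cannot terminate — nothing would ever raise a flexion load,
and the femoral recut in the medial-tight branch would never relieve the
tightness it is chosen for. Magnitudes overall were tuned against the
cohort-level statistic of ~3 corrections per case (below) under the
constraint that every noiseless case must reach acceptance within the
correction cap.

## The synthetic cohort

`generate_patients` draws ages from a normal distribution truncated to
[39, 96] with mean 68.6 y and SD 9 y (the SD is unreported; 9 y keeps the
truncated mean at the target within the printed range), sex
Bernoulli(0.49 male), and the patient offsets from `sigma_patient`.

Initial post-initial-cut states come from a six-phenotype mixture (weights
and per-channel uniform ranges in `data/default_config.yaml`):

* `balanced` (4%) — accepted at the outset; zero-correction cases exist.
* `medial_tight_varus` (32%) — medial loads over the ceiling at both
  angles, varus 3.5–6°; resolved by one or two pie-crusts.
* `medial_tight_neutral` (6%) — medial tightness with neutral/valgus
  alignment; exercises the varus-tibial-recut branch.
* `lateral_tight_valgus` (18%) — lateral loads over the ceiling, valgus
  1.5–5°; resolved by arcuate/popliteus/ITB chains.
* `flexion_contracture` (22%) — extension deficit 6–12°, loads in window;
  femoral recuts then a capsule release.
* `hyperextension_loose` (18%) — hyperextension 2.5–8° with low extension
  loads; insert upsizing.

The closed loop per case: recommend → if accept stop → apply the
correction through the effect model → record the pre/post event → repeat,
capped at 7 corrections (the observed per-case maximum). With
`batch_prob` > 0 a second, distinct correction (the engine's next call on
the noiseless preview state) is folded into the same event, producing the
multi-correction rows the mixed model treats as multi-hot; the default is
single-correction events. Exactly `n_missing` = 21 randomly chosen
patients are flagged missing (missing completely at random, mirroring
"insufficient documentation") and excluded from analysis but kept in the
table.

The mixture and calibration defaults were tuned jointly so that (i) the
10-seed mean of corrections per analyzable patient is ≈ 3.0, (ii) MCL
pie-crusting and insert upsizing are the two most frequent corrections,
and (iii) with `sigma_patient = sigma_resid = 0` every case terminates in
acceptance within the cap (verified over 15,000 cases). The termination
property is stated for fully deterministic dynamics: patient offsets enter
every event's delta and therefore accumulate over a case, so termination
cannot be guaranteed for unbounded offsets.

What the generator does *not* emulate: measurement error distinct from
biological variability, effect heterogeneity by deformity severity,
correlated channels, surgeon learning, or dose within a correction.
Passing tests therefore show that the statistical machinery recovers the
effects that generated the data under the stated noise model — not that
the calibrated magnitudes match any particular clinical population.

## The mixed-model stage

For one outcome channel, each analyzable event contributes
`delta = post − pre` and 0/1 indicators of the corrections applied.
The model is a random-intercept LMM with cell-means coding (no global
intercept): each β_c is the mean effect of correction c itself, matching
how per-correction changes are reported, rather than a contrast against a
reference category. Estimation is REML (ML selectable) via statsmodels
MixedLM with its default optimizer; an earlier L-BFGS override was removed
after it returned spuriously "converged" degenerate fits. Significance
uses two-sided Wald z tests at α = 0.05 — appropriate at ~460 patient
clusters — with no multiple-testing correction across the 48
correction × channel cells. Corrections absent from a cohort are reported
not-estimable rather than fitted; a rank-deficient design raises an error
naming the collinear columns; with the random intercept disabled the fit
reduces exactly to OLS cell means (the σ_u² = 0 limit, used as a test
oracle). Missing-flagged patients are dropped, and rows with non-finite
outcomes are deleted per channel.

`summarize_cohort` reports the raw ratio of corrections to analyzable
patients without rounding games (1391 corrections over 458 patients gives
3.037, printed elsewhere as ~3.03).

## Problem sizes and numerical notes

Test and acceptance runs use the full 479-case cohort size throughout;
replicate counts are 10 seeds for the corrections-per-case mean, 100
simulate-and-refit replicates for the insert-effect coverage check, and
200 for parameter recovery (bias within 3 Monte-Carlo SEs, 95%-interval
coverage within [0.92, 0.98]). The decision-engine oracle equivalence runs
on a 4⁴ × 5 × 4 = 5120-state factorial grid against an independently coded
nested-conditional oracle. Degenerate inputs are errors, not warnings:
empty model frames, single-patient frames under a random intercept, weight
vectors not summing to one, and missing counts not below the cohort size
all raise typed exceptions.

## Known limitations

The calibration magnitudes beyond the insert's +2.5° are plausible
defaults, not estimates from clinical data; the phenotype mixture is
invented to span the algorithm's decision branches with realistic
frequencies. Batched events assume additive effects. The engine collapses
femoral-recut subtypes (distal varus vs joint-line elevation) and MCL band
selection into single categories, mirroring how the corrections were
recorded. Femoral rotation, flexion-angle-continuous load curves and
clinical outcome measures are out of scope.
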