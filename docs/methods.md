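# Methods

## Model

The simulator treats the term uterine wall as `rows x columns` (≤ 64)
functional tissue regions evolving in discrete time steps of roughly
5 s. State per region: contractile activity `a_ij >= 0`, a phase
(QUIESCENT, BURSTING, REFRACTORY) and the age within that phase. One
organ-level scalar couples the regions: intrauterine pressure.

Per step, in order:

1. **Phase update.** Passive wall tension is `T_ij = p * anatomy_ij`
   where `p` is the pressure from the previous step (Law of Laplace: the
   anatomy factor stands for radius/wall-thickness). Transitions:
   - QUIESCENT → BURSTING when `T_ij > threshold_ij` (strict).
   - BURSTING → REFRACTORY when the burst age would exceed
     `burst_duration`, or when the amplified tension
     `T_ij * ap_multiplier` falls below `threshold_ij`.
   - REFRACTORY → QUIESCENT when the refractory age would exceed
     `refractory_duration`; the region then spends at least one full
     step quiescent before it can re-fire (so an isolated
     supra-threshold strip has period `burst + refractory + 1`).
2. **Activity.** `a_ij = clip(T_ij * f, 0, activity_cap)` with
   `f = ap_multiplier` (bursting), `refractory_multiplier` (refractory)
   or 1 (quiescent).
3. **Pressure (Pascal).** `p = max(min_pressure,
   mean_ij(a_ij / anatomy_ij))`.

There is no neighbor coupling; synchronization emerges only through the
shared pressure. The initial state is all-quiescent with
`a_ij = clip(initial_pressure * anatomy_ij, 0, cap)` and the pressure
recomputed from it; the recorded trace has `timesteps + 1` entries
(initial state plus one per step).

### Edge case: zero refractory duration

Entry into REFRACTORY happens with age 1, so `refractory_duration = 0`
still produces exactly one damped step. The invariant checked in the
tests is that every *completed* refractory run has length
`max(1, refractory_duration)`. All published input sets use ≥ 10.

## Heterogeneity fields

Anatomy factors and AP thresholds are sampled independently as
three-parameter Weibull variates `X = location + scale * W(shape)` using
`numpy.random.default_rng(seed)` (PCG64). Defaults: anatomy
(shape 1.8, scale 1, location 0.3), seed 1000; threshold
(shape 4, scale 0.6, location 0.4), seed 2000. The two fields use
separate seeded streams, so changing one seed never perturbs the other
field. Because the original implementation used a different generator,
seeded runs are reproducible *within this package* but not
bit-comparable to any external run; explicitly measured matrices can be
injected via `fields_from_matrices` or CSV files.

A region's *total sensitivity* is `anatomy_ij / threshold_ij` — the
larger it is, the lower the pressure needed to recruit the region. The
region with the highest total sensitivity is the nominal (static)
pacemaker candidate, but the run-time pacemaker is determined from the
simulation itself (below).

## Parameters and presets

Fourteen preset input sets cover the published experiments; set 1 is the
default 4×4 / 300-step parameterization (initial pressure 0.5, floor
0.5, burst 10, refractory 20, multipliers 3 / 0.2, cap 10). Descriptor
strings serialize a configuration as
`<x>.S<seed>:shape/scale/location;S<seed>:shape/scale/location` where
`<x>` is a preset number or the nine scalar inputs slash-separated.
Validation enforces positive durations, `ap_multiplier > 1`,
`0 < refractory_multiplier < 1`, ≤ 64 regions, and warns (without
rejecting) when `min_pressure` leaves the physiologically plausible
[0.35, 0.7] band — the floor stands for the baseline tone that keeps
~15 torr between contractions against ~300 torr peaks (ratio 1/20 on
the 0–10 activity scale).

## Metrics

- **Contraction detection.** After discarding a 20-step initial
  transient, events are maximal runs where pressure ≥ baseline + 50% of
  the post-transient range (baseline = post-transient minimum). The
  relative level makes detection invariant under rescaling; flat traces
  yield no events.
- **Pseudo-Montevideo units.** `pMV = mean event peak x event count per
  300-step window`. The canonical single-strip run gives 9 events,
  peaks 10, pMV 90.
- **Pacemaker attribution.** Per event: the first region whose burst
  onset (after the previous event) persists into the event's rising
  phase. Dominant pacemaker: the region with the most burst onsets over
  the run. In heterogeneous grids the per-event pacemaker commonly
  shifts between contractions.
- **Behavior classes.** 1 = uniform post-transient trace; 2 = ≥ 3
  contractions with inter-onset coefficient of variation < 5%;
  4 = ≥ 3 contractions with CV ≥ 5%; 3 = anything else (sustained
  irregular fluctuation without organized contractions). The optional
  physiological-relevance modifier (N/X/P) is caller-supplied
  annotation only.

## Geometry

Closed forms only: a 4.5 L cavity (4.5 kg conceptus at unit density)
gives a sphere radius of 10.2 cm and area ≈ 1318 cm²; the oblate-spheroid
wall area is taken as the quoted 1900 cm². Square regions tile that area
exactly (`edge² x n = area`): 5.45 cm edges at 64 regions, 14.53 cm at
9. At 3 cm/s AP propagation, recruitment of a 9-region tile takes
~4.84 s ≤ one time step. Rounding conventions for printed values
(nearest 0.1 cm, 0.5 cm, 100 cm²) live in the tests.

## Scenarios and synthetic data conditions

- **Drug sweeps** reuse one sampled field across multipliers (same
  "patient", different dose). "Coordinated" is operationalized as ≥ 3
  detected contractions with mean peak ≥ 5 (half the activity cap).
- **Region sweeps** resample fields per grid (matrix shapes change), so
  each row also reports mean total sensitivity to separate force trends
  from sampling drift.
- **Two-tissue runs** use the bench fixture anatomy (0.986, 0.989),
  thresholds (0.428, 0.670) on a 1×2 grid and report the fraction of
  steps with both regions bursting simultaneously (`in_phase` when
  > 10%).
- **Seed panels.** Stochastic claims are existence claims over fixed
  seed panels: a master seed expands into (anatomy, threshold) seed
  pairs drawn from the conventional 1000–1999 / 2000–2999 ranges. The
  test suite uses master seed 0, fixed before any outcomes were
  inspected.

## Operationalized stochastic checks

- **Complex (class-4) traces** and the **[7, 13] peak-pressure band**
  are asserted on a fixed 20-pair panel. Population note: over larger
  random panels ~2% of contraction-expressing runs peak slightly above
  13, so the band is a panel property, not a worst-case bound.
- **Calcium-blocker paradox** (coordinated at multiplier 3, lost at 2,
  re-emergent at 1.5): rare under this RNG stream (~0.3% of seed
  pairs), so the existence scan covers up to 2000 pairs with early exit.
- **pMV non-monotonicity over region count**: asserted as an aggregate
  rise from coarse (≤ 9 regions) to fine (≥ 18) grids of ≥ 5 pMV plus
  at least one panel member with an explicit rise–dip–recovery of ≥ 5
  pMV. The per-seed dip location varies, so the panel-mean profile alone
  can appear monotone.

## Known limitations

- **The two-tissue out-of-phase regime is not reachable.** With the
  bench fixture values above and the update rules exactly as specified
  (which are pinned by the single-strip hand oracle), a lone burst of
  the low-threshold strip raises organ pressure past the second strip's
  threshold within one step, so the strips always co-burst
  (overlap ≈ 0.36 at baseline timing, and under every variant reading
  of the rules we tried). The alternating regime reported for this
  fixture therefore cannot be reproduced from the published description;
  the corresponding acceptance test is expected to fail and documents
  this. The in-phase regimes (doubled initial pressure; shortened
  refractory period) are reproduced.
- Seeded field matrices are not bit-comparable to runs of the original
  (non-numpy) implementation; printed per-region values from bench
  measurements must be injected as explicit fixtures.
- No spatial propagation delays, neighbor coupling, tissue fatigue, or
  hormonal dynamics: single-scalar pressure coupling only.
- The model is qualitative; pressures are on a 0–10 activity-derived
  scale, not torr.
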