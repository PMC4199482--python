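# uterosim

A cellular-automaton model of human labor: regional myometrial
contractions synchronize into organ-level uterine contractions through
pressure–tension mechanotransduction.

## The model in one paragraph

The uterine wall is divided into a grid of up to 64 functional regions
(sized so that one action potential can recruit a whole region within a
few seconds at ~3 cm/s). Each region follows three rules per time step
(~5 s each):

1. **Pressure (Pascal's principle).** Intrauterine pressure is the mean
   of each region's contractile activity divided by its anatomy factor,
   floored at a minimum baseline pressure.
2. **Tension (Law of Laplace).** Pressure produces passive wall tension
   in every region in proportion to its anatomy factor (radius/thickness).
3. **Excitation.** A quiescent region whose passive tension exceeds its
   action-potential threshold starts *bursting*: its activity is the
   passive tension multiplied by an AP multiplier (capped at 10). Bursts
   last a fixed duration (or end early if amplified tension falls below
   threshold), then the region is *refractory* (activity damped by a
   refractory multiplier) for a fixed duration before becoming quiescent
   again.

There is no neighbor coupling and no pacemaker region: coordination
emerges solely through the shared pressure. Regional heterogeneity comes
from two three-parameter Weibull random fields (anatomy factors and
AP thresholds), seeded for reproducibility.

## Worked example

A single isolated "strip" (1×1 grid, anatomy 1, threshold 0.558) with
preset input set 9 contracts repetitively:

```python
>>> import uterosim as us
>>> cfg = us.default_config(9)              # 1x1, 300 steps, floor 0.6
>>> fields = us.fields_from_matrices([[1.0]], [[0.558]])
>>> result = us.run(cfg, fields)
>>> result.activity_tensor[:4, 0, 0]        # ignition: 1 -> 3 -> 9 -> cap
array([ 1.,  3.,  9., 10.])
>>> events = us.detect_contractions(result.pressure_trace)
>>> len(events), events[1].onset_step - events[0].onset_step
(9, 31)
>>> us.pseudo_montevideo(result.pressure_trace)
90.0
>>> us.classify_behavior(result.pressure_trace).class_id
2
```

Dropping the pressure floor from 0.6 to 0.55 (preset 10) puts the floor
tension below threshold: the strip produces exactly one initial
contraction and then stays silent — the model's bistability.

Full-size heterogeneous runs go through the same API:

```python
cfg = us.default_config(1, anatomy_seed=1474, threshold_seed=2500)
report = us.metrics_report(us.run(cfg))
```

## Command line

```bash
uterosim presets                       # the 14 published input sets
uterosim geometry --regions 64         # organ/region sizing table
uterosim simulate --preset 1 --out runs/demo
uterosim simulate --descriptor "1.S1474:1.8/1/0.3;S2500:4/0.6/0.4"
uterosim sweep --variable ap_multiplier --values 1.5,2,3 --preset 1
uterosim sweep --variable n_regions --values 2x2,4x4,8x8
```

`simulate --out DIR` writes `pressure.csv`, `activity.csv`,
`metrics.json` and `run.json`; add `--frames` for per-step activity
heat maps (requires matplotlib).

## In-silico experiments

- `scenario_drug_sweep` varies the AP multiplier with fields held fixed
  (lowering it emulates a calcium-channel blocker such as nifedipine;
  raising it, oxytocin). For a small fraction of seed pairs the model
  shows the paradox in which lowering the multiplier from 3 to 2
  abolishes coordinated contractions but lowering it further to 1.5
  restores them.
- `scenario_region_sweep` varies the grid size (4–64 regions),
  resampling fields per grid, and tabulates pseudo-Montevideo units
  against region count.
- `scenario_two_tissue` runs two strips linked end-to-end (a 1×2 grid)
  and reports per-region burst timing plus a burst-overlap statistic.

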