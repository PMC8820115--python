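# peckside

Analysis of visual lateralization in wild birds from observational feeding
records — and a synthetic-data generator for testing every stage of that
analysis without field data.

Many birds inspect a food patch with one eye (lateral head position) before
pecking. Because the avian optic nerves decussate almost completely, a
consistent eye preference is a behavioural readout of hemispheric
specialization. Given a table of pecks — each annotated with the inspecting
eye (`L`/`R`/`NONE`), whether the peck ended in food consumption, and visit
timing — `peckside` answers the questions such field studies ask:

* Is each individual left-eyed, right-eyed, or non-lateralized?
  (two-tailed binomial test of its eye counts; birds with fewer than 15
  monocular inspections, or interrupted visits, are excluded)
* Is lateralization prevalent at the population level, and directional?
  (continuity-corrected binomial z on the group counts; one-sample
  Wilcoxon signed-rank of the laterality index `LI = (L−R)/(L+R)`;
  Mann-Whitney on `|LI|` between food types)
* Does lateralization pay? (per-bird success proportions, ingestion rate
  in items/minute of active feeding time with >5 s freezes excluded, and
  feeding latency, compared between groups; a balanced six-error design
  testing whether errors concentrate after non-preferred-eye inspections)
* Could repeated sampling of the same individuals across flocks bias the
  results? (Monte-Carlo comparison of each real flock against ten
  simulated flocks drawn from the other flocks' members, Kruskal-Wallis)

The rank and binomial tests are implemented in-package with exact
small-sample modes (full enumeration of the permutation/sign null) and are
verified against brute-force oracles, scipy and statsmodels in the test
suite. See `docs/methods.md` for the statistical details and the
generator's assumptions.

## Worked example

```python
from peckside import binomial_z, classify_individual, BirdSummary, FoodType

# population prevalence from group counts: 54 of 74 birds lateralized
res = binomial_z(54, 74)
print(f"z = {res.statistic:.2f}, p = {res.p_value:.2g}")
# z = 3.84, p = 0.00012

# one bird: 18 left-eye vs 4 right-eye inspections
summary = BirdSummary(
    bird_id="P-017", food_type=FoodType.MAHUA_FLOWER,
    site_id="Pench", tree_id="T2", flock_id="F5",
    n_left=18, n_right=4, n_nonlateral=10,
    n_pecks=32, n_success=24, active_time_s=410.0, latency_s=7.9,
)
r = classify_individual(summary)
print(r.classification.value, f"LI = {r.li:.2f}", f"p = {r.test.p_value:.4f}")
# LEFT LI = 0.64 p = 0.0043
```

The bird inspected with its left eye 18 times out of 22 monocular
inspections; the exact binomial p of 0.0043 classifies it LEFT, with a
laterality index of +0.64 (positive = left bias).

End to end on synthetic data:

```python
from peckside import synth, pipeline

events = synth.simulate_population(synth.SimulationConfig(seed=1))
report = pipeline.run_full_analysis(events, pipeline.AnalysisConfig(seed=1))
pop = report["food_types"]["mahua_flower"]["population"]
```

At seed 1 the generator emits 8554 pecks from 219 birds. The mahua-flower
population report counts 76 analyzable birds — 47 left-preferent, 13
right-preferent, 16 non-lateralized — with prevalence z = 4.93
(p = 8.1e-07), a LEFT majority among the lateralized (z = 4.26), and LI
location W = +1747 (p = 6.1e-06); the fig population shows the mirrored
pattern (49 right- vs 21 left-preferent, W = −1810). These mirror the
planted mixtures: the generator's defaults encode a left-dominant mixture
for the flower task and a right-dominant one for the fruit task.

## Command line

```sh
peckside simulate --seed 1 --out events.csv
peckside summarize events.csv --out birds.csv
peckside analyze events.csv --seed 1 --out report.json
peckside mc-flock events.csv --flock S1-mahua_flower-T1-F2 --seed 1 --out mc.json
peckside kappa confusion.csv
```

`simulate` writes the canonical event CSV; `analyze` writes the full JSON
report bundle; `kappa` scores a square rater-by-rater confusion matrix.

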