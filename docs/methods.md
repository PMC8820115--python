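# Methods

`peckside` analyses visual lateralization in wild birds from observational
feeding records: one row per peck, annotated with the eye (left/right/none)
used to inspect the food patch immediately before the peck, whether the peck
ended in swallowing, and visit timing. The package grew out of field studies
of yellow-footed green pigeons (*Treron phoenicoptera*) feeding on two food
types with different visual demands — mahua flowers (detection of large,
uniformly coloured objects) and sacred fig fruits (colour-based ripeness
discrimination) — but nothing in the code is species-specific.

## The statistical model

### Individual classification

A bird with `L` left-eye and `R` right-eye monocular inspections is treated
as `L + R` Bernoulli trials with unknown per-inspection left-eye probability
`q_i`. Under the no-preference null `q_i = 1/2`. Birds with
`L + R < 15` inspections are excluded (`min_inspections`, inclusive
threshold); so are birds whose visit was interrupted by a social
interaction, since social context can itself shift lateral biases.

The null is tested two ways:

* **Exact binomial** (default): two-tailed p by doubling the smaller tail of
  Binomial(L+R, 1/2), capped at 1. At the per-bird sample sizes of field
  data (15–60 inspections) the exact test has correct size, which is why it
  is the default classification path.
* **Continuity-corrected z**: `z = sign(d)·(|d| − 0.5)/sqrt(n/4)` with
  `d = L − n/2`. This is the statistic whose printed group-level values the
  package reproduces (see the acceptance script), and is available for
  classification with `classification_method="z"`.

A bird with p < α (default 0.05) is classified toward its majority eye
(LEFT/RIGHT); otherwise NONE.

### Laterality index and population inference

`LI = (L − R)/(L + R)` ∈ [−1, 1], positive = left-eye bias;
`ABS-LI = |LI|` measures strength irrespective of direction. Population
inference per food type:

1. *Prevalence*: is the count of lateralized birds more than expected among
   the analyzable birds? Continuity-corrected binomial z against proportion
   1/2. (Testing against 1/2 — not against the α expected by chance — is
   what reproduces the published z values from their counts.)
2. *Direction*: among lateralized birds, binomial z on the majority
   direction's count.
3. *Location*: one-sample Wilcoxon signed-rank of all analyzable birds' LI
   against 0. NONE-classified birds are included — the index exists for
   every analyzable individual — and this is configurable by passing a
   different `li_values` sequence.

The median number of inspections per analyzable bird is reported with a
distribution-free CI from binomial order statistics. It is descriptive
only: the CI method for the analogous published interval is unknown, so no
equality is asserted anywhere.

### Rank tests with exact small-sample modes

All downstream comparisons route through `stats_core`:

* **Wilcoxon signed-rank** (one-sample and matched-pairs): zero differences
  dropped (classic convention, not Pratt), midranks for ties in |d|. The
  reported statistic is the *signed rank sum* `W = Σ sign(d)·rank|d|`, so
  its sign states the direction. The p-value is exact — the full sign-flip
  null computed by dynamic programming — for tie-free samples of up to 20
  non-zero differences; otherwise a tie-corrected normal approximation on
  T⁺ is used.
* **Mann-Whitney**: `U = min(U_a, U_b)`; exact p by enumerating all
  `C(n_a+n_b, n_a)` labelings when the pooled size is ≤ 14, else normal
  approximation with tie and continuity corrections. The min-U convention
  is one of several in circulation; published U values from other software
  need not match it, and the package never asserts equality to any.
* **Kruskal-Wallis**: tie-corrected H, chi-square reference with
  (groups − 1) degrees of freedom.
* **Cohen's kappa** for inter-rater agreement on the inspecting eye, with
  the Fleiss–Cohen–Everitt large-sample standard error and raw percent
  agreement.

The enumeration thresholds (20 and 14) keep the exact paths under a second
of compute; they are constants in `stats_core`, not config.

### Feeding accuracy and efficiency

*Active feeding time* is the visit duration minus "freezes" — pauses without
food-searching behaviour — strictly longer than 5 s (`freeze_threshold_s`);
shorter pauses are normal searching. *Ingestion rate* is
`60·successes/active_time` (items per minute). Accuracy (per-bird success
proportion of monocular pecks), ingestion rate and feeding latency are
compared between groups with Mann-Whitney tests.

The **balanced six-error design** equalises error counts across birds
before asking whether errors concentrate after non-preferred-eye
inspections: only lateralized birds with ≥ 6 pecking errors enter; only the
first six errors (chronological within the visit — the only order the data
has) are used; errors without a monocular inspection count toward the six
but enter neither eye tally. Within each preference direction, a Wilcoxon
matched-pairs signed-rank test compares per-bird errors after the
non-preferred eye against errors after the preferred eye (W > 0 = more
errors after the non-preferred eye). With the cap fixed, comparing counts
and comparing proportions of six are rank-identical.

**A design caveat worth stating plainly:** the six errors are sampled
through usage. A bird that uses its preferred eye for a fraction `u` of
inspections accrues errors after that eye at rate ∝ `u·e_pref`, so even
with equal error probabilities the raw counts tilt toward the more-used
eye. The count-based comparison is therefore calibrated (type-I error ≈ α)
only under balanced eye use, and a *positive* W in real data means the
non-preferred eye's error probability is high enough to overcome its rarer
use — a conservative direction for the usual "non-preferred eye is worse"
conclusion. The calibration studies in the test suite are run at balanced
use for exactly this reason.

### Synthetic-flock pseudoreplication test

Field protocols cannot rule out that the same individual was recorded in
two different flocks. Within one flock, members are guaranteed distinct.
The Monte-Carlo check compares a real flock's LI values against `n_sim = 10`
simulated flocks of the same size, each a uniform without-replacement draw
from the pool of birds in *other* flocks (same food type, since direction
differs by food), drawn independently across rosters so an individual can
recur between rosters — mimicking hidden repeats. The omnibus
Kruskal-Wallis H over the 11 groups is the primary statistic; an optional
Dunn-style each-roster-vs-real Mann-Whitney post hoc is available but off
by default. Rosters are returned in the result for audit, and the whole
procedure is deterministic given its seed.

**Known limitation:** this test runs conservative. Two structural causes,
separable by simulation: the chi-square reference for H is approximate at
eleven groups of ~6 (null rejection ≈ 0.033 even with independent groups),
and cross-roster overlap positively correlates the simulated groups,
deflating between-group rank variance (observed null rejection ≈
0.02–0.03 at α = 0.05 for flock sizes 6–30 with proportional pools).
Because the test's scientific role is to *fail to reject* when repeated
sampling is absent, its conservatism means a significant result is strong
evidence of heterogeneity, while a non-significant one is somewhat weaker
evidence of exchangeability than the nominal level suggests. Power against
a real flock whose LI is shifted by +0.8 (SD 0.3) is ≈ 0.8 at flock size 6
with a pool of 60.

## The synthetic-data generator

`synth.simulate_population` emulates the observed study structure: 2 sites
× 2 food types × 3 trees × (default 3) flocks per tree; flock sizes
rounded Normal(6, 3) truncated at 1. Per bird:

* lateralization class ~ mixture (defaults from the observed class tables:
  mahua 0.527/0.203/0.270 L/R/N, figs 0.209/0.558/0.233);
* preferred-eye probability `q = 0.85` for lateralized birds (0.5 for
  NONE). `q` is not observable directly in group counts; 0.85 was chosen
  so that classification power at the observed ~20 median inspections
  yields the observed ~3/4 lateralized fraction;
* total pecks ~ negative binomial (means 32 mahua / 43 figs, dispersion 8 —
  over-dispersed so a realistic share of birds falls below the 15-inspection
  threshold); each peck monocular with probability 0.63 / 0.52, giving
  ~20 monocular inspections at the mean;
* success ~ Bernoulli(1 − e) with eye-conditional error probabilities.
  Mahua defaults (e_pref, e_nonpref, e_nonlateral) = (0.05, 0.6, 0.3):
  the ratio e_nonpref/e_pref must exceed q/(1−q) for errors to concentrate
  after the non-preferred eye despite its rarer use (the usage confound
  above), and the pair keeps lateralized vs non-lateralized success rates
  near the observed ~74%/66%. Fig errors default to 0 — almost every fig
  peck ends in swallowing — and the pipeline handles the resulting
  degenerate (all-success) accuracy branch by omitting those tests rather
  than failing;
* latency ~ lognormal (means 8.7 s mahua / 15.0 s figs, σ = 0.5), with
  multiplicative penalties for non-lateralized birds on latency (×1.6) and
  inter-peck interval (×1.4) so efficiency contrasts can be switched on or
  off;
* freezes: probability 0.1 per peck, Exponential(mean 4 s) duration, so a
  minority exceed the 5 s exclusion threshold;
* 2% of birds are flagged interrupted (excluded downstream).

Eye choice is i.i.d. across pecks within a bird. Real inspection sequences
may be serially autocorrelated; nothing here models that, nor tree
geometry, satiation, or observer error. Passing tests on this generator
show the *inference machinery* is correct under the stated generative
assumptions — they cannot show those assumptions hold in any particular
field dataset.

Two light-weight generators back the calibration studies without the cost
of full event tables: `simulate_birds` (per-bird eye counts from the
mixture) and `simulate_error_splits` (per-bird six-error eye splits with an
explicit usage rate).

`ground_truth(table)` returns the latent per-bird labels attached by the
generator; analysis code never reads them.

## Numerical and design choices

* Two-tailed tests throughout, α = 0.05 by default.
* Exact binomial two-tailed p by tail doubling (capped at 1), not the
  minimum-likelihood method — simpler and monotone in |k − n/2|.
* A bird with exactly tied eye counts is NONE regardless of α (p = 1 and no
  majority direction exists).
* One visit = one (bird, tree, landing) grouping key; a bird recorded on
  two trees yields two visit rows, and cross-tree identity is not modelled
  (the pseudoreplication test addresses it statistically instead).
* Active time runs from landing to the last peck: departure is not an
  event in the record schema, and trailing non-feeding time should not
  dilute ingestion rates.
* Degenerate inputs raise typed errors (`InvalidInputError`,
  `DegenerateInputError`) at the library level; the pipeline catches them
  per analysis stage and reports the stage as omitted with the reason,
  so one degenerate food type never aborts a run.
* All simulation sizes in the test-suite calibration studies (10,000 null
  birds; 2,000 calibration replicates; 300–500 power replicates) were
  chosen to put three Monte-Carlo standard errors well inside the effect
  sizes being checked while keeping the whole suite fast.

## Reported quantities that are deliberately not asserted

Published statistics that depend on the raw per-bird field values (the
one-sample W values, the various U values, mean latencies, per-group
success percentages, the rater-agreement kappas) cannot be recomputed from
group counts alone; the package reproduces their *qualitative* pattern on
synthetic data in the end-to-end test and reports the algebraically
implied kappa (90% agreement with chance agreement 0.375 gives
κ = 0.84) but asserts no numeric equality against them. The sign
convention of the published one-sample W values is additionally
inconsistent with the stated LI convention (left-bias data printed with
negative W), which the signed-rank-sum convention here does not follow.
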