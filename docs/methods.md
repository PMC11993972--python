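# Methods

## Model structure

The simulator advances a panmictic medfly population in weekly steps with
overlapping generations. Each week runs, in order: (1) injection of any
scheduled sterile-male release, (2) mating, (3) reproduction, (4)
density-dependent competition applied to that week's clutches, (5)
mortality, aging and stage transitions. Mating precedes reproduction
because mating is the first event of the week in the biology being
modelled; competition acts once per clutch cohort, on the week it is laid.

A fly laid in week *t* spends that week as an age-0 larva (this is when
competition thins the cohort), weeks *t*+1 and *t*+2 as a pupa, and is an
adult from week *t*+3. Females can mate in their emergence week but lay
nothing until their second adult week.

### Population representation

Individuals are exchangeable within (age, sex, mating state, origin), so
the population is stored as integer counts per class: a 13 x 4 array for
females (age x mating state), a length-19 vector for wild males, and one
such vector per released strain. Every stochastic operation draws the
class-level equivalent of per-individual sampling — binomial thinning for
survival and remating, a fitness-weighted multinomial for mate assignment,
Poisson totals for clutch sums — so any census statistic has exactly the
distribution of an explicit per-individual simulation. This keeps a
full-scale 150-week run in the low milliseconds and makes replicate
experiments cheap.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `beta` | 10 | low-density growth parameter of the Beverton-Holt term |
| `base_larval_survival` | 0.3344/9.373 ≈ 0.03568 | larval survival at competition factor f = 1 |
| `poisson_mean_eggs` | 9.37 | mean weekly clutch size (eggs/female/week) |
| `remating_prob` | 1/3 | weekly remating probability of a mated female |
| `rescue_fertility` | 0.5 | weekly clutch probability after sterile-then-fertile mating |
| `adult_background_survival` | 0.9 | weekly adult survival from non-age causes |
| age schedules | 5 weeks at 1, then k/(k+1) declining to 0 | linear decline in survivor numbers; max age 19 wk (M) / 13 wk (F) |
| `init_adult_females` | 50,000 | equilibrium adult female count at scale 1 |
| `burn_in_weeks` / `horizon_weeks` | 50 / 100 | equilibration and release-phase lengths |
| `scale_factor` | 1 | linear scaling of all absolute counts; no per-capita rate changes |

Strain profiles: standard SIT (radiation, fitness 0.83, multiplier 1.0);
DmPub.2 as radiation or pgSIT (multiplier 1.011, from its stated 1.1%
effective-release gain); CcPub.1 as radiation or pgSIT (85% relative
rearing survival, 35% XX-to-male conversion, multiplier
0.85 x 1.35 = 1.1475; reporting rounds to 15%). pgSIT variants have mating
fitness 1.0. The simulation uses the exact 1.1475, not the rounded
percentage.

## Calibration

`expected_larvae` (the weekly larval count at which f = 1) is the one free
constant. At stationarity the weekly egg total E must return R = E s(f)
adult recruits, while egg production of the standing females fixes
E = (R/2) x 9.37 x W_r, where W_r is the expected number of reproductive
female-weeks per female recruit implied by the survival schedules
(W_r ≈ 3.81 at defaults). That pins the equilibrium survival rate
s\* = 2/(9.37 W_r) ≈ 0.056, hence the equilibrium competition factor
f\* = (β s₁/s\* − 1)/(β − 1) ≈ 0.60, and `expected_larvae` follows linearly
from the target female count. Because the equilibrium size is exactly
linear in `expected_larvae`, a single pilot burn-in can correct any
residual drift in one rescale step; calibration fails loudly if the
verified mean still misses the target by more than 10% (wider for
populations of a few hundred, where the 20-week mean itself has
O(1/sqrt(N)) noise). With the default demography the analytic value is
already within ~0.5% at full scale.

The initial state is seeded at the stable age distribution (adults per age
proportional to survivorship, one recruit cohort per juvenile age), so the
burn-in only has to absorb rounding and stochasticity, not a transient.

## Release semantics

The release ratio is weekly effort as a fraction of the standing adult
wild male population at carrying capacity, measured per run as the mean
over the last 10 burn-in weeks. On each release week the injected count is
`round(ratio x M_eq x multiplier x interval)`; the interval scaling keeps
total effort over the horizon interval-invariant up to one release of
rounding. Released males are always sterile, enter at the adult emergence
age, compete for matings at their strain's fitness, and die by the same
background-times-age-schedule survival as wild males (effective
competitive lifespan ~6 weeks, so the standing sterile pool under weekly
releases is about six times the weekly release). Elimination is the first
week with zero wild-derived individuals in every life stage; runs are
censored at 100 release weeks. The last-20-week female metric counts
post-elimination weeks as zero.

## Design choices made where the source material was open

- **Reproduction eligibility** is "from the second adult week"
  (weeks-as-adult ≥ 1), the plain reading of excluding the first adult
  week.
- **Background survival interpretation**: the 0.9 parameter is weekly
  *survival* (equivalently 10% weekly mortality from other causes), the
  only reading consistent across its two descriptions; it applies to
  adults of all ages, including ages 3–4 where the age schedule is still 1.
- **Virgin mating** is certain when males exist; remating draws exactly
  one new mate.
- **Rescue gating** is per whole weekly clutch (a Bernoulli gate at 0.5),
  not a halved clutch size.
- **Offspring sex** is iid 1:1; survival is sex-independent, so survivor
  sex splits are binomial.
- **Competition survivors** are drawn binomially rather than rounded
  deterministically, preserving individual-based semantics.
- **Elimination** requires all stages empty, not just adults.
- One seeded generator drives an entire run (burn-in included);
  experiment grids derive independent per-run seeds from a base seed via
  `SeedSequence`, so grids replay bit-identically.

## What the scaled scenarios do and do not show

The `micro` (≈100 females), `desk` (≈5,000) and `paper` (50,000) scenarios
share every per-capita rate; only absolute counts scale. Demographic noise
therefore shrinks as 1/sqrt(scale), and absolute elimination is easier at
small scale simply because zero is closer: a system that leaves a few
hundred females at full scale can tip to elimination at one-tenth scale.
Desk-scale behavioural checks (system ordering, ratio and interval
responses) transfer to full scale, which the test suite confirms directly
for the headline comparisons; exact elimination weeks at reduced scale are
a few weeks earlier than at full scale. Default problem sizes are chosen
so the full behavioural suite runs in seconds: 5–12 replicates for
desk-scale comparisons, 5 seeds for full-scale stationarity.

The generator emulates a closed, well-mixed population with stationary
environment. It does not represent spatial structure, seasonality,
immigration, rearing-facility fitness costs beyond the food-equivalence
multiplier, or explicit inheritance of the CRISPR cassettes (released
males are sterile by assumption). Passing tests therefore validate the
demographic and mating machinery, not field-level predictions.

## Known limitations

- With the printed demographic constants, the carrying-capacity
  equilibrium sits at competition factor f\* ≈ 0.60 rather than exactly 1;
  stability is unaffected (any interior equilibrium of the Beverton-Holt
  map is stable here), and calibration targets the female count, not f.
- Suppression at a given release ratio is strong: with the standing-pool
  release semantics above, every built-in system eliminates the population
  within 100 weeks at ratio 1, and the contrast between systems appears as
  elimination speed (CcPub.1-pgSIT ≈ 2 months faster than standard SIT)
  rather than as elimination vs persistence. Comparisons across systems,
  ratios and intervals are the robust outputs; absolute thresholds should
  be read with this in mind.
- Release-interval degradation sets in between 10 and 16 weeks at ratio 1
  (intervals ≤ 4 are indistinguishable from weekly); the exact onset
  depends on the released males' competitive lifespan, the least
  constrained part of the model.
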