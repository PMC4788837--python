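# Methods

`qaleplan` chains four models: a multiobjective evolutionary IMRT planner, a
pair of discrete Bayesian outcome networks, a Markov cohort simulation, and
sensitivity machinery around the whole pipeline. This note records the models,
their assumptions, the defaults, and the choices made where the design was
genuinely open.

## Dosimetric summaries

All downstream models consume a handful of plan summaries:

* **Cumulative DVH.** Bin-exact: the fraction at edge *b* is the exact count
  fraction of voxels with dose ≥ *b*; default bin width 0.1 Gy. `D95` is the
  largest bin dose whose cumulative fraction is ≥ 0.95, with no interpolation —
  deterministic and bin-exact, which keeps every test assertion sharp at the
  cost of ≤ one bin width of quantization.
* **Generalized EUD** is the power mean `(mean(dᵃ))^(1/a)`, computed in log
  space for stability at large |a|. The PTV default is `a = −10`, so cold
  voxels dominate — the convention that matches "equivalent cell kill" for a
  tumour. Any voxel at 0 Gy sends the negative-power mean to 0.
* **LKB NTCP.** The DVH is reduced to an effective uniform dose with the
  power mean at `a = 1/n`, then mapped through the probit
  `Φ((D_eff − TD50)/(m·TD50))`. The published fits behind the organ parameters
  are not part of this package's calibration surface; the shipped defaults
  (rectum TD50 76.9 Gy, m 0.13, n 0.09; bladder TD50 80 Gy, m 0.11, n 0.5)
  are implementation defaults, tagged as such in `Calibration.sources`, and
  every entry is editable through the calibration JSON. The model is static:
  no setup error or organ motion.
* **Hotspot proximity** is the minimum Euclidean distance from an organ at
  risk to any voxel above the organ's TD50 (the hotspot definition used
  throughout), `None` when no voxel qualifies.

## Outcome networks

Both networks are discrete Bayesian networks solved by exact variable
elimination (min-degree heuristic). Networks here have ≈ 11 nodes, so exact
inference costs microseconds and is audited in tests against brute-force
enumeration of the full joint (agreement to 1e-10). CPT rows are ordered
with the last parent cycling fastest, and the JSON serialization states this
convention explicitly. Inconsistent evidence raises an error rather than
returning a zero vector, so modelling bugs cannot masquerade as structural
zeros.

**Tumour control.** Staging evidence fixes the recurrence-risk group
(NCCN-style: T2c+, Gleason ≥ 8 or PSA > 20 ⇒ high risk); risk group maps to
an RPA prognostic class whose 5-year biochemical control rate is a
calibration entry. The class table values are implementation defaults except
the reference stratum, pinned at 28 % failure — the no-ADT arm of the
hormone-therapy trial the model is anchored to. The ADT node (none / 3
months / 6 months) carries a uniform prior; the chosen schedule enters as
evidence. Its effect is encoded as the hazard-rate ratio implied by the
failure anchors {28 %, 17 %, 12 %} over the 5-year horizon, applied
multiplicatively to any baseline rate — this reproduces the anchors exactly
on the reference stratum and extends the effect sensibly to other classes.

The dose-modified control node multiplies the baseline control probability
by two rescaled logistics, one rising in (EUD − prescription) at 0.08/Gy and
one falling in (cold-spot fraction − 0.05) at slope 4; each factor equals 1
at the reference point (EUD = prescription, cold spot 5 %), so the anchors
are preserved for a reference plan. Only the monotone directions are
clinically established; the slopes are implementation defaults.

Two metastasis pathways feed a deterministic OR node. DM1 is progression
signalled by a rising PSA, observed through the ASTRO failure definition
with sensitivity 73 % and specificity 76 %; the metastasis risk given true
biochemical status is a per-risk-group 3-year (failure) or 5-year (control)
cumulative probability, implementation defaults. DM2 is progression of
occult nodal disease: the nodal-involvement node is pinned to 26 % (high
risk) and 10 % (intermediate), and whole-pelvic irradiation intercepts the
pathway with the physician's cure-rate belief; prostate-only treatment has
cure rate 0. The probability that uncured occult disease progresses (0.60)
is an implementation default.

**Toxicity.** Per organ, the LKB NTCP is adjusted on the odds scale by a
hotspot-proximity multiplier `exp(β(d₀−d)/d₀)` clamped to [1/κ, κ]
(β = 0.5, d₀ = 10 mm, κ = 2; neutral when no hotspot exists) and by
retrospective dose-volume predictor rules (e.g. rectum V70 > 25 % ⇒ odds
×1.3). Switching the field decision to whole-pelvic adds 8 percentage
points to each organ's complication probability, clamped to [0,1]. The
increment is read as additive points; a relative-risk reading is also
defensible, but the additive one matches the stated "increase by 8 %"
against baselines in the 5–20 % range, and it makes the increment exact and
testable away from the clamp.

The two networks are separated by construction: tumour control never reads
organ-at-risk dosimetry and toxicity never reads target dosimetry. A test
asserts this separation.

## Markov cohort simulation

States: POST_RT, three biochemical-failure tunnel years (no
self-transition), late biochemical failure, distant metastasis (DM), and
absorbing DEAD. Cycle length 1 year, from radiotherapy until attained age
119 (the life-table horizon). Conventions, chosen once and used in all
analytic oracles:

* Cycle *t* covers years [t−1, t) after treatment; the life-table lookup
  uses `start_age + t − 1`.
* No half-cycle correction: one full cycle of occupancy is credited per
  cycle survived (occupancy is recorded after each annual transition), so a
  constant death probability *p* yields a life expectancy of `(1−p)/p` —
  frozen as a closed-form test.
* Competing risks within a cycle combine as independent hazards,
  `p_total = 1 − Π(1−p_k)`, with destinations allocated proportionally.

Cumulative network probabilities become annual probabilities through a
constant-rate assumption (`p_c = 1 − e^{−r·t}`, `p_a = 1 − e^{−r}`).
Window rules: biochemical-failure onset and metastasis-without-failure are
live for cycles 1–5 and zero after; the tunnel metastasis rate applies for
the first three failure years, after which the rate drops to one third; all
entry into the DM state is switched off once the model reaches 15 years
post-treatment (entry is cut, residence is not — a cohort already in DM
keeps dying at the DM rate). DM exits combine the cancer-specific rate
implied by a 19-month median survival with age-specific natural death,
again as independent competing hazards.

The deterministic engine propagates occupancy fractions exactly and is the
default; a seeded Monte-Carlo engine simulates individual patients with
multinomial draws, and a test holds the two within three standard errors at
n = 100,000 (the standard error is derived from the deterministic death-time
distribution, an independent route).

**QALE.** Life expectancy is unweighted alive time. Quality adjustment
mixes four complication branches (none / rectal / bladder / both, treated as
independent) weighted by the lifetime toxicity probabilities. Complications
are late effects: their multiplicative disutility factors apply from cycle 3
onward (onset at the end of year 2) in every alive state except DM, where
metastatic disease dominates quality of life. Three preference attitudes are
supported: population-average utilities, utilities two standard deviations
lower (complication-averse), and all-ones (pure survival maximization, under
which QALE ≡ LE). The published utility study behind the averages is not
reproduced here; the shipped values (e.g. biochemical failure 0.95, DM 0.25,
rectal factor 0.92, bladder 0.94) are implementation defaults tagged in the
calibration.

## Plan evaluation and policy comparison

`evaluate_plan` is a deterministic composition of the three stages and
retains every intermediate output. Ranking is by QALE, descending, ties
broken by plan id. `compare_policies` evaluates prostate-only against
whole-pelvic treatment at each cure-rate belief and attitude with shared
dosimetry; QALEs are compared at full precision and reported at 0.1-year
precision in the CSV.

## Multiobjective planner

The planner runs on a synthetic 2-D phantom: a circular PTV between an
elliptical rectum and bladder on a 40×40 grid at 2.5 mm spacing, five
equi-spaced beams of nine 5-mm beamlets; each beamlet deposits exponential
depth attenuation (0.004/mm) times a Gaussian lateral penumbra (σ = 3 mm).
This reproduces the geometry of the planning problem — conflicting coverage
and sparing through shared beam paths — not clinical transport physics.

A gene holds a weight and dose target per quadratic objective (PTV
two-sided, organs one-sided overdose). The inner problem
`min Σ w_j f_j(A x)` over `x ≥ 0` is convex and solved by projected
quasi-Newton iteration (L-BFGS-B with analytic gradients); a test checks it
against an independent non-negative least-squares route on a two-sided
problem to 1e-5 relative objective. Decision criteria — PTV D95 and EUD
(higher better), cold-spot fraction and the two NTCPs (lower better) — are
computed from the dose metrics module, never from the inner objectives.
Pareto dominance and archive updates follow the standard definitions; the
archive is audited against an O(n²) brute-force filter. An optional D95
constraint gates entry into the archive; infeasible plans remain available
for breeding. The default run (population 20, 50 generations, Gaussian
mutation of log-weights at σ 0.5 and targets at σ 2 Gy, uniform crossover at
rate 0.5, uncapped archive) is seed-reproducible, and its per-generation
dominated hypervolume — computed exactly by WFG recursion against a fixed
reference point — is non-decreasing, which follows from archive updates
never shrinking the dominated region. With an archive cap configured,
crowding-distance pruning applies (and the hypervolume guarantee no longer
holds, which is why the default is uncapped).

## Sensitivity machinery

One-way sweeps re-evaluate the pipeline over a parameter grid. The two-way
threshold map overrides the nodal-involvement probability and the cure-rate
belief per cell and labels the dominant field strategy; cells are verified
against independent single-cell policy evaluations. The PSA draws each
parameter from a normal distribution truncated to its physical bounds via
the inverse CDF (exact, seedable, no rejection loop), evaluates every draw
through the full pipeline, and fits ordinary least squares on standardized
inputs so coefficients are comparable importance measures; zero-variance
inputs are dropped and recorded. The reference PSA size is 10,000 draws;
tests use 500, which is ample for the linear-recovery check (coefficients
within 2 standard errors, R² > 0.99 on a constructed linear outcome).

## What the synthetic fixtures do and do not show

The DVH library spans a seeded coverage-versus-sparing frontier (plans
ordered so higher PTV EUD comes with higher rectal NTCP); the life table is
Gompertz–Makeham (λ = 5e-4, α = 3e-5, β = 0.095 per year), monotone in age
and covering ages up to 119 with a CSV loader for a real actuarial table.
Passing tests therefore demonstrate internal correctness — anchors, oracle
agreement, monotonicity, determinism — on data with realistic shape.
They do not validate the model clinically: absolute life expectancies and
QALEs depend on the implementation-default tables (RPA control rates,
metastasis baselines, LKB fits, utilities), which a user fitting the model
to a clinic's evidence base should replace through the calibration JSON.
For the same reason the headline policy tables are reproduced structurally
(same experiment, same logic) but their absolute values are configuration-
dependent and are not asserted.

## Numerical choices and limitations

* CPT rows must sum to 1 within 1e-9; cohort occupancy conserves to 1e-12
  per transition row.
* Probability/rate conversions round-trip to 1e-12 over cumulative
  probabilities up to 0.999 and horizons of 1–10 years.
* Ties in plan ranking break on plan id; ties in the threshold map go to
  prostate-only treatment (the less toxic default).
* No discounting of life-years, no acute toxicity, no cost dimension.
* The phantom is 2-D and fraction-size effects (LQ corrections) are out of
  scope; NTCP inputs assume a static geometry.
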