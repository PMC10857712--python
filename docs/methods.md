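# Methods

## Model structure

The simulator tracks the *expected* stage composition of two isogenic
*P. pacificus* strains — "P" (plastic, diet-dependent mouth-form induction)
and "NP" (non-plastic, obligately predatory) — on an m×m lattice of demes.
It is deterministic throughout: population state is real-valued, predation
removes expected kills, and dispersal moves expected fractions. The only
stochastic elements are initial-condition choices (random resource layouts,
random seed locations, boom-bust diet reassignment), all driven by named
RNG substreams derived from one master seed, so every run replays
bit-identically.

The per-strain life cycle is a column-oriented 10×10 transition matrix
`U(ε)` over E, J, D, YA, RA1–RA5, OA, plus a fertility matrix `F(ε)` whose
egg-row entries are `z̄_j(ε) · γ_{j→j+1}(ε)`. The survival factor
`σ(N_c) = exp(−ψ N_c)` multiplies each *source stage's* column of `U` —
the stay term and all exits of a stage share that stage's survival — with
the dauer column exempt (σ₃ = 1) because dauers are stress-resistant and
non-feeding. Fertility entries carry no survival factor. The old adult is
terminal: stay probability σ(N_c), no diet effect on adult survival (no
diet-specific adult survival is established, so the OA column uses the
same σ as other stages).

### Time calibration and default transitions

One step represents roughly one hour. Day-scale transitions use
γ = 0.0415, which gives an expected occupancy of 1/0.0415 ≈ 24.1 steps via
the fundamental matrix `N = (I − U)⁻¹`. Defaults (per resource state):

| transition | OP50 | L76 | starved | rationale |
|---|---|---|---|---|
| γ21 (E→J) | 0.0415 | 0.0415 | 0.0415 | ~1-day embryonation; hatching continues under starvation |
| γ32 (J→D) | 0.001 | 0.001 | 0.25 | dauer formation is a starvation response; a small on-food trickle |
| γ42 (J→YA) | 0.017 | 0.017 | 0 | ~2.5-day juvenile phase; no maturation without food |
| γ43 (D→YA) | 0.0415 | 0.0415 | 0 | dauers resume development only on food |
| γ54 (YA→RA1) | 0.0415 | 0.078 (P) / 0.083 (NP) | 0 | the inducing diet speeds maturation, slightly differentially by strain |
| γ65…γ109 | 0.0415 | 0.0415 | 0.0415 | day-class advances; adults age regardless of food |

Fecundity under starvation is zero (configurable): the starved state
represents resource exhaustion, and egg laying without food is not
modelled.

### Fixture fecundities are placeholders

The measured mean egg counts per adult day class are published only as a
figure, so the shipped fecundity tables are synthetic fixtures chosen once
to respect the established qualitative orderings: the plastic strain
out-produces the non-plastic strain on OP50 (phenotypic-mismatch cost
Δw_E2 for the fixed strain) and the reverse on L76 (plasticity cost
Δw_E1), with peak laying on day 2 and a long right tail. With the default
tables the dominant eigenvalues of U+F are 1.0616 (P) vs 1.0559 (NP) on
OP50 and 1.0612 (P) vs 1.0713 (NP) on L76. They live only in
`iohub.default_fixture_params` and the config layer — no model code
hard-codes them — so measured means can be dropped in via the YAML config
without code changes. Consequently the lattice experiments are validated
at the level of directions and orderings (who gains when a cost is
removed), never at the level of exact abundances.

### Deme update and ordering conventions

Within one step, in order:

1. **Projection + consumption.** The effective state ε and consumer count
   N_c are evaluated on the *pre-step* composition (starved iff
   `R < β N_c`, strictly); the deme is projected with `A(ε)` (σ(N_c) baked
   into U); the resource is decremented with the same N_c, clamped at 0.
2. **Predation.** Both directions are computed from the same
   pre-predation state (simultaneous, order-independent). Predator number
   is `λ_{j,ε} · (YA + ΣRA)` at the deme's *current* effective state — no
   cohort memory of the diet an adult developed on; under starvation λ
   falls back to the diet label's value (mouth forms are fixed at
   development, food running out does not change them; configurable).
   Kills per prey stage (J and D separately) are clamped at the prey
   available, since the raw type-II expression can exceed the prey count
   for large predator numbers. Predation does not feed the predator (no
   numerical response); only prey removal is modelled.
3. **Dispersal.** Each deme exports `r·n_D` to *each* valid von Neumann
   neighbour and receives the symmetric imports, synchronously from the
   pre-dispersal state; corners export 2r, interior demes 4r of their
   dauers (hence the invariant 4r ≤ 1). Boundaries are plain edges, not
   toroidal. Dispersal conserves lattice dauer totals to machine
   precision.

Replenishment, when scheduled, applies at the *start* of the step that
leaves `t = k·interval` (t > 0): every deme's resource resets to R₀ and,
optionally, all diets are redrawn uniformly from the replenishment
substream. The choice of start-of-step application is a fixed convention
documented for reproducibility; nothing establishes the alternative.

### Extinction threshold

Linear projection never reaches zero, so expected counts below 10⁻⁶ are
zeroed after each step. This makes competitive exclusion a reachable,
testable state. Exclusion of a strain is recorded at the first step where
all of its feeding stages are zero. Note that with σ = e^(−ψN_c) the
post-starvation decay of a residual population is power-law, so exclusion
effectively happens during crowded phases (σ small, recruitment blocked by
predation); scenario runs therefore use a fixed step budget (12 000 steps
for the 20×20 runs, 5 000–6 000 for well-mixed) rather than waiting for a
quiescent state, and report the dauer share `f̂_Dauer,P` at that horizon.
An optional early stop (lattice-wide resource exhausted and no feeding
stages left) is available for single-boom runs.

## Default global parameters

| symbol | meaning | default | units |
|---|---|---|---|
| β | per-capita consumption | 0.002 | resource · consumer⁻¹ · step⁻¹ |
| ψ | density-mortality intensity | 6×10⁻⁵ | consumer⁻¹ |
| a | attack rate | 0.2 | prey⁻¹ · step⁻¹ |
| h | handling time | 0.15 | steps · prey⁻¹ |
| r | per-neighbour dispersal fraction | 0.01 | — |
| R₀ | initial/replenished resource per deme | 500 | resource units |
| λ_P | predatory probability, plastic | 0.11 (OP50) / 0.83 (L76) | — |
| λ_NP | predatory probability, non-plastic | 1.0 | — |
| — | extinction threshold | 10⁻⁶ | expected individuals |

## Quadrant and random layouts

Quadrant layouts split the lattice into four ⌈m/2⌉ blocks. Pattern A puts
the main-diagonal quadrants (containing the plastic-seeded corners S₁,₁
and S_m,m) on OP50 and the anti-diagonal quadrants on L76; pattern B is
the complement, placing the plastic-seeded corners on the inducing diet.
Random layouts draw each deme's diet independently and uniformly;
randomized seeding draws the four seed locations uniformly *without*
replacement over all demes (corners not excluded).

## Mouth-form inference

Worm-level mouth form is Bernoulli(λ) within a condition (strain × diet);
plates are replicates. Two estimators:

- **Pooled**: counts summed within a condition, conjugate
  Beta(α+k, β+n−k) posterior under a Beta(α, β) prior (default flat).
  Exact; used for the interval-calibration experiments.
- **Hierarchical**: per condition, plate probabilities
  `p_k = expit(μ + τ z_k)` with `z_k ~ N(0,1)` (non-centred),
  `y_k ~ Binomial(n_k, p_k)`, priors `μ ~ N(0, 1.5²)` and
  `τ ~ HalfNormal(1)`. Sampled with emcee (2·dim+2 walkers, 1 000 burn-in
  + 2 000 kept steps); the reported λ is the posterior of `expit(μ)`, the
  median-plate probability, which coincides with the population mean when
  plates are exchangeable and overdispersion is small. Convergence is
  checked via acceptance fraction and autocorrelation time; failures are
  flagged in the summary table and as a warning, never silently dropped.

The plate hierarchy here is a standard weakly-informative formulation
chosen by this package; the non-plastic strain's λ is fixed at 1.0 rather
than estimated.

### Synthetic count generator

`simulate_mouthform_counts` mirrors the assay structure: per plate a
probability is drawn as `expit(logit(λ) + ω z)` (ω = 0 gives exactly λ),
then a binomial count. It emulates plate-level sampling noise and optional
logit-scale overdispersion; it does **not** emulate scorer error,
within-plate density effects, or diet-batch effects, so recovery and
calibration results certify the estimator under the assumed sampling
model, not robustness to those artefacts. Default recovery experiments use
10 plates × 30 worms, a realistic assay size.

## Numerical choices

- Occupancy diagnostics solve `(I − U) x = e_start` directly; a singular
  system (no leakage) raises rather than returning garbage.
- The lattice engine vectorises the per-deme update by grouping demes by
  effective state; equality with the scalar per-deme reference operations
  is asserted in the test suite at rtol 1e-9 (associativity of floating
  multiplication is the only difference).
- `f̂_Dauer,P` is explicitly undefined (NaN per deme, None lattice-wide)
  where no dauers exist — never coerced to 0.
- Dominance classification at the horizon: a strain is dominant with
  >99 % of lattice dauers; coexistence means both strains hold >1 %.
  These thresholds are definitions of this package, not measured
  quantities.

## Problem sizes

Shipped scenarios use the 20×20 lattice with a 12 000-step budget
(≈ 7 s each); well-mixed runs (m = 1) use 5 000–6 000 steps; isolation
growth 1 500 steps; interval calibration 200 synthetic datasets per λ.
These sizes put every experiment comfortably past its transient behaviour
(growth-rate convergence is at 1e-15 by step 1 500; lattice colonisation
completes well before the budget) while keeping a full suite run around a
minute.

## Known limitations

- Expected-value dynamics: no demographic stochasticity, so founder
  effects and extinction by chance are absent; the extinction threshold is
  a surrogate.
- No cohort memory of developmental diet for mouth forms; λ switches with
  the deme's current state.
- No prey preference between juveniles and dauers, no predator
  interference, no conversion of kills into predator fecundity.
- Fecundity fixtures are placeholders (see above); quantitative abundances
  are not comparable to laboratory data until measured means are supplied.
- Dispersal is deterministic nearest-neighbour flux; no distance-decay
  kernels or strain-specific dispersal rates.
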