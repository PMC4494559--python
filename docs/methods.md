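# Methods

## Model structure

A deterministic cohort (Markov) model with two states, *alive* and *dead*,
and yearly cycles.  Cycle t = 1 is the first post-surgical year; the cohort
enters it at age 18 with probability 1 of being alive.  Death is absorbing
and accrues neither cost nor utility.  All differences between the surgery
and no-surgery cohorts are driven by the BMI difference in each cycle, which
feeds three channels: annual medical-cost savings, an HRQL increment, and a
mortality hazard reduction.  No comorbidity-specific states are modelled;
their effect is understood to be folded into the per-BMI-unit coefficients.

### BMI trajectory

The surgery arm's reduction in cycle t is

    ΔB(t) = ΔB₁ · (1 − min(p, f · max(0, t − c₀ + 1)))

with initial reduction ΔB₁ = 13.2 BMI units, annual regain fraction
f = 0.05, first regain cycle c₀ = 2 and plateau p = 0.25.  Regain is simple
(not compounding) and expressed as a fraction of the initial reduction,
since the model operates entirely in BMI units.  With the defaults the
series over 7 years is (13.2, 12.54, 11.88, 11.22, 10.56, 9.90, 9.90):
five 5% increments in cycles 2–6, constant at 75% of the initial reduction
thereafter.  This reading — increments in years 2 through 6, plateau "after
year five" — is the one that reconciles the published "5%/year (years 2 to
5)" schedule with the published plateau of 25% and with the savings column
it implies.  The no-surgery arm has ΔB ≡ 0 (BMI constant at 48.7).

In one-way sweeps of the regain fraction, the plateau scales as
min(1, 5f): regain accrues for the same five years, so f = 0.20 means
complete regain from year 6 on (and f = 0.05 reproduces the base 0.25).
A fixed plateau would silently cap any swept fraction above 5% after a
couple of years and make the "complete regain" scenario unreachable.

### Mortality

The no-surgery annual death probability is Gompertz:
q(a) = min(1, q₀ e^{g(a−18)}) with anchor q₀ = 0.008 at age 18.  This is a
deliberately parametric, synthetic stand-in for a national age-indexed life
table; `LifeTable` round-trips through a two-column text file so a real
table can be substituted without code changes.  A BMI reduction ΔB
multiplies the probability by e^{−βΔB} (clipped to [0, 1]) — a log-linear
hazard link whose magnitude is *calibrated*, not assumed, because no
functional form for the BMI–mortality association is published.

### Accrual and discounting conventions

Unstated in the source material and therefore fixed here as package
conventions (validated by reproducing the published savings and QALY
columns; see "Calibration"):

- savings in cycle t accrue to the fraction alive at the cycle *start*,
  discounted by (1+r)^t with t = 1 in the first cycle;
- utility accrues to the fraction alive at the cycle *end*, discounted
  identically; the surgery arm's utility is u_base + 0.0042·ΔB(t);
- no half-cycle correction anywhere;
- the intervention cost falls at time 0 and is never discounted;
- the comparator accrues zero incremental medical cost by construction (the
  model is specified directly in incremental savings per BMI unit);
- the reported added-life-year column is the *discounted* end-of-cycle
  survival gap, the same 3% discounting as costs and QALYs.  The per-cycle
  ledger also records raw survival.  The discounted convention is a
  deliberate choice: under undiscounted accumulation the reproduced QALY
  column drifts systematically low (−0.4% at year 1 down to −5.3% at year
  7) and the calibrated Gompertz slope comes out negative (mortality
  falling with age); the discounted reading reproduces every published
  QALY within 1.1% with a plausible positive slope g ≈ 0.043.

## Calibration

Three parameters are not external inputs and are calibrated to published
model outputs:

1. **β (BMI log-hazard)** and **g (Gompertz slope)** solve the
   two-dimensional root problem "added life-years at years 1 and 7 equal
   0.00624 and 0.15815".  The problem decomposes exactly: the year-1 value
   depends only on β — added LY(1) = q₀(1 − e^{−βΔB₁})/(1+r) — giving β in
   closed form (β ≈ 0.1232, i.e. one BMI unit cuts the annual death hazard
   by ~12%); g is then solved from the year-7 residual by Brent's method
   (g ≈ 0.0431).  The search is deterministic, idempotent, and recovers
   synthetic (g*, β*) pairs to machine precision.  Infeasible targets (a
   year-1 target at or above q₀/(1+r), non-increasing targets) raise a
   calibration error that reports the degenerate β = 0 behaviour.
2. **u_base (utility of the no-surgery state)** solves "added QALYs at year
   1 equal 0.060".  Year-1 added QALYs are affine and strictly increasing
   in u_base, so the root is computed exactly.  With the published targets
   the attainable maximum at the admissible ceiling u_base = 1 is 0.059981
   — the exact root sits ≈ 0.0003 above 1 because the 0.060 target is a
   3-decimal rounding.  Calibration therefore clamps to the boundary when
   the shortfall is below a boundary tolerance of 5×10⁻⁴ (the target's
   printed resolution) and raises otherwise, reporting residuals at both
   endpoints.  A config override allows fixing u_base instead.

A consequence worth stating plainly: with u_base at the ceiling, the
surgery arm's per-cycle utility u_base + 0.0042·ΔB exceeds 1.  This is an
artifact of forcing a single baseline utility to reproduce the published
QALY column and is retained knowingly; utilities above 1 have no
interpretation beyond "better than the reference state by the HRQL gain".

## Incremental outcomes and ICERs

ΔCost(h) = intervention cost − cumulative discounted savings; ICER(h) =
ΔCost(h)/ΔQALY(h) when the QALY gain is positive, with explicit
`dominant`/`dominated`/`undefined` flags instead of misleading ratios
otherwise.  The first cost-effective year is the smallest horizon with
NMB ≥ 0 (equivalently ICER ≤ λ for positive QALY gains), λ = $100,000/QALY
by default.

The published ICER column itself is internally inconsistent with the
published component columns (recomputing ΔCost/ΔQALY from its own rows
gives values ~8% lower at every horizon, e.g. $32.5k vs the printed $36.6k
at year 7).  The component columns are treated as primary; ICERs are
validated against the $100k threshold crossings, which hold under either
reading (year 3 above, year 4 below).  One published claim is *not*
reproducible under any consistent reading that also reproduces the QALY
column: that with no HRQL gain surgery first becomes cost-effective after
year 9.  With the QALY column reproduced to 2%, zero HRQL gain leaves
exactly the (discounted) life-year gap, 0.15815 at year 7, giving an ICER
of ≈ $93k < $100k at year 7 — the crossing moves from year 4 to year 7, in
the published direction but not beyond year 7.  The corresponding test
asserts the published claim and fails; it is kept failing rather than
weakened, as a record of the inconsistency.

## Probabilistic sensitivity analysis

Parametric Monte-Carlo (the published analysis calls its 1,000 replicates
"bootstrap", but with only summary moments available the stated gamma/beta
machinery defines parametric draws): each replicate draws four inputs
independently — intervention cost, savings per BMI unit and BMI reduction
from gamma distributions, the HRQL gain from a beta distribution, all
moment-matched (gamma: shape = (m/s)², scale = s²/m; beta by the standard
method of moments) — and re-runs the deterministic model.  Calibrated
mortality and u_base are held fixed.  Draws with an infeasible BMI
reduction (≥ pre-operative BMI) are rejected, redrawn and counted.

Uncertainty magnitudes: the savings slope ($157, SE $47) and HRQL slope
(0.0042, SE 0.0011) enter at their regression standard errors as
published.  The intervention-cost spread ($2,044) and weight-loss spread
(13.5 kg) are patient-level SDs across the 11-patient cohort, so the
corresponding *mean* parameters are sampled at SD/√11 (weight-loss
uncertainty mapped to BMI units by the ratio 13.2/37.5, giving SD ≈ 1.43).
Sampling them at the raw patient-level SDs instead yields a 4-year ICER
interval of [$25k, $213k] and an acceptability of 0.66 at $100k/QALY —
inconsistent with the published interval [$43,452, $144,347] and
acceptability 75.1% — whereas the SE convention gives [$44k, $127k] and
~0.84: the published analysis evidently propagated uncertainty in the
means.  Replicates with non-positive QALY gain are excluded from ICER
percentiles but retained in CEACs via NMB.  The default WTP grid is
$0–$200,000 in $5,000 steps.

One-way sweeps re-run the deterministic model over a value grid for one of:
HRQL gain, intervention cost, savings rate, discount rate, regain fraction
— everything else, including calibration, held at base case.

## Synthetic data

The generators emulate the statistical *structure* the analysis assumes,
not the real sources:

- **Cohort**: sex ~ Bernoulli(10/11 female); age, height, weight from
  truncated normals at the published moments (age clipped to [14, 20]);
  BMI derived as weight/height² so the weight–height–BMI triangle is
  consistent (hence the generated BMI SD ≈ 8 exceeds the published 6.6 —
  documented, not corrected); 12-month weight loss truncated to
  (0, weight) record-by-record; one non-negative truncated-normal charge
  per billing line.  Truncation at zero biases the small-mean/large-SD
  charge lines upward (generated total charges average ≈ $48.5k vs the
  $47.4k input); the model itself takes charges from the published table,
  not from this generator.  The mean 12-month post-surgical BMI,
  (weight − loss)/height², lands within 0.5 units of the published 35.4.
- **Survey**: BMI gamma-distributed above the severe-obesity cutoff 34;
  an EQ-5D-like utility falls linearly in BMI (slope 0.0042) with additive
  Gaussian noise (SD 0.08); annual expenditure rises linearly in BMI
  (slope $157) with gamma-distributed values around the linear mean
  (right-skewed, non-negative, mean exactly linear so OLS slope recovery
  is unbiased).  Age and sex covariate effects are included in generation
  and adjusted for in recovery, mirroring the published age/sex-adjusted
  estimates.  The anchors (utility 0.75 and expenditure $2,500 at BMI 34)
  are unpublished and chosen as plausible for a severely obese US adult
  subgroup; they are intercepts and do not affect slope recovery.  No
  survey weights, panel structure or cost top-coding are emulated.
- **Life table**: the Gompertz table above, written to a two-column file.

What passing tests show: the pipeline recovers known generating parameters
(slopes within 2 SEs at n = 50,000, unbiased over 200 replications) and the
model reproduces the published outputs under the stated conventions.  What
they do not show: anything about real billing, survey or mortality data —
the generators share none of the messiness (skewed charges, clustered
survey design, cohort-specific mortality) of the real sources.

## Numerical choices and problem sizes

- Root finding: closed forms where exact (β, u_base), Brent's method with
  xtol 10⁻¹⁴ for g; calibration residual tolerance 10⁻⁹ relative.
- Monte-Carlo sizes: 1,000 PSA replicates (as published), 10,000-patient
  synthetic cohorts for moment checks, 50,000-respondent surveys for slope
  recovery; chosen so sampling error sits well inside the asserted
  tolerances while the full suite runs in about a minute.
- Determinism: every stochastic routine takes a seed and uses an
  independent `numpy` Generator; identical seeds give bit-identical
  output, including across the CLI.
- Degenerate inputs are errors, not silent defaults: zero-variance survey
  designs, empty cohorts/summaries, infeasible calibration targets,
  out-of-range ages, unknown config keys and unknown sweep parameters all
  raise with actionable messages.

## Known limitations

- Two states only; no comorbidity-specific states, costs or utilities.
- One sex-aggregated mortality anchor (the cohort is 91% female).
- u_base at the utility ceiling (see above); surgery-arm utility exceeds 1.
- The published ICER column and the published zero-HRQL crossing year
  cannot be reproduced jointly with the published component columns (see
  "Incremental outcomes and ICERs").
- Added life-years are reported discounted; undiscounted survival is
  available in the per-cycle ledger but not in the headline table.
- No correlation between sampled PSA parameters (none is published).
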