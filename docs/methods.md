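# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind `boombust`, and what the synthetic test bed does and
does not establish about real survey data.

## The minimum-set problem and its objective

A scenario is a species × planning-unit count matrix `a_{s,i}` with PU
costs `c_i` (constant 1 by default: the "cost" of a solution is its number
of wetlands) and a representation fraction `p` applied to every species.
Targets are `T_s = p · Σ_i a_{s,i}`. When counts are integers, `p` is held
as an exact rational (a float `0.1` is read through its decimal repr as
1/10) and feasibility uses exact comparison with `≥`, so a PU holding
exactly 10 of 100 individuals meets a 10% target — boundary cases are never
lost to binary rounding.

The annealing objective is

    Σ_{i∈S} c_i + Σ_s spf · (shortfall_s / T_s) · base_s

where `shortfall_s = max(0, T_s − Σ_{i∈S} a_{s,i})` and `base_s` is the
greedy cost of covering species `s` alone from the empty set, computed once
per instance. Scaling the penalty by `base_s` makes "species entirely
unmet" cost roughly what covering it would cost, so the species penalty
factor (`spf`, default 100) needs no per-dataset tuning. Species with
`T_s = 0` contribute nothing. A feasible set scores exactly its cost.

## Annealing schedule and repair

Moves are single-PU flips from a random half-occupied start. The initial
temperature is adaptive: 100 probe moves are evaluated (not applied) and
the temperature is set so the median |Δ| uphill move is accepted with
probability 0.8. Cooling is geometric down to 1e-4 of the initial
temperature over the configured number of iterations (default 100,000).
The kernel tracks the best state visited and returns it. A repair pass then
(1) greedily adds PUs by largest summed fractional unmet-target gain per
unit cost until every target is met, and (2) prunes redundant PUs scanning
by descending cost then descending index. Because removals only shrink
holdings, a single prune pass yields an irredundant set; every returned
solution is feasible and irredundant by construction. The boundary-length
(spatial clumping) term of reserve-design tools is deliberately omitted:
the analyses here use no spatial objective, and wetland-complex clumping is
handled upstream by cell aggregation.

Irreplaceability is selection frequency: run `R` independent annealing
solutions (run `r` uses seed `seed + r`); `IrSc_i` is the fraction of
solutions containing PU `i`. Class bands are left-closed, right-open —
[0, 0.2) very low, [0.2, 0.4) low, [0.4, 0.6) moderate, [0.6, 0.8) high,
[0.8, 1) very high — with IrSc = 1 its own "completely irreplaceable"
class, making the bands a partition of [0, 1]. Counting "selected"
wetlands uses IrSc ≥ 0.6 throughout.

Two oracles accompany the annealer. The greedy heuristic (same add rule,
reverse-addition-order prune, lowest-index tie-breaks) is deterministic and
always feasible. The exact solver enumerates all subsets of PUs holding
counts (vectorised, ≤ 20 such PUs) with integer-exact feasibility and
returns *all* co-optimal sets, enabling tie-aware checks of selection
frequencies. No installed ILP solver was available, and at oracle scale
exhaustive search is both faster to trust and exact.

## Phases, functional classes, type contrast

Years are classified from total annual flow with type-7 (numpy default)
quantiles: dry strictly below the 0.25 quantile, wet strictly above the
0.75 quantile, else normal; constant flow therefore yields no extreme
years. Strict inequalities are a deliberate convention — quantile ties at
the cutpoint fall into "normal".

Functional classification takes the arithmetic mean of per-year IrSc over
each phase's years (the alternative — re-running the prioritisation on
counts pooled within a phase — is available but not the default). With
threshold 0.6: refuge if the dry mean reaches the threshold and the wet
mean does not; breeding in the converse case; "both" if both do; otherwise
neither. The threshold is inclusive (≥ 0.6) on both sides.

The wetland-type contrast computes, per phase,
`score_type = (Σ_{i∈type} IrSc_i) / area_type`, normalised to proportions;
for the chi-squared test each phase's proportions are rescaled to that
phase's total summed IrSc. The test is Pearson's chi-squared on this
area-corrected, generally non-integer table — a contrast of score
distributions rather than a count-based test; its p-values should be read
as descriptive support, not as an exact sampling-theory test.

Annual prioritisations reuse the same base seed for every year, so two
years with identical counts receive identical IrSc vectors; the pipeline
assigns each stage (sweep, annual, drivers) its own seed derived from the
master seed by a fixed counter scheme (`seed + 100000·k`), recorded in the
report.

## Drivers analysis

Predictors (log-transformed total flow, year, regional rainfall, annual
climate index) are centered and scaled to sample sd 1 (n−1). Collinearity
is screened by iteratively removing the largest VIF ≥ 5 (highest column
index on ties; perfect collinearity surfaces as infinite VIF).

All predictor subsets are enumerated (full enumeration up to 20
predictors). Each submodel is fitted by maximum likelihood with an
intercept — Gaussian via least squares with the error variance profiled
out, Poisson via IRLS — and weighted by `exp(−BIC/2)` with
`BIC = −2·loglik + k·ln(n)`, where `k` counts all estimated parameters
(for the Gaussian family this includes the error variance; being common to
all submodels it shifts every BIC equally and leaves the weights
unchanged). Occam's window (default odds 20) optionally discards models
far behind the best before renormalising. Reported per term: posterior
inclusion probability (summed weights of containing models), the
unconditional model-averaged coefficient (0 where excluded) and the
inclusion-conditional value, and an sd from the law of total variance
(within-model squared standard errors plus between-model spread). With
standardized predictors and Gaussian errors every submodel's intercept is
the response mean, so the averaged intercept equals mean(y) exactly.
Goodness of fit is Efron's pseudo-R², the squared Pearson correlation of
observed and model-averaged fitted values.

Selection frequencies are not Poisson-distributed on [0, 1]; when a PU's
IrSc series is the response, the pipeline models the integer selection
count `IrSc·R` (out of `R` runs), whose coefficients differ from a
rate-scale model only through a constant offset. Per-PU driver models are
restricted to PUs with nonzero IrSc in at least five years, and by default
enumerate a reduced predictor set (flow, year, climate index — 8 submodels
per PU) so that a basin-scale run stays cheap; the full covariate set is a
parameter away.

## The synthetic generator

The generator emulates the statistical structure of a boom–bust survey
record, not any particular river basin:

- **Flow**: `log flow_t = μ + φ(log flow_{t−1} − μ) + β_soi·soi_t + ε_t`
  with `ε ~ N(0, σ²)`; defaults μ = 9 (≈ 8,100 volume units), φ = 0.5,
  σ = 0.8, β_soi = 0.3. The climate index is its own standardized AR(1)
  (persistence 0.75). Rainfall regions are lognormal around fixed means
  with per-region log-scale correlation to standardized flow (0.2–0.7;
  in-basin rain couples tightly, remote regions weakly) — heterogeneous on
  purpose, as a continental rainfall field is not a single noisy copy of
  basin flow.
- **Abundance**: species totals `λ_{s,t} = N_s · exp(γ_s z_t)` with `z_t`
  the standardized log flow; boom elasticities `γ_s ~ U(0.6, 1.4)` and
  baselines `N_s` lognormal around 20,000. PU shares are
  `w_{i,t} ∝ r_i + f_i · max(z_t, 0)`: the refuge weight `r_i` acts every
  year, the flood weight `f_i` only in wet-signed years. Counts are
  negative binomial (size k = 5) around `λ_{s,t} w_{i,t}` — aerial counts
  are strongly overdispersed; k is a surfaced parameter, with `None`
  giving the Poisson limit.
- **Ground truth**: roles are assigned by stratified weight draws (refuge:
  high `r`, negligible `f`; breeding: the converse; "both": both high;
  default 8 + 8 + 2 of 60 PUs) and recorded via fixed cutoffs (geometric
  mean of the high and low weight levels), so recovery tests score against
  an unambiguous truth table. The recovery preset uses a 20:1 weight
  contrast, 12 species, 60 PUs, 30 years.

What the generator does *not* emulate: observation/detection error,
species interactions, spatial dispersal or site fidelity, within-year
seasonality, and survey-band geometry. Passing recovery tests shows the
pipeline correctly inverts the generator's habitat structure under heavy
count noise; it does not certify performance on real surveys, whose
habitat-use signal may be weaker or confounded.

## Problem sizes and defaults in tests

The test suite and the acceptance script run reduced but structurally
faithful problems, chosen as the package's own working scale: oracle
comparisons use 50 random 12-PU/6-species instances at the default 100,000
annealing iterations; the recovery check uses the 60-PU/12-species/30-year
preset with R = 200 solutions of 5,000 iterations each (ample for 60-PU
problems, where annealing converges quickly); the fixture checks use
R = 100. The survey-scale configuration (R = 1000, 100,000 iterations,
~1,300 PUs, 52 species) is the library default and runs in minutes per
scenario thanks to the compiled annealing kernel.

## Degenerate inputs and tie-breaking

- Species with zero total abundance get `T_s = 0` and are ignored by both
  the objective and feasibility; an all-zero year yields an empty solution.
- Greedy ties break on lowest PU index; the exact solver orders co-optimal
  sets lexicographically and reports the first.
- `marginal_increase` after a zero count is undefined: flagged NaN with a
  warning (later increments remain valid). Percent increases are rounded
  to the nearest integer percent.
- An all-zero IrSc vector leaves type proportions undefined (NaN, warned);
  a wetland type with zero mapped area but positive IrSc is an error.
- Zero-count PUs are retained in written scenario files; under constant
  costs they are never selected.

## Known limitations

- The exact solver is an oracle, not a production solver: 20 PUs max.
- Occam's window is applied by posterior odds against the single best
  model; the stricter "leaps and bounds" pre-search of large model spaces
  is unnecessary at ≤ 20 predictors and is not implemented.
- The chi-squared contrast inherits the caveat above about non-integer
  tables.
- Reproduction of survey-scale headline numbers requires the original
  survey export, which this repository cannot redistribute; the
  corresponding acceptance test fails loudly in its absence rather than
  passing vacuously.
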