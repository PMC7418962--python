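# Methods

This note documents the statistical procedures implemented in `cheimp`,
the conventions adopted where several are in circulation, and what the
synthetic-data tests do and do not establish.

## Model and procedure

The pipeline treats one cross-sectional household expenditure survey at
a time. Inputs per household are counts of adults (15+) and children
(14 and under), monthly food expenditure under two definitions (the
narrow "WHO" definition excluding alcohol, tobacco and food away from
home; the broad "WB" definition including them), total monthly
consumption, monthly out-of-pocket (OOP) health payments net of
insurance premiums and reimbursements, and a positive survey weight.
Analysis proceeds in order:

1. **Equivalence.** he = (A + αK)^θ. Per-capita scaling overstates the
   needs of large households because children cost less than adults and
   part of consumption is shared; α and θ encode those two effects.
   Non-integer counts are rejected rather than coerced, since a
   fractional person count always signals an upstream join or
   aggregation error.
2. **Food shares and the subsistence band.** wf = f/x using the narrow
   food definition (the poverty-line formula is written in terms of
   that f, so the band and the line use it consistently). Households
   with x = 0 are excluded with a logged count before any share is
   formed. The band is the 45th–55th percentile of wf; a household on
   either boundary value is inside (inclusive comparisons), so tied
   households are never split.
3. **Poverty line.** ℓ is the weighted mean of fe = f/he over the band,
   per adult equivalent per month, computed per dataset and never
   pooled across surveys. Subsistence is s = ℓ·he.
4. **Capacities to pay.** ctp_who = x − s when s ≤ f and x − f
   otherwise (household currency); ctp_wb = x/he and ctp_nf = z/he
   (currency per adult equivalent), where z = x − food_wb uses the
   broad food definition.
5. **Flags and incidence.** The OOP share is oop/ctp; catastrophe at
   threshold κ is share ≥ κ (inclusive); impoverishment is x ≥ s and
   x − oop < s. Incidence is the weighted percentage of flagged
   households with a normal-approximation confidence interval.

## Conventions and why

**Weighted quantile.** Defined as the left-continuous inverse of the
weighted ECDF: the smallest *observed* value whose cumulative
normalised weight reaches the requested level, with no interpolation.
This makes the estimator deterministic and order-statistic-valued, and
it guarantees a non-empty percentile band: the upper quantile is itself
an observed food share, so at least one household always qualifies.
Both band percentiles are computed weighted, for consistency with the
weighted poverty-line mean they feed.

**Literal OOP share.** `ctp_wb` and `ctp_nf` are per adult equivalent
while OOP is a household total, so the default ratio oop/ctp mixes
scales. It is kept as the default deliberately: it is the form the
three-capacity comparison is defined in, and it produces the
characteristic ordering in which equivalence-based incidence exceeds
subsistence-method incidence. The `equivalise_oop` switch divides OOP
by he first, which cancels he algebraically and reduces the wb and nf
shares to oop/x and oop/z — the convention used in parts of the
literature. The cancellation is property-tested as an exact flag
identity.

**Inclusive threshold.** Catastrophe uses ≥, so a share exactly at κ is
flagged. A household with positive OOP and zero capacity gets an
infinite share and is flagged at every threshold (and counted in the
diagnostics); zero OOP with zero capacity yields share 0.

**Confidence intervals.** The variance is the Horvitz–Thompson-style
sum Σω²(c − p̂)² over the squared total weight, with a normal quantile
and truncation to [0, 100]. Stratum and cluster identifiers are not in
the data schema, so design effects beyond unequal weighting are not
reflected; CI widths should be read as approximate. Incidence
denominators are weighted households, not persons.

**OOP inside totals.** OOP is assumed to be included in reported total
and nonfood expenditure; no netting-out occurs before capacities are
formed. The schema invariant 0 ≤ oop ≤ x − food_wb enforces
consistency with that reading.

## Tunable parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| α (child cost) | 0.5 | – | each child counts as half an adult |
| θ (scale economy) | 0.9 | – | θ = 1, α = 1 recovers household size |
| band | 0.45–0.55 | proportion | food-share percentile band |
| κ thresholds | .05, .10, .15, .25, .40 | proportion | inclusive |
| equivalise_oop | false | – | see above |
| ci_level | 0.95 | – | normal approximation |

## Synthetic data generator

The generator emulates the structural features the estimators rely on,
each from its own named random stream derived from the master seed (so
adding a variable never perturbs existing draws):

- composition: adults = 1 + Poisson(1.7), kids = Poisson(1.3) — about
  2.7 adults and 1.3 children per household on average, with at least
  one adult always;
- living standard: per-adult-equivalent total expenditure is lognormal
  (μ = 6.8, σ = 0.9 on the log scale, a median near 900 currency
  units/month with heavy right skew);
- Engel curve: logit(wf) = 2.5 − 0.45·log(x/he) + N(0, 0.35²), clipped
  to [0.02, 0.95] — the food share declines with living standard, with
  a mean share near one third;
- food definitions: food_who = food_wb × Beta(8, 1.2), a ratio around
  0.87;
- OOP: zero with probability 0.55, otherwise lognormal (μ = 3.5,
  σ = 1.5) capped at 95% of nonfood expenditure so every schema
  invariant holds by construction rather than by rejection;
- weights: lognormal(0, 0.5).

These magnitudes are a qualitative emulation of a middle-income
household expenditure survey — right-skewed budgets, mostly-zero OOP
that is a small budget share when positive, falling food shares — not a
calibration to any particular survey's moments. Features of real
surveys the generator does **not** reproduce: stratified two-stage
cluster sampling (weights are i.i.d.), item nonresponse and reporting
error, recall/diary mode effects, within-year price drift, and any
correlation between OOP and household composition or health need.
Passing tests therefore demonstrate that the estimators implement their
definitions correctly and behave as the theory predicts on data with
the assumed structure; they are not evidence about any real
population's CHE incidence.

The independent poverty-line oracle redraws from the same generating
process and recomputes ℓ naively — pure-Python sort, cumulative-weight
scan for the two band percentiles, weighted average over the band —
sharing no estimator code with the pipeline. Parameter recovery is
checked at 20,000 pipeline households against a 10⁶-draw oracle within
2% relative error, a band dominated by the sampling noise of the band
quantiles at that size.

## Numerical choices

- Quantile comparisons use cumulative weight against q × (running
  total), with the cumulative sum computed in the same left-to-right
  order as a sequential accumulation, so agreement with the brute-force
  oracle is exact rather than within a tolerance.
- CSV output writes floats via shortest round-trip `repr` and input
  parses with round-trip precision, so write→read is bit-exact.
- Results JSON is serialised with sorted keys and fixed indentation;
  identical inputs give byte-identical files.
- Degenerate inputs: empty households, zero-total households, zero
  weights, and food > total are rejected (strict mode) or dropped with
  a logged count (lenient mode); an empty band cannot occur under the
  ECDF quantile but is guarded regardless.

## Problem sizes used in checks

The shipped test and reproduction scripts use 50 simulated surveys of
2,000 households for the monotonicity/dominance/impoverishment sweeps,
one 20,000-household survey for the headline run and parameter
recovery, a 10⁶-draw Monte-Carlo oracle, and 1,000 random instances for
the quantile oracle sweep. These sizes make the Monte-Carlo error small
relative to every asserted tolerance while keeping a full run to
seconds.

## Known limitations

- No design-based variance (strata/PSUs out of schema scope).
- The WHO cross-country food-share elasticity motivating the scale
  (≈0.56) is taken as given, never re-estimated; α and θ are inputs.
- Person-weighted incidence (household weight × household size) is not
  computed.
- The poverty line is survey-specific by design; cross-survey
  comparisons of ℓ require external deflation, which is out of scope.
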