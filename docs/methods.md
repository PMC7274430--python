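# Methods

This note documents the model implemented by `ebis`, the numerical and
statistical choices made, and the provenance of every fixture parameter.

## 1. Model

A project is described by a `ProjectSpec`: an evaluation period of `T`
years, an adoption model, an impact model, a finance model and three
categories of risk factors. One Monte-Carlo draw realizes every uncertain
quantity and rolls the value chain forward year by year.

### 1.1 Value chain

For year `t = 1..T` (discounting exponent equals the year index, so the
first year's net benefit is already discounted once):

| symbol | meaning |
|---|---|
| `TB` | target beneficiary pool (households or hectares) |
| `AR_t` | cumulative adoption fraction in year `t` |
| `B_t = AR_t · TB` | adopters |
| `IB` | baseline income per beneficiary per year ($) |
| `IP = IB · RI` | adopter income ($), `RI` a relative-impact multiplier, or elicited directly |
| `EP_t`, `EB_t` | retained-income multipliers under natural hazards (1 when no hazard) |
| `PR_t = IP·EP_t − IB·EB_t` | productivity impact per adopter ($) |
| `CL = GHGB · GHGC` | climate impact per adopter ($): GHG balance (tCO2e) × carbon price ($/tCO2e) |
| `I_t = B_t · (PR_t + CL)` | total impact ($) |
| `C_t` | project cost in year `t` ($) |
| `REB_t` | 1 once cumulative cost exceeds the realized budget `BD`, else 0; monotone by construction |
| `IA_t = REB_t·I_t·RR + (1−REB_t)·I_t` | impact after budget penalty, reduction rate `RR ∈ [0,1]` |
| `R_t = (IA_t − C_t)/(1+d)^t` | discounted net benefit |

`NPV = Σ R_t`. `ROI = NPV / Σ C_t` with the **undiscounted** cost sum by
default; a `roi_denominator: discounted` option divides by
`Σ C_t/(1+d)^t` instead. Both are defensible conventions; the undiscounted
form is the default because the numerator already carries the discounting
and the denominator is then the nominal amount spent. When all costs are
zero the ROI is undefined (`NaN`, `roi_defined = False`) rather than ±inf.

### 1.2 Adoption

Two modes:

* **direct** — a Beta (or any) prior per year for `AR_t`, elicited from
  expert bands; values are not forced to be monotone because experts may
  genuinely expect dis-adoption.
* **bass** — `AR_t = (1 − e^{−(P+Q)t}) / (1 + (Q/P)·e^{−(P+Q)t})` with
  innovation rate `P > 0` and imitation rate `Q ≥ 0`, drawn once per
  Monte-Carlo draw; the curve is 0 at `t = 0`, non-decreasing and → 1.

### 1.3 Risk factors

Each category is a multinomial with an implicit none-state whose
probability is `1 − Σ p_i` (validation rejects sums above 1). At most one
factor per category is active at a time.

* **Natural** risks re-sample independently every year (a drought this year
  says nothing about next year). The active factor supplies the
  `EP_t`/`EB_t` multiplier distributions for that year.
* **Adoption** risks are realized once per draw (a political crisis is a
  project-lifetime condition). The active factor may attenuate the yearly
  adoption rates (a single multiplier drawn once and applied to all years,
  or explicit per-year distributions), shrink the beneficiary pool, and/or
  shift the Bass `P`/`Q`.
* **Financial** risks are realized once and replace the budget
  distribution, which drives `REB_t`.

Scenarios (`ebis.scenarios`) switch categories on/off and may override
individual factor probabilities; the four standard scenarios are No Risks,
Natural Risks Only, Adoption and Financial Risks Only, and All Risks.

### 1.4 Inference

Inference is forward Monte-Carlo sampling, not exact propagation on a
discretized network. Dynamic discretization solvers answer the same queries
but impose discretization error and external tooling; with a generative
per-year model, forward sampling is unbiased, trivially parallel, and
`n = 5,000–30,000` draws give standard errors well below decision
relevance in seconds on one CPU. Backward queries ("which risk states
dominate the losing futures?") are answered by rejection: `condition_result`
filters the stored draws on a predicate and renormalizes the weights,
raising `EmptyConditionalError` when nothing survives. This agrees with
forcing the conditioning state's probability to 1 (tested to 3 SE) whenever
the predicate is a function of the risk realization alone.

Sampling granularity: lifetime quantities (`TB`, `IB`, `RI`/`IP`, `GHGB`,
`GHGC`, budget, Bass `P`/`Q`, adoption-risk multipliers, `ARF`/`FRF`
states) are drawn once per draw; per-year quantities (`AR_t` in direct
mode, natural-risk states and `EP_t`/`EB_t`, `C_t`) are drawn every year.
Negative samples of inherently non-negative quantities (incomes, pools,
costs) are clamped to 0 and counted in
`SimulationResult.clamped_negative_draws` so heavy clamping is visible
rather than silent.

## 2. Elicitation procedures

* **Normal from percentiles** — exact: `sd = (hi − lo)/(z_hi − z_lo)`,
  mean from either anchor. Residuals of the fitted CDF at the anchors are
  below 1e−9 by construction.
* **Beta from percentiles** — `scipy.optimize.root` in log-parameter space
  on the two CDF residuals; convergence tolerance 1e−6, failure raises
  `ConvergenceError` rather than returning a bad fit.
* **Annual probability from frequency** — `min(count/span, 1)`; a
  homogeneous-Poisson reading (count/span as a rate) capped at 1 as a
  probability.
* **Indicator scale → probability** — linear interpolation between a score
  anchored at certainty and a score anchored at impossibility:
  `p = (score_impossible − score)/(score_impossible − score_certain)`,
  clamped to [0, 1]; a score sd maps to a probability sd by the absolute
  slope. The mapping is invariant to affine rescaling of the score axis.
* **Drought counting (SPI-12 style)** — rolling 12-month rainfall totals
  are z-scored against their own mean/sd; an event opens when the index
  falls to ≤ −1 and closes when it returns to ≥ 0; an event still open at
  the end of the record counts. A zero-variance series has an index that
  never departs its average, so it contains 0 events. Series shorter than
  12 months are an error. The count and span then feed
  `annual_prob_from_frequency`.
* **Pooling effect sizes** — fixed-effect inverse-variance weighting, or
  random-effects via DerSimonian–Laird: `Q = Σ w_i (x_i − x̄_w)²`,
  `C = Σw − Σw²/Σw`, `τ² = max(0, (Q − (k−1))/C)`, then inverse-variance
  weights with `1/(se_i² + τ²)`. Hand-written because no pre-installed
  package exposes DL directly; verified against an independently computed
  frozen oracle.
* **Product distributions** — `IP = IB × RI` is represented as an exact
  product of the two sampled factors rather than a moment-matched normal,
  so skew induced by the product is preserved.

## 3. Reproducibility

`run_monte_carlo(spec, scenario, n, seed)` builds
`numpy.random.SeedSequence(seed).spawn(n)` and gives each draw its own
child generator. Consequences, both tested:

* bit-identical reruns for a fixed `(seed, n)`;
* prefix stability: the first `k` draws of an `n`-draw run equal the
  `k`-draw run, so increasing `n` refines rather than reshuffles.

`compare_scenarios` uses `seed + i` for the i-th scenario so scenarios are
independent but individually reproducible. Exports re-serialize
byte-identically.

## 4. Fixtures and provenance

All fixtures are generated programmatically; nothing binary ships. Each
`FixtureManifest` carries a provenance map (`printed`, `derived` or
`stand_in`) for every parameter path, and every `stand_in` must carry a
note — enforced by tests.

* **Point-mass toy** (`make_point_mass_fixture`) — every distribution is a
  point mass; the docstring records the complete hand arithmetic
  (NPV 45,000 / ROI 1.5 baseline; NPV 7,500 when the budget binds in year
  1; NPV 37,603.30578512396 at `d = 0.1`). It is the zero-tolerance oracle
  for the value chain.
* **Case-like project** (`make_case_like_fixture`) — a five-year
  flood-recession agriculture program. Printed values: budget 89 m$,
  yearly costs (38.27, 11.48, 13, 9.98, 8.86) m$, target pool fitted from
  the 1st/99th-percentile pair (168,000; 280,000) → Normal(224,000; ≈24,072),
  relative impact Normal(1.463, 0.589) from random-effects pooling,
  adoption Beta priors fitted to widening yearly bands, natural-risk
  probabilities (pests 0.15, flood 0.10, drought 0.10) with uniform
  retained-income multipliers, adoption-risk probabilities (political
  0.40, governance 0.25, conflict 0.20) from indicator-scale conversions.
  Stand-ins (values not available from the source material, chosen a
  priori and documented in the manifest notes): baseline income
  Normal(800, 200) $/household/yr, discount rate 0.05, reduction rate
  0.5, GHG balance 0.2 tCO2e and carbon price 5 $/tCO2e, adoption-risk
  multipliers Uniform(0.75, 0.85). Because of the stand-ins the fixture
  reproduces the qualitative scenario ordering (natural risks mild,
  socio-political risks dominant, all-risks lowest), not any published
  numeric table.
* **Random fixtures** (`make_random_fixture(seed, size_class)`) —
  seed-deterministic valid specs ("small": 2–4 years, few factors;
  "medium": 4–8 years, more factors; sizes are this package's own choices
  for test economy) used by round-trip, invariant and mixture-law tests.

## 5. Statistical testing policy

Deterministic oracles are asserted with zero (or 1e−9 floating-point)
tolerance. Stochastic assertions compare a Monte-Carlo estimate against an
independent closed form or an independently seeded second estimate at
3 standard errors. When many stochastic checks run in one test (the
100-fixture mixture-law check), the criterion is family-wise — worst
|z| < 4 and at most 3 beyond 3 SE — because a per-fixture 3-SE rule would
false-alarm with ~24% probability even when the model is exactly correct.
Tolerances were fixed from the statistics, not adjusted after observing
failures.

## 6. Limitations

* Risk factors within a category are mutually exclusive per year/draw; the
  model cannot express a simultaneous flood and pest outbreak in the same
  year, nor correlation between natural hazards in adjacent years.
* Costs are exogenous: a realized hazard does not feed back into spending
  or budget, only the financial risk factor does.
* The Bass curve assumes a fixed eventual ceiling of full adoption of the
  (possibly risk-shrunk) pool; partial long-run ceilings must be encoded
  through the pool itself.
* Rejection conditioning is inefficient for rare events; no importance
  sampling is provided.
* Elicitation helpers fit two-percentile families exactly but cannot
  detect inconsistent expert input beyond ordering checks.
* The indicator-scale conversion is linear by assumption; real
  governance-score/risk relationships may be convex.
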