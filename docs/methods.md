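# Methods

## Model

A paired comparative diagnostic accuracy study observes, for each subject,
the results of two binary index tests (A, the candidate; B, the comparator)
and a binary gold standard. Within each gold-standard stratum the four
possible test-result pairs follow a multinomial law. The study-level data
are therefore eight counts — diseased (A, B, C, D) = (both+, A+/B−, A−/B+,
both−) and non-diseased (E, F, G, H) likewise — and the model for the whole
cohort is a single 8-category multinomial with probabilities
π·p_dis and (1 − π)·p_non, π the prevalence.

Both endpoints are superiority hypotheses on rate ratios: γ₁ = TPR_A/TPR_B
for sensitivity, γ₂ = TNR_A/TNR_B for specificity, each tested two-sided at
level α by a Wald statistic on the log ratio. The variance estimate for
log γ̂₁ on a diseased stratum of size m is

    se² = ((γ̂₁ + 1)·r̂_B − 2·ĵ) / (m · γ̂₁ · r̂_B²),

with r̂_B the observed comparator rate and ĵ the observed both-positive
rate. Inverting the power equation of exactly this test gives the planning
formula implemented in `sample_size`, so planned size and final test are
mutually consistent by construction: the simulated power at the planned
size equals the nominal power up to Monte-Carlo error, which the simulation
suite checks directly.

## Conditional dependence and feasible bounds

Within a stratum the joint agreement probability p₁ (TPPR for diseased,
TNNR for non-diseased) determines the whole probability vector once the
marginals are fixed:

    p = (p₁, m_A − p₁, m_B − p₁, 1 − m_A − m_B + p₁).

Requiring all four cells to be non-negative bounds p₁ by
[max(0, m_B − (1 − m_A)), m_B] with the convention m_A ≥ m_B (the API
refuses swapped marginals rather than silently reordering, since every
downstream formula assumes test A is the better one). The lower clamp at
zero matters only when m_A + m_B < 1 — weak tests — and reduces to the
usual interval otherwise. Equivalently p₁ = m_A·m_B + e, where e is the
conditional covariance between the tests; the bounds map to
e ∈ [−(1 − m_A)(1 − m_B), m_B(1 − m_A)] (clamped likewise).

## Constrained MLE at the interim

With hypothesised marginals substituted, the stratum likelihood is
one-dimensional in p₁. `mle_joint_prob` minimises the negative
log-likelihood with SciPy's bounded scalar minimiser
(golden-section/parabolic, absolute tolerance 1e−10 on the position).
Three numerical conventions:

- a factor with zero count contributes nothing (0·log 0 := 0), so boundary
  MLEs are legitimate whenever the vanishing cell was not observed;
- a candidate p₁ that makes a positively-weighted factor non-positive gets
  an infinite-NLL *sentinel*, not an exception, so the optimiser may probe
  the boundary freely;
- because the bounded minimiser controls the position but not the
  gradient, strictly interior optima are polished by root-finding on the
  score x₁/p − x₂/(m_A−p) − x₃/(m_B−p) + x₄/(1−m_A−m_B+p) in a small
  bracket (Brent, xtol 1e−15), which drives the score below ~1e−8 in
  practice. The exact endpoints are evaluated separately and win ties.

The MLE is carried at full precision into the planning formula; rounding
to three decimals is display-only. Prevalence is re-estimated by its
binomial MLE (the observed fraction diseased) by default; a `design`
option retains the pre-study value for populations where the literature
estimate is judged more trustworthy than the interim one. Re-estimated
totals below the subjects already observed are floored at the interim
size and flagged, since un-recruiting is impossible.

The naive comparator (`naive_reestimate`) plugs the raw observed joint
rates and prevalence into the same formulas in a permissive mode: results
outside the feasible range are returned signed and flagged infeasible
rather than suppressed, because exhibiting that failure mode (e.g. a
negative size when the observed TPPR exceeds both hypothesised
sensitivities) is the point of the comparison. An optional
`rate_precision` rounds the observed rates first, reproducing the
arithmetic of a report that quotes two-decimal interim rates.

## Rounding

Sample-size rounding is an explicit parameter — `nearest` (default), `up`,
`down` — because no single convention is canonical in practice: planners
quote nearest-integer values while conservative protocols round up. Raw
(unrounded) values are always retrievable. Normal quantiles are used at
full double precision; truncating them to two decimals shifts several
borderline integers.

## Monte-Carlo engine

A `Scenario` separates the *design* (hypotheses used for planning,
re-estimation and testing) from the *generating truth* (marginals, joint
probabilities, prevalence used to draw data). The separation is essential
for null scenarios: data are generated with equal true rates while the
study keeps re-estimating under its — now false — alternative hypotheses,
which is precisely the situation whose type-I error needs checking.

Each replicate: draw `interim_n` subjects in one 8-category multinomial;
compute the constrained MLE for the endpoint under study with the design
marginals and the interim prevalence; re-estimate the endpoint size; draw
the shortfall from the same law; pool; run the Wald test at the design α.
No alpha-spending correction is applied at the final analysis — the
pooled data are tested once at nominal level, which is the procedure
whose stability the null simulations confirm. Replicates use independent
`SeedSequence` substreams, so summaries are bit-identical for a given
seed and independent of execution order.

Summary conventions: degenerate replicates (tables where the statistic is
inestimable, e.g. a zero comparator rate) count as non-rejections and are
tallied separately — conservative, and increasingly relevant as the
dependence approaches its positive maximum where the discordant cell
empties. Bias is reported for γ̂ and coverage for its CI; the RMSE of the
final sample size is measured against the closed-form size evaluated with
the design marginals at the *true* joint probability and prevalence (under
a null generating law the true marginals would make the formula undefined,
so the design-marginal reading is the only coherent one). The non-diseased
stratum of a sensitivity scenario defaults to conditional independence at
the design specificities; it only influences the interim prevalence
estimate.

## What the generator does and does not emulate

The generator reproduces the stochastic structure the design assumes:
multinomial sampling, exact marginals, a chosen dependence level, constant
prevalence, instantaneous outcomes. Real studies add verification delay,
drift in prevalence or test performance between interim and completion,
clustered or multi-reader measurements, and missing gold standards. Tests
passing here validate the statistical procedure under its own model, not
robustness to those violations.

## Problem sizes

The simulation checks in the test suite run at desk scale, chosen so the
Monte-Carlo standard error is small relative to each tolerance: 10,000
replicates for null calibration (MC-SE of a 5% rate ≈ 0.0022, tolerance
3·MC-SE ≈ 0.0065), 5,000 for the power floor, and 2,000 per cell for the
mean-size and RMSE trend checks. Interim sizes 50–200 and true TPPR
0.71–0.81 mirror the design with sensitivities 0.9 vs 0.81 at prevalence
0.45.

## Known limitations

- Superiority only; non-inferiority or one-sided variants are not
  implemented.
- Wald asymptotics degrade as the dependence nears its positive maximum
  (the discordant cell probability tends to zero); coverage dips slightly
  there, and degenerate-table tallies should be inspected for small
  strata.
- No group-sequential alpha adjustment is offered; the procedure re-uses
  interim data only through the dependence/prevalence estimates, and the
  simulations support nominal-level testing of the pooled data, but users
  layering additional interim looks would need spending functions beyond
  this package's scope.
- No support for unpaired designs, multi-reader studies, or imperfect
  gold standards.
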