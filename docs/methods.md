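# Methods

## Scope and data model

The package implements the quantitative synthesis of study-level evidence
on a dichotomized tumor marker in hepatocellular carcinoma: nine cohort
studies (1435 patients, published 2011–2016, all Asian populations), of
which eight report overall survival (OS), three disease-free survival
(DFS), and one no survival data at all. The packaged characteristics
table carries exactly what the publications printed: identifiers, arm
sizes (marker-high / marker-low), assay (IHC or western blot), follow-up,
endpoints. Per-study hazard ratios and per-feature 2×2 tables were
published only as figures and supplements and are deliberately *not*
transcribed; analyses over real per-study effects are therefore exercised
on synthetic data with the same structure, and the quantities that *are*
desk-checkable (patient totals, subgroup totals, the identity pool of the
headline estimate) are checked exactly.

One study reports 153 + 98 = 251 classified patients out of 252; the
record keeps the discrepancy (the invariant is `n_high + n_low ≤ n_total`,
with equality only when every patient was classifiable). Sex counts
reported as "NR" are missing values and drop out of sex denominators, never
zeros. Proportions are displayed rounded half-up to 0.1%.

## Effect extraction

All evidence is converted to a natural-log effect with standard error.

**Reported HR + 95% CI.** `log_effect = ln HR`,
`se = (ln U − ln L) / (2 z)` with `z = 1.959964` kept at full precision so
that CI → SE → CI round-trips reproduce a log-symmetric interval to
display precision. Degenerate (zero-width) CIs are rejected rather than
given `se = 0`. Published intervals that are not exactly log-symmetric
round-trip only approximately; this is a property of the intervals, not of
the transform.

**2×2 tables.** Woolf's method. The 0.5 continuity correction is added to
all four cells only when some cell is zero, matching the behavior of the
standard meta-analysis packages rather than an always-add convention.

**Digitized KM curves.** The publications that did not report an HR were
digitized from their survival figures; this package consumes the
already-digitized (time, survival) pairs. Reconstruction uses the
piecewise-exponential observed-drop method: the common span (restricted to
where both curves are positive) is split into `n_intervals` equal
intervals (default 5, a typical figure-reading granularity); intervals in
which either arm shows no drop are merged forward so every contributing
interval has events in both arms (this merge rule is symmetric in the
arms, which makes the estimator exactly antisymmetric under arm swap). In
an interval `[t1, t2]`, each arm's cumulative-hazard increment is
`−ln S(t2)/S(t1)`, the interval log HR is the log ratio of increments, and
its variance is `1/d_high + 1/d_low` with events
`d = n_at_risk · (1 − S(t2)/S(t1))`. Numbers at risk come from the
figure's at-risk row when available; otherwise the initial n is depleted
by the estimated events plus an optional exponential censoring rate
(default 0, i.e. no censoring assumed before the span end — adequate for
the follow-up spans here; a nonzero rate widens the variances without
moving the point estimate). Intervals are combined by inverse-variance
weighting and the estimate is flagged `km_curve` in its provenance.

On noise-free exponential curves sampled monthly the method is exact; on
simulated digitizations at n = 200/arm the mean log-HR bias is measured by
the test suite and stays below 0.05.

**Precedence.** When a study reports several estimates for the same
endpoint, multivariate beats univariate beats curve-derived, because
multivariate estimates adjust for confounders; ties resolve to the first
listed, so selection is deterministic.

## Pooling engine

Fixed-effect weights are `w_i = 1/se_i²`; Cochran's
`Q = Σ w_i (y_i − ŷ)²` has `k − 1` df under homogeneity and
`I² = max(0, (Q − df)/Q) × 100`. The random-effects model is
DerSimonian–Laird — the moment estimator
`τ² = max(0, (Q − df) / (Σw − Σw²/Σw))`, then re-pooling with
`w*_i = 1/(se_i² + τ²)`. DL is what the mainstream review software
computes, so both models coincide with the published convention; no
Hartung–Knapp adjustment and no iterative τ² estimators are offered.
With `τ² = 0` the random-effects result equals the fixed-effect result
bit-for-bit, a tested invariant. Significance conventions are fixed:
association at p < 0.05 (two-sided normal z), heterogeneity flagged only
when both I² ≥ 50% **and** the Q-test p < 0.1.

Because the eight OS studies pool with I² ≈ 12%, fixed and random results
agree at display precision and the pipeline emits both rows rather than
guessing which one a given published table used.

**Subgroups.** Each subgroup is pooled with the chosen model; the
between-subgroup statistic is `Q_between = Σ_g w_g (est_g − est_all)²`
with `w_g = 1/se_g²` and `est_all` their inverse-variance combination,
chi-square with `G − 1` df — the fixed-effect-over-summaries convention of
the standard software. Subgroup rules are declarative range predicates
over declared study fields (`*_min` inclusive, `*_max` exclusive, so the
printed complementary pairs — before/after 2015, </≥ 150 subjects, </≥
100 months, NOS >6 — partition exactly). A study missing a tested field
never matches, and survival subgroups never claim the study without
survival data. NOS quality scores of the real studies were published only
in a supplement; the quality subgroup therefore runs on synthetic scores
only.

**Sensitivity.** Leave-one-out re-pools each of the k reduced sets in
input order, carrying each reduced set's own Q and I².

## Publication bias

**Begg** (rank correlation, Begg–Mazumdar variant): deviates
`t_i = (y_i − ŷ_fixed)/√(v_i − 1/Σv_j⁻¹)` are correlated with the
variances via Kendall's S; the normal approximation uses the tie-corrected
variance and a continuity correction of 1 on S. The two-sided p is
reported uncapped (some software folds p to 1; that convention is not
reproduced). **Egger**: unweighted OLS of the standardized effect on
precision; the intercept's t statistic has `k − 2` df, matching the
printed t/df convention. All-equal standard errors make the regressor
collinear with the intercept and are rejected explicitly. Both tests
require k ≥ 3 and are order-invariant; scaling all SEs by a common factor
leaves Begg's p unchanged.

With only eight studies both tests are low-powered and conservative
(measured type-I error ≈ 2–5% at nominal 5%); this mirrors their role in
the source analysis, where they serve as a sanity check rather than a
sensitive detector.

## Bootstrap re-sampling

The re-sampling procedure validates a 2×2 association at patient scale:
tables are expanded into `Σ(a+b+c+d)` (exposure, outcome) pairs in
deterministic order (study order, then cells a, b, c, d); each of 1000
groups draws 5000 pairs with replacement from the pooled pool; each
group's OR (Woolf, 0.5 correction on zero cells) forms the group-OR
distribution; and the single 2×2 accumulated over all 5,000,000 draws
gives the combined OR with Woolf CI. Drawing a group is implemented as a
multinomial over the four cell probabilities — exactly equivalent to
5000 individual with-replacement draws — and each group gets its own RNG
stream spawned from the root seed, so the output is reproducible and
independent of any parallelization or execution order.

Structurally, the combined OR converges to the plug-in OR of the input
tables (relative deviation below 0.5% at 5×10⁶ draws for tables with all
cells ≥ 50 — a ~3σ bound, since the multinomial SD of the deviation is
about 0.18%), and the combined CI width at that size is below 0.02 on the
OR scale near OR 1.7 and shrinks as 1/√N. Pooling the 1000 groups as
pseudo-studies (fixed model) agrees with the combined table within
Monte-Carlo error; both estimators target the same plug-in quantity. The
original source's resampling program is not available, so whether it
resampled within study is unknown; pooled resampling is the default and a
stratified mode (per-study draws allocated proportionally to study size)
is provided as a config flag without any claimed equivalence.

The group distribution is summarized by min/max and quantiles; a
percentile CI on the group distribution is deliberately not offered — the
headline interval is the combined-sample Woolf CI.

## Synthetic data generator

The survival generator emulates what the analysis assumes about the source
cohorts: k = 8 studies of 70–300 patients, marker-high probability 0.54
(the observed 54.2% prevalence), per-study true log HR ~ N(ln 1.8, 0.1²)
(the headline pooled HR with mild between-study spread consistent with
I² ≈ 12% at these SEs), exponential event times with marker-low hazard
0.01/month (≈ 70% events by 120 months, matching the 60–140-month
follow-ups), independent exponential censoring at 0.003/month truncated at
the follow-up cap, and product-limit curves emitted on a monthly grid (the
granularity a human digitizer produces). Each study reports its
closed-form proportional-hazards MLE — for exponential data the event-rate
ratio `ln((d₁/T₁)/(d₀/T₀))` with variance `1/d₁ + 1/d₀`, cross-checked in
the tests against a semiparametric Cox fit — plus the KM curve pair, so
both extraction paths see the same patients. The contingency generator
draws 2×2 tables from the multinomial implied by exposure probability
0.54, baseline outcome probability 0.30 and true OR 1.7 via the logistic
relation.

All generators are pure functions of their config including the seed.
What they do *not* emulate: non-proportional hazards, informative
censoring, digitization noise beyond grid discretization, assay-cutoff
heterogeneity between studies, and selective publication. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated model, not robustness of the scientific
conclusion to violations of it.

## Numerical conventions and degenerate inputs

`z = 1.959964` everywhere internally; rounding only at display (4
significant digits in report tables). Identical SEs across studies are
fully supported in pooling (no jitter); they are rejected only where they
are genuinely unidentifiable (Egger). Empty inputs, mixed log-HR/log-OR
scales, k below a test's minimum, flat KM curves, non-overlapping spans,
single-level patient pools and zero-width CIs raise typed errors naming
the offending study or field. I² is floored at 0 when Q ≤ df. Weights are
reported normalized to sum 1.

## Verification strategy and problem sizes

Every statistic is tested against an independently coded brute-force
oracle (spreadsheet-style arithmetic, exhaustive pair enumeration for
Kendall's S, closed-form OLS) to 1e−9 on small instances, and the DL
engine is additionally cross-checked against `statsmodels`'
`combine_effects`. Calibration checks use the generator at the study
conditions: 2000 replicates for random-effects CI coverage (observed
within 92–97% at k = 8), 500 replicates for each bias test's type-I error
(within 2–10% at α = 0.05), 500 replicates for generator-level CI
coverage, and 200 replicates for KM-reconstruction bias; these sizes give
Monte-Carlo standard errors comfortably below the width of the asserted
bands while keeping the whole suite around ten seconds.

## Known limitations

- The real per-study HRs and 2×2 tables are not in the packaged data, so
  the published pooled effect values themselves are not recomputed from
  real inputs; the package checks instead everything that is exactly
  checkable plus the full machinery on synthetic twins of the conditions.
- KM reconstruction inherits the usual caveats of curve-derived HRs:
  piecewise-exponential approximation, estimated event counts, and no
  access to censoring patterns unless the at-risk row is supplied.
- Begg/Egger at k = 8 have very low power; a non-significant result is
  weak evidence of absence of publication bias.
- The synthetic NOS scores make the quality subgroup a demonstration of
  the mechanism, not a reconstruction of the published quality split.
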