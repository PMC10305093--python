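# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real survey data.

## Scoring and the missing-data policy

Each instrument is scored by summing per-item contributions defined in a
versioned item map (YAML). Three missing-data codes are distinguished in
the data dictionary — refused (901), not asked (902), don't know (903) —
and all count as missing for scoring. The default policy is
`max_missing_allowed = 0` for every instrument: a single missing item
makes the score non-evaluable. This mirrors an exclude-don't-impute
analysis design; prorating (rescaling the observed sum to the full range)
exists for the severity/IADL scales but is off by default. A record with
an entire section missing is always non-evaluable, never scored 0.

The shipped item maps are synthetic demo inventories with the documented
instrument ranges (COGSCORE 0–9, RELSCORE 0–6, CERAD recall 0–10, EURO-D
0–12, DSRS 0–54 over 12 graded items, Lawton 0–8). They exercise the
engine; they are not the published item sets.

## Caseness

The diagnostic algorithm is external configuration: a logistic linear
predictor over named scores with a caseness threshold, or an ordered
rule chain for algorithms published as decision rules. Records missing
any required input are non-evaluable and excluded from the analysed
denominator by the completeness filter, which logs exclusions by reason
and conserves counts (retained + excluded = input).

Tie handling at the threshold is not standardised anywhere we know of;
this implementation uses `probability >= threshold` (ties are cases) so
the rule is deterministic and testable.

## Weighting and estimation

Demographic cells are age band (65–69, 70–74, 75–79, 80+; the top band
open because small old-age cells are otherwise unstable) × sex ×
literacy. Two weighting routes:

- **Direct post-stratification** when the full national
  cross-classification is available: weight ∝ population share / sample
  share per cell. A non-empty sample cell with zero population share is
  resolved by collapsing age bands within sex × literacy (logged), or
  fails if collapsing is disabled.
- **Raking (IPF)** when only the three marginal tables exist: sequential
  proportional adjustment over the margins, iterated until every weighted
  margin matches its population margin to 1e-8 (as shares), at most 100
  sweeps, error on non-convergence.

Weights are normalised to sum to the sample size (mean 1), which keeps
the Kish effective sample size interpretable. Unweighted prevalence CIs
are Wilson score intervals; weighted CIs are logit-scale intervals with
`se = 1/sqrt(n_eff p (1-p))`, `n_eff = (Σw)²/Σw²`. Survey reports rarely
name their CI method, and printed intervals alone cannot identify it, so
both families are explicit here and swappable. At boundary estimates
(p = 0 or 1) the logit interval degenerates and the Wilson interval at
n_eff is used instead; intervals are clamped to bracket the point.

The precision-based sample-size formula is
`n = ceil(z² p (1-p) / d²)` for estimating a proportion p to half-width d
— at p = 4.5%, d = 0.9%, 95% confidence it gives n = 2039.

## Associations

Effect models are unweighted GLMs on the analysed cohort: binomial for
odds ratios, Poisson with log link for prevalence ratios. Because the
outcome is binary, the Poisson model's variance is misspecified, so
prevalence-ratio CIs use an HC0 sandwich variance (the literature rarely
states the estimator; this is our documented choice). Age adjustment
enters as age-band indicators. Reference levels: 65–69, female,
illiterate. Separation or non-convergence withholds the estimate and
flags the diagnostic rather than reporting a huge CI. Pearson chi-squared
uses no continuity correction (configurable at the call site). No
multiple-testing adjustment is applied anywhere, matching standard
practice in prevalence reports; interpret nominal p-values accordingly.
Mantel–Haenszel pooled ratios (risk ratio by default; the odds-ratio
pooling and MH chi-squared come from
`statsmodels.stats.contingency_tables.StratifiedTable`) summarise the
literacy-by-sex gap; a single stratum collapses to the crude ratio.

## Convergent validity

Hedges' g uses the df-weighted pooled SD and the small-sample correction
J = 1 − 3/(4 df − 1); sign convention is cases minus non-cases, so
impairment-coded outcomes (DSRS, RELSCORE) yield positive g and
ability-coded outcomes (COGSCORE, Lawton) negative g. A zero pooled SD is
an undefined-effect error, not ±∞. Group-difference p-values use Welch's
t-test (our choice; not claimed to reproduce any published test).

"AUC" in this survey literature means balanced accuracy of binary-vs-
binary agreement, (sensitivity + specificity)/2 — not a ROC integral —
and is implemented exactly so under the name `balanced_auc`. Its CI is a
seeded nonparametric bootstrap over records (default 2000 resamples;
replicates that lose a reference class fall back to the point estimate).

## The synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not any real
population:

- ages from a truncated normal on [65, 105] whose location is solved by
  bisection so the expected observed (floored) age equals the scenario's
  mean-age anchor (left truncation would otherwise inflate it); the
  realized SD is slightly below the nominal scale, an accepted
  consequence of truncation;
- sex and sex-specific literacy probabilities chosen to emulate observed
  literacy gaps (risk ratios ≈ 2.5 and ≈ 1.73 in the two default
  scenarios);
- latent caseness per demographic cell from a logistic model with stated
  odds ratios (age-band ORs 1.7/2.8/4.5, male 0.7, literate 0.5);
- item responses conditional on caseness only: per-item Bernoulli (or
  graded binomial) draws with class-specific success probabilities, so
  scores are stochastically ordered by caseness;
- a recruitment flow (listed → ineligible → recruited) and instrument-
  level missingness, either exact planted counts (disjoint record sets,
  used by the default scenarios: 2216 − 106 → 2110 and 490 − 82 → 408,
  with 64 of the small cohort's exclusions being refusals of the
  depression screen) or independent per-record rates, MCAR by default
  with an optional MAR tilt.

Because item totals are class-conditional binomials, the exact posterior
log-odds of caseness is **linear** in the four algorithm scores. The demo
algorithm spec is therefore derived, not fitted: coefficients are the
per-item log-likelihood-ratio weights, and the threshold is calibrated on
the exact convolution of the score distributions so the expected
classified prevalence equals the scenario's true prevalence. With that
matched spec, pipeline prevalence converges to scenario truth (verified
at n = 20 000 within ±1 percentage point) and classification accuracy is
~99%.

Scenario prevalences are arbitrary test values (overall 27.9% and 12.5%
in the two defaults, magnitudes chosen for realism); national 65+
population totals (15.4M, 3.6M) exist only to exercise the extrapolation.
The latent truth (caseness, severity, cell prevalence) is written to a
sidecar file and never into analysis inputs — a schema test enforces it.

**What passing tests do not show.** Real questionnaire data have
correlated item errors, education- and culture-dependent item
functioning, informant disagreement, non-MCAR refusal and interviewer
effects; none of these are generated. Passing the suite demonstrates the
*pipeline arithmetic* — scoring, filtering, weighting, estimation and
their contracts — not the field validity of any diagnostic algorithm.

## Numerical choices

- Raking tolerance 1e-8 on margin shares, max 100 sweeps.
- Threshold ties classify as cases; cut-off rules are disjunctions of
  conjunctive predicates evaluated with exact comparisons.
- Percentages print at one decimal, half-up; CSV floats serialize at
  fixed `%.8g` precision so re-runs are byte-identical.
- Bootstrap and simulation randomness flow from a single seeded
  `numpy.random.Generator` per run; seeds are echoed in all metadata.
- Problem sizes in the test suite: the two default scenarios (2216 and
  490 records), 200-replicate studies at n = 2000 for estimator recovery
  and coverage, a 100-replicate permutation null at n = 200, and one
  n = 20 000 convergence check — sizes at which Monte-Carlo error is
  small relative to the asserted tolerances.

## Known limitations

- The shipped algorithm/cut-off configs are synthetic stand-ins; results
  on real data require the validated coefficient sets.
- Weighted CIs ignore the variance effect of estimating the weights
  themselves (standard for post-stratification at this scale; a design
  with many tiny cells would need replication variance).
- Effect models are unweighted by design, mirroring common practice of
  reporting unweighted association tables alongside weighted prevalence.
- The rule-chain caseness path reports probabilities only as 0/1.
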