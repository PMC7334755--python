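# Methods

This note documents the models, numerical choices and calibration behind
`eyescreen`: what is assumed, what the defaults mean, and what passing tests
do and do not establish.

## Acuity representation

Distance acuity is stored as a Snellen fraction (test distance / denominator,
both in metres) with logMAR = log10(denominator/numerator) as the canonical
comparison scale: 6/6 = 0.0, 6/60 = 1.0, larger is worse. All ordering,
thresholding and banding is done on logMAR, so equivalent fractions (6/12,
3/6) are the same acuity. Two choices worth making explicit:

* **"Worse than 6/12" is strict.** An eye at exactly 6/12 does not trigger
  referral; the rule fires only above logMAR 0.301.
* **All acuities are presenting (unaided, as measured).** The package does
  not model correction; if your data are best-corrected, the thresholds mean
  something different and the referral rule's intent (detect people who
  currently cannot see) is weakened.

Reporting bands follow the survey convention on the better eye: 6/6–6/12
(normal), 6/18–6/60 (impaired), worse than 6/60 (severe), with band edges
inclusive as written; children under 6 are "not assessed". Whether published
band tabulations use the better eye is usually not stated; better-eye is
assumed here.

## The referral rule and its iterations

A participant record keeps every elicited answer as a tri-state
(yes/no/not-applicable) so "question not asked under this version" is
representable and auditable rather than silently defaulted. Hard invariants:
the guardian question applies exactly to ages under 6; distance acuity is
measured exactly from age 6; near vision (N8 print at 33 cm) from age 40.
All age boundaries are taken literally from the rule wording (child rule
strictly < 6, near vision ≥ 40).

The seven iterations differ on four axes: the catch-all "any eye problem"
question's duration scope (unlimited → today only), whether distance acuity
is mandatory, the pain question's wording (pain → pain or discomfort), and
the near-vision check (added last, 40+ only). Under iterations 1–2 acuity is
consulted only if measured; absence is neither an error nor a trigger. Under
iterations 3–7 a missing mandatory field raises an error naming the field
and iteration — a screening decision is never computed from silently
imputed data. Reason codes are emitted in a fixed canonical order
(child_problem, any_eye_problem, pain_or_discomfort, vision_difficulty,
low_distance_va, near_vision_fail) so outputs are byte-stable.

Two modelling compromises, since a record stores answers, not interviews:
the record's single `any_eye_problem` slot answers whichever duration scope
the data were collected under (the version carries the scope); and the
single `pain_or_discomfort` slot answers whichever pain wording the version
asks. The child rule is applied uniformly across iterations: under-6s are
decided solely by the guardian's report.

## Accuracy statistics

* **Confusion tables** are oriented with the reference standard on rows:
  tp+fn is the count of reference-positive participants, invariant under
  choice of index strategy.
* **Confidence intervals** are Clopper–Pearson exact intervals, computed as
  beta quantiles (low = B(α/2; k, n−k+1), high = B(1−α/2; k+1, n−k)), with
  hard 0 and 1 endpoints at k = 0 and k = n. Exact intervals are used
  because screening validations conventionally report them and because the
  large-sample alternatives (Wilson, Wald) visibly disagree at these sample
  sizes (for 344/378, Wilson's upper bound is 93.5% vs the exact 93.7%).
  The test suite cross-checks against an independent bisection inversion of
  the binomial tail sums and verifies, by full binomial enumeration for
  every n ≤ 25, that coverage never falls below nominal.
* **Cohen's κ** uses the marginal-product chance agreement; degenerate
  marginals (chance agreement 1) leave κ undefined rather than 0/0. The
  verbal bands follow the scheme used in CV-training reports: 0.41–0.60
  moderate, 0.61–0.80 fair, ≥ 0.81 good (this scheme ranks "fair" above
  "moderate"; the banding is applied to the 2-d.p. displayed value).
* **2×2 reconstruction from marginals.** Given n, each rater's positive
  count, and raw percent agreement, the concordant count c = round(p·n)
  fixes the both-positive cell a = (A + B − (n − c))/2; the rest follow from
  the marginals. Non-integer or negative cells mean the printed numbers are
  mutually inconsistent, and the error says which constraint failed. The
  reconstruction is exact — applying percent-agreement and marginal
  extraction to the result returns the inputs (property-tested).
* **Sample size** implements Buderer's precision method:
  cases = ⌈z²s(1−s)/d²⌉ reference positives for half-width d at sensitivity
  s, total n = ⌈cases/prevalence⌉. With s = 0.90, d = 0.05,
  prevalence = 0.30 this gives 139 cases and n = 464. Published designs with
  these same inputs sometimes print different totals (e.g. 517, whose
  derivation is not stated and is not reverse-engineered here); the package
  also reports the achieved half-width for a given case count
  (155 cases → ±4.7%), which is how such designs are best audited.
* **Rounding for display** is half-up at the conventional precisions
  (percentages 1 d.p., κ and odds ratios 2 d.p.). Internal computation is
  never rounded.
* **Logistic regression** delegates to a standard maximum-likelihood fit
  (Newton/IRLS); non-convergence, separation, or infinite standard errors
  raise an error instead of returning an unstable fit. Odds ratios from a
  single binary covariate agree with the 2×2 cross-product ratio to 1e-6
  (cross-checked in tests). The Haldane–Anscombe +0.5 correction is applied
  to 2×2 odds ratios only when a zero cell exists, and never to
  sensitivity/specificity.

## The synthetic population

The simulator exists so the pipeline is exercisable end to end, with known
ground truth, at any size. It emulates a community screening sample rather
than any real epidemiology; its per-diagnosis parameters are **calibration
targets**, not estimates.

Generative process per person: age group → uniform integer age within group;
sex; diagnosis; a Bernoulli reference-referral draw given the diagnosis;
reference-interview answers (pain, vision difficulty, catch-all question in
both duration scopes, guardian report) from per-diagnosis probabilities; a
better-eye acuity band per diagnosis, uniform over the band's discrete
Snellen lines, with the worse eye 0–1 lines below and clamped inside the
band; an N8 result for ages 40+. Screener-observed fields then pass through
a noise channel: every answer flips independently with probability
`symptom_flip_prob` (default 0.03 — a few percent of answers differ between
two elicitations of the same person) and each eye's logMAR gains Gaussian
test-retest noise (`acuity_logmar_sd`, default 0.05 ≈ half a chart line)
before snapping back to the nearest line.

Calibration. Age-group weights (43.9% under 15, …, 2.4% 75+) and the sex
split (62.9% female) are the observed sample proportions. The diagnosis mix
is solved, not guessed: with per-diagnosis referral probabilities r_d fixed,
P(d) = prevalence · share_d / r_d, where share_d is the observed diagnosis
share among referred participants. This makes the referable-conditional
diagnosis distribution match the observed shares exactly and the expected
referable prevalence equal the 65.9% target by construction; remaining mass
is "normal". Referral is probabilistic given diagnosis (conjunctivitis
r = 0.85, refractive/presbyopia 0.95, sight-threatening disease 1.0,
normal 0) because the same diagnosis can be referable or not; the
symptom profiles make conjunctivitis primarily pain-driven and media/
refractive disease vision-driven, which reproduces the observed pattern
that misses are dominated by conjunctivitis while over-referrals are
symptom-driven.

Reproducibility contract: one integer seed, one numpy `default_rng` stream,
single pass; identical seed ⇒ byte-identical fixture files. An alternative
reference standard (`reference_rule=k`) sets the reference referral to rule
k applied to the reference-interview fields, which makes index and
reference identical under zero noise — the self-consistency tests use this.

What the simulator does **not** model, hence what passing tests do not
show about real data: diagnosis is independent of age and sex (so child
"presbyopia" exists, and the near-100% referral rates observed in older age
groups are not reproduced); symptom severity is binary; answers flip
symmetrically and independently; eyes are nearly concordant; no cluster,
household or venue structure; no missingness mechanism. Simulated accuracy
(≈ 91% sensitivity, ≈ 65% specificity at defaults) is in the neighbourhood
of a real community validation but is not a reproduction of one, and no
test asserts that it is.

## Evaluation and counterfactual strategies

`evaluate_iteration` replays a rule over records, excluding (and counting)
records without a reference decision — the STARD-style flow object keeps
eligible = analyzed + excluded explicit. The counterfactual strategies are
defined literally: `va_only` refers on the objective tests alone (distance
acuity, plus near vision at 40+), `symptoms_only` on the two symptom
questions alone, `age40_or_symptoms` refers everyone 40+ regardless of
findings plus younger people with either symptom. Children are decided by
the guardian's report under every strategy, since the counterfactuals do
not address them. By construction the final rule is exactly the union of
the objective and symptom trigger sets (verified by exhaustive enumeration
over a discretized record grid), so its referrals are a superset of either
strategy's.

## File formats

Participant files are UTF-8 CSV with a mandatory header, "NA" as the
missing/not-applicable token, Snellen strings for acuity, yes/no for
tri-states, pass/fail for near vision, refer/no_refer for the reference
decision. An optional `any_eye_problem` column carries the early
iterations' catch-all answer; without it those iterations correctly refuse
to decide rather than defaulting. Population models serialize to JSON.
Validation errors always carry the row number and column.

## Problem sizes in tests and the acceptance script

Statistical checks run at sizes chosen to make Monte-Carlo error negligible
relative to the asserted tolerances: goodness-of-fit and prevalence
recovery on one shared 50,000-person draw (binomial SE ≈ 0.2 percentage
points against a ±2-point tolerance), noise-monotonicity on 12,000-person
draws per grid point with a 1-point slack between adjacent points, logistic
parameter recovery at n = 5,000 against a 3-SE band. The acceptance script
simulates 50,000 participants at the caller's seed.

## Known limitations

* The simulator's independence assumptions above; its specificity is more
  sensitive to the symptom-profile choices than its sensitivity.
* Band-level acuity generation cannot produce within-band heterogeneity
  beyond the discrete chart lines.
* κ banding on displayed (rounded) values means a raw κ of 0.6049 and
  0.6050 can land in different bands — matching how reports band printed
  values, not a statistical claim.
* The decision engine models answers as given; it cannot represent a CV
  re-asking or rephrasing a question mid-screening.
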