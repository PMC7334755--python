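# eyescreen

Referral algorithms for community eye screening, and the statistics used to
validate them.

In task-shifted eye-care programmes, lay community volunteers (CVs) screen
people in the community and refer those with probable eye disease to primary
eye-care services. A smartphone app guides the CV through a short decision
rule: symptom questions, a distance visual-acuity test, and — for people aged
40 and over — a near-vision reading check. `eyescreen` implements such a
referral rule across its seven development iterations, the
diagnostic-accuracy machinery used to validate each iteration against an
ophthalmic clinical officer's (OCO) reference decisions, and a calibrated
synthetic-population simulator so the whole pipeline runs without any study
data.

It is intended for biostatisticians and programme evaluators working on
screening validation: people who need exact binomial intervals, chance-
corrected agreement, and reproducible replays of a rule set over participant
records.

## The rule and the statistics

The final (seventh) iteration refers a participant when any trigger fires:

* age < 6: the guardian reports the child has an eye problem today;
* age ≥ 6: presenting distance acuity worse than 6/12 (logMAR > 0.3) in
  *either* eye;
* age ≥ 6: self-reported eye pain or discomfort today, or difficulty seeing
  far or near objects;
* age ≥ 40: inability to read N8 print at 33 cm.

Earlier iterations used a catch-all "any eye problem" question (first
unlimited in duration, later restricted to "today"), optional rather than
mandatory acuity testing, and pain-only rather than pain-or-discomfort
wording; `eyescreen.catalog()` enumerates all seven.

Validation compares the CV's automated decision with the OCO's on the same
participants. For a 2×2 table with `tp` true referrals, `fn` missed
referrals, `fp` over-referrals and `tn` agreed non-referrals:

* sensitivity `= tp/(tp+fn)`, specificity `= tn/(fp+tn)`,
  PPV `= tp/(tp+fp)`, NPV `= tn/(fn+tn)`, each with an exact
  Clopper–Pearson interval (inverted binomial tails);
* interrater agreement via Cohen's κ `= (p_o − p_e)/(1 − p_e)`, including
  reconstruction of the 2×2 from published marginals and percent agreement;
* precision-driven sample size via Buderer's method
  `cases = ⌈z² s(1−s)/d²⌉`, `n = ⌈cases/prevalence⌉`;
* logistic regression (maximum likelihood, Wald intervals) and 2×2 odds
  ratios for factors associated with correct decisions.

## Worked example

Reproduce the final validation round's accuracy from its 2×2 counts:

```python
from eyescreen import ConfusionTable, accuracy_summary

s = accuracy_summary(ConfusionTable(tp=344, fn=34, fp=43, tn=153))
print("sensitivity:", s.sensitivity)
print("specificity:", s.specificity)
```

```
sensitivity: 91.0% (87.7-93.7)
specificity: 78.1% (71.6-83.6)
```

i.e. the rule caught 91.0% of the 378 participants the reference standard
would refer, and correctly cleared 78.1% of the 196 it would not; the
parentheses are exact 95% confidence bounds.

From the shell, simulate a screening population and evaluate the final rule
against the simulated reference standard:

```bash
$ eyescreen simulate --n 2000 --seed 7 --out pop.csv
$ eyescreen evaluate pop.csv --iteration 7
       label    tp    fn    fp    tn            sensitivity            specificity                    ppv                    npv
--------------------------------------------------------------------------------------------------------------------------------
      iter 7  1164   124   257   455      90.4% (88.6-91.9)      63.9% (60.3-67.4)      81.9% (79.8-83.9)      78.6% (75.0-81.9)
```

Interrater agreement from published marginals alone (59 participants, 44 vs
49 referrals, 84.8% raw agreement):

```bash
$ eyescreen kappa --n 59 --a-pos 44 --b-pos 49 --agreement 0.848
observed agreement: 84.7%
expected agreement: 66.2%
kappa: 0.55 (moderate)
```

Other subcommands: `screen` (per-record decisions with reason codes),
`scenarios` (counterfactual strategies: vision tests only, symptoms only,
refer-everyone-40+), `samplesize`, and `flow` (STARD-style participant
accounting).

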