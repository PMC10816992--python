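# abratio

Positivity thresholds for the plasma Aβ42/Aβ40 ratio, and what a test
result at such a threshold means for an individual's probability of brain
amyloidosis.

## The problem

Brain amyloid-β accumulation precedes the cognitive symptoms of
Alzheimer's disease by years, but confirming it requires a lumbar puncture
(CSF Aβ42) or an amyloid-PET scan. The plasma Aβ42/Aβ40 ratio, measurable
by single-molecule array from an ordinary blood draw, is *lower* in
amyloid-positive individuals and is a candidate screening test — provided
a cutoff is defined. This package implements, for biostatisticians and
clinical researchers, the full cutoff-derivation workflow on a cohort
table of volunteers and memory-clinic patients:

* **Gaussian-mixture cutoff (unsupervised).** After removing outliers by
  the Tukey rule (outside `q0.25 − 1.5·IQR, q0.75 + 1.5·IQR`), the ratio
  distribution of *all* participants — labelled or not — is fitted with a
  two-component, unequal-variance Gaussian mixture by EM. The cutoff is
  the crossing of the two fitted curves, i.e. the root of
  `π₁ φ(x; μ₁, σ₁) = π₂ φ(x; μ₂, σ₂)` between the means, available in
  closed form from the quadratic in the log-density difference.
* **Gini stump (supervised).** On participants with a CSF/PET amyloid
  label, a depth-one decision tree scans every midpoint between
  consecutive distinct ratios and minimises the size-weighted Gini
  impurity `n_L/n·G(L) + n_R/n·G(R)`, `G = 1 − Σ p_c²`.
* **ROC / Youden cutoff.** On labelled participants *without dementia*
  (MMSE ≥ 24), the ROC curve over all cutoffs gives the trapezoidal AUC
  (equal to the Mann–Whitney probability), a DeLong or bootstrap 95% CI,
  and the cutoff maximising Youden's `J = Sn + Sp − 1`.

In every method a ratio **at or below** the cutoff is called plasmatic
Aβ+. A cutoff's sensitivity and specificity then convert into posttest
probabilities through the likelihood-ratio calculus
`LR+ = Sn/(1−Sp)`, `LR− = (1−Sn)/Sp`,
`posttest odds = pretest odds × LR`, with pretest odds `p/(1−p)` from the
age-specific prevalence of amyloid positivity (15.8% at 60, 32.6% at 80).

Deterministic cohort rules are included: amyloid positivity from CSF
Aβ42 < 438 pg/mL or Centiloid > 26; dementia from MMSE < 24/30; APOE ε4
carriage; and a two-year blood-to-amyloid-measurement eligibility window
whose one exception is an older *positive* measurement (amyloid
positivity persists in an untreated cohort).

Because participant-level study data of this kind are rarely shareable, a
seeded synthetic-cohort generator (`abratio.synthetic`) reproduces the
statistical structure the analysis assumes — bimodal ratios,
group- and age-dependent amyloid prevalence, ε4 enrichment among the
amyloid-positive, MMSE tracking dementia status, and randomised
measurement delays — so every stage is testable end to end. See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

```
$ abratio simulate --seed 1 --out cohort.csv
$ abratio thresholds --cohort cohort.csv --seed 1
gmm: 0.0477
stump: 0.0473
youden: 0.0466
```

A synthetic cohort of 365 participants (277 volunteers, 70 AD, 18 non-AD
patients) yields three concordant cutoffs near 0.047: a ratio at or below
~0.047 is called plasmatic Aβ+. The generator's true component curves
cross at 0.0472, so the fitted mixture recovered the cutoff to well
within sampling noise.

```python
>>> from abratio import posttest
>>> r = posttest(0.158, 44/53, 42/73)   # age-60 prevalence; Sn, Sp as count fractions
>>> round(r.pretest_odds, 3), round(100*r.posttest_prob_pos, 1), round(100*r.posttest_prob_neg, 1)
(0.188, 26.8, 5.2)
```

At a screening cutoff with sensitivity 44/53 (83.0%) and specificity
42/73 (57.5%), a 60-year-old without dementia who tests *positive* has a
26.8% probability of brain amyloidosis (up from the 15.8% pretest
prevalence), while a *negative* test lowers it to 5.2% — the pattern that
makes the test useful for ruling out, and for prescreening before
confirmatory CSF/PET.

`abratio report --cohort cohort.csv --seed 1 --format markdown` renders
the full analysis (confusion tables by subgroup, AUC with CI, posttest
grid); `--roc-csv` and `--figure` export the curve.

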