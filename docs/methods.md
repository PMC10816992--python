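# Methods

## Cohort model and fixed classification rules

A participant row carries demographics (age in years, sex), clinical
group (volunteer / AD / non-AD patient), MMSE (0–30), APOE genotype,
plasma Aβ42 and Aβ40 concentrations in pg/mL (the dimensionless 42/40
ratio is computed when both are present), and optionally one or both
confirmatory measurements: CSF Aβ42 (pg/mL) or an amyloid-PET Centiloid
value, with the measurement date.

Fixed rules, applied verbatim and never fitted:

| rule | definition |
|---|---|
| amyloid positive | CSF Aβ42 < 438 pg/mL, or Centiloid > 26 |
| dementia | MMSE < 24/30 |
| ε4 carrier | genotype in {ε2ε4, ε3ε4, ε4ε4} |
| eligibility | \|amyloid date − blood date\| ≤ `window_days`, or amyloid measurement *before* blood draw and positive |

Design choices where the rules leave room:

* **CSF precedence.** When CSF and Centiloid are both present the CSF
  value decides by default (`csf_precedence=False` flips this). The two
  can disagree; precedence is a package decision and the chosen modality
  is recorded in the output.
* **Two years = 730 days.** The window is a fixed day count, no leap-year
  handling; the day difference is an absolute calendar-date difference.
* **Missing MMSE or genotype raise** rather than silently classify,
  because subgrouping (non-demented analyses, carrier stratification)
  depends on them. Missing CSF *and* Centiloid simply mean
  status-unknown, which is a normal, non-error state (unlabelled
  participants still feed the mixture fit).

## Mixture threshold

Outliers are removed once (not iteratively) by the Tukey rule with
quartiles computed by linear interpolation between order statistics — the
common statistical-software default; the convention matters because the
fences move with it, so it is pinned here.

The EM fit is a two-component, unequal-variance univariate Gaussian
mixture, `tol=1e-8` on the log-likelihood, `max_iter=1000`, best of
`n_starts=10` seeded restarts (first start splits the sorted sample at
the median; later starts jitter the means by 0.25× the data range and
scale the spreads by U(0.5, 2)). The log-likelihood is non-decreasing
across iterations and this is asserted in tests. Components are reported
with means in increasing order; component 1 (lower ratio) is the
plasmatic-Aβ+ component.

Two guards handle the known pathologies of this likelihood:

* a variance floor of 1e-12 prevents exactly singular components;
* restarts whose component scales differ by more than a factor 20
  (`min σ / max σ < 0.05`, a Hathaway-style constraint) are discarded as
  spurious: the unequal-variance likelihood is unbounded, and solutions
  with a near-zero-width component sitting on a few points otherwise
  dominate the genuine fit. If every restart is discarded the fit errors
  out rather than returning a spike.

The cutoff is the crossing of the two fitted curves. Equating the
weighted log-densities gives a quadratic in x (linear when σ₁ = σ₂,
solved directly); the root strictly between the means is the threshold,
computed with the numerically stable quadratic formula and verified in
tests against bisection to 1e-10. With extremely unbalanced weights no
root may lie between the means; this raises an error carrying both roots.
By default the *weight-multiplied* densities are intersected — the
posterior-0.5 decision boundary of the fitted mixture, which is the
boundary the mixture itself would classify by. `weighted=False` equates
the raw component curves instead, since a published overlay of two
component curves can be read either way; the weighted form is the
default because it is the one with a decision-theoretic meaning.

## Stump threshold

Candidate cuts are the midpoints between consecutive distinct sorted
values (midpoint, not left-value, convention); the scan is exhaustive.
Ties on the minimal weighted Gini impurity — compared with a 1e-12
absolute tolerance so that last-ulp arithmetic noise cannot override the
rule — resolve to the smallest cut. The left branch (≤ cut) always
predicts amyloid-positive; the direction is fixed a priori by the biology
(amyloidosis lowers the ratio) rather than auto-detected, so a noisy
sample cannot silently flip the test. Training uses all labelled data
with no cross-validation, pruning or class weights; the reported Sn/Sp
are therefore apparent (training) performance.

## ROC, AUC and Youden

The curve has one operating point per distinct observed value plus the
two trivial endpoints. The trapezoidal AUC equals the Mann–Whitney
probability P(x⁺ < x⁻) + ½P(x⁺ = x⁻) (exact equality asserted against a
pair-counting oracle). The default 95% CI is DeLong's, from the variance
of placement values; a stratified percentile bootstrap (B = 2000, seeded)
is available — both are provided because published intervals rarely state
their method. Intervals are clipped to [0, 1]; an all-tied sample has
degenerate zero variance and errors out. The Youden cutoff is the
*observed value* (not a midpoint) maximising J, with ties resolved toward
the higher-specificity (smaller) cutoff, favouring fewer false positives
in a screen-then-confirm chain.

## Posttest calculus

All arithmetic runs on exact count fractions; rounding (half-up, one
decimal for percentages) is applied only at report time. This matters:
chaining pre-rounded percentages changes last digits. One published-style
worked value illustrates it — with Sn = 40/53, Sp = 49/73 and prevalence
15.8%, the exact positive-test posttest probability is 30.107%, whereas
chaining the rounded values 75.4%/67.1% gives 30.0%; similarly exact
LR− values 0.295 and 0.365 print as 0.30/0.37 under half-up but appear
as 0.29/0.36 when truncated. The package reports exact-fraction values.
Specificity 1 yields an infinite LR+ (reported as a sentinel);
specificity 0 leaves LR− undefined and errors. Prevalences outside (0, 1)
are rejected. Pretest prevalence is supplied per age (defaults 15.8% at
60 and 32.6% at 80); no interpolation between ages is applied in the
posttest grid — intermediate ages need a user-supplied prevalence.

## Pipeline

Stage order and the population each stage sees is the defining structure
and is enforced, not optional: eligibility filter → mixture fit on **all**
participants with a ratio (labelled and unlabelled, outliers removed) →
stump on the eligible labelled subset → ROC/Youden on the eligible
labelled non-demented subset → each cutoff evaluated on both labelled
subgroups → posttest grid from the non-demented operating point. Counts
in and out of every filter are logged and reported. With no labelled (or
single-class) participants the supervised stages are skipped with a
recorded warning and the mixture threshold still runs. Reports render to
canonical JSON (sorted keys) or markdown; identical inputs and seed give
identical bytes.

## Synthetic cohort generator

The generator emulates the structure the analysis relies on: a bimodal
ratio distribution whose lower component is the amyloid-positive one;
latent amyloid status drawn per group (AD 0.87, non-AD 0.10, volunteers
from an age-linear prevalence through 15.8% at 60 and 32.6% at 80,
clamped to [0.01, 0.99]); APOE ε4 carriage at 0.70/0.30 given
positive/negative status; MMSE from a non-demented (28.3 ± 1.3, clipped
to 24–30) or demented (20 ± 3, clipped to 0–23) distribution with
group-specific dementia probabilities; group-shaped ages (truncated
normals on [50, 95]); and a labelled fraction per group (all patients,
73/277 of volunteers) split CSF/PET 50:50 with CSF and Centiloid values
drawn uniformly on the correct side of their cutpoints. Blood-to-amyloid
delays are within ±730 days with probability 0.9, otherwise up to ±1460
days (before the blood draw with probability 0.7), so the eligibility
filter, including its positive-scan exception, is genuinely exercised:
the defaults land near 151 eligible labelled participants of whom about
126 are without dementia. Default sizes are 277/70/18. Ratios are
truncated to > 0 by rejection (negligible at the defaults). A
`label_noise` parameter (default 0) flips the observed CSF/PET value
against the latent status to emulate imperfect plasma–CSF/PET
concordance.

**Calibration of the ratio components.** Defaults are μ = (0.0391,
0.0584), σ = (0.0040, 0.0050). With the cohort's expected amyloid-positive
mass (≈ 0.335 after integrating the age curve over the volunteer age
distribution), the weighted crossing of the true component curves sits at
0.0472 — the neighbourhood where published plasma 42/40 cutoffs fall, so
recovered thresholds are directly comparable. The separation
(≈ 3 pooled SDs) was chosen so that the crossing is *estimable* at cohort
scale: with substantially more overlap a two-component unequal-variance
mixture is weakly identified at n ≈ 365 (weight estimates range roughly
0.15–0.85 over seeds, verified against scikit-learn's best-of-20
likelihoods), and the fitted crossing wanders by ±0.005 or more. The
consequence is that the generator's labelled subset discriminates more
cleanly (AUC ≈ 0.99 at zero label noise) than real plasma assays do
(published AUCs near 0.6–0.9); realistic discordance levels are the role
of `label_noise`, not of component overlap. These defaults are
structural stand-ins and must not be read as estimates of any study's
component parameters.

**What passing tests show — and don't.** Tests certify the estimators
(EM recovery within Monte-Carlo SEs, closed-form intersection against
bisection, stump against exhaustive scan, AUC against pair counting,
cohort-scale intersection recovery within 0.002) and the exact
reproduction of the screening calculus from count fractions. They do not
certify performance on real plasma data, where assay noise is
non-Gaussian, components need not be two, and CSF/PET discordance is
structured rather than independent.

## Problem sizes and numerics

Default test/report sizes: cohorts of 365; EM recovery at n = 10⁴;
property scans at n ≤ 500 (stump) and n ≤ 200 (AUC oracle); bootstrap
B = 2000 (500 in tests). EM tolerance 1e-8, intersection verified to
1e-10, identity properties to 1e-12. Degenerate inputs (single-class
labels, all-tied values, < 4 values for the IQR rule, < 10 for EM,
missing dates with a measurement present) raise explicit errors rather
than returning defaults.
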