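# Methods

This note documents the modelling and simulation choices behind
`psyreadmit`, in the spirit of a statistical package's model documentation:
what is assumed, which knobs matter, and what the bundled synthetic data can
and cannot show.

## Cohort construction

Encounters are day-granularity closed intervals.  Per patient, inpatient
encounters whose intervals intersect are unioned into one stay; **same-day
adjacency counts as intersection**, so a transfer admitted on the discharge
day merges into the index stay rather than counting as a readmission.  The
merged stay takes the site of its earliest component and the union of its
ICD-10 codes.  Records with discharge before admit are rejected (count
logged); outpatient rows never form stays.

A stay is labeled *readmitted* iff the patient's next inpatient stay — any
site, any diagnosis (all-cause) — admits at most 30 days after this stay's
discharge.  The boundary is inclusive: a 30-day gap is a readmission.  A
patient's last stay is labeled not readmitted.

**Classification-instance rule.**  By default a stay is a prediction unit if
it carries any ICD-10 F-chapter (mental/behavioural) code; the stricter rule
"F2x/F3x code only" is available (`inclusion="f2f3"`).  The looser default
was chosen because real multi-site summaries show stays whose psychosis and
mood percentages sum to less than 100%, i.e. instances carrying neither
flag, and because the generator draws the diagnosis flags independently, so
a small fraction of instances has neither a psychosis nor a mood code.
Those instances receive a residual psychiatric code (F60.3) that maps to
none of the four diagnosis flags.

**Covariates.**  Age at discharge in whole calendar years from the birth
date; LOS = discharge − admit in days; diagnosis flags from the numeric
ICD-10 sub-ranges F20–29 / F30–39 / F40–48 / F10–19 (the anxiety and SUD
ranges are conventional chapter groupings; source analyses rarely state
them exactly).  For modelling, rows with missing legal sex are dropped
(they are a handful per tens of thousands in real summaries) and missing
race is folded into "Other"; descriptive tables still report Missing
separately.

**Train/test split.**  3:1 by patient identifier only, so a patient is in
the same partition at every site.  Rule: with d the last and e the
second-to-last decimal digit of the identifier, the patient is a test
patient iff d ∈ {0, 1}, or d = 2 and e is even — expectation exactly 1/4
under uniform digits, deterministic, and configurable.  Identifiers without
two decimal digits fall back to a stable MD5-derived digit pair.

## Models

*Logistic.*  Main effects only: age and LOS numeric and untransformed; sex
and the four diagnosis flags binary; race a 4-level categorical with White
as reference.  Fitting is (optionally weighted) maximum likelihood via IRLS;
inference is Wald, reported as odds ratios with 95% CIs.  Optional per-row
weights enter the likelihood multiplicatively.  Constant predictor columns
(e.g. a race level absent from a small subsample) are dropped for
identifiability; prediction ignores them.  Perfect separation is flagged and
the coefficients are still returned — small-site subsamples occasionally
separate and aborting would bias the replication averages.

*Tree ensemble.*  500 bagged classification trees, √p candidate variables
per split, unlimited depth, minimum node size 5 (conventional defaults; the
hyperparameters are recorded in every fit).  Per-sample weights act through
a **weighted bootstrap**: each tree's sample of size n is drawn with
replacement with probability proportional to the weights.  Out-of-bag (OOB)
rows of each tree are tracked; OOB accuracy is the headline fit diagnostic.

*Permutation importance.*  For each original variable (a categorical's dummy
columns permuted as one unit), importance = baseline OOB accuracy minus the
mean OOB accuracy over 10 independent permutations of that variable.
Importance is computed on OOB predictions, not on a held-out split.  Reading
guide: |importance| < 0.01 is negligible noise; > 0.1 is a substantial
dependence.  Permuting a constant column changes nothing, so its importance
is exactly 0.

## Evaluation protocol

AUC is the Mann–Whitney probability with ties counted 1/2 (equal to the
trapezoidal area under the empirical ROC).  The operating threshold
maximises sensitivity² + specificity² over the candidate set {distinct
scores} ∪ {+∞}; ties break toward the **largest** threshold (fewest
predicted positives), deterministically.  F1 is reported for the readmitted
class at that threshold, computed per replication on each target's test
ROC — conventional, but optimistic in the sense that the threshold is
tuned on the evaluation data.

Cross-site protocol: n_sub (default: the smallest site's training size)
training rows are subsampled without replacement, a model is fitted and
scored on every site's test split; this is replicated n_reps times (default
100) with per-(source, replication) seed streams, and metrics are averaged.
One-class subsamples are redrawn up to 10 times, then the replication is
skipped (logged).  When n_sub equals the source's full training size every
replication would be identical, so n_reps collapses to 1 (the smallest
default site hits this).  Reported means are exactly the means of the
stored per-replication values.

## IPW covariate-shift adjustment

For source s and target s′, a main-effects logistic discriminator on the
stacked *training* covariates (target test rows never touch training)
estimates p(x) = Pr(site = s′ | X = x), fitted once per ordered pair.  Each
source training row receives w = p/(1−p) with p clipped to [1e−6, 1−1e−6];
optional truncation at the 99th percentile is off by default.  For discrete
covariates with a saturated discriminator these weights equal the empirical
density ratio (target count / source count per cell) and sum to the target
sample size.  Weighted training then proceeds under the identical seed
stream as the unadjusted run, so constant weights reproduce the unadjusted
matrix exactly.  A near-separated discriminator (|coefficient| > 15 or
non-convergence) is flagged and surfaced in the weight summaries.

When can weighting help?  If the two sites share the conditional
distribution y | X **and the fitted model is correctly specified**, the
unweighted source MLE already estimates the shared conditional consistently
and weighting only adds variance.  Weighting has first-order value exactly
when the fitted model is misspecified: it moves the estimate from the
source-optimal approximation to the target-optimal one.  The bundled
`covariate_shift_pair` scenario therefore equips the shared outcome model
with a LOS × age interaction (clinically plausible — LOS can proxy severity
differently across age profiles, echoing the non-monotone LOS effects seen
at large sites) while the fitted models remain main-effects.  With the age
marginal shifted between sites, the source- and target-optimal linear LOS
coefficients differ in sign, and IPW visibly repairs the cross-site AUC
(from a gap of ≈0.35 to < 0.01 at n = 20,000/site).  The complementary
`conditional_shift_pair` scenario (identical marginals, LOS odds ratios
0.981 vs 1.013 per day) makes all weights ≈ 1, reproducing the negative
finding that IPW offers little when the sites' outcome models genuinely
differ.

## Synthetic multi-site generator

The generator's defaults encode the four study sites' published summaries:

* **Sex, race, diagnosis flags** — categorical/Bernoulli draws at the
  published per-site counts (so simulated percentages reproduce the printed
  one-decimal values).  Missing sex is generated at rate 0 (negligible in
  the source data); missing race at the published rates.
* **Age** — truncated normal on the study inclusion range [18, 65], with
  parent parameters solved numerically so the *truncated* mean/SD match the
  published values; rounded to whole years.
* **LOS** — log-normal with μ = log(median) and σ = log(q3/q1)/(2·z₀.₇₅),
  i.e. matched to the published median and IQR (the published means/SDs are
  inconsistent with any simple two-parameter family; median/IQR is the
  robust choice), truncated to [0, 365] and rounded to whole days.
* **Outcome** — Bernoulli through the site's logistic model with slopes set
  to the logs of the published odds ratios; the intercept is calibrated by
  Brent root-finding on a fixed 200,000-draw covariate sample so marginal
  prevalence matches the published outcome mean to 1e−3.
* **Covariate independence** — only marginals are published, so covariates
  are drawn independently.  Consequently simulated sites cannot reproduce
  real covariate correlation (e.g. LOS–diagnosis), and refitted models
  recover the generating coefficients more cleanly than real data would.
* **Cross-site overlap** — a configurable fraction of instances (default
  5%) takes patient identifiers from a shared pool; a shared patient's
  demographics are harmonised to whichever site first drew them, before
  labels are drawn.

**Encounter emission** (`instances_to_encounters`) writes the instance table
back out as a raw stream: each stay spans its LOS with one ICD code per
diagnosis flag; a configurable fraction (default 20%) of stays is emitted as
two overlapping or same-day-adjacent encounters that must re-merge;
positive-label stays are followed by a non-psychiatric inpatient admission
at a gap drawn uniformly on [1, 30] days (gap 0 would merge as a same-day
transfer and can never realise a positive label), negative-label stays by
either nothing or one admission at 31–120 days; outpatient noise visits are
interleaved; consecutive stays of one patient are spaced > 60 days so labels
never interact.  Each patient has one birth date; when a patient carries
several stays the realised ages are recomputed from that birth date and
written back to the returned ground-truth table (the age coefficients are at
most ~0.013 log-odds per year, so the effect on drawn labels is
negligible).  Round trip through the cohort builder is exactly the identity
on labels, LOS and covariates — verified over many seeds.

## Numerical conventions

* Seeds: every stochastic routine takes an explicit seed and builds
  per-site / per-replication `SeedSequence` streams from it; a fixed
  internal seed governs intercept calibration so site defaults are stable
  across processes.
* Tie-breaks: threshold ties → largest threshold; OOB vote ties (fraction
  exactly 0.5) → predicted positive.
* Degenerate inputs: one-class labels are an error for fitting and metrics;
  fewer than 10 rows is an error for the forest (no usable OOB); empty
  encounter input yields empty output.
* Probability clipping for IPW at 1e−6 bounds weights by ~1e6 under
  separation.

## Problem sizes used in checks

The bundled checks run at deliberately modest scale chosen to make the
statistical properties unambiguous: marginal goodness of fit at n = 100,000
(χ², α = 0.001), coefficient recovery at n = 50,000 × 100 replicate
simulations (pooled 95% Wald coverage ≈ 95%), shift scenarios at
n = 20,000/site, oracle comparisons on 500–1,000 random datasets of n ≤ 200,
and round trips at n = 1,000 across multiple seeds.

## Limitations

* Sites are simulated from marginals plus a main-effects (optionally
  interaction-augmented) logistic outcome; real sites differ in coding
  practice, case mix and unmeasured severity, none of which is modelled.
  Passing tests show the pipeline's correctness and the shift phenomena
  under the stated generative models — not predictive performance on real
  EHR data.
* No regularisation, interactions, calibration analysis, confidence
  intervals over patients, or significance tests on AUC differences; no
  socioeconomic predictors or text-derived features.
* The optimal-threshold F1 is tuned on the evaluation ROC and is therefore
  an optimistic summary; AUC is the primary transportability metric.
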