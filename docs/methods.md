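# Methods

This note documents the generative model, the decision engines, the
statistical procedures, and the design choices where more than one
reasonable option existed.

## Cohort generator

**Cluster randomization.** Clinicians are randomized 1:1 to arms in blocks
of 4 (defaults: 30 clinicians, so seven complete blocks plus a balanced
partial block of 2, giving 15 per arm deterministically).  Patients are
assigned uniformly at random to clinicians and inherit their assessing
clinician's arm.  The trial this emulates had unequal arm sizes because
stratified-arm clinicians assessed more patients per week; we do not model
assessment throughput, so simulated arms are approximately balanced.

**Baseline scores.** Each instrument score is a normal draw rounded to an
integer, redrawn until it falls inside the instrument bounds (PHQ-9 0–27,
GAD-7 0–21, WSAS 0–40, SAPAS 0–8).  This is a truncated-normal-then-round
model: the simplest family matching the two printed moments under hard
bounds.  Defaults are the published baseline means/SDs (PHQ-9 15.47/5.86,
GAD-7 14.21/4.65, WSAS 20.33/9.31, SAPAS 3.97/1.43).  PHQ-9, GAD-7 and
WSAS share a latent severity factor inducing a configurable pairwise
correlation (default 0.5); only marginals are published, and 0.5 is typical
of observed depression–anxiety–impairment correlations in this population.
On rejection only the idiosyncratic component is redrawn, so the factor
loading is preserved.  Categorical features (sex 65.1% female, unemployment
19.7%, ethnicity 95.3% White, diagnosis mix 52.7/42.8/2.9/1.5% as exact
count fractions) are independent draws.

**Latent prognosis and complexity.** A severity index
`s = 1.6·z(PHQ-9) + 0.6·z(WSAS) + 0.4·z(SAPAS) + 0.4·unemployed`
feeds a logistic link `prognosis = σ(−s)`, monotone decreasing in every
complicating factor (their effect is cumulative).  The lowest
`complex_prevalence` quantile (default 23.7%) of each cohort is labelled
complex, so the flagged share is exact by construction.  The PHQ-9-dominant
weighting makes essentially all complex patients baseline PHQ-9 cases,
matching the trial's accounting in which every complex patient appears in
the primary-analysis denominator; it also puts the complex share among
cases near 28%, which is what reconciles the arm-level RCSI rates with the
subgroup probabilities under a single prevalence parameter.

**Outcomes.** For baseline cases, the binary remission indicator is
Bernoulli with probability `subgroup_rcsi_probs[(arm, complexity)]`
(defaults: stratified 0.583 standard / 0.394 complex; stepped 0.483 /
0.338; the GAD-7 analogue uses its own table).  The posttreatment score is
then drawn from the baseline-conditioned integer distribution (centred at
baseline − 6.5, SD 5) restricted to the set consistent with the indicator —
equivalent to rejection sampling, implemented as direct sampling from the
masked pmf.  This guarantees the outcome classifier reproduces the latent
labels exactly.  Sub-threshold patients receive unconstrained post scores
and a missing latent label; they are excluded from the primary analysis
downstream, as in the trial.  GAD-7 remission is drawn independently of
PHQ-9 remission given the subgroup — a simplification; real joint remission
is positively correlated beyond what the shared subgroup induces.

**Pathway.** Low-intensity non-remitters step up to HIT with arm-specific
probability (defaults 0.34 stratified, 0.18 stepped, calibrated so the
step-up prevalence among final HIT patients is near the published 13.9% and
7.6%).  Session counts are truncated-normal integers (LIT mean 5, SD 2.5,
range 1–8; HIT mean 9, SD 5, range 1–20); stepped-up patients accrue both a
LIT and a HIT phase.  Dropout is Bernoulli(0.30) independent of arm (the
trial found no arm difference), and endpoint scores are set missing
completely at random at 38/951 ≈ 4% — the mechanism is our choice; the
source reports only the count.  An optional clinician random intercept on
the remission log-odds (default SD 0) supports the cluster-check power
analyses.

**What the generator does not emulate.** No session-by-session
trajectories, therapist effects, waiting-time dynamics, or
informative missingness.  Passing tests therefore demonstrate internal
consistency of the pipeline under the published calibration, not external
validity on routine-care data.

## Prognosis module

L1-penalized logistic regression (scikit-learn saga on standardized
features, coefficients mapped back to the original scale) on the six intake
features.  Training labels default to joint remission of depression and
anxiety symptoms (the reliable-recovery flag), configurable to PHQ-9 RCSI
alone.  Penalty 0 reduces exactly to the unpenalized ML fit (verified
against a hand-coded IRLS solver to 1e-6); at extreme penalties all
coefficients vanish and the intercept is set to the analytic optimum
logit(base rate).  The default penalty weight is 1.0 (mild shrinkage on
standardized features); 5-fold cross-validated log-loss selection is
available but not the default, to keep the pipeline fast and deterministic.
The complexity threshold is the empirical quantile of training-set
predictions at the configured prevalence; a probability exactly at the
threshold is *standard* — "poorer expected prognosis" defines complex, so
the boundary belongs to the better side.  Raw scores enter linearly; the
original algorithm's optimal-scaling transformation is deliberately not
reproduced (its coefficients are not public), so this module is a surrogate
with the same interface and calibration, not a reimplementation.

## Allocation module

Stratified recommendation is a deterministic function of (diagnosis,
complexity label): fast-track disorders → HIT, complex → HIT, standard →
LIT.  The fast-track set for the simulated diagnosis categories is
{PTSD, OCD}; disorders like social anxiety, which the guidelines also
fast-track, are not separable from the aggregate anxiety category, which is
why the simulated stratified arm allocates fewer patients to HIT at intake
than the trial did.  Shared decision-making is an independent Bernoulli
override (default 0.10, matching ~90% adherence).  The stepped engine
refers fast-track disorders and severely impaired patients (WSAS ≥ 32 OR
PHQ-9 ≥ 23, rule and cutoffs configurable) to HIT and everyone else to LIT.
The cutoffs were chosen by a one-off grid search over round values so that
about 78–79% of stepped-arm patients start in low intensity, the figure the
design targets; they are not published quantities.  Adherence is summarized
by percent agreement and Cohen's κ = (p_o − p_e)/(1 − p_e), with κ
undefined (signalled) when p_e = 1.

## Outcomes module

Pure threshold rules, strict `<` at the clinical cutoff and `≥` for
reliable change (both per the published primary-outcome wording).  The
GAD-7 cutoff 8 and reliable change 4 follow the IAPT convention and are
exposed in configuration.  Reliable deterioration is defined symmetrically
(worsening ≥ the reliable-change magnitude); it is needed by the
reliable-recovery definition, whose three conditions are implemented
verbatim: improvement on case-level measures, subclinical on both after
treatment, no reliable deterioration on either.

## Analysis module

*EM imputation*: joint multivariate normal over (baseline predictors,
endpoint scores), missingness confined to endpoints, convergence on an
observed-data log-likelihood change < 1e-6, final values imputed as
conditional means, clipped to instrument bounds and rounded.  *Adjusted
OR*: ML logistic fit of outcome on arm + same-instrument baseline score;
Wald 95% CI (the CI method is our choice; the source does not state one).
*Cluster check*: random-intercept logistic likelihood via 20-point
Gauss-Hermite quadrature, maximized from multiple starts; −2ΔLL floored at
0 and referred to χ²(1) — conservative at the boundary, which only makes
the null check stricter.  *χ²*: no continuity correction; this choice
reproduces the published statistics (70.51, 96.41) exactly.
*Mann-Whitney*: U counts pairs favouring the first sample (ties ½), SE with
the standard tie correction, no continuity correction on z.  Intention to
treat throughout: patients are analyzed under their assigned arm regardless
of step-up or override, and sub-threshold patients are excluded only from
the case-level analyses.

## Economics module

Unit-cost defaults (LIT £24 per 30-min session, HIT £48 per hour,
assessment £40) are round NHS-banding-style placeholders — configuration
parameters, not published values.  The CEAC bootstrap resamples patients
within arm (default 5,000 replicates; percentile CI for the incremental
cost).  The effect measure defaults to PHQ-9 reliable improvement
(change ≥ 6).  The break-even property — the CEAC's 0.5-crossing
approaching Δcost/Δeffect — is asserted on synthetic data with known
deltas.  No quality-adjusted life-years or post-treatment service use.

## Problem sizes

The test suite and acceptance script use 200 simulated trials of n = 951
for calibration checks, 500 replicates of n = 600 for CI coverage, 200
replicates of n = 400 across 15 clusters for the cluster-check operating
characteristics, and 100 fresh cohorts for the complex-flag rate — sizes
chosen to keep Monte-Carlo error well inside the asserted tolerances.
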