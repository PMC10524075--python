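# Methods

## Setting and model

`crcscreen` evaluates the diagnostic accuracy of a two-track triage
screening programme for colorectal cancer (CRC). Every participant
completes a questionnaire-based risk assessment (RA) and a two-specimen
qualitative fecal immunochemical test (FIT); a positive result on either
track triggers a colonoscopy referral. Because only a fraction of
referred participants actually undergo colonoscopy, cancers surface in
three ways, distinguished by the lag from screening to a
registry-confirmed diagnosis:

* **screen-detected** — positive screen, diagnosis within 90 days;
* **missed** — positive screen, diagnosis after 90 days but within the
  1-year case horizon (the work-up never happened in time);
* **interval** — negative screen, diagnosis within the case horizon.

Both windows are configurable (`OutcomeWindows`); the defaults are 90 and
365 days. Two conventions deserve note. First, a *negative* screen
diagnosed within 0–90 days is classed interval: the interval definition
has no lower lag bound. Second, repeat participants contribute one
independent episode per screening round; all indices are per test, not
per person.

### The RA rule and the seven strategies

RA is positive when any of three major history items holds (any cancer,
colorectal polyps, first-degree-relative CRC) or at least two of six
minor items (chronic constipation, chronic diarrhea, mucus/bloody stool,
serious adverse life event, appendicitis/appendectomy,
cholecystitis/cholecystectomy). The rule is exercised exhaustively in
the tests against a brute-force enumeration of all 2^9 item profiles.

Seven initial-test strategies are evaluated on the same episodes: RA
alone, first-specimen FIT alone, two-specimen FIT alone (positive in
either specimen), RA combined with first FIT or with two-specimen FIT in
parallel (either positive) or in series (both positive). Two-specimen
FIT positivity means *any* positive specimen throughout, including
inside the serial combination: serial RA+2-FIT defaults to
`RA AND (fit1 OR fit2)`, which is the reading consistent with the
programme's published both-positive count. A stricter
`RA AND fit1 AND fit2` variant is available via
`serial_both_specimens=True` (CLI `--serial-both-specimens`).

### Accuracy indices

From a 2x2 table: sensitivity, specificity, PPV, the detection rate of
CRC per 1000 tests, LR+ = sens/(1−spec), LR− = (1−sens)/spec, and the
single-test trapezoidal AUC (sens+spec)/2 — the area under the ROC
polygon through (0,0), (1−spec, sens), (1,1), reported as a convention
since a binary test has no intrinsic curve. Proportion intervals are
Wilson by default (Clopper–Pearson optional); LR intervals use Simel's
log method. Zero cells in LR computations receive a 0.5 correction to
all four cells, flagged on the result. Report rounding (half-up, two
decimals, PPV as a percentage) happens only at serialisation.

## Packaged programme margins

`crcscreen.fixtures` ships the published aggregate counts of the
Shanghai programme's first-round (1,901,360 tests) and repeat-round
(1,143,748 tests) cohorts: positives split into RA-only / FIT-only /
both-positive tracks, and cancers split into screen-detected, missed and
interval. These margins determine the 2x2 table for four of the seven
strategies (those not needing the first-specimen split), and the
accuracy pipeline reproduces the published table from them exactly at
printed precision. The repeat-round per-track cancer rows are known to
sum to 30 fewer missed cases than the aggregate row; the module exposes
the deficit (`MULTI_TIME_MISSED_ROW_DEFICIT`) and uses aggregate totals
for the all-tracks table, per-track numerators otherwise.

## Meta-analysis stack

### Bivariate random-effects model

Study *i* contributes (logit sens_i, logit spec_i) whose true values are
bivariate normal with means (μ_sens, μ_spec), SDs (τ_sens, τ_spec) and
correlation ρ. Two fitting routes:

* **`reml_normal`** (default): within-study variances 1/tp+1/fn and
  1/tn+1/fp on the logit scale (0.5 added to all four cells of any study
  containing a zero, per-study); the restricted likelihood is maximised
  over (τ_sens, τ_spec, ρ) with the means profiled out by GLS. L-BFGS-B
  from six deterministic starts; τ bounded at 0 (reported τ² floored at
  0), |ρ| capped at 0.999; non-convergence from every start raises a
  `ConvergenceError` carrying the best parameters found.
* **`ml_binomial`**: exact binomial within-study likelihoods integrated
  over the random effects by adaptive Gauss–Hermite quadrature — 21
  nodes per dimension, centred per study at the posterior mode (found by
  a vectorised 2-D Newton iteration) and scaled by the Laplace
  curvature. Slower; used as a cross-check and for sparse tables.

Standard errors for the means come from the GLS information; for
(τ_sens, τ_spec, ρ) from a central finite-difference Hessian of the
profiled objective.

### Derived summaries

Pooled sens/spec are inverse-logits of the fitted means with Wald
intervals on the logit scale. Pooled LRs are *plug-in* functions of the
pooled proportions (the bivariate-model LR pooling in the spirit of
Zwinderman–Bossuyt), with delta-method intervals on the log-LR scale
from the mean covariance; a parametric bootstrap (`bootstrap=` draws) is
available as a cross-check and as fallback for degenerate covariances.
The plug-in route is the default because it reproduces the published
Fagan posttest arithmetic exactly.

The summary ROC curve uses the accuracy/threshold reparameterisation of
the bivariate parameters (Harbord): shape β = ln(τ_spec/τ_sens),
accuracy Λ = √(τ_spec/τ_sens)·μ_sens + √(τ_sens/τ_spec)·μ_spec, curve
sens(FPR) = expit(Λe^{−β/2} + e^{−β} logit FPR), AUC by trapezoid over
the full (0,1) FPR range (invariant to grid size beyond ~10³ points to
1e−4; verified against independent quadrature). When both τ² are zero
the curve degenerates to the summary point and AUC is reported absent.
Study weights by sample size affect only plot point sizes, never the
fitted curve.

Proportion pooling (detection rates, missed-case shares) is
DerSimonian–Laird on the logit scale with 0.5 corrections at the
boundaries; I² = max(0, (Q−df)/Q) from the fixed-effect Q, the
per-outcome univariate convention. A single study reduces exactly to
its Wilson interval.

Meta-regression puts category indicators on both means. Per-outcome
p-values are likelihood-ratio tests of ML fits (REML objectives are not
comparable across mean structures); the share of heterogeneity explained
per outcome is the relative reduction in REML τ², clipped to [0,1].
Singleton categories are dropped with a warning.

Deeks' asymmetry test regresses ln DOR on 1/√ESS with weights
ESS = 4·n_dis·n_nondis/n (two-sided t-test on the slope). When every
study has the same ESS the slope is not estimable and is reported as 0
with p = 1. Fagan posttest probabilities are Bayes' theorem in odds
form.

## Synthetic data

The cohort generator draws case status, item-level RA responses
(odds-multiplied among cases, then pushed through the actual decision
rule), and two FIT specimens with per-specimen sensitivity/specificity
and a shedding correlation: with probability `specimen_correlation` the
two specimens share one Bernoulli draw, otherwise they are independent,
so the union positivity has the closed form c·p + (1−c)(1−(1−p)²) used
as the oracle in tests. Diagnosis lags are constructed from the
programme logic: screen-positive adherent cases land in the
screen-detected window, screen-positive non-adherent cases in the missed
window (so the missed share converges to 1 − adherence), screen-negative
cases anywhere within the one-year horizon.

Defaults emulate the programme's first-round operating point: prevalence
0.25%, per-specimen FIT sensitivity 0.57 and specificity 0.908 with
correlation 0.46 (solving the published one-specimen 9.2% and
two-specimen 13.7% positivity and the union sensitivity 0.70), RA item
rates giving ~10.3% RA positivity with case enrichment 1.8 (RA
sensitivity ~0.22), colonoscopy adherence 0.60. The generator does not
model age/sex structure, quantitative hemoglobin values, multi-wave
participation dynamics, or colonoscopy adherence as a behavioural
process — so passing tests validate the statistical machinery at this
operating point, not those aspects of real screening data.

The study-set generator draws per-study logits from the bivariate
normal, then binomial cells at a log-uniform study size (default
500–5000) and a uniform per-study prevalence (default 0.1–0.3). The
case-enriched prevalence default is deliberate: at a few thousand
subjects per study, population-screening prevalence (~0.3%) would leave
per-study sensitivities essentially uninformative, whereas published
diagnostic-accuracy collections have case-rich margins. Optional
covariate effects add per-category logit shifts for meta-regression
recovery tests. All randomness flows through PCG64 with explicit seeds.

## Problem sizes and numerical choices

The test suite runs in well under a minute: recovery checks use one
200-study collection (parameters within 2 observed-information SEs of
truth), Deeks calibration 500 replicates of 30 studies drawn with large
cells (sizes 2000–20,000, prevalence 0.2) so that the O(1/cell) logit
small-sample bias of ln DOR — which would otherwise masquerade as
asymmetry — is negligible; law-of-large-numbers cohort checks use 10⁶
subjects at 3 Monte-Carlo-SE tolerance. Optimizer tolerances: L-BFGS-B
ftol 1e−12 / gtol 1e−8 for REML, six fixed starts spanning small/large τ
and negative/positive ρ.

## Known limitations

* The published pooled values for the real 103-study collection are not
  reproducible here because the per-study 2x2 data are not packaged; the
  meta-analytic stack is validated by simulation recovery at the same
  operating point instead.
* The normal-approximation REML route mildly attenuates τ for sparse
  studies; the binomial ML route avoids this at higher cost.
* Single-test AUC for a binary test is a reporting convention, not an
  estimate of an underlying continuous-threshold curve.
* Deeks' test is anticonservative under strong between-study
  heterogeneity (the WLS weights ignore τ²), a property of the test
  itself, not of this implementation.
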