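# Methods

## Scoring model

Each timed subtest reduces to (n_correct, n_items, total_time); the raw
score is n_correct / total_time in correct-per-second, with total_time the
sum of per-item response times from stimulus onset to answer (instruction
and demonstration screens excluded). The memory subtest scores the delayed
(second) cued-recall trial only — the standard diagnostic trial in
two-stage recall batteries; `score_memory(..., trial=)` exposes the
immediate trial and the per-item conjunction of both as alternatives. The
composite is the unweighted mean of the three z-scores and exists only for
complete triplets; a skipped item propagates to an incomplete subtest and
an absent composite. This is deliberate: unlike paper instruments, where an
administrator scores a skipped item as zero, automated scoring treats skips
as missing data.

The z-reference uses the sample (n−1) standard deviation, the conventional
estimator for cohort norms, and is fitted only on participants with all
three subtests complete. By default the analysis cohort is its own
reference (so pooled composite z-scores average zero by construction, which
is consistent with the near-zero pooled composite mean in the study's
demographic table at the 38:34 group mix); externally fitted norms can be
passed instead.

## Synthetic cohort

A single latent severity factor L ~ Normal(δ·group, 1), with δ = 2 for the
impaired group, drives all group differences. Subtest ability is
S_k = λL + τε_k with loading λ = 1 and idiosyncratic sd τ = 1, giving a
within-group cross-subtest correlation of about 0.3–0.5 before item noise;
λ = 0 removes both the correlation and the group separation. Item
correctness is Bernoulli(expit(base − slope·S_k)) — with guessing floors
1/4 (immediate) and 1/8 (delayed) for the cued-recall options — and log
response times are Normal(location + rt_slope·S_k, scale) per item. The
MMSE-2 total is round(intercept − slope·L + noise) clamped to [0, 30]; the
clamp produces the healthy-group ceiling effect, and the discretised
pre-clamp normal gives exact analytic moments (`expected_mmse_moments`)
used by the parameter-recovery tests.

Calibration (one-time, frozen into `default_config`): the MMSE intercept,
slope and noise were solved against the discretised-censored-normal moments
so the analytic group means equal 28.6 (healthy) and 26.1 (impaired)
exactly; with a single shared latent scale the implied group sds are 1.79
and 2.51 against the study's printed 1.2 and 2.8 — matching all four
moments would need group-specific noise, which the single-factor model
deliberately avoids. The subtest severity slopes were then scaled (by
Monte-Carlo root-finding at n = 400,000) so the self-referenced composite
group means sit at +0.47 / −0.52 at the 38:34 mix; the resulting composite
within-group sds are about 0.63/0.66 versus the printed 0.47/0.77 — the
observed variance asymmetry would require severity-dependent dispersion the
model does not include.

Missingness has two regimes. The stochastic regime skips each section with
probability expit(base_k + 0.8·L) (bases solved so the mixture-marginal
rates are 9/98, 5/98, 12/98, the observed section split) and fails uploads
with probability 7/105. The flow-emulation regime (the default) fixes the
study's flow-diagram counts exactly — 108 consented, 1 revoked consent,
2 CDR > 1 screening failures, 7 upload failures (5 healthy, 2 impaired) and
26 single-section skippers (7 healthy, 19 impaired) — and randomises only
who is excluded: skippers are drawn severity-weighted within group (so
excluded participants score lower on MMSE, as observed) and each skips one
section chosen with the skip-model propensities. CDR = 1 labels among the
impaired follow the study's split (1 among included, 6 among missing in
expectation through `p_cdr1_impaired`). Because included participants are
then a mildly severity-selected subset, their group means sit slightly
above the unselected calibration targets — well within sampling error at
n = 38/34, which is the scale the flow regime is meant for.

What the generator does not emulate: cognitive-process response-time
structure (no diffusion dynamics), practice/fatigue effects, site effects,
longitudinal change, and the within-group MMSE–composite correlation needed
to pin the pooled Spearman rho at a specific value — that correlation is a
by-product of the shared latent factor (pooled rho typically 0.5–0.7 at
study scale) rather than a separately identified parameter, since
within-group correlations are not identifiable from the published group
summaries. Passing tests therefore demonstrate correctness of the analysis
machinery under a plausible generative model, not distributional fidelity
of real participant data.

## Statistical conventions

* Mann-Whitney U: mid-rank ties; reported statistic min(U₁, U₂) (the
  convention that reproduces published education comparison U = 583; the
  complementary U follows from U₁ + U₂ = n₁n₂); p from the normal
  approximation with tie correction and 0.5 continuity correction,
  two-sided.
* Chi-squared on 2×2 tables: Yates continuity correction by default (the
  uncorrected statistic contradicts the published 4.2 for the
  missing-data comparison; the corrected 4.15 matches).
* Fisher's exact: two-sided by the probability-mass rule.
* t-test: Student's pooled variance by default, Welch as an option.
* Spearman: mid-rank ties, two-sided t-approximation on n − 2 df
  (adequate at cohort scale; exhaustive permutation is used as the test
  oracle at n = 6).
* Shapiro-Wilk is an advisory gate recorded in report metadata; the
  pipeline always reports the rank-based comparisons so outputs stay
  comparable across cohorts.
* Quartiles use linear interpolation (numpy's default, the common default
  of the Python analysis stack).

## ROC machinery

AUC uses the rank (Mann-Whitney) formulation with between-class ties
contributing 1/2; it equals the trapezoidal area under the empirical curve
and brute-force pair counting to 1e-12 (tested). The decision rule is
strict: score < c ⇒ impaired, matching screening cut-offs quoted as
"< 27" / "< 0.21"; candidate thresholds are the observed unique scores plus
a +∞ sentinel. Youden's J ties break toward higher sensitivity (screening
favours detection), then toward the smaller threshold.

The bootstrap CI resamples ⌈0.75·n_g⌉ per class, stratified, with
replacement (subsampling without replacement is available as a switch — the
published description does not specify), and takes the percentile interval
over 10,000 replicate AUCs. The reduced replicate size makes the interval
mildly conservative: measured coverage for a known binormal AUC of 0.794 at
n = 100/100 is ≈ 97% at the nominal 95%. The DeLong comparison uses the
classic placement-value (structural components) covariance estimator with
the normal reference distribution, two-sided; its variance estimate
averages within 15% of a 10,000-replication Monte-Carlo oracle at paired
n = 30 (tested).

Degenerate cases: single-class label vectors, constant score vectors in
correlation tests, zero-margin tables and zero-variance references raise
typed errors rather than returning NaNs; a zero DeLong variance returns
p = 1 when ΔAUC = 0 and p = 0 with a runtime warning otherwise.

## Exclusion flow

Dispositions are assigned in the fixed priority order revoked consent →
CDR > 1 → upload failure → incomplete triplet, each participant counted
once; the ledger always conserves the roster size. The z-reference is
fitted after exclusions, on included participants only.

## Problem sizes used by the test suite

Moment-recovery checks run at n = 10,000 participants; composite-mean
calibration checks at n = 1,800 with the 38:34 group ratio; the bootstrap
coverage study uses 500 outer replications of n = 100 + 100 with 500
bootstrap replicates each; flow-level properties use the study-scale
roster of 108. These sizes keep every Monte-Carlo tolerance at 3 standard
errors or tighter while the full suite stays fast.
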