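# Methods

## Model and procedure

The package discovers qualitative prognostic signatures of the
top-scoring-pair family. The primitive is the REO indicator of an oriented
gene pair: x<sub>s</sub> = 1{expr<sub>s</sub>(gene_high) >
expr<sub>s</sub>(gene_low)} for sample s, with strict inequality — a tie
votes 0. Every downstream quantity (screening statistics, votes, risk
labels) depends on expression only through these indicators, so it is
invariant to any strictly increasing per-sample transform. The one
exception, by construction, is the first funnel stage: the age-stratum
differential-expression screen compares a gene's values *across* samples
and is therefore invariant only to transforms shared by the whole cohort
(e.g. a global renormalization), not to per-sample distortions. Once the
candidate gene universe is fixed, everything downstream is per-sample
monotone invariant, and the test suite asserts both statements separately.

Discovery funnel (all thresholds are raw p-values; no multiplicity
correction at any stage, matching common practice for this signature
family):

1. Wilcoxon rank-sum (two-sided) of each gene between the early-onset
   (< 50 y) and late-onset (> 60 y) strata, independently in two training
   cohorts; genes with p < α_deg (default 0.05) in both qualify. Ages in
   [50, 60] belong to neither stratum and are excluded from every
   age-contrast analysis (strict cut-offs).
2. All C(m, 2) unordered pairs of qualifying genes are encoded as binary
   indicator rows (lexicographic pair order fixes indexing).
3. Univariate Cox proportional-hazards screen of each indicator against
   relapse-free survival in each cohort's surgery-only population (both age
   strata; the filter is an explicit parameter). Pairs with Wald p < α_cox
   (default 0.05) survive and are canonicalized so the reported hazard
   ratio of "gene_high > gene_low" exceeds 1 (swapping orientation inverts
   the HR exactly and leaves the p-value unchanged). Pairs with a constant
   indicator or a monotone partial likelihood are discarded: an infinite HR
   estimate in a small stratum is an artifact, not evidence.
4. Consistency: pairs significant with the same orientation in both
   cohorts; both cohorts' statistics are attached.
5. De-redundancy: pairs are ranked by the *worse* (larger) of their two
   per-cohort p-values — the significance level the pair guarantees in
   every training cohort — and greedily accepted in ascending order iff
   neither gene already appears in an accepted pair. Ties break
   lexicographically on (gene_high, gene_low), so the output is a
   deterministic, gene-disjoint set. Ranking by the worst cohort was a
   genuinely open choice (best-cohort and single-cohort rankings are
   defensible); worst-cohort was chosen because it is symmetric in the
   cohorts and conservative.
6. Forward-stepwise selection maximizes Harrell's C-index on the
   surgery-only early-onset stratum of the first training cohort. The seed
   is the single pair with the largest C-index; each round evaluates every
   remaining gene-disjoint candidate and adopts the one with the largest
   strict improvement (tolerance 1e-12 as a floating-point guard); the
   search stops when no addition improves. Ties break by larger
   improvement, then smaller de-redundancy ranking p, then lexicographic
   pair id, making the result independent of candidate input order.

Classification: a sample is high-risk iff strictly more than k/2 of the k
signature pairs vote high-risk; with even k a split vote is low-risk.

### Selection score: vote count, not binary label

During stepwise search, samples are ranked by the signature's raw vote
count (0..k) rather than by the binary majority label. The deployed
classifier is the label, and label-based scoring is available
(`cindex_on="label"`), but it is a poor search objective: a two-level score
wastes the C-index's resolution, and growing a signature from k=1 to k=2
turns the majority rule into an AND, so the greedy search frequently
cannot improve and stalls at one pair. In simulation under the reference
conditions, label scoring recovered at least 3 of 5 planted pairs in only
about half the runs, while vote scoring recovered at least 4 of 5 in
essentially all runs. Vote-count scoring is therefore the default.

## Survival machinery

* **Cox fitter** (`reosig.survival.cox_fit`): Newton maximization of the
  partial likelihood with step-halving; Efron tie handling by default,
  Breslow by flag (Efron matches mainstream survival software defaults;
  Breslow is retained because the β=0 Breslow score test reproduces the
  log-rank statistic on tie-free data, an identity the tests exploit).
  Convergence: max |score| < 1e-9 or relative log-likelihood change
  < 1e-10. A coefficient walking past |log HR| = 15 flags a monotone
  likelihood (risk groups' event times perfectly separated); such fits are
  reported unconverged with the offending covariate named. Wald statistics
  and exp(β ± 1.96·se) intervals are reported, matching the HR + 95% CI + p
  reporting convention. Constant and collinear covariates are rejected.
* **Batch screening path** (`cox_binary_batch`): thousands of univariate
  binary-covariate models are fitted simultaneously by a vectorized Newton
  solver exploiting x² = x and per-sample relative hazard 1 + x(e^β − 1).
  The fast path requires unique event times (where Efron ≡ Breslow);
  tied-event data fall back to the general fitter per pair. Synthetic
  survival times are continuous, so ties have measure zero there.
* **Kaplan–Meier and log-rank** are delegated to lifelines; samples
  censored exactly at an event time are counted at risk at that time.
* **Harrell's C**: comparable pairs are (i, j) with t_i < t_j and
  event_i = 1; equal observed times are non-comparable and skipped (one of
  the common conventions; it is symmetric and needs no censoring-status
  tie-breaking). Score ties earn 0.5.
* **Wilcoxon rank-sum**: exact null when both groups ≤ 25 and the pooled
  sample is tie-free, otherwise the normal approximation with tie and
  continuity corrections (via scipy).
* **Fisher's exact test**: 2×2 via scipy (probability-mass ordering);
  2×K tables with K ≤ 5 and n ≤ 500 by full enumeration of the conditional
  hypergeometric distribution (validated against R's `fisher.test`),
  larger tables by seeded Monte-Carlo permutation.
* **Multivariate Cox covariates**: complete cases only; categorical
  covariates are reference-coded with the most frequent level as reference.

## Synthetic data generator

The generator emulates the *statistical* structure the funnel assumes —
it makes no attempt to mimic real colorectal-cancer expression covariance,
pathway structure, or platform noise, so passing tests demonstrate that the
pipeline recovers the signal class it targets, not that it will perform
identically on real tumors.

Per cohort: gene baselines μ_g ~ N(7, 1) with i.i.d. N(0, noise_sd) noise
per sample (log-intensity-like scale); a configurable number of purely
age-differential genes receive an additive ±age_effect_size shift in the
early-onset stratum (default 2.0 on unit noise — a clearly detectable but
not trivial separation). Each planted pair's two genes share a baseline
mean, so the high-risk ordering occurs in about half the samples, and both
receive the same age shift so the pair can enter the funnel's candidate
universe (whose first stage only passes age-related genes) without the
ordering itself being age-dependent. Planted roles, means and signs depend
only on the seed, so cohorts with different labels share one ground truth;
noise, ages and survival draws are label-specific.

Survival: event times are exponential with hazard
h_s = baseline_hazard · exp(β · (Σ_p x_{p,s} − P/2)), where x_{p,s} is the
true REO state of planted pair p, β = planted_log_hr (default ln 3) and
P the number of planted pairs — the proportional-hazards model the
screening stage assumes, acting through the REO state and hence invariant
to batch distortions by construction. Censoring is independent uniform
U(0, τ) with τ solved numerically (bracketed Brent) so the expected
censored fraction equals the target (default 20%); the realized fraction is
reported in the ground truth. Default cohort size is 300 samples split
evenly between strata; all samples are surgery-only unless `frac_act` is
set. Baseline hazard 0.02 events/month puts the median event time near
three years, a plausible relapse-free-survival scale.

Batch distortions (`apply_batch_transform`) replace each sample's column by
a strictly increasing map: positive-slope affine, per-sample shifted log or
power, within-sample ranks, or a random increasing piecewise-linear map;
non-monotone specifications are rejected.

## Problem sizes used by tests and the acceptance script

The reference study is 300 samples per cohort, 500 genes, 40 age-DE genes,
5 planted pairs at HR 3, 20% censoring, with a different distortion family
per cohort; recovery statistics aggregate 25 independent seeds. Oracle
agreement checks use 100–200 random instances of size ≤ 60; the null
calibration of the dual-cohort screen uses 2000 genes × (10–20) seeds.
These sizes give Monte-Carlo errors comfortably below the asserted margins
while keeping the suite quick on a single CPU.

## Known limitations

* The DEG stage's Wilcoxon p-values are computed per gene with no
  dependency modelling; correlated genes inflate the variance of funnel
  counts relative to the independence calculation.
* The greedy subset search offers no optimality guarantee (the tests only
  assert it never exceeds the exhaustive best); no cross-validation or
  backward elimination is provided, mirroring the single-split design the
  method targets.
* Expression input must be complete: REO of a missing value is undefined
  and no imputation rule is applied.
* Multi-probe-to-gene collapsing for array platforms is upstream of this
  package.
* No time-dependent covariates, competing risks, or proportional-hazards
  diagnostics.
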