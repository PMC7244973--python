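# Methods

This note documents the model implemented by `mtskit`, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where the method's literature is silent.

## The model

MTS treats diagnosis as one-class scoring: the "normal" condition is
modeled, and abnormality is distance from it. The reference
(Mahalanobis) space is the triple (μ, σ, **C**) estimated from healthy
subjects — per-variable sample mean and SD (n−1 denominator) and the
Pearson correlation matrix of the standardized variables. The score is
the scaled Mahalanobis distance MD = zᵀ**C**⁻¹z/k with
z = (x − μ)/σ and k the variable count. Scaling by k gives the
conventional MTS diagnostic anchor: the construction sample's mean MD is
exactly (n−1)/n, so healthy ≈ 1 regardless of how many variables are
used. The classical quadratic form (no /k) is available via
`md_definition: unscaled`.

Assumptions worth stating: the method uses only first and second
moments, so it does not require Gaussian data, but its distance is only
as meaningful as the correlation estimate — hence the pruning and
pseudo-inverse safeguards below. It assumes the healthy group is a
coherent single population; the control-chart screen exists to remove
contaminating outliers before the space is frozen.

## Pipeline stages and their parameters

| Parameter | Default | Meaning |
|---|---|---|
| `correlation_threshold` | 0.80 | prune one member of each variable pair with \|r\| strictly above this (fraction, fitted on the healthy group only) |
| `reserved_variables` | 14 CBC names | ordered keep-list deciding which member of a flagged pair survives |
| `refinement_max_passes` | 1 | rounds of XmR outlier screening of the healthy set |
| `md_definition` | `scaled` | divide MD by k (healthy mean ≈ 1) or not |
| `condition_bound` | 1e10 | correlation condition number above which a Moore–Penrose pseudo-inverse is used (with a warning, never silently) |
| `cv_folds` | 10 | folds for the optional group-stratified cross-validation |
| `rng_seed` | 0 | drives fold assignment and simulation |

**Missing data.** Any blank or non-numeric cell is an explicit NaN
marker; subjects with any missing cell are dropped (no imputation).
Missingness is never coerced to a number.

**Correlation pruning.** Flagged pairs are processed greedily in
descending |r|; the survivor is the pair member appearing earlier in the
keep-list, falling back to the lower column index; if both members are
reserved, both are kept. Greedy descending order makes the result
invariant to input column permutation when the r values are distinct.
Pruning an already-pruned table is a no-op. Constant variables have
undefined correlation and are removed up front with a warning.

**Refinement.** Each pass scores the construction rows *in input order*
and removes those with MD strictly above T = μ + 2.66·R̄, where R̄ is the
mean absolute successive difference (the individuals/moving-range chart
with d₂ = 1.128, 3/d₂ = 2.66). The moving range is inherently
order-dependent; the row order used is the input order and removals are
recorded by position. One pass is the default; more passes iterate to
convergence and the construction set can only shrink.

**Orthogonal-array screening.** `generate_oa(m)` uses the
Hadamard/parity construction: n_runs = the smallest power of two
strictly greater than m; column c (1…n_runs−1) has row-r entry
1 + popcount(r AND c) mod 2. Every column is balanced and every column
pair shows each level combination n_runs/4 times; both properties are
verified exhaustively in tests up to 64 runs. Level 1 = included,
level 2 = excluded; run 1 (row 0) is the full model. The per-run space
is refitted on the *refined* healthy survivors restricted to the run's
included variables. Run SN ratios use the larger-the-better form on the
abnormal group's distances; gains are level-1 minus level-2 mean SN, and
selection keeps strictly positive gains (a zero gain is not selected),
ordered by descending gain. If no gain is positive the pipeline falls
back to all pruned variables with a prominent warning (exit code 2 in
the CLI). The column ordering of the parity construction differs from
Taguchi's canonical tables; the packaged worked example therefore ships
its printed design matrix verbatim (`mtskit.datasets`), since gains
depend on the actual column assignment.

Two properties of the larger-the-better SN on scaled MDs deserve
explicit mention, because they shape what "null" gains look like:

* E[1/MD] for a k-variable scaled distance behaves like k/(k−2) — runs
  with very few included variables have strongly negative SN (and for
  k ≤ 2 the expectation diverges). Designs should keep every run's
  included count comfortably above 2.
* With genuine signal of fixed noncentrality λ, adding an uninformative
  variable spreads λ over k+1 instead of k dimensions, shifting that
  run's SN by ≈ 10·[log₁₀((k+1+λ)/(k+λ)) − log₁₀((k+1)/k)] < 0. Null
  variables therefore carry a small *negative* expected gain (about
  −0.5 dB at λ ≈ 27 and k ≈ 6–10) under the scaled definition — visible
  also in the packaged worked example, where every non-selected variable
  has a small negative gain. Under the unscaled definition the bias is
  instead slightly positive. This is a structural property of the
  statistic, not an estimation artifact.

**Thresholding.** Candidate thresholds are midpoints between
consecutive sorted unique pooled MDs plus sentinels beyond both
extremes; the decision rule is strict (abnormal iff MD > t, so a subject
exactly at the threshold is called normal). AUC is computed by the
trapezoidal rule and verified internally against the Mann–Whitney rank
statistic with ties half-weighted — the two must agree to 1e-9 or the
computation aborts. The operating point maximizes the Youden index; at
ties the smallest threshold wins (favoring sensitivity). The final
threshold is taken from the training ROC of the refined healthy
survivors versus all training abnormals, scored in the selected-variable
space. When all pooled scores are identical the curve is flagged
degenerate (AUC 0.5, threshold NaN).

**Cross-validation.** The two groups are partitioned independently
(group-stratified) into near-equal folds by the seeded RNG; the entire
training procedure — pruning, refinement, screening, thresholding — is
re-run on each training portion, and held-out subjects are classified at
that fold's threshold. Folds whose training fails are skipped with a
warning. Same seed, same folds, same metrics, byte-identical reports.

## Synthetic data: what it emulates and what it does not

The generator draws the healthy group from a multivariate normal with
configurable means, SDs, and correlation (eigen-decomposition square
root, so positive-semidefinite matrices are accepted), and the abnormal
group identically except for mean shifts expressed in healthy-SD units.
Optional near-duplicate columns (a noisy standardized copy of an
existing variable) manufacture |r| > 0.99 pairs to exercise pruning, and
missing cells can be injected completely at random.

`default_blood_profile()` is a 14-variable complete-blood-count profile
at adult reference scales with 1,480 healthy / 355 abnormal subjects, a
moderate physiological correlation structure (counts with their ratios
and the total white count; red-cell indices with each other; platelet
morphology variables with each other), one near-duplicate of EO#, and a
0.001 missing rate. Disease shifts are concentrated on seven markers —
PDW 2.5, MPV 1.6, WBC 1.2, EO# 1.0, LY −1.0, LY# 0.8, MCHC 0.6 SD —
sized so the groups separate about as strongly as in the clinical
setting the profile emulates (training AUC in the mid-0.9s) and so the
dominant markers are PDW then MPV.

What passing tests on this profile show: the pipeline recovers planted
structure (pruned duplicates, shifted markers, strong separation) from
data whose second-moment geometry resembles a real CBC panel. What they
do not show: behavior under the skewness, heavy tails, measurement
quantization, age/sex structure, and instrument batch effects of real
blood counts — the generator is Gaussian by design, because the method
consumes only means and covariances and Gaussian data admits closed-form
checks (a log-normal switch would be the natural extension point). No
claim is made that the profile matches the unpublished clinical data's
distributions.

## Numerical choices and degenerate inputs

* Near-singular correlation (condition number > 1e10) or n ≤ k triggers
  a pseudo-inverse plus a warning; tiny negative quadratic forms from
  pseudo-inverse round-off are clipped at zero, anything below −1e-8 is
  an error.
* Zero-variance variables: an error when fitting a space (named in the
  message); dropped with a warning during pruning.
* Pearson pruning requires ≥ 3 complete subjects; refinement requires
  k + 2 survivors to refit.
* An orthogonal-array run whose included set would be empty is a
  configuration error (cannot occur for the parity construction, whose
  first row is all level 1 and whose columns are balanced).
* Report serialization converts non-finite floats to JSON null; field
  order is declaration order so identical runs produce byte-identical
  reports.

## Known limitations

* No robust covariance (MCD) option; a single gross outlier influences
  the initial space before the control chart can remove it.
* Single-pass refinement by default; the multi-pass variant can be
  overly aggressive on heavy-tailed healthy data.
* No interaction columns or three-level arrays; gains are main-effect
  contrasts only.
* Threshold selection is unweighted Youden; no costs, prevalence
  adjustment, or confidence bands on the ROC.
* Problem sizes in the test suite (hundreds of subjects, ≤ 14 variables,
  ≤ 100 replicate seeds) were chosen to keep the full suite fast while
  leaving Monte-Carlo margins wide; all are set in one place per test and
  scale up directly.
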