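# Methods

## Data model

Reporter-ion intensities are modelled on the log2 scale.  For protein *g*,
biological sample *j* in batch *b*:

    y_gj = mu_g + beta_g·1[j is case] + gamma_bg + delta_bg · eps_gj,
    eps_gj ~ N(0, sigma²)

where `mu_g` is the protein baseline, `beta_g` a group effect (0 for most
proteins), `gamma_bg` an additive per-batch, per-protein shift,
`delta_bg` a multiplicative inflation of the residual scale, and `sigma`
the within-group residual SD.  Intensities are exponentiated to the linear
scale for storage, matching reporter-ion semantics; zero intensities on
input are treated as non-detections (missing).

### Synthetic generator (`tmtdiff.simulate`)

The generator draws from exactly this model and emulates the multi-batch
TMT design end to end: `n_batches` batches (default 3), each holding one
pooled reference channel plus an even split of the `n_case` + `n_control`
biological samples (default 15 + 15, i.e. 5 + 5 per batch).  Defaults are
the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `effect_log2fc` | log2 1.5 ≈ 0.585 | spiked group effect, split 50/50 up/down |
| `residual_sigma` | 0.208 | within-group log2 SD (typical for TMT protein-level data) |
| `spike_fraction` | 0.10 | fraction of proteins with a true effect |
| `batch_additive_sd` | 0.3 | SD of `gamma_bg` (log2 units) — a clearly visible batch effect |
| `batch_multiplicative_shape` | 20 | inverse-gamma shape of `delta²_bg`, mean fixed at 1 (mild inflation); `None` disables |
| `missing_rate` | 0.02 | per-entry MCAR missingness on biological channels |
| `baseline_mean`, `baseline_sd` | 20, 2 | log2 baseline law (reporter intensities span a few orders of magnitude) |

The reference channel holds, per protein, the linear mean of all
biological samples' noise-free intensities, as a pooled aliquot would.
Batch effects perturb biological channels only: they represent the
*residual* technical variation that survives master-pool normalization
(if the same shift also hit the reference it would cancel exactly in the
ratio and batch correction would have nothing to do).  Missingness is
MCAR and restricted to biological entries.

What the generator does **not** emulate: intensity-dependent (MNAR)
missingness, peptide-to-protein rollup noise, isotopic-interference
compression of fold changes, correlated proteins (co-regulation), and
outlier samples.  Calibration results on these simulations therefore
certify the statistical machinery under its stated model, not robustness
to every pathology of real data.

## Normalization cascade (`tmtdiff.normalize`)

Order is enforced (a `StateError` otherwise): reference → median →
log2/z-score → missing filter → batch correction.

- **Reference normalization** divides each biological intensity by the
  same-batch reference value; missing propagates, and a missing (or zero)
  reference blanks that protein for the whole batch.
- **Median centring** divides each protein row by its median over observed
  samples, so every row has median 1.
- **log2 + z-score** standardizes within each sample column using the
  sample SD (*n*−1).  Whether the original convention was per sample or
  per protein is genuinely ambiguous in the field; both are provided
  (`axis="sample"` default, `axis="protein"` option).  Note that the
  per-sample z-score rescales effect sizes: a log2 effect of 0.585
  appears as ≈ 0.585/SD(column) in z units.  All downstream statistics
  (t, AUC) are scale-invariant, so this affects display, not inference.
- **Missing filter** keeps exactly the proteins with zero missing entries.
  Under MCAR at rate r with n samples, a fraction (1−r)^n survives
  (0.98³⁰ ≈ 0.55) — the steep cost of the complete-case rule is a
  property of the rule, not of this implementation.

## Batch correction (`tmtdiff.combat`)

Standard parametric empirical-Bayes location/scale adjustment.  Each
protein is standardized against an OLS fit of batch indicators (plus an
optional protected covariate); per-batch location `gamma_hat` and scale
`delta2_hat` estimates are shrunk toward a Normal and an inverse-gamma
prior (moment-matched per batch) by the usual joint iteration until the
relative change falls below `tol` (1e-4, the conventional value), then
removed, and the grand mean/covariate structure restored.  The
implementation agrees with Bioconductor `sva::ComBat` to ~1e-5 on shared
inputs (cross-checked in the test suite, with and without covariates).

Two deliberate design choices:

- **No protected group covariate by default.**  In a batch-balanced
  design the case/control contrast passes through the correction
  untouched (group effects cancel in batch means), while *including* the
  group in the standardization model preserves the observed contrast by
  construction and demonstrably exaggerates downstream significance: on
  global-null simulations the probability that the SAM procedure makes
  any false selection at q < 0.05 rises from ≈0.06 to ≈0.13 when the
  covariate is protected.  Protection remains available
  (`protect_group="auto"`) for designs where groups are unevenly spread
  over batches — there it is necessary to avoid erasing signal.
- **Correction is not exactly idempotent.**  Shrinkage leaves a residual
  of order the per-batch SEM; re-application contracts it further
  (measured contraction ratio ≈ 0.5 per pass on batch-free data).  The
  tests assert contraction and the shrinkage-floor bound rather than a
  fictitious exact fixed point.

The PCA diagnostic treats samples as observations and reports the mean
silhouette of batch labels on the first two components: ≈0 for no batch
structure, →1 for complete separation.  On simulated data with the
default batch effects, silhouette falls from ≈0.95 to ≈−0.1 after
correction.

## SAM selection (`tmtdiff.sam`)

The moderated statistic is d = (x̄_case − x̄_control)/(s + s0) with s the
pooled two-sample SE and s0 ≥ 0 a stabilization constant.  s0 defaults to
0.1 — a conventional volcano-plot choice — and is an analysis setting to
be reported, not a constant; it shapes the curved significance boundary
(`volcano_boundary` reproduces that curve, flat when s0 = 0).  Plain
Student t (pooled variance) p-values accompany d, per the usual practice
when Shapiro–Wilk checks (`shapiro_normality`) show most proteins
consistent with normality; a Welch variant sits behind
`equal_variance=False`.

q-values: for the threshold at each observed |d|,
q = (mean over permutations of #{|d*| ≥ |d|}) / #{observed |d| ≥ |d|},
clipped to [0, 1] and monotonized by a running minimum from the least
significant rank upward, so q is non-decreasing as |d| falls and the
selected set is upward-closed.

Permutation scheme — two choices that matter for calibration:

- **Within-batch permutations (default).**  Labels are permuted inside
  each batch, preserving per-batch group counts.  Unrestricted
  permutations are not exchangeable with the observed labelling when the
  data retain any batch structure (including the small residue left by
  empirical-Bayes correction), and measurably inflate the null selection
  rate (≈0.09 vs ≈0.06 per dataset).
- **Uniform rather than balanced draws.**  "Balanced" permutations
  (swapping exactly half of each group) are offered behind a flag but are
  not the default: they are not a subgroup of the permutation group and
  are known to bias extreme tails.

When the requested permutation count reaches the number of distinct label
assignments, the implementation enumerates them exhaustively (and the
result becomes seed-independent).

Calibration, measured on global-null simulations (1000 proteins, 15 vs
15, defaults): the probability that any protein is selected at q < 0.05
is ≈0.05–0.07 per dataset — i.e. FDR = E[FDP] sits at the nominal level —
and with 10% spiked proteins at the design effect size, power is 1.0 at
empirical FDR ≈ 0.03–0.05.

## Bootstrap ROC/AUC selection (`tmtdiff.bootauc`)

AUC uses the Mann–Whitney pair-counting identity with midrank ties; a
protein's B resamples (default 1000) are stratified — cases resampled
from cases, controls from controls, sizes preserved — and evaluated
exactly from resample multiplicities (`c^T G m / (n1·n2)` with G the
pairwise win matrix), which makes the whole matrix a single einsum.  An
all-tied resample contributes AUC 0.5 automatically.

The q procedure compares observed mean AUCs against mean AUCs recomputed
under label permutations (default 20, within-batch).  Proteins split into
an upper (mean AUC > 0.5) and lower (< 0.5) tail; within each tail,
sorted toward its extreme, q at each observed value is the per-permutation
average count of null means at least as extreme divided by the observed
count, clipped and monotonized; exactly 0.5 gets q = 1.  The ratio is
oriented null/observed — the orientation that estimates an FDR in [0, 1];
the transposed literal variant is available behind `literal_ratio`.
Measured null calibration: P(any selection) ≈ 0.07 per dataset at B = 200.

`rank_by_sd` orders selected proteins by bootstrap-SD ascending (ties:
larger |mean AUC − 0.5| first, then id) — the "most stable discriminators
first" reading of the AUC table.

## Over-representation analysis (`tmtdiff.enrichment`)

One-sided hypergeometric upper tail P(X ≥ k) (`method="fisher"`), or the
EASE variant P(X ≥ k−1) that discounts one selected member
(`method="ease"`), with BH correction across sets.  The background is the
tested universe — the proteins surviving the missing-value filter — and
PH (the pathway total) is the set restricted to that background, keeping
the hypergeometric model coherent; the raw set size is available as a
display option.  Gene symbols match case-insensitively.  p-values agree
with exhaustive enumeration on all instances with background ≤ 12
(tested).

## Power analysis (`tmtdiff.power`)

Exact two-sample noncentral-*t* power: with standardized effect
d = |delta|/sigma, per-group size n, the test statistic under the
alternative is noncentral t with noncentrality d·√(n/2) and 2n−2 df;
power is the rejection mass beyond the central-t critical value
(two-sided by default — the conventional calculator; one-sided
available).  `sample_size` inverts this for fractional n by bracketing +
Brent to |power − target| < 1e-8.  The defaults (delta 0.585, sigma
0.208, alpha 1e-4, power 0.8) give n = 9.4, confirmed independently by
Monte-Carlo rejection rates in the tests.  scipy's noncentral-t tail
underflows to NaN in extreme regimes; the implementation falls back to
the Normal limit for the dominant tail and 0 for the vanishing one.
Designs whose target power is already reached below n ≈ 1.1 (df < 0.2)
are rejected as meaningless.

## Problem sizes and tolerances

Calibration tests and the acceptance script use 1000-protein simulations,
20 seeds, 250 label permutations (SAM) and B = 200 bootstrap resamples —
sizes at which every Monte-Carlo quantity has stable first digits while
the full suite runs in minutes.  The null FDR checks apply a one-sided
binomial criterion (selections across 20 seeds compatible with a 5%
per-dataset rate at 95% confidence) because the per-seed FDP on null data
is Bernoulli and its 20-seed mean is coarse (granularity 0.05).
Numerical tolerances: z-score post-conditions at 1e-9; EB convergence at
1e-4 relative; oracle agreements at 1e-12 (combinatorics) and 1e-3
(cross-implementation ComBat).

## Known limitations

- Complete-case missing-value handling only; no imputation.
- Parametric empirical-Bayes priors only (no non-parametric variant).
- Two-class designs only; no paired or multi-class statistics.
- ORA p-values depend on the chosen background; enrichment levels from
  tools with proprietary backgrounds are reproducible in rank order and
  arithmetic (Count/PH/Percent) but not in exact p.
- The pipeline's FDR guarantees are certified under the generator's
  model; correlated proteins or MNAR missingness can degrade them.
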