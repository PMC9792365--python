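# tmtdiff

Differential-expression analysis for multi-batch isobaric-labelling (TMT)
proteomics: reference-pool normalization, empirical-Bayes batch correction,
dual feature selection by SAM-style permutation FDR and bootstrap ROC/AUC,
gene-set over-representation analysis, and two-sample power/sample-size
planning — plus a synthetic-data generator with ground truth so the whole
cascade can be calibrated without any external download.

## The problem

Multiplexed TMT experiments quantify thousands of proteins across samples,
but a single run holds at most ~11 channels, so cohorts are split into
several batches.  Each batch carries one channel of a *master pool* (equal
parts of every biological sample) as an internal reference.  Comparing
case vs control across batches then requires a normalization cascade and a
selection procedure whose false-discovery rate can be trusted.  `tmtdiff`
implements that pipeline as a tested, reusable library:

1. **Reference normalization** — each reporter intensity is divided by the
   same-batch master-pool value for that protein, cancelling shared
   run-level effects.
2. **Median centring** — each protein row is divided by its median ratio,
   putting proteins on a common relative-abundance scale.
3. **log2 + z-score** — relative abundances are log2-transformed and
   z-scored within each sample (sample SD, *n*−1).
4. **Missing-value filter** — proteins with any missing value are removed
   before statistics.
5. **Batch correction** — a parametric empirical-Bayes location/scale
   adjustment (the ComBat model): per-batch, per-protein effects
   γ̂<sub>bg</sub>, δ̂²<sub>bg</sub> are shrunk toward Normal /
   inverse-gamma priors and removed.  A 2-D PCA with a silhouette-by-batch
   score quantifies batch separation before and after.
6. **SAM selection** — a moderated statistic d = (x̄₁ − x̄₂)/(s + s₀) with
   label-permutation q-values: at the threshold of each observed |d|,
   q = (mean permuted count ≥ |d|) / (observed count ≥ |d|), clipped,
   monotonized, selected at q < 0.05.
7. **Bootstrap ROC/AUC selection** — per protein, B stratified resamples
   with replacement give a mean and SD of the AUC (Mann–Whitney pair
   counting, midrank ties); q-values come from a sorted-ratio comparison
   of observed vs label-permuted mean AUCs, split into upper (>0.5) and
   lower (<0.5) tails.
8. **Intersection + ORA** — the final differential set is the intersection
   of both selections; over-representation against GMT gene sets uses the
   hypergeometric upper tail (or the EASE variant) with Benjamini–Hochberg
   correction, reporting Count/PH/Percent like the usual pathway tables.
9. **Power analysis** — exact noncentral-*t* two-sample power: the
   fractional per-group n solving power(n) = target with noncentrality
   (δ/σ)·√(n/2) and 2n−2 degrees of freedom.

## Worked example

```python
from tmtdiff import (SyntheticConfig, generate_dataset, reference_normalize,
                     median_center, log2_zscore, drop_missing, combat_adjust,
                     SamConfig, sam_q, BootAucConfig, bootstrap_auc,
                     null_bootstrap_auc, bootauc_q, intersect_selections,
                     evaluate_selection)

table, truth = generate_dataset(SyntheticConfig(n_proteins=1000, seed=11))
adjusted, _ = combat_adjust(drop_missing(log2_zscore(median_center(
    reference_normalize(table)))))

sam_rows = sam_q(adjusted, config=SamConfig(n_permutations=250, seed=1))
cfg = BootAucConfig(n_bootstrap=1000, n_label_permutations=20, seed=2)
auc_rows = bootauc_q(bootstrap_auc(adjusted, config=cfg),
                     null_bootstrap_auc(adjusted, config=cfg), cfg)
common = intersect_selections(sam_rows, auc_rows)
cc = evaluate_selection(common.index, truth, universe=adjusted.protein_ids)
print(common.attrs, cc.empirical_power, cc.empirical_fdr)
```

prints

```
{'n_sam': 51, 'n_auc': 53, 'n_common': 50} 1.0 0.04
```

meaning: of ~550 proteins surviving the missing-value filter (10% of them
carrying a true ±1.5-fold effect at residual σ = 0.208), the SAM call
selected 51 and the bootstrap-AUC call 53; the 50 proteins common to both
recover every detectable spiked protein (power 1.0) at an empirical FDR of
0.04 — inside the q < 0.05 guarantee.  The power calculator
(`sample_size(PowerSpec(delta=0.585, sigma=0.208, alpha=1e-4,
target_power=0.8))`) returns **9.4** per group for that design, which is
why 15 per group leaves comfortable headroom.

Longer narrated versions of each capability live in `examples/` (run them
as plain scripts), and a thin CLI mirrors the library:

```bash
tmtdiff power --delta 0.585 --sigma 0.208 --alpha 0.0001 --power 0.8
tmtdiff simulate --n-proteins 1000 --seed 7 --outdir data/
tmtdiff run --config run.yaml --seed 42 --outdir results/
```

## Documentation

`docs/methods.md` describes the statistical model behind every stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.
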