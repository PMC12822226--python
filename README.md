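# sdcfe

Feature selection for high-dimensional omics classification tasks —
pancancer typing from RNA-seq, tumour staging from paired RNA-seq and
DNA-methylation profiles — where the features that separate the labelled
classes are not necessarily the features that capture the cohort's latent
structure.

`sdcfe` ranks genes by a **synergistic discriminative class feature
extraction** score that blends a supervised, robustly regularized variance
ratio with an unsupervised cluster-separation statistic:

```
            Σ_c w_c (μ_ic − μ_i)²
DCFE_i = ─────────────────────────────        w_c = n_c / N
          Σ_c w_c σ_c²(i) + λ·MAD_i

CS_i    = one-way ANOVA F of gene i across a K-means partition of samples

sDCFE_i = α · DCFE_i + (1 − α) · CS_i
```

where μ_ic and σ_c²(i) are the class mean and (population) class variance of
gene *i*, μ_i its grand mean, MAD_i its median absolute deviation across all
samples, and α ∈ [0, 1] weighs discrimination against cluster structure
(defaults α = 0.7, λ = 0.1; both components min–max normalized across genes
before blending). The MAD term damps genes whose apparent class separation
is an artifact of heavy dispersion; the CS term promotes genes tracking
hidden subtypes that the labels do not encode.

Around the scorer the package provides, for anyone assembling an omics
classification pipeline:

- **preprocessing** — missingness audit and filtering, KNN imputation,
  log2 transform, z-score scaling with train/test discipline, clinical-label
  matching, and zero-fill alignment of a validation cohort to a trained
  feature list;
- **selection algebra** — an XGBoost importance-ranking adapter
  (importance > 0 retention), intersection with Venn accounting,
  non-redundant union, and late fusion of per-omics selections on matched
  samples;
- **novelty tiering** — classifying candidate biomarkers as
  established / emerging / novel from a binary gene-by-resource evidence
  table (COSMIC, OncoKB, CIViC, ONGene, HPA, DisGeNET);
- **evaluation** — a nearest-centroid baseline plus confusion matrices,
  precision/recall/F1, balanced accuracy, macro-F1, multiclass MCC, macro
  one-vs-rest AUC and macro expected calibration error;
- **synthetic data** — a generator for multi-class expression cohorts with
  planted informative genes, latent subtypes, MCAR missingness and paired
  two-omics designs, so everything is testable offline.

## Worked example

Score a simulated four-class cohort (200 samples × 1000 genes, 30 planted
marker genes shifted by two standard deviations):

```python
from sdcfe import (SimulationConfig, simulate_expression,
                   SDCFEParams, score_features, select_top_k)

cfg = SimulationConfig(n_classes=4, n_per_class=50, n_genes=1000,
                       n_informative=30, effect_size=2.0, seed=0)
m, y, planted, _ = simulate_expression(cfg)
table = score_features(m, y, SDCFEParams(alpha=0.7, lam=0.1, seed=42))
print(table.head(5).to_string(index=False))

top30 = select_top_k(table, 30)
print("recall of planted genes in top 30:",
      len(set(top30) & set(planted)) / 30)
```

prints

```
feature_id     dcfe       cs    sdcfe  rank      mad
    G00022 0.832179 7.543295 0.869679     1 1.034427
    G00019 0.909657 5.874442 0.863902     2 0.923545
    G00024 0.980769 2.435352 0.788794     3 0.768095
    G00028 0.925522 3.277983 0.780201     4 0.905132
    G00017 0.942456 2.909723 0.778810     5 1.008460
recall of planted genes in top 30: 1.0
```

Every top-ranked gene here is one of the 30 planted markers: its
between-class variance dominates the regularized within-class spread
(`dcfe`), and several also separate the K-means clusters (`cs`). The same
run is available from the shell:

```sh
sdcfe simulate --seed 0 --out-dir fixtures/
sdcfe score --matrix fixtures/matrix.tsv --labels fixtures/labels.tsv \
      --alpha 0.7 --lam 0.1 --seed 42 -o scores.tsv
sdcfe select scores.tsv --fraction 0.5 -o top.txt
```

Other subcommands: `preprocess`, `intersect`, `fuse`, `tier`, `evaluate`,
and `pipeline` (a JSON-configured end-to-end run writing a reproducible
manifest).

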