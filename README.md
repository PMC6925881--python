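# spectrocycle

Label-free identification of cell-cycle phase from multispectral
autofluorescence microscopy.

Dividing cells pass through G1 (growth), S (DNA synthesis), G2 (second
growth) and M (mitosis).  Standard ways of assigning a cell's phase need
DNA stains, antibody markers (PCNA) or reporter transformation.  Endogenous
fluorophores — free and protein-bound NAD(P)H, FAD and protoporphyrin IX
(PPIX) — offer a label-free alternative: imaging cells in many
excitation/emission channels captures metabolic and compositional state
without touching the cells.  `spectrocycle` implements the complete
analysis pipeline for such data and, because no public dataset of this kind
exists, a synthetic-scene generator with known ground truth that every
stage is tested against.

## Pipeline

1. **Channels** (`spectrocycle.channels`) — the 34-channel acquisition
   layout: 18 narrow-band excitations (340–660 nm, ±5 nm) crossed with four
   emission bands (440/475/593 nm bandpass ±20 nm, 715 nm long-pass).
2. **Synthetic scenes** (`spectrocycle.synth`) — elliptical cells from three
   cancer lines (HeLa, MIA-PaCa-2, PANC1) in four phases; per-cell
   abundances **a** of the four fluorophores drawn lognormally with strong
   between-line and weak between-phase effects; pixel signal
   `photon_scale · (M a) · texture(p)` plus background, vignetting, Poisson
   shot noise and dead/saturated pixels, written as 16-bit multi-page TIFF.
3. **Preparation** (`spectrocycle.preprocess`) — neighbour-median repair of
   defective pixels, polynomial flat-field, percentile background
   subtraction, Anscombe-domain denoising.
4. **Features** (`spectrocycle.features`) — per cell: 34 channel means, 561
   channel ratios, per-channel standard deviation, skewness, GLCM entropy
   and homogeneity (731 features).
5. **Classification** (`spectrocycle.discriminate`) — per feature one-way
   ANOVA gate (P < 0.005, at most 13 features kept), projection to two
   canonical variables (Fisher discriminant axis plus the orthogonalised
   leading within-class residual axis), linear classifier
   `sign(wᵀz + b)`, stratified 10-fold cross-validation, ROC/AUC.
   Cell-cycle phase uses a two-stage decision tree — G1 vs S/G2+M, then
   S vs G2+M (M is merged with G2) — and the same machinery classifies
   cell origin (pancreatic vs cervical).
6. **Cluster overlap** (`spectrocycle.overlap`) — each projected cluster is
   summarised by its 1-SD (Mahalanobis distance 1) covariance ellipse;
   overlap of two clusters is IoU = 100 · intersection / union ∈ [0, 100] %.
7. **Unmixing** (`spectrocycle.unmixing`) — nonnegative least squares
   against the endmember matrix recovers abundance fractions per cell, the
   optical redox ratio FAD/NAD(P)H and the bound/free NAD(P)H ratio, with
   two-sided Mann–Whitney U comparisons between phases within each line.

## Worked example

```python
import numpy as np
from spectrocycle import synth, preprocess, features, discriminate as disc

dataset = synth.make_dataset(synth.DatasetConfig(), seed=7)  # 600 cells
stacks = [preprocess.prepare(s, background=m == 0)[0]
          for s, m in zip(dataset.stacks, dataset.masks)]
table = features.build_feature_table(stacks, dataset.masks, dataset.truth)
cols = features.feature_columns(table)

sub = table[table.line == "PANC1"]
merged = disc.merge_g2m(sub["phase"])
report = disc.cross_validate(sub, np.where(merged == "G1", "G1", "rest"),
                             k=10, seed=7, positive_label="rest",
                             feature_cols=cols)
print(report.accuracy, report.auc)
```

On the default study (3 lines × 4 phases × 50 cells, seed 7) the pipeline
prints:

```
600 cells x 731 features
HeLa        G1|S/G2+M: acc 71.0% AUC 0.79 IoU 6% | S|G2+M: acc 72.0% AUC 0.78
MIA_PaCa_2  G1|S/G2+M: acc 67.0% AUC 0.72 IoU 16% | S|G2+M: acc 68.0% AUC 0.72
PANC1       G1|S/G2+M: acc 81.0% AUC 0.85 IoU 3% | S|G2+M: acc 72.7% AUC 0.82
origin      acc 99.8% AUC 1.000 IoU 0%
PANC1 bound NAD(P)H G1 vs S: U=252 p=6.1e-12 medians 0.555 -> 0.648
```

Cell-cycle stages are separable but noisy (accuracies ~67–81 %, AUC
0.72–0.85, overlapping 1-SD clusters), while cell origin separates almost
perfectly (disjoint clusters, AUC ≈ 1) — origin differences dominate phase
differences.  Unmixing detects the encoded phase effects, e.g. bound
NAD(P)H elevated in S vs G1 for PANC1.

A command-line interface mirrors the stages:

```bash
spectrocycle simulate --out data --seed 7
spectrocycle features --data-dir data --out features.csv
spectrocycle classify --features features.csv --task cycle --out report.json
spectrocycle unmix --features features.csv --endmembers data/endmembers.yaml --out abundance.csv
spectrocycle compare --abundance abundance.csv --out comparisons.csv
```

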