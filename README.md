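# stainshift

Tools for studying how **PHH3-assisted labelling changes mitotic-figure
ground truth** — and what that does to detectors that only ever see H&E.

Mitotic figures (MFs) are counted in hematoxylin & eosin (H&E) sections for
tumor grading, but raters disagree substantially on what counts as an MF.
Re-staining a slide against phospho-histone H3 (PHH3), an
immunohistochemical marker of mitosis, and overlaying the co-registered
image makes annotation far more consistent. The catch: PHH3 highlights
early-prophase cells that have **no mitotic morphology in H&E at all**.
Labels produced with PHH3 assistance therefore contain objects an H&E-only
observer — human or convolutional — cannot identify. From the H&E
perspective this is an *information mismatch* that acts like asymmetric
label noise and shifts the interpretation of what an MF label means.

`stainshift` makes this mechanism reproducible at desk scale, without any
clinical data:

* **`synthgen`** — generates co-registered H&E/PHH3 image pairs with known
  cell-level ground truth (five mitotic phases, PHH3-negative telophases,
  MF lookalikes, and *mismatch cells*: PHH3-positive early-phase cells
  rendered pixel-identically to plain nuclei in H&E) and simulates a
  13-expert, two-phase annotation study with per-rater sensitivities,
  localisation jitter, lookalike false positives and hindsight bias.
* **`consensus`** — distance clustering of multi-rater point annotations
  (7.5 µm radius, one vote per rater per cluster), support-thresholded
  consensus sets (≥ 6 of 13 experts), leave-one-out variants, the
  H&E-only / PHH3-assisted label-set derivation, and post-hoc cleaning.
* **`agreement`** — per-rater precision/recall/F1 against the leave-one-out
  consensus, ICC(3,k) of mitotic counts (the Spearman–Brown-adjusted
  fixed-panel form), Fleiss' kappa, and paired t-tests with Shapiro–Wilk
  checks and Bonferroni correction.
* **`detector`** — an anchor-free, FCOS-style detector plus a dual-input
  variant that fuses the H&E and PHH3 backbones per pyramid level with
  `F = ReLU(Conv1×1(LayerNorm(Cat(H, P))))`. Networks run on a small
  numpy automatic-differentiation engine included in the package
  (`stainshift.nn`), so everything trains on one CPU.
* **`evaluation`** — tiled whole-image inference with overlap, global NMS
  and seam-safe tile ownership; distance-matched average precision; and the
  train-label × eval-label experiment grid.
* **`latent`** — a mapping-network embedding of MF patches with test-time
  augmentation, UMAP projection, majority-vote TP/FN colouring across
  cross-validation models, and 75 % highest-density regions per mitotic
  phase group.

## Worked example

```python
import numpy as np
from stainshift.datamodel import StudyConfig
from stainshift.experiments import run_rater_study

report, study, label_sets = run_rater_study(StudyConfig(n_images=20, rng_seed=1))
print(f"leave-one-out F1:  P1 {report.f1_p1:.2f} -> P2 {report.f1_p2:.2f}")
print(f"count ICC:         P1 {report.icc_p1:.2f} -> P2 {report.icc_p2:.2f}")
print(f"consensus MFs:     P1 {report.consensus_count_p1} -> P2 {report.consensus_count_p2}")
print(f"paired F1 t-test:  t({report.f1_test.df}) = {report.f1_test.t_statistic:.2f}")
```

prints

```
leave-one-out F1:  P1 0.80 -> P2 0.88
count ICC:         P1 0.96 -> P2 0.98
consensus MFs:     P1 295 -> P2 371
paired F1 t-test:  t(12) = -7.93
```

i.e. on this synthetic panel, PHH3 assistance raises object-level agreement
(F1 0.80 → 0.88), makes the mitotic count nearly rater-independent
(ICC 0.96 → 0.98), and grows the consensus ground truth substantially —
the newly found objects dominated by mismatch cells identifiable only
through the IHC signal. The negative t statistic at 12 degrees of freedom
(13 raters) says P2 F1 is systematically higher.

A generated study can be written to disk and explored from the shell:

```bash
stainshift generate --out study/ --n-images 20 --seed 1
stainshift consensus study/annotations.jsonl --study-phase P2 --min-support 6
stainshift agree study/annotations.jsonl
```

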