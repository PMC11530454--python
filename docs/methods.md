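# Methods

## The mechanism under study

A mitotic figure (MF) label can be grounded in two different observables:
morphology visible in the H&E stain, or the biological fact of mitosis as
reported by the PHH3 immunostain. The two disagree systematically: PHH3
marks early prophase nuclei that show no mitotic morphology in H&E, and its
signal weakens in late telophase where the H&E morphology is clearest. A
ground truth built *with* PHH3 assistance therefore contains objects that
are invisible to any observer restricted to H&E. For an H&E-only detector
those labels behave as asymmetric label noise — during training they demand
positives that carry no signal, during evaluation they cap the measurable
recall — while a detector that receives both stains sees exactly the
information the annotators saw. Everything in this package exists to make
that asymmetry measurable on synthetic data with known cell-level truth.

## Synthetic study generator

`synthgen` generates images whose *information structure*, not texture,
matches a dual-stain annotation study.

**Cells.** Each image holds true MFs (Poisson mean 20 per 512-px image),
MF lookalikes (mean 10) and plain nuclei (mean 70), placed uniformly with a
minimum pairwise separation of one nucleus diameter (7.5 µm) so distance
clustering can never merge distinct cells. Phases follow a configurable mix
(default 24/24/37/7.5/7.5 % for pro/prometa/meta/ana/telophase). A fraction
`mismatch_fraction` (default 172/308 ≈ 0.56) of prophase/prometaphase cells
is PHH3-positive but not H&E-visible — the mismatch class. Telophases are
PHH3-positive with probability 0.7 (the marker's reduced late-phase
sensitivity); lookalikes and plain nuclei are never PHH3-positive. A cell
invisible in both stains cannot occur by construction.

**Rendering.** Flat eosin background, one shared disc renderer for all
nuclei. H&E-visible MFs additionally receive a phase-specific glyph:
metaphase an oriented bar, ana/telophase two separating lobes, and
prophase/prometaphase a deliberately *subtle* condensed disc with a small
dark core — the same cells human raters most often miss are also the
hardest for a detector. Lookalikes get exactly the metaphase glyph: in H&E
alone they are indistinguishable from true metaphases, and only the missing
PHH3 signal separates them. Mismatch cells go through the identical plain
nucleus code path, so their H&E rendering is pixel-identical to a
non-mitotic nucleus — the central invariant of the generator. The PHH3
raster shows faint counterstained nuclei plus brown blobs (intensity in
[0.6, 1]) at positions displaced by a smooth random deformation field with
bounded magnitude (default 3 px), emulating residual registration error;
annotations are always placed in H&E coordinates. The PHH3 raster also
carries nonspecific DAB background speckle (Poisson mean 40 small blobs per
512-px image at intensities below the positive range), as ubiquitous in
real immunohistochemistry: a detector cannot treat brown signal alone as
proof of mitosis.

**Raters.** Each of the 13 simulated experts carries per-phase H&E
sensitivities (panel means 0.55/0.65/0.85/0.80/0.80 plus an individual
skill offset, sd 0.12 — high enough that the first-phase consensus covers
most morphologically clear MFs, so the consensus growth under PHH3
assistance is driven by the mismatch class), a PHH3 sensitivity near 0.95,
a lookalike
false-positive rate (mean 0.25), Gaussian localisation jitter (mean
1.25 µm), and a hindsight-bias probability (mean 0.55) of calling a
morphology-free PHH3-positive cell H&E-identifiable. In the PHH3-assisted
phase a rater annotates both-stain cells with the larger of the two
sensitivities, H&E-only cells (PHH3-negative telophases, plus lookalikes at
0.3× their false-positive rate — the missing IHC signal suppresses most of
those errors) and mismatch cells with the PHH3 sensitivity, classed
`PHH3_ONLY` unless hindsight upgrades them. The washout between phases is
modelled as independent random substreams per (phase, rater): no memory.
These defaults place the simulated panel in the regime the mechanism
requires — object agreement markedly higher with assistance, a consensus
that grows by mixed newly-found objects (genuinely overlooked MFs and
hindsight-upgraded mismatch cells) — without targeting any particular
numeric value.

**What the generator does not emulate:** tissue texture, stain variability,
scanner artefacts, focus problems, registration failure beyond smooth
deformation, inter-tumor-type differences, or rater correlation (experts
err independently here; real raters share biases). Passing tests therefore
demonstrate the *information-mismatch mechanism and the correctness of the
statistics*, not performance on real slides.

## Consensus clustering

Greedy incremental clustering with a deterministic processing order:
annotations sorted by (rater id, x, y); each joins the nearest existing
cluster whose running-mean centroid lies within 7.5 µm and which has no
member from the same rater (ties broken by lowest cluster index), otherwise
it founds a new cluster. Support counts are counts of distinct experts.
The full-panel consensus threshold is 6 (half of the *remaining* experts,
matching the one-vs-all scoring that uses 6 of 12); the leave-one-out
threshold is ceil(0.5 · (k − 1)). The processing order, running-mean
centroid update and tie-break are implementation decisions — the clustering
rule itself does not determine them — and the test suite pins them against
an independently coded executor of the same ordered rule.

PHH3-assisted labels pool the `HE_AND_PHH3` and `HE_ONLY` classes *before*
clustering; `PHH3_ONLY` clicks never contribute support. Cleaning removes
newly-found consensus points that a ≥3-expert majority judged
non-recognizable; points already present in the H&E-only set are never
removed. The synthetic post-hoc panel in the experiments is truthful
(verdict = the cell's `he_visible` flag); the reproduction script
additionally simulates a noisy three-expert panel (each expert correct with
probability 0.7, reflecting how hard borderline early-phase calls are) to
exercise Fleiss' kappa in the low-agreement regime such a review produces.

## Agreement statistics

* **Matching** is greedy one-to-one by ascending distance within 7.5 µm
  (deterministic tie-breaks). Greedy matching is not guaranteed
  maximum-cardinality: on deliberately overcrowded instances (ten points in
  a 150-px square) it can lose one pair to a chain. At cell density —
  points separated by at least a nucleus diameter — it is exactly optimal
  on every tested instance, and the tests pin both facts.
* **ICC** is the two-way mixed-effects, consistency, average-of-k-raters
  form computed from ANOVA mean squares, ICC(3,k) = (MS_T − MS_E)/MS_T,
  with the single-rater form and the Spearman–Brown identity exposed for
  verification; a two-way random-effects ICC(2,k) is available behind
  `icc_random_raters`. Zero between-target variance raises an explicit
  error.
* **Fleiss' kappa** is the standard (P̄ − P̄e)/(1 − P̄e) on an
  n-subjects × categories count matrix with constant row sums; a single
  ever-used category is an explicit error. 0/0 conventions for P/R/F1 are
  zero throughout.
* **Paired testing** uses the paired t-test on per-rater metric differences
  (df = k − 1), reports the Shapiro–Wilk p of the differences, and declares
  significance at alpha divided by the number of metrics tested. Zero
  variance is reported explicitly rather than raised.

## Detectors

Both detectors are anchor-free, single-class, three-level designs in the
FCOS family: a backbone emits stage-2/3/4 feature maps, a feature pyramid
(lateral 1×1 + top-down nearest-neighbour upsampling + 3×3 smoothing)
feeds shared towers predicting per-location classification, centerness
(sqrt(min/max(l,r) · min/max(t,b))) and exp-scaled distances to the four
box sides; the losses are a focal classification loss (α 0.25, γ 2),
−log IoU box regression and centerness BCE, normalised by positive count.
Locations are assigned to pyramid levels by scale brackets of 8× the level
stride. Point labels become square boxes (default 50 px ≈ nucleus scale at
40×; the desk experiments use 32 px with 128-px patches).

The dual-input model duplicates the backbone per stain and fuses per level
with one independent merging network: channel concatenation (2C), LayerNorm
over the channel axis at each spatial position (a per-level whole-map
normalisation is available via `layernorm_mode="per_level"`), a 1×1
convolution halving 2C → C, then ReLU. Note that because the normalisation
mixes the concatenated channels, a constant PHH3 input still shifts the
statistics seen by the H&E channels — the fused model does not reduce
exactly to an H&E-only function, and its PHH3 input gradient is not zero;
the fusion contracts that do hold (shape, non-negativity, order
sensitivity, determinism) are what the tests pin.

Networks run on `stainshift.nn`, a reverse-mode automatic-differentiation
engine over numpy arrays written for this package (im2col convolutions,
LayerNorm, pooling, the optimiser), with gradients verified against finite
differences. Batch-norm layers of the reference ResNet designs are folded
away (their affine part is absorbed into convolution biases), which leaves
per-stage shapes and the parameter-count ordering of the single-18 <
dual-18 < single-101 configurations intact. ImageNet-pretrained weights are
not used; `pretrained` exists in the config for full-scale setups.

**Training protocol.** AdamW, 512-px patches at full scale (128 px in the
desk experiments) sampled so at least 50 % of training patches contain a
labelled MF strictly inside; augmentation is color jitter, Gaussian blur,
pixel drop and 90°-multiple rotation (in dual mode spatial transforms are
shared between the stains, color transforms independent — the conservative
choice, since the two stains never share color statistics); validation AP
is computed each epoch on a fixed sampled-patch set, and early stopping
uses a patience of 5 with the best-AP checkpoint returned. The protocol
default learning rate is 1e-4; the desk-scale experiment configuration
raises it to 2e-3 because a small from-scratch network must converge
within a few hundred steps on one CPU — with ~300 AdamW updates this
reaches a stable validation AP where 1e-4 is still far from convergence.

## Evaluation

Test images are tiled (512 px, 50 px overlap at full scale; 128/25 in the
desk grid), tile origins snapped down to the backbone-stride grid so all
tiles share one convolutional feature grid, per-tile detections transferred
to global coordinates, and duplicates removed by one global IoU NMS
(threshold 0.3; a centre-distance NMS is available). Each detection is kept
only from the tile in which it is most interior ("ownership"), because
zero-padding at interior tile edges fabricates context a full-image pass
does not have; with tiles comfortably larger than the receptive field this
makes tiled and full-image inference agree to the detection and the pixel.
The pre-NMS candidate cap scales with tile area.

AP uses centre-distance matching at 7.5 µm (consistent with the consensus
radius; an IoU criterion would be arbitrary for point-derived boxes),
ranked greedy matching, and the all-point interpolated area under the PR
curve. Empty ground truth is an explicit error, no detections give AP 0.
The experiment grid trains every (model × training label set) on every
Monte-Carlo split (70/15/15 by image, rounding toward train, identical
splits for all models) and evaluates each trained model under all label
sets from one shared inference pass.

Raw scores are not calibrated across runs, so each trained model's
operating score threshold is selected on its validation images by
maximising instance F1. The grid AP is computed over the detections the
model emits above that operating point, and the same threshold drives the
hard TP/FN decisions of the latent analysis. This matters at desk scale:
a briefly trained network remains miscalibrated near zero score, and a
full-ranking AP with a permissive floor would credit residual scores on
objects the model has effectively rejected — in a synthetic world that
offers the dual-stain model almost no competing false positives, that
artefact alone can hold AP near 1.0. Full-scale networks suppress such
objects below the detection floor; the operating-point evaluation
restores that regime.

## Latent analysis

A small convolutional classifier (MF morphology vs plain nuclei, same
augmentation pipeline, early stopping on validation loss) with its
classification layer removed embeds 32-px cell patches into a
`feature_width`-dimensional space (512 at full scale, 64 in the desk
experiments). All MFs are embedded with test-time augmentation: augmented
copies are allocated round-robin until exactly `n_total` representations
exist (2000 at full scale), the first copy of each cell unaugmented. One
UMAP projection (n_neighbors 15, min_dist 0.1, fixed seed) is shared by
all phase-group views; only the colouring differs. A cell is a true
positive if more than half of the cross-validation models detect it within
7.5 µm. "Three quartiles of the distribution" is implemented as the 75 %
highest-density region of a Gaussian KDE (Scott's rule): the density
threshold is the 25th percentile of the densities at the points, and the
region is returned as iso-density contour polygons; fewer than three
distinct points collapse to a point region. The decision-boundary shift is
the distance between the false-negative region centroids of the two
training-label conditions, per phase group; a group with fewer than three
false-negative representations in either condition reports no measurable
shift (0).

## Numerical and design notes

* All randomness flows through `numpy.random.Generator` seeded from
  explicit integer seed sequences; identical (config, seed) reproduce
  datasets, trainings and projections bit-for-bit on a fixed BLAS.
* Desk-scale problem sizes: 200 rendered 512-px images, two Monte-Carlo
  splits and three seeds for the detector grid; 16-image studies with three
  cross-validation models per condition for the latent analysis; 20 seeds
  for the panel-statistics direction. These sizes give stable directional
  means while keeping every experiment runnable on a single CPU.
* Known limitations: stylised rendering (no texture/stain variance means
  absolute APs are far above anything achievable on real slides — only
  orderings and differences between label conditions are meaningful);
  independent rater errors; truthful post-hoc verdicts in the cleaning
  experiments; UMAP layouts are comparable only within one fitted
  projection, never across runs or implementations.
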