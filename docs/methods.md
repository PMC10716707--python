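# Methods

This note documents the models, parameter choices and numerical
decisions behind `cxrfuse`, and what the synthetic experiments do and
do not demonstrate.

## Problem and labels

The prediction target is binary: will a post-acute COVID-19 patient
benefit from preventive corticosteroid (CS) treatment against pulmonary
fibrosis. Ground truth derives from a radiologist's 0–10 lung-damage
regression score recorded at follow-up (0 = immutable state, 10 =
complete regression); scores of 7–10 count as significant improvement.
When a table carries an explicit `benefit_label` column it is used
verbatim. Otherwise the mapping from (treated, improved) to "benefit"
encodes clinical semantics that the package refuses to invent: the
caller must pass a `LabelRule` covering all four combinations. A
documented counterfactual reading ships as `COUNTERFACTUAL_RULE`
(treated ∧ improved → benefit; untreated ∧ no spontaneous improvement →
would have benefited) but is never applied implicitly.

The reference cohort geometry is 273 patients (141 negative / 132
positive), split stratified 80/20 into 218 train / 55 test; on the test
side that is 30 negatives and 25 positives. An exact externally
provided partition can be supplied as index arrays instead of the
seeded split.

## Two-branch network

Input is a lung-cropped grayscale CXR, resized to `input_size`
(default 224 px; 64 px in the desk-scale profile) and replicated to 3
channels.

* **Global branch** — an Inception-v3-style backbone written in this
  package's numpy layer library: a stride-2 conv stem, then three
  inception modules (parallel 1×1 / 1×1→3×3 / 1×1→5×5 / pool→1×1 paths,
  concatenated; same-padding preserves spatial dims) with stride-2 max
  pooling between stages, followed by global max pooling, a dense layer
  (default width 256, desk scale 64) and dropout (0.3).
* **Local branch** — three inception modules applied to the input
  (stride-2 pooling after each, so the map side shrinks 8×), then a
  Vision Transformer: non-overlapping patch embedding, learned
  positional embeddings, a class token (or mean pooling), and `depth`
  pre-norm encoder blocks of multi-head self-attention + GELU MLP with
  residual connections and layer normalization. Defaults: patch size
  7 at 224 px input (16 tokens), embed dim 128, depth 4, heads 4,
  MLP ratio 2, dropout 0.1.
* **Head** — the two branch embeddings are concatenated and passed
  through dense layers of 64, 32 and 14 units; the last is
  sigmoid-activated, one unit per finding label. The activations of
  these three layers are the latent features used downstream, exposed
  as taps −3/−2/−1.

Capacity hyperparameters of both branches (channel widths, ViT
depth/heads/dim, dense width, dropout) are not pinned by the reference
design and are config options; every default is recorded in run logs.
Backbone weights are randomly initialized (He/Glorot); there is no
bundled pretrained checkpoint, and requesting one raises an error.

The layer library implements forward and manual backward passes for
conv (shift-and-add over kernel offsets), max/global pooling, dense,
dropout (inverted; identity at inference), ReLU/GELU/sigmoid, layer
norm and multi-head attention, in float64. Gradient correctness is
finite-difference tested layer-by-layer and through the full network.
Inference is deterministic; save/load round-trips are bit-exact (`.npz`
parameters + JSON architecture sidecar).

## Asymmetric focal loss

Per label, with p the predicted probability, y the target, and
p_m = max(p − m, 0):

    L = −[ y·a⁺·(1−p)^γ⁺·log p + (1−y)·a⁻·(p_m)^γ⁻·log(1−p_m) ]

Defaults γ⁺ = 1, γ⁻ = 5, m = 0.001: negatives (the overwhelming
majority in sparse multilabel data) are strongly down-weighted when
easy, and below the margin contribute exactly zero loss and gradient.
The focal-loss balancing factor (a⁺ = α, a⁻ = 1−α) is available but
disabled by default — the focusing exponent of the focal loss is
already present as the γ's, so balancing is the only genuine addition,
and the pure asymmetric form is the reference setting. Probabilities
are clamped to [ε, 1−ε], ε = 1e−7, for log stability. Aggregation is
sum over labels, mean over the batch. Whether the negative probability
is shifted before or after applying the focusing exponent is ambiguous
in the source description; both readings coincide at the default
margin, and this implementation shifts first.

## Pretraining

Reference recipe: batch 8, 1000 steps/epoch, 100 epochs, AdamW
(decoupled weight decay), lr 1e−4, weight decay 1e−5. A seeded 20%
validation carve-out tracks per-epoch loss and macro ROC-AUC; the best
validation-loss parameters are restored at the end. Non-finite loss
aborts with a diagnostic. For the public 14-label corpus, the index
filter keeps images with at least one finding, partitions by the
official train/test lists, and carves validation per-image at random
(stratification is not attempted).

The **desk-scale profile** used by the tests and the acceptance script
is 64-px input, a width-reduced model (~37k parameters), a 300-image
synthetic stream and 10 epochs × 60 steps. Around 600 optimizer steps
is where the small network starts separating the synthetic finding
labels (held-out macro AUC rises from ~0.5 to ~0.6–0.65); shorter
schedules only demonstrate loss decrease.

## Preprocessing and augmentation

Lung masks come from an external segmentation model (mask files or a
model hook); the built-in fallback is Otsu thresholding plus the two
largest bright connected components — a heuristic, not a segmentation
model, adequate for the synthetic geometry (IoU ≥ 0.8) but not
validated on radiographs. Cropping takes the mask's bounding box
expanded by a 5% margin per side, then min-max renormalizes. Resizing
is bilinear with anti-aliasing on downsampling; constant images map to
zero. Augmentation (training streams only) draws one random affine per
call — translation up to 5% of the frame, rotation up to ±10°, zoom
0.9–1.1 — with zeros filling out-of-frame regions; draws are
deterministic under a replayed generator state. In the training loop
augmentation is opt-in (`pretrain(..., augment_params=...)`) and is
applied to training batches only, never to validation or evaluation
streams; the desk-scale profile trains without it, since on a tiny
synthetic stream with a short schedule the regularizer only slows
convergence — it is intended for the full-scale regime.

## Feature selection and fusion

The 21-feature clinical manifest (pneumonia, comorbidity, CS use,
olfactory loss, post-COVID disability, IgG qualitative, IgM
quantitative, CS amount/total/duration, RDW, VC, FVC %pred, FEV1,
monocyte %, PEF %pred, DLCO, KCO, cough, dyspnea, MEF25) ships as a
versioned column manifest; binary fields encode 0/1, tri-state
symptoms impute "missing" → "no" (missingness in the reference cohort
is ≤ 5 records per field), with optional companion missing-indicator
columns. k-best scoring uses ANOVA-F for numeric and chi-square for
binary columns (the statistic choice per column type is this package's
reading of "k-highest scores based on p-values"); constant columns
score 0 with p = 1; ties break on column name. Tree-based Shapley
importance fits a depth-limited decision tree and attributes its
predicted probability exactly (see below).

Fusion concatenates the latent block (width 14/32/64, aligned by
patient id) with the clinical block, recording the boundary.
Classifier tuning is seeded random search (default 50 candidates;
8 in the desk-scale runs) over envelope spaces reconstructed around
plausible operating ranges (RF estimators 1–30, depth 1–20; MLP one
hidden layer 10–200, max_iter 1–150; LR/SVM C ∈ [0.1, 10]; kNN
neighbors 1–15; AdaBoost estimators 1–30, lr 0.1–1), scored by mean
balanced accuracy over stratified 5-fold CV; ties go to the
first-sampled candidate. kNN, SVM, logistic regression and the MLP
see z-scored features with statistics computed inside each training
fold (the scaler lives inside the estimator pipeline, so no statistics
leak across folds or into the test set); tree-based methods see raw
values. ROC-AUC uses predicted probabilities where available and the
decision margin otherwise.

## Shapley attribution engine

Attributions use the interventional value function v(S) =
E_b[f(x_S, b_∖S)] over a background sample (≤ 64 rows). For a fitted
decision tree, only features on decision paths affect the score, so
unused features are dummy players with exactly zero attribution and
exact coalition enumeration over the used features (up to 12 players;
one batched model call per explained row) is exact for the full game.
Larger player sets fall back to seeded permutation sampling. Exactness
is verified against a brute-force all-features enumeration oracle, and
local accuracy (signed attributions sum to f(x) minus the background
mean) holds by construction for the exact path. Reports average |φ|
over a seeded row subsample (≤ 100 rows) and tag each feature as
latent or clinical.

## Synthetic cohort generator

The generator emulates the *structure* of the study, not radiographic
appearance: images are two elliptical lung fields (bright plateau,
soft rim) on a dark background; each active finding label adds a
textured Gaussian blob at a fixed per-label location (templates keyed
by label index, so geometry is reproducible across seeds); additive
Gaussian noise (σ = 0.05) and clipping to [0,1]. Label prevalence
defaults to 0.2 per label. The clinical table follows the column
manifest, with printed cohort summary statistics used where available
(age 64.4 ± 11.2, weight 88.0 ± 15.9, height 170.0 ± 9.8, binary
prevalences from the cohort counts) and physiologically plausible
defaults elsewhere. The benefit label is drawn from
P(benefit) = sigmoid(b₀ + β·z) on standardized clinical features —
defaults β: CS amount 1.2, IgM 0.9, pneumonia 0.8, ERV −0.6,
monocyte % 0.5; b₀ targets the 132/273 prevalence — and is the only
source of label information. When `image_effect` > 0, a diffuse
intra-lung opacity of that amplitude is added to benefit-positive
images so the images alone carry signal.

`image_effect` defaults to 0.04: below the pixel noise amplitude but
spatially coherent. This places the desk-scale pipeline in the
reference operating regime — CXR-only best accuracy in the
mid-0.7s/low-0.8s and mixed-data consistently higher — rather than a
saturated-separability ceiling where every classifier scores 1.0 and
the image/clinical comparison becomes vacuous. Missingness is MCAR on
symptom fields only (rate 0.02), since nothing characterizes the real
missingness mechanism.

What passing synthetic tests shows: the pipeline is wired correctly
end to end, fusion adds information when both modalities carry signal,
permuted labels destroy skill, planted effects are recovered. What it
does not show: performance on real radiographs (no anatomy, no
acquisition variation, no label noise), robustness of the heuristic
lung segmenter on clinical images, or transfer of the pretrained
features beyond the synthetic label geometry.

## Numerical choices and limitations

* float64 throughout the network; single-threaded determinism under
  fixed seeds; derived seeds stay below 2³¹.
* Undefined metric ratios (zero denominators) are NaN markers, never 0.
* Report metrics round to 4 decimals.
* Max pooling routes gradients to the (first) argmax; ties are
  measure-zero for continuous inputs.
* The margin makes the negative loss term non-smooth at p = m; the
  subgradient 0 is used below the margin.
* ROC-AUC for margin-based classifiers (SVM without probabilities)
  uses the decision function; values can legitimately fall below 0.5
  for weak classifiers.
* Full-scale pretraining on the public 112k-image corpus is supported
  through configuration but not exercised here; the reference headline
  numbers (80.0% accuracy, 78.7% balanced accuracy, ROC-AUC 0.8933 on
  the 55-patient test set) require the deposited cohort and full-scale
  pretraining and are not reproduced by the synthetic desk-scale runs,
  which target the same operating regime instead.
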