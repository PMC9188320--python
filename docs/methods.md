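# Methods

This note documents the modeling and numerical choices behind `sleepscan`:
what each stage assumes, what the synthetic corpus does and does not
emulate, and where the design was genuinely open.

## Problem setting

Scanned sleep-study reports print the apnea–hypopnea index (AHI) and the
minimum oxygen saturation (SaO₂) somewhere inside several pages of
narrative text that also carries many other numbers (respiratory
disturbance index, sleep efficiency, arousal index, mean saturation, ...).
Extraction is cast as 3-way classification of *numeric candidates* — is
this number the AHI, the SaO₂, or something else — followed by a
document-level argmax: per report and target, the candidate with the
highest class score is the extracted value, and a document counts as
correct only if that value equals the recorded gold value (tolerance 0 by
default; a tolerance flag exists for rounded gold records). Reports whose
gold value was never recovered as a candidate stay in the denominator as
failures.

## Synthetic corpus

The generator (`sleepscan.synth`) replaces a private clinical corpus. Its
defaults are the study conditions the package is tested under:

| parameter | default | note |
|---|---|---|
| pages/report | categorical on 1–6, median 2 | matches the reference page median; very long reports (tens of pages) are not emulated |
| numerics/page | rounded lognormal, median 44, σ = 0.35, clipped to [8, 120] | median pinned; real corpora have a heavier upper tail (table-dense pages) than this choice |
| AHI | truncated normal on (0, ∞), realized mean 34.9, SD 31.3 | see moment matching below |
| SaO₂ | truncated normal on (0, 100], realized mean 76.5, SD 15.6 | |
| multiple AHI mentions | p = 0.528 (if multi: 2, sometimes 3 mentions) | |
| multiple SaO₂ mentions | p = 0.459 | |
| page geometry | 2550×3300 px (300-dpi US Letter), ~44 px font with a 2 px outline | outline makes rendered stroke widths ≥3 px, the weight of 300-dpi print |

**Moment matching.** Truncating a normal shifts its mean and shrinks its
spread, so using the reported sample moments directly as location/scale
would generate values whose *sample* mean differs from the target
(for AHI, by ~8 points). `TruncNormal` therefore solves numerically for
the underlying location/scale such that the truncated distribution itself
has the target mean and SD; at n = 1000 the generator recovers all
configured moments within 3 standard errors (tested).

**Text.** Reports are sentence templates in narrative style — index
sentences ("The total APNEA/HYPOPNEA INDEX (AHI) was 19.5."), distractor
sentences carrying other indices, and occasional prose — flowed word by
word onto the page with recorded bounding boxes. A page-1 header plants a
synthetic patient name, MRN and study date so the deidentification stage
has real work to do. Gold mentions are always placed within the first 25
sentences of their page, so an unusually dense page can never overflow
them off the layout (key findings sit in the upper part of real reports
too). Distractor values colliding with a gold value are resampled by
default, making value-match label assignment exact; a flag re-enables
collisions for robustness experiments.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: tables and column structure (windows are purely
left/right — real table values lack horizontal context), logos, figures,
handwriting, skew and bleed-through, template diversity across
laboratories, and real OCR error structure beyond a character-confusion
table. Synthetic text is far more regular than real reports; absolute
accuracies here are upper bounds, and the test suite treats them as
plumbing checks and direction checks, not clinical performance claims.

**Ablation corpus.** With `positional_labels=True` every numeric sentence
uses one identical template, AHI mentions are placed at the top of page 1
and SaO₂ mentions at the bottom, so the class signal lives almost entirely
in the layout features. A sequence-only model is near chance on it while
the dual-branch model is not — the corpus exists to test that *direction*,
not to mimic a real document class.

## Image preprocessing

Six methods: gray (luma weights 0.299/0.587/0.114, rounded), optional one
iteration of 3×3 dilation then erosion, optional multiplicative contrast
(pixel → clip(round((1+pct/100)·pixel)), pct ∈ {20, 60}), composed in that
order; `gray_de_c20` is the default. Open choices made here:

* **Kernel 3×3, one iteration each** — the minimal neighborhood that
  removes isolated speckles while sparing ≥3 px strokes.
* **Polarity** — with the standard bright-region-growing convention,
  dilation-then-erosion is a closing of the bright background, i.e. an
  opening with respect to dark strokes: it erases dark specks, is
  idempotent, and never darkens a pixel (all property-tested).
* **Contrast as pure gain about zero** (not about a midpoint): on
  light-background scans a gain pushes near-white noise to saturation,
  which is the stated purpose of the step.
* **Stroke-survival metric**: a word's strokes are preserved when every
  connected dark component of at least kernel area (9 px) inside its bbox
  retains ≥50% of its pixels. Opening may shave single pixels off glyph
  junctions (which a component-count criterion would misread as damage);
  it must never erase a stroke.

PDF ingestion is out of scope for this build (no rasterizer dependency);
pages are accepted as PNG/TIFF.

## OCR layer

The pipeline is engine-agnostic: words travel as a TSV dialect
(`page_num, left, top, width, height, conf, text`, top-left origin). A
Tesseract adapter maps the engine's native word-level TSV into it and
fails with an explicit environment error when the engine is missing. The
default test path is the *perfect* backend, which returns exactly the
generator's planted words — by design, so NLP-stage tests are decoupled
from any OCR install — plus a seeded character-confusion wrapper
(I→!/), l→1, O→0, S→5) for noise experiments. Reading order concatenates
pages in page order and trusts engine order within a page; confidence is
carried but unused (no threshold is applied by default). Words are never
spell-corrected.

## Deidentification

Per-token case-insensitive exact match of name tokens and the MRN string
from a lookup table, then any token matching `\d{1,2}/\d{1,2}/(\d{2}|\d{4})`
becomes `[DATE]`. Exact token matching is conservative and testable;
the broad date shape errs toward masking. Masking never changes counts,
order or geometry, is idempotent, and its placeholders cannot match the
numeric-candidate regex. This is *not* full Safe-Harbor deidentification —
only names, MRNs, dates.

## Segmentation choices

* Full-token regex match (`[0-9.,%]+`), with pure-punctuation tokens
  excluded after a parse attempt.
* Parsing strips `%` and trailing `.`/`,`; commas between digit triplets
  are thousands separators. `19.5.` → 19.5, `95%` → 95.0, `1,234` → 1234.
* Windows cross page boundaries (reading-order concatenation) but never
  report boundaries; candidates also carry `page_num` so models can learn
  page effects.
* Dual gold match (AHI = SaO₂): AHI wins, pinned by test. Suppressed in
  the default corpus anyway.
* Duplicate candidate values within a report are *not* deduplicated
  before labeling.
* Split rounding: development = half-up(0.7·N), validation = floor(dev/7)
  — the only rule set reproducing 669/286 and 574/95 from 955.

## Bag-of-words models

Vocabulary: lowercase non-stopwords (vendored frozen English list), ranked
by raw corpus term frequency, top 400, lexicographic tie-break; smoothed
idf ln((1+n)/(1+df))+1; L2 normalization per segment. Structured features
are standardized (train mean/SD) for the geometry-sensitive models
(LR/L1/L2/SVM/kNN) and fed raw to the count/tree models (NB needs
non-negative inputs; forests are scale-free). λ = 0.01 for the penalized
logistic models maps to C = 100. The L1 model uses the saga solver (the
only sklearn solver supporting 3-class L1). Random-forest defaults: 500
trees, √d features per split, seeded. Cross-validation folds partition
*reports*, never segments, and ties in mean fold accuracy resolve to the
first grid point.

## Dual-branch network

Implemented in numpy with explicit backward passes (environment has no
deep-learning framework; numerical gradient checks in the test suite pin
every layer, including the mask-aware BiLSTM and the attention block).

* Structured branch: batch-norm(6) → Dense(100)+ReLU+dropout 0.2, twice.
* BiLSTM path: frozen 100-d CBOW embeddings (full-softmax CBOW, context
  ±2, linearly decaying learning rate, OOV → zero vector), 2 BiLSTM
  layers of 100 units per direction; padded steps pass state through
  unchanged, so the second layer's final forward/backward states are the
  last/first real-token states; their concatenation feeds a FFNN(100).
* Transformer path: learned token+position embeddings, post-norm blocks
  with key-padding-masked multi-head attention; all 32 per-token states
  are flattened (padded positions included, as an architecture that takes
  the full state grid) and fed to the FFNN. The default encoder is small
  (d = 32, 2 layers, randomly initialized) — it plays the architectural
  role of a pretrained masked-LM encoder at a size that trains on one
  CPU; any module with the same (ids, mask) → (B, 32, d) contract plugs
  in, including a pretrained clinical encoder.
* Head: concat → FFNN(200)+dropout 0.2 → 3 sigmoid outputs trained with
  per-class binary cross-entropy against one-hot targets (the outputs
  need not sum to 1; the document-level argmax is unaffected). A
  softmax+categorical head is available behind `loss="softmax"`.
* Training: Adam, batch 64, *fixed* epoch count — no early stopping —
  with a checkpoint per epoch; the returned model is the checkpoint with
  minimal validation cross-entropy, earliest epoch on ties. Reference
  learning rates: 2e-4 (BiLSTM path), 2e-6 for fine-tuning a pretrained
  transformer; the small randomly initialized transformer used in tests
  trains at 2e-3 for a handful of epochs.
* All randomness (init, dropout, shuffling) derives from the configured
  seeds; same seed ⇒ identical selected epoch and weights (tested).

## Evaluation statistics

AUROC is the Mann–Whitney concordance probability with ties counted ½,
computed from average ranks and cross-checked in tests against brute-force
pair counting. DeLong's test uses the placement-value covariance estimator
(sample covariance, ddof 1); CIs are auc ± 1.96·SE; when the variance of
the AUC difference degenerates (e.g. both models separate perfectly) the
p-value is reported as 1, with a warning if the AUCs differ. Document
accuracy gets a Wald 95% CI by default (Wilson behind a flag). Model
accuracies are compared with Pearson's chi-squared on the 2×2
correct/incorrect table without continuity correction, as is conventional
for this design even though documents are paired across models; McNemar's
test is available behind a flag for the paired reading. Bonferroni family
size is always explicit — never inferred silently from the number of
comparisons unless the caller asks for that default.

## Experiment matrices and problem sizes

The three designs (10-model classifier grid, 6-method preprocessing grid,
{10, 25, 50, 100}-report training-size curve) run on synthetic corpora at
desk scale: the package's defaults for these matrices use reduced network
widths, ~8 training epochs, and corpora of tens to hundreds of reports,
completing in seconds to a few minutes on one CPU. The preprocessing grid
renders a sample of noisy pages per method, measures residual speckle, and
scales the simulated OCR character-confusion rate by the residual-noise
fraction — a mechanistic stand-in (worse speckle suppression → more
misreads) that lets all six cells produce downstream metrics without an
OCR engine; the image-quality measurements themselves ride along in each
cell. The acceptance script (`scripts/acceptance.py`) states its own
problem sizes: n = 300 reports for the random-forest benchmark, 60-report
corpora × 3 seeds for the ablation, 200 replicates for null calibration,
2000 bootstrap replicates for the DeLong SE check.

## Known limitations

* No table-structure parsing: values printed in tables lack the
  left/right narrative context the window captures.
* Candidate tokens broken by OCR (e.g. "19 . 5") are not reassembled.
* The synthetic corpus is cleaner and more regular than real scans;
  absolute metrics on it overstate real-world performance.
* Deidentification covers names/MRNs/dates only.
* PDF rasterization is delegated to external tooling.
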