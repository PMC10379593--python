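# Methods

## Problem and model

Breast-ultrasound (BUS) reading is experience-bound: a senior radiologist's
BI-RADS characteristic annotations support far better benign/malignant
discrimination than a junior reader's, and the package's purpose is to
quantify that gap and to narrow it by transferring senior knowledge into the
junior inference model.

Each annotated image is expressed as knowledge triples K = (h, r, t): the
image is the head entity h, each of the ten BI-RADS characteristics
(angular, calcification, distortion, indistinct, margin, micro-lobulation,
orientation, posterior, shape, speculation) is a relation r whose tail t is
the recorded categorical value, and an eleventh relation `pathology` links
the image to the biopsy outcome (`benign`/`malignant`). Diagnosis is
knowledge-graph completion: predict the missing pathology edge of a patient
entity whose characteristic edges are known.

Triples are scored by a Tucker decomposition,

    phi(h, r, t) = W ×₁ e_h ×₂ w_r ×₃ e_t,

with entity embeddings e ∈ R^{d_e}, relation embeddings w ∈ R^{d_r} and a
shared core tensor W ∈ R^{d_e×d_r×d_e}. Training is 1-N: each
(head, relation) pair is scored against every entity, scores pass through a
logistic to (0, 1), and the mean Bernoulli negative log-likelihood is
minimised by Adam with label smoothing. The benign and malignant tail
probabilities are independent Bernoullis; the diagnosis compares the two
tail scores (exact ties resolve to benign — the conservative reading), and
the ROC score is the logistic-squashed malignant-tail score.

### Accuracy definition

Accuracy is (TP+TN)/(TP+TN+FP+FN). A variant with TP alone in the numerator
circulates in some write-ups of these metrics but is inconsistent with the
standard definition and with the sensitivity/specificity values it usually
accompanies; this package uses the standard form throughout.

## Senior-to-junior fusion

Two correction strategies are implemented, because "use the senior core
tensor to correct the junior one" admits more than one algorithmic reading
and no formula pins it down; neither is claimed to be anyone's exact
procedure.

- **data_union** (default): the senior and junior training triples are
  pooled (set union over the shared patient/relation vocabulary) and one
  model is trained on the union; test queries use junior annotations only.
  For cross-validated runs the union is restricted to training-fold cases,
  so no senior reading of a test image ever reaches the model.
- **core_blend**: the junior model is trained warm-started from the senior
  model's parameters over a shared vocabulary, so the two cores live in a
  comparable space; the fused model keeps junior embeddings and uses
  W_fused = α·W_senior + (1−α)·W_junior (α = 0.5 by default). By
  trilinearity every fused score is the same convex combination of the two
  cores' scores. The warm-start alignment is this package's own
  construction: independently trained cores live in unrelated parameter
  spaces and cannot be meaningfully averaged.

## Class balancing

Tensor-space link predictors are sensitive to the benign/malignant mix, so
cohorts are balanced before training. Random undersampling of the majority
class to 1:1 is the default (and is what the experiment driver uses, done
once globally before fold assignment). Fictitious-head oversampling is also
provided: because head entities are real-named, duplicating a row adds
nothing to the optimisation, so each duplicate receives a freshly minted
`synthetic::`-prefixed head carrying a copy of the source image's triples.
Fictitious heads are excluded from test queries.

## Synthetic cohorts

No compatible annotation dataset is publicly deposited, so the generator
simulates the statistical structure the pipeline assumes:

- a latent case-level pathology label, Bernoulli(0.78 malignant) by default
  — the image-level class mix of the motivating dataset;
- per-image class-conditional binary characteristics. The default
  suspicious-reading probabilities span strong to weak discriminators
  (e.g. shape/margin 0.85 vs 0.10–0.20 across classes, posterior 0.50 vs
  0.35), reflecting that BI-RADS descriptors differ widely in
  discriminative power; alphabets and probabilities are configurable per
  characteristic;
- two annotation channels reading the same underlying truth: senior with
  per-characteristic flip probability ε_s = 0.05 and junior with
  ε_j = 0.25 (ε_j ≥ ε_s enforced). Flips are independent per image and
  characteristic; pathology is biopsy ground truth and is never corrupted.

What the generator does **not** model: inter-characteristic correlation,
reader-specific bias (noise is symmetric), case-level correlation between
images of one case beyond the shared label, and the age covariate. Passing
tests therefore demonstrate that the pipeline recovers the designed
structure under annotator noise — not that any particular clinical AUC
would be attained on hospital data.

## Experiment driver and study sizes

The default study: 500 cases (one image per case), undersampled to ≈1:1,
case-level fold cross-validation (the headline study uses k = 2 so every
image is tested exactly once while keeping 60 model fits across 10 seeds
tractable on one CPU), per-fold training of the three arms, test scores
pooled across folds into a single ROC per arm, and pairwise DeLong tests
on the pooled paired scores. Ten independent seeds give the mean-AUC
ordering senior > fused > junior; the fused−junior gap is assessed by a
one-sided sign test. Exact AUC magnitudes depend on the generator's noise
and effect-size settings; only the ordering and the gap's sign are treated
as reproducible findings.

KNN and SVM baselines (scikit-learn) run on one-hot encodings of the
senior channel with small validation grids (k ∈ {1,3,5,7,9,15};
C ∈ {0.1, 1, 10}, RBF kernel), mirroring the classical comparators such
frameworks are judged against.

## Numerical choices

- d_e = d_r = 30, Gaussian(0, 0.1) initialisation, Adam at 5·10⁻³, 200
  epochs, batch 128, label smoothing 0.1, dropout available but 0 by
  default. The graphs here have tens of entities; larger cores mostly add
  overfitting capacity.
- Probabilities are clamped to [10⁻⁷, 1−10⁻⁷] before logs so the Bernoulli
  NLL stays finite.
- Contractions are reshaped BLAS matmuls; a brute-force nested-loop
  contraction serves as the test oracle.
- All randomness flows from one master seed via `SeedSequence`, with
  crc32-keyed derivation per stage/fold/arm (Python's salted `hash` would
  break cross-process determinism). Results JSON is written with sorted
  keys, so identical seeds give byte-identical files.
- DeLong uses the fast midrank algorithm; per-curve CIs use the DeLong
  variance by default. A "binomial exact" CI option (Clopper–Pearson on
  the concordant-pair proportion with effective n = min(n⁺, n⁻)) is
  provided and labelled as a heuristic, since the binomial convention for
  an AUC is ambiguous.
- In `GridSearchCV`-backed baselines the fold count adapts to the smallest
  class and k candidates are capped by the CV-split size.

## Known limitations

- The two fusion strategies bracket, but cannot claim to replicate, the
  original correction mechanism.
- Metrics are reported on the balanced (1:1) test pool; precision on an
  unbalanced population would differ.
- The generator's independence assumptions make the synthetic task easier
  than real BUS reading at equal noise rates; absolute AUCs are not
  transferable.
- Embeddings are not normalised and no batch normalisation is used; very
  high learning rates can diverge (detected and reported as a training
  error rather than silently producing NaNs).
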