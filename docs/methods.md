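# Methods

`enhancerscan` implements a two-layer sequence classifier for enhancer
biology: layer 1 separates enhancers from non-enhancers, layer 2 separates
strong from weak enhancers. Both layers share one architecture — a 3-mer
word embedding feeding a dual-scale convolutional network with spatial
attention — and differ only in their training data.

## Sequence representation

A DNA sequence of length K over {A, C, G, T} is treated as a sentence of
overlapping 3-mers ("words"): positions 1..K−2 each contribute the word
starting there, so `ATCGG → ATC, TCG, CGG` and a 200-nt sequence yields 198
words. Consecutive words overlap by two nucleotides, which preserves local
order information that a bag of k-mer counts discards. The minimum accepted
sequence length is 14 nt: tokenization yields K−2 words and the widest
default convolution filter spans 12 words.

Word vectors are trained with the skip-gram objective and negative sampling.
The trainer is a compact numpy implementation of the classic word2vec
algorithm specialized to the closed 64-word DNA vocabulary:

* **Parameters** (defaults): vector size d = 20, context window c = 5,
  minimum count 1, initial learning rate 0.025 decaying linearly to 1e-4,
  51 epochs, 5 negative samples per pair, frequent-word down-sampling
  threshold 1e-3. The embedding corpus is the training split only — never
  test sequences — and windows never cross sequence boundaries.
* **Mechanics**: each epoch re-draws sub-sampling decisions and per-center
  shrunk windows b ~ U{1..c}; negatives come from the unigram^(3/4) noise
  distribution; (center, context) pairs are processed in corpus order in
  mini-batches of 512 whose per-word gradient sums are accumulated with
  deterministic bincount reductions. The batch size is kept small relative
  to the 64-word vocabulary so accumulated updates stay close to sequential
  stochastic descent. Input vectors start at U(−0.5/d, 0.5/d), output
  (context) vectors at zero.
* **Closed vocabulary**: after training, any of the 64 possible 3-mers
  absent from the corpus is added with a small deterministic init vector so
  prediction-time sequences are always embeddable; such words carry no
  learned signal.
* The full-softmax conditional probability p(context | center) =
  exp(e′ᵀe) / Σ_j exp(e′_jᵀe) is exposed as a diagnostic query; the training
  objective itself uses negative sampling.

With the 1e-3 threshold and a near-uniform 3-mer distribution (frequency
≈ 1/64 each), roughly two thirds of tokens are down-sampled per epoch; this
mirrors standard word2vec behavior on small-vocabulary corpora and is
deliberate, not a defect.

Embeddings are **frozen** during classifier training: the network consumes
the d × (K−2) embedding matrix as fixed input and no gradient flows into the
word vectors.

## Network

For an embedded sequence E (d channels × N positions):

1. **Dual-scale fusion.** Two parallel 1D valid convolutions (stride 1, no
   padding) with M = 1024 filters each, of widths 10 and 12 — bracketing the
   ~11-bp typical transcription-factor motif — followed by ReLU. Their
   outputs, M × (N−9) and M × (N−11), are concatenated **along the spatial
   axis** into F (M × L), L = 2N − 20. Spatial (not channel) concatenation
   is forced by the shape law of the architecture: channel count is
   preserved while lengths add (198 → 189 + 187 = 376).
2. **Spatial attention.** Per-position mean and max over channels form a
   2 × L descriptor; a width-7 convolution (zero padding 3, the only padded
   convolution in the model) plus sigmoid yields the gate S ∈ (0,1)^L, and
   F̂ = F ⊙ S with S broadcast across channels. The printed output shape of
   the multiply step in some descriptions of this module (1 × L) is read as
   a typographic slip; the broadcast semantics make F̂ M × L.
3. **Head.** Global max-pool over positions gives v ∈ R^M; a single dense
   layer with 2-way softmax produces the class probabilities. No hidden
   layer and no dropout by default (optional dropout is deliberately not
   implemented; the architecture is already small).

The network is fully convolutional up to the pooling step, so prediction
accepts any sequence length ≥ 14 nt even though the benchmark-style training
data is uniformly 200 nt; variable-length behavior is an extension, not a
property carried over from the original protocol.

Ablation switches reproduce the standard variants: `-SS1`/`-SS2` disable
one convolution branch, `-SA` removes the gate (F̂ = F), and `-SS1-SS2-SA`
routes the raw embedding straight into max-pool + head (head input d).

### Implementation and numerics

All tensors are float32; convolutions are im2col + matmul with hand-written
backward passes, verified against loop-level oracles at 1e-5 relative
tolerance (and against finite differences in float64 during development).
Weights use seeded fan-in-scaled uniform initialization U(−1/√fan_in,
+1/√fan_in), biases zero. Softmax and sigmoid are computed in numerically
stable forms; cross-entropy clamps probabilities at 1e-12. BLAS is pinned to
a single thread inside training and scoring so runs are bit-reproducible
functions of the data order and seed regardless of host parallelism.

## Training protocol

Adam (lr 1e-3, β = 0.9/0.999) minimizes mean cross-entropy over shuffled
mini-batches of 64 for 50 epochs. A stratified 10% validation split is held
out by default and the weights of the best-validation-loss epoch are
returned; setting the validation fraction to 0 returns final weights, and an
optional patience parameter enables early stopping on the validation loss.
Divergent (non-finite) loss aborts with diagnostics. These optimizer
settings are this package's defaults; the original protocol specifies only
the optimizer family and the loss.

## Evaluation

ACC, SN, SP are exact ratios of confusion counts; MCC uses the standard
2×2 formula with the convention MCC = 0 when any denominator factor is zero.
A score exactly at the 0.5 threshold predicts positive. AUC is the
trapezoidal area under the ROC curve (equivalently the tie-corrected
Mann–Whitney statistic), computed from the continuous positive-class
probability. Positive classes: enhancer (layer 1), strong enhancer
(layer 2).

Cross-validation uses stratified folds by default, which reduces fold
variance without changing the expectation (a switch restores plain random
folds); the embedding is retrained
per fold on that fold's training portion only, so no held-out token ever
enters embedding training. Fold metrics are averaged unweighted. Multi-seed
stability reports the population variance (divide by the number of seeds) of
ACC and MCC, matching the magnitude convention of typical stability tables;
sample variance is available via a flag.

The two-layer cascade gates each sequence through classifier I and sends
predicted enhancers to classifier II, yielding
{non-enhancer, weak enhancer, strong enhancer}; per-layer isolated
evaluation is the primary protocol, the cascade a convenience.  On
synthetic data the cascade's dominant error mode is weak enhancers rejected
at the gate: a single noise-flattened motif instance is much harder to
detect than the strong class's two faithful instances, so three-class
accuracy sits well below either layer's isolated accuracy — the same
asymmetry that makes real strength classification the harder task.

## Synthetic data generator

The generator emulates the *layout* of the enhancer benchmark — balanced
classes of fixed-length 200-nt sequences (1484 per class at full scale) —
with exact ground truth instead of real chromatin-derived labels:

* negatives are i.i.d. background (uniform base composition by default);
* layer-1 positives carry one faithful motif instance sampled column-wise
  from a PWM (built-in fixtures of lengths 8, 10 and 12 nt; defaults are the
  10- and 12-nt families, matching the two receptive-field scales);
* layer-2 strong sequences carry two faithful instances, weak sequences one
  instance from a PWM mixed 30% toward uniform — a dosage-and-fidelity
  contrast that makes the second task learnable but harder, mirroring the
  relative difficulty of real strength classification;
* insertions never overlap, positions are uniform over admissible starts,
  intervals are reported 0-based half-open on the forward strand
  (reverse-complement planting at probability 0.5 behind a flag);
* generation is a pure function of its configuration (byte-identical FASTA
  for identical config), and the rate of consensus strings arising by chance
  in negatives is measured and reported per dataset (for ≥ 10-nt motifs on
  uniform background it is essentially zero).

What passing on this generator shows — and does not show: it validates the
full mechanical pipeline (embedding → fusion → attention → optimization →
evaluation) and the *directional* claims (multi-scale filters help when
motif families of different lengths coexist; removing all structure is far
worse). It does not certify performance on real enhancers, whose signal is
weaker, context-dependent and not reducible to exact PWM instances; the
reference benchmark numbers can be reproduced only with the externally
distributed benchmark FASTA via the command line.

## Problem sizes in the shipped tests

The test-suite and summary-script experiments run the architecture at
reduced width (64 or 32 filters per branch instead of 1024) and moderate
sample sizes (500 sequences per class for motif recovery, 150 per class for
the 5-seed ablation sweep, 30 training epochs with patience 5 there). These
sizes were chosen once as the package's desk-scale study conditions: every
structural property (shape laws, gradient flow, metric behavior,
reproducibility) is width-independent, and the planted-motif signal is
strong enough that recovery accuracy ≥ 0.9 is expected at these sizes.

## Known limitations

* The skip-gram trainer processes pairs in mini-batches rather than strictly
  sequentially; with a 64-word vocabulary this is a close approximation of
  classic SGD, but vectors are not numerically identical to a reference
  word2vec run.
* Embeddings are frozen; end-to-end fine-tuning of word vectors is not
  implemented.
* Training requires all sequences in one fit to share a length (the
  benchmark layout); mixed lengths are supported at prediction time only.
* One embedding table per layer is the default; sharing one table across
  layers is supported but the choice between the two is a judgment call.
* More than two convolution branches are accepted through configuration for
  filter-size experiments but are not an optimized code path.
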