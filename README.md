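# enhancerscan

Enhancers are short non-coding DNA elements that upregulate transcription of
target genes, often over long genomic distances; finding them — and telling
strong from weak ones — from sequence alone is a standard problem in
regulatory genomics. `enhancerscan` implements a two-layer sequence
classifier for this problem: **classifier I** separates enhancers from
non-enhancers, **classifier II** grades predicted enhancers as strong or
weak. Both layers share one architecture:

1. **3-mer word embedding.** A K-nt sequence S = {w₁,…,w_N}, N = K − 2, is
   tokenized into overlapping 3-mers and each word mapped to a 20-d vector
   trained with skip-gram + negative sampling
   (p(w_{n+i}|w_n) = exp(e′ᵀ_{w_{n+i}} e_{w_n}) / Σ_j exp(e′ᵀ_{w_j} e_{w_n})).
2. **Dual-scale fusion.** Two parallel valid 1D convolutions with M = 1024
   filters of widths 10 and 12 (bracketing the ~11-bp typical
   transcription-factor motif), ReLU, concatenated along the spatial axis:
   F = [ReLU(f¹⁰(E)), ReLU(f¹²(E))]. For a 200-nt input the 20×198
   embedding becomes a 1024×376 feature matrix (189 + 187 positions).
3. **Spatial attention.** S = sigmoid(f⁷[AvgPool(F), MaxPool(F)]) gates
   each position, F̂ = F ⊙ S (broadcast over channels).
4. **Head.** Global max-pool over positions, one dense layer, 2-way softmax;
   trained with Adam on cross-entropy.

Evaluation follows the standard enhancer-benchmark protocol: ACC, SN, SP,
MCC and AUC on an independent test set, stratified k-fold cross-validation
with per-fold embedding retraining, multi-seed stability, and the standard
ablation variants (−SS1, −SS2, −SA, −SS1−SS2−SA).

Because the original benchmark is distributed as supplementary data rather
than an archive with an accession, the package ships a **synthetic
generator** that emulates its layout — balanced classes of 200-nt sequences
— with planted PWM motifs (lengths 8/10/12 nt) and exact BED-like ground
truth, so the entire pipeline is testable offline. Strong vs. weak enhancers
are modelled as a motif dosage/fidelity contrast.

The implementation is pure numpy (hand-written gradients, seeded and
bit-reproducible single-threaded) organized as sklearn-style estimators, so
models compose with sklearn tooling (`clone`, pipelines, model selection).

## Worked example

```python
from enhancerscan import DualScaleAttentionClassifier, SimConfig, generate_dataset
from enhancerscan.sequence_io import train_test_split_dataset

# balanced 200-nt dataset: positives carry one planted 10- or 12-nt motif
sim = generate_dataset(SimConfig(n_per_class=500, seed=11))
train, test = train_test_split_dataset(sim.dataset, test_fraction=0.2, seed=1)

clf = DualScaleAttentionClassifier(n_filters=64, random_state=5)
clf.fit(train.sequences, train.labels)          # embeds, then trains the net
print(clf.evaluate(test.sequences, test.labels))
```

which prints (deterministically, for these seeds):

```
ACC 94.50%  MCC 0.891  SN 92.00%  SP 97.00%  AUC 98.96%
```

i.e. on 200 held-out sequences the model recovers planted motifs with 94.5%
accuracy; sensitivity (92%) is the fraction of motif-bearing sequences
found, specificity (97%) the fraction of pure-background sequences
correctly rejected, and MCC summarizes the confusion table in [−1, 1].

The same workflow is available from the shell:

```bash
enhancerscan simulate --out-prefix data/sim --n-per-class 500 --seed 1
enhancerscan train --fasta data/sim.fasta --model-dir run/model --n-filters 64 --seed 1
enhancerscan evaluate --model-dir run/model --fasta data/sim.fasta --out run/report.json
enhancerscan cv --fasta data/sim.fasta --k 10 --out run/cv.json --n-filters 64
enhancerscan ablate --fasta data/sim.fasta --variant=-SA --out run/ablate.json
```

Users holding the original benchmark FASTA files can train and evaluate on
them directly (`--positive enhancers.fa --negative non_enhancers.fa`);
every command writes a config echo sufficient to reproduce the run.

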