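# exp2sl

Cell-line-specific **synthetic lethality (SL)** prediction from L1000 shRNA
knockdown expression signatures.

Two genes form an SL pair when perturbing both kills a cell while perturbing
either alone does not — the principle behind drugs like PARP inhibitors in
*BRCA*-mutated cancers. Most SL interactions are cell-line specific, and
experimentally screening gene pairs is expensive, so this package predicts SL
pairs for a single cell line from that line's own transcriptional responses:
the 978-dimensional L1000 landmark expression signature measured after shRNA
knockdown of each gene.

It is written for computational biologists who have (a) L1000 Level-3
expression plates with shRNA and empty-vector-control samples, and (b)
pairwise SL scores from combinatorial CRISPR screens (e.g. GEMINI "strong"
scores) for the same cell line.

## The method

**Signatures.** Each shRNA profile `x` on a plate is robust-z-scored against
the empty-vector controls `V` of the same plate,

```
z_k = (x_k − median(V_k)) / (1.4826 · MAD(V_k)),
```

then replicates of one shRNA, and shRNAs targeting one gene, are collapsed by
a Spearman-correlation-weighted average (MODZ-style), giving one signature
`f_i ∈ R^978` per gene.

**Model.** Gene signatures pass through `E` ReLU layers
(`h^e = ReLU(W^e h^{e−1} + b^e)`); a pair `(i, j)` is scored symmetrically by
a linear head over both concatenation orders,

```
s_ij = ½ (W_out·[h_i, h_j] + W_out·[h_j, h_i]) + b_out ,
```

so `s_ij = s_ji` holds by construction.

**Semi-supervised objective.** Labeled pairs (positives `P` scored toward +1,
negatives `N` toward −1) contribute a summed squared error; the vast unknown
set `U` contributes a Bayesian-personalized-ranking (BPR) term that pushes
positives above sampled unknowns and unknowns above sampled negatives:

```
L = Σ_{P∪N} (s_ij − y_ij)² + λ₁ Σ_k [−log σ(s_pos − s_unk) − log σ(s_unk − s_neg)] + λ₂‖θ‖².
```

Training is full-batch Adam (lr 0.001, 1000 epochs, global gradient norm
clipped at 5), resampling `|P|` unknown and `|P|` negative pairs each epoch.

Also included: the sign-plus-rank SL labeling rule (top 5 % and > 0 →
positive; bottom 50 % and < 0 → negative), order-symmetrized LR / RF / SVM /
GBDT baselines, NetLapRLS over PPI-Jaccard / expression-Pearson kernels,
split-pair and split-gene cross-validation with the full metric panel,
gradient-saliency feature attribution, and a synthetic-fixture generator that
emulates all three external inputs.

## Worked example

```python
import numpy as np
from exp2sl import (EXP2SL, FixtureSpec, SLLabelSet, assemble_dataset,
                    generate_fixture, label_pairs, saliency_importance)
from exp2sl.evaluation import cross_validate

# a small synthetic study: 40 genes, 100-dim signatures, planted SL rule
fixture = generate_fixture(FixtureSpec(n_genes=40, n_landmark=100, seed=0))
signatures = fixture["signatures"]

pos, neg = label_pairs(fixture["scores"])   # 5% / 50% sign-plus-rank rule
labels = assemble_dataset(SLLabelSet(pos, neg, set(signatures.index)), signatures)
print(f"{len(labels.positives)} positive, {len(labels.negatives)} negative, "
      f"{len(fixture['scores']) - labels.n_labeled} unknown pairs")

hyper = dict(n_encoder_layers=1, hidden_dim=64, lambda_bpr=32.0,
             lambda_l2=0.01, n_epochs=1000)
panels = cross_validate("EXP2SL", hyper, signatures, labels,
                        protocol="split_gene", seed=0)
print(f"split-gene AUC  {np.mean([p.auc for p in panels]):.3f} "
      f"+/- {np.std([p.auc for p in panels]):.3f}")
print(f"split-gene AUPR {np.mean([p.aupr for p in panels]):.3f}")

model = EXP2SL(random_state=0, **hyper).fit_label_set(signatures, labels)
imp = saliency_importance([model], signatures, labels.labeled_pairs(), k=10)
print("top-10 salient dimensions:", sorted(int(i) for i in imp.top_k))
```

prints

```
39 positive, 390 negative, 351 unknown pairs
split-gene AUC  0.984 +/- 0.013
split-gene AUPR 0.880
top-10 salient dimensions: [3, 4, 15, 18, 22, 35, 72, 81, 84, 85]
```

Under the split-gene protocol every test pair contains at least one gene
never seen in training, so 0.984 measures generalization to unscreened genes.
Four of the ten most salient dimensions (3, 4, 15, 18) fall inside the
fixture's 20 planted informative dimensions (indices 0–19), double what a
random ranking would give; a 10-model ensemble sharpens this further.

The same workflow is available from the shell:

```
exp2sl simulate --out fixtures/                      # synthetic study
exp2sl preprocess --expr fixtures/expression.gct \
    --meta fixtures/metadata.tsv --out signatures.tsv
exp2sl build-labels --scores fixtures/scores.tsv \
    --signatures signatures.tsv --out labels.tsv
exp2sl train --signatures signatures.tsv --labels labels.tsv \
    --d 64 --l1 32 --seed 0 --out model.npz
exp2sl predict --model model.npz --pairs pairs.tsv --out scores.tsv
exp2sl evaluate --config run.yaml --out results/
```

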