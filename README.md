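# gpcnet

A knowledge-masked sparse neural network for predicting tumour-cell
malignancy (differentiation grade) from multi-omics gene profiles, together
with the tooling needed to interrogate and evaluate it: DeepLIFT
rescale-rule attribution for every node, a statistical comparison harness
(DeLong, bootstrap, BH-FDR, fold-level t-tests), classical baselines, and a
synthetic-cohort generator with planted ground truth so the entire method is
testable offline.

## The model

The network has five layers: an input layer of four per-gene features
(mutation, amplification, deletion, methylation), three hidden layers whose
nodes correspond one-to-one to **genes**, **pathways** and **compounds**,
and a sigmoid output. The input features of gene *i* are combined into its
gene node by a grouped linear map

```
h_i = tanh( Σ_j W⁰_ij x_ij + b_i ),   j ∈ {0..3}
```

and each subsequent hidden layer applies a weight matrix Hadamard-multiplied
by a binary mask *M* encoding curated gene→pathway and pathway→compound
relations:

```
H_l = tanh( (M_l ∘ W_l)ᵀ H_{l-1} + b_l ),   l ∈ {2, 3}
```

so only biologically annotated connections carry signal. A sigmoid
predictive head follows every hidden layer; the compound-layer head is the
model's grade score in [0, 1] (1 = poorly/undifferentiated) and the training
objective is the weighted sum of the three heads' binary cross-entropies,
`H_total = α₁H₁ + α₂H₂ + α₃H₃`, optimized with Adam (initial learning rate
0.008, halved every 50 epochs). Node importance is computed with the
DeepLIFT rescale rule against an all-zero reference and aggregated as
`C(x_li) = (1/N) |Σ_s C_s(x_li)|`; per layer the sample-level scores satisfy
the completeness identity `Σ_i C_s(x_li) = t − t₀`.

The forward pass, backpropagation and Adam are implemented directly in
NumPy — the models are deliberately CPU-sized — and the gradients are
checked against finite differences in the test suite.

## Worked example

```python
import numpy as np
from gpcnet import (GeneratorSpec, generate_hierarchy, generate_cohort,
                    init_params, TrainConfig, train, split_data, forward,
                    compute_metrics, attribute)

spec = GeneratorSpec(seed=1)                 # 200 genes, 20 pathways,
h = generate_hierarchy(spec)                 # 50 compounds, 2000 samples,
x, y, truth = generate_cohort(h, spec)       # 5 planted drivers
s = split_data(x.n_samples, y, seed=1)
fit = train(init_params(h, 1), x, y, TrainConfig(seed=1),
            s.train_idx, s.val_idx)
m = compute_metrics(y[s.test_idx], forward(x.values[s.test_idx], fit.params).p3)
print(f"test AUC {m.auc:.3f}  AUPRC {m.auprc:.3f}")

report = attribute(fit.params, x.subset(s.test_idx))
top20 = [n for n, _ in report.top_k("gene", 20)]
print("drivers recovered:", sum(d in top20 for d in truth.driver_genes), "of 5")
print("top pathway:", report.top_k("pathway", 1)[0][0],
      "(planted:", truth.driver_pathway + ")")
```

prints

```
test AUC 0.760  AUPRC 0.771
drivers recovered: 5 of 5
top pathway: PW01 (planted: PW01)
```

— the masked model recovers all five planted driver genes in its top-20
gene importances and ranks the planted pathway first, while beating the
dense unmasked twin (test AUC 0.724 under the same conditions) with roughly
a quarter of its parameters.

The same pipeline is available from the shell: `gpcnet simulate`,
`gpcnet train`, `gpcnet explain`, `gpcnet compare` and `gpcnet visualize`
(see `gpcnet --help`); every command writes into a timestamped run directory
with a manifest.

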