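# Methods

## Model

The classifier is a sparse multilayer perceptron whose hidden nodes are
biological entities. For sample *n* with input `x[n, i, j]` (gene *i*,
channel *j* ∈ {mutation, amplification, deletion, methylation}):

1. **Gene combiner.** `h1[n,i] = tanh(Σ_j w_gene[i,j]·x[n,i,j] + b_gene[i])`.
   The bias is per-gene: the grouped-layer analogue of the shared scalar, and
   a strict generalization of it. A channel flagged unavailable (e.g. an
   external cohort without methylation) is zero-filled, which contributes
   nothing to the sum and therefore preserves the semantics of weights
   trained with the channel present.
2. **Masked layers.** `h2 = tanh(h1 · (M_gp ∘ W_gp) + b_p)` and
   `h3 = tanh(h2 · (M_pc ∘ W_pc) + b_c)`, where the binary masks come from a
   GMT gene-set file (gene→pathway) and a two-column TSV (pathway→compound).
   Because the mask multiplies the weight in the forward pass and the
   gradient is multiplied by the same mask, entries at mask = 0 never
   influence any output and never move — this is asserted bit-exactly in the
   tests, not just to tolerance.
3. **Heads.** A sigmoid head after each hidden layer; the compound-layer
   head *is* the output (three losses, one output — a separate fourth output
   layer would add a loss the objective does not have). A config option can
   instead predict a weighted mean of the three heads.
4. **Loss.** `H_total = α₁·BCE(p1,y) + α₂·BCE(p2,y) + α₃·BCE(p3,y)` with
   default α = (1,1,1); predictions are clipped to [1e-7, 1−1e-7] before the
   log. Labels encode tumour differentiation grade: poorly/undifferentiated
   → 1, well/moderately differentiated → 0.

### Hierarchy construction

Node order is lexicographic over identifiers so the parameter layout is
reproducible regardless of input file order. Pathways mapping no gene of the
cohort's gene universe are dropped (logged), as are compounds whose parent
pathways were all dropped: dead nodes receive no gradient and would distort
the importance normalization. Gene symbols match case-sensitively after
whitespace stripping; no alias resolution is attempted.

### Optimization

Hand-written reverse-mode gradients (verified against central finite
differences to 5e-8 in the tests) with Adam (β = 0.9/0.999, ε = 1e-8).
Learning rate `lr(e) = 0.008 · 0.5^⌊e/50⌋`; the 0.5 decay factor is a
package default where only "actively reduced every 50 epochs" is prescribed.
Training is full-batch for cohorts up to 2000 samples, otherwise mini-batches
of 64; 300 epochs by default. The returned model is the epoch checkpoint
with the best validation AUC (the selection criterion matches the reported
metric family); with no usable validation signal the final weights are kept.
NaN loss aborts with a diagnostic rather than returning a corrupt model.

### Splitting

Train/validation/test at 0.85:0.05:0.10, stratified by label. Rounding rule:
within each class, train and validation receive the floor of their
proportional share and the remainder goes to the test split; 1892 balanced
samples therefore split 1608/94/190. Cross-validation uses stratified
5-fold (scikit-learn `StratifiedKFold`, shuffled, seeded).

## Attribution

DeepLIFT rescale rule, implemented from scratch. The reference input is
all-zeros across channels (configurable; a channel-wise training mean is
also supported through the `x0` argument). The default target is the
**pre-sigmoid logit** of the final head: completeness then holds without the
output sigmoid's saturation flattening the scores; rescaling through the
sigmoid (`target="probability"`) is also implemented. Linear pieces use the
effective (masked) weights as multipliers; each nonlinearity uses
`m = (f(z)−f(z0))/(z−z0)` with a fall-back to `f′(z0)` when |Δz| < 1e-7
(standard rescale stabilization). Per layer and per sample the node
contributions sum to t − t₀; the tests require the residual ≤ 1e-5 and
observe ~1e-15 in practice.

Aggregate importance follows the printed formula `C = (1/N)|Σ_s C_s|` — the
absolute value of the signed mean — even though opposing sample-level
contributions cancel; a mean-of-absolute variant exists behind the
`mean_absolute` flag and is clearly an off-formula diagnostic. Rankings
break ties lexicographically by node id. Edge flows for the visualization
are |effective weight| × source importance, normalized to a maximum of 1
per layer pair, with only mask = 1 edges emitted. Input-channel importances
are DeepLIFT contributions of the input nodes (not weight magnitudes).

## Statistical harness

AUC and AUPRC come from scikit-learn (rank statistic with midranks;
step-wise precision–recall integration — not trapezoidal); threshold metrics
use a 0.5 cutoff (configurable). The paired DeLong test is implemented from
its structural components with midranks and checked against an O(n²)
brute-force oracle; zero variance returns a degenerate result with p = 1.
The bootstrap comparison resamples indices jointly for both models
(B = 1000 default), redraws single-class resamples, and reports
p = 2·min(Pr(diff ≤ 0), Pr(diff ≥ 0)) with +1 smoothing on the distribution
of per-resample metric differences. BH-FDR delegates to statsmodels and is
verified against a literal step-up implementation. Fold-level model
comparison uses a two-sample equal-variance t-test. Classical baselines
(random forest, SVM, logistic regression, decision tree) are scikit-learn
models at default settings, seeded — comparison scaffolding, not the
contribution.

The urinary-tyrosine utility returns
`Tyr(µmol/L)·1000·(10/9) / (Cr(mmol/L)·113)` — µmol tyrosine per mmol
creatinine; 10/9 undoes the urine/stabilizer dilution and 113 is the molar
mass of creatinine.

## Synthetic cohorts

The generator mirrors a real grading cohort's statistical shape at desk
scale: defaults G = 200 genes, P = 20 pathways, C = 50 compounds, n = 2000
samples, ~50/50 class balance (full scale is a config change, not a code
change). Gene→pathway edges are Bernoulli(0.05) and pathway→compound edges
Bernoulli(0.10), with three structural guarantees: every pathway keeps at
least one member gene, every compound at least one parent pathway, and every
pathway at least one downstream compound — the last because a pathway with
no compound child is disconnected from the output head, so planted signal
routed through it could never reach the prediction. Binary channels are
Bernoulli (rates 0.10/0.05/0.05 — sparse alterations, with mutations more
common than copy-number events), methylation is Beta(2, 2).

Signal enters through **gene burden** (matching the network's assumed causal
direction gene → pathway): for the 5 planted driver genes, all wired into
one planted pathway, `B = Σ_driver (mut + amp + del + 1[meth > 0.5])` and
labels are Bernoulli(σ(β·B − offset)) with β = 2 by default, the offset
bisected so the expected balance hits the target; label draws are retried
(bounded, seeded) until the realized balance is within ±2%.

What the generator does **not** emulate: co-alteration / linkage structure
between genes, per-gene rate heterogeneity, batch effects, survival times,
or realistic pathway overlap. Passing driver-recovery tests therefore shows
the method recovers signal consistent with its own causal assumptions, not
that it would rank genes correctly under confounded real-cohort structure.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default n = 2000 cohort
(about ten seconds to train on one CPU) and use smaller nets (≤ 10 nodes per
layer) wherever a brute-force oracle is compared, e.g. triple-loop forward
checks at 1e-10, DeLong structural components at 1e-10, linear-regime
attribution at 1e-8. The sparse-vs-dense cross-validation comparison uses
n = 200 over 5 seeds — the regime where the knowledge prior should matter
most. The null-calibration check formalizes "no systematically outlying
gene" as: no gene exceeds 3× the median importance in *every* seed (within a
single null run many genes exceed 3× the median because the |mean|
aggregation makes the median itself near zero; consistency across
independent seeds is the meaningful signal).

Weight initialization is uniform in ±1/√fan_in per layer, seeded. All
computation is float64. Reported reproducibility tolerance for training
histories is 1e-6, though identical seeds reproduce bit-identically on a
given platform.

## Known limitations

- No identifier translation (Entrez/Ensembl/HGNC) or gene-set merging; the
  hierarchy is taken as given.
- Binary channels must arrive thresholded; CNA calling is upstream.
- No multi-class grading, survival outputs, GPU kernels or hyperparameter
  search.
- Importance aggregation by |mean| can hide genes with strong but
  sign-opposed subpopulation effects; use the `mean_absolute` diagnostic to
  detect this.
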