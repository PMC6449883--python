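# Methods

## Model and assumptions

`gne` assumes that genes which interact, or which share interaction
partners, lie close together in some latent space, and that genes with
similar expression profiles tend to be functionally related. It encodes
both signals into one d-dimensional vector per gene:

1. **Structure pathway.** Gene identity is embedded by table lookup: column
   *i* of `W_id ∈ ℝ^{d×M}`. This is the direct-encoding convention of
   skip-gram models; nothing about the graph is hard-coded in the input, so
   all topological structure must be absorbed by training.
2. **Attribute pathway.** The expression profile `xᵢ ∈ ℝᴱ` (z-scored per
   gene) passes through `ELU(W_att·xᵢ)`. ELU keeps gradients alive for
   negative pre-activations, which matters because z-scored expression is
   symmetric around zero.
3. **Early fusion.** The concatenation `[vᵢ⁽ˢ⁾ ; λ·vᵢ⁽ᵃ⁾]` feeds a shared
   MLP (default: one tanh layer, all hidden widths d), so interactions
   *between* topology and expression can be learned, in contrast to late
   fusion where separate models are merged after the fact. λ=0 reduces the
   model exactly to a topology-only embedder (verified as a bitwise
   equivalence with a zeroed expression matrix).
4. **Output.** A second table `W_out ∈ ℝ^{M×d}` holds each gene's
   representation as a neighbor, `ṽⱼ`. Pair score `ṽⱼ·hᵢ`; neighborhood
   likelihood via softmax over all genes. The final embedding adds the two
   roles: `yᵢ = hᵢ + ṽᵢ`.

The full-softmax likelihood is approximated by skip-gram negative sampling:
each directed edge i→j contributes `−log σ(ṽⱼ·hᵢ) − Σₙ log σ(−ṽₙ·hᵢ)`
with `num_neg` noise genes per edge. Noise genes are drawn from a
degree^0.75 unigram distribution (the word2vec convention), restricted to
genes outside `Nᵢ ∪ {i}`; the restriction is implemented by renormalizing
the noise distribution over the eligible set, which is distributionally
identical to rejection sampling but cannot stall. An isolated network
(all degrees zero) falls back to a uniform noise distribution.

## Training

Both directed instances of every undirected training edge are used. One
epoch is a seed-shuffled pass over all directed instances in mini-batches;
each batch draws fresh noise genes and applies one Adam update (β₁=0.9,
β₂=0.999, ε=1e-8). Weights start Glorot-uniform, biases zero. Dropout (on
hidden activations) and batch normalization (before the hidden activation,
with running statistics for inference) are implemented but off by default:
at the problem sizes this package targets they are unnecessary and
disabling them keeps runs bit-deterministic. All gradients are
hand-derived and checked against central finite differences (relative
error < 1e-4 enforced in tests, observed ~1e-9) for every tensor,
including the batch-norm scale/shift path.

Numerical choices: `log σ(x)` is computed as `−logaddexp(0, −x)`; the
softmax in `conditional_prob` subtracts the max score; z-scoring maps
zero-variance expression rows to zeros rather than dividing by zero; ELU
exponentiates only non-positive arguments.

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| `d` | 128 | embedding dimension |
| `lam` (λ) | 1.0 | weight of expression relative to topology |
| `k` | 1 | hidden layers (tanh), widths d |
| `learning_rate` | 0.005 | Adam step size |
| `batch_size` | 256 | directed edges per update |
| `epochs` | 20 | passes over the directed edge list |
| `num_neg` | 10 | noise genes per positive edge |
| `dropout` | 0.0 | hidden-activation dropout (0.5 is the usual rate when enabled) |
| `batch_norm` | False | batch normalization before the hidden activation |

These are the validation-selected optima for a yeast-scale interaction
network and they transfer well to the synthetic benchmark: on held-out
validation edges of the default benchmark they are indistinguishable from
the best of a wider grid (d ∈ {16…256}, epochs ∈ {20…100}, learning rate
∈ {0.002…0.01}), all of which plateau at the same validation AUROC.
Hyperparameter selection, when needed, should use a validation edge split
(`split_edges` with `val_frac > 0`), never the test split.

## Link-prediction protocol

Positive edges are split uniformly at random into train/validation/test
(fractions of the full edge set). Negative evaluation pairs are sampled
uniformly from non-edges, matched in count to their positive sets, and are
kept disjoint from *all* positives and from each other — validation
negatives can otherwise leak into test negatives. The classifier is an
L2-regularized logistic regression (C=1, tolerance 1e-6) on Hadamard
features `yᵢ ∘ yⱼ`, trained on the training edges plus an equal number of
freshly sampled non-edges excluded from every other set. Hadamard features
make the predicted probability exactly symmetric in pair order.

AUROC uses midrank tie handling (equals the Mann–Whitney statistic); AUPR
is average precision, the step-wise integral of precision over recall,
which is stable for small test sets. Both are verified against
from-scratch oracles (exhaustive pair counting; threshold-grouped step
integral) to 1e-12 including ties.

The probability-bin audit groups scored pairs into right-closed bins
(default (0.5, 0.6] … (0.9, 1.0]) and reports, per bin, the pair count,
the fraction confirmed in a reference network and the mean number of
shared interaction partners — high-probability pairs sharing many partners
is the structural signature expected of missed true interactions.

Temporal holdout trains on a sample (default 50%) of an older network
snapshot and tests on the edges present only in a newer snapshot,
restricted to genes the model has embeddings for; test negatives are
absent from both snapshots.

## Synthetic benchmark

The generator produces a planted-partition graph — balanced contiguous
modules, within-module edge probability `p_in`, between-module `p_out` —
with expression `xᵢ = μ_{module(i)} + ε`, module mean profiles
`μ ~ N(0, signal_sd²)` per experiment and i.i.d. noise
`ε ~ N(0, noise_sd²)`. Defaults: 200 genes, 4 modules, p_in=0.25,
p_out=0.02, 300 experiments, signal_sd=1.0, noise_sd=0.5 (within-module
expression correlation ≈ signal²/(signal²+noise²) = 0.8). The expected
edge count is ~1,525 and the graph is almost surely dominated by one
connected component. A degree-corrected block model, count noise, batch
effects and operon-level structure are deliberately not modeled; the
generator exists to realize the two proximities the model assumes, not to
imitate microarray data.

**What passing tests on this generator do and do not show.** Edges in a
planted-partition graph are i.i.d. given module assignments, so a held-out
within-module edge is statistically exchangeable with a within-module
non-edge. The Bayes-optimal test ranking is therefore the module-indicator
oracle, whose AUROC under the default 50%-holdout protocol is ≈0.80 (it
depends only on the within-module share of test positives, ~0.80, and of
test negatives, ~0.20). Both the full model and the Pearson baseline
operate at this ceiling — under these defaults Pearson separates modules
perfectly, so the benchmark can show that the model *reaches* the ceiling
and that expression rescues a sparsified network (at 10% training edges
the λ=1 model leads λ=0 by ≈0.27 AUROC), but it cannot show the model
*exceeding* a correlation baseline the way real data can, because real
networks carry within-module structure (hubs, shared partners) that this
generator deliberately omits.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on generated data:
the default 200-gene benchmark for end-to-end checks (5 seeds, 50%
holdout; the sparsity sweep adds 30 training runs), 30–80-gene datasets
for unit and protocol tests, and ≤10-gene models for exact gradient and
closed-form checks. A full reproduction run takes a couple of minutes on
one CPU; BioGRID-scale inputs (≈6,000 genes, 5×10⁵ interactions) are
within reach of the same code but take hours, not minutes.

## Known limitations

- Single numeric attribute matrix only; sequence or annotation attributes
  are out of scope.
- Dense adjacency internals (fine to ~10⁴ genes; beyond that the
  adjacency and output tables should move to sparse or blocked forms).
- CPU only; no GPU path.
- The best λ is dataset-dependent; it should be selected on a validation
  split per dataset rather than taken from the default.
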