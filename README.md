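# gne — gene network embedding for interaction prediction

`gne` learns a dense vector representation for every gene in an organism by
fusing two complementary data sources: the topology of the known gene
interaction network (e.g. a BioGRID export) and the gene's expression
profile across a compendium of experiments (e.g. a DREAM5 matrix). The
embeddings feed a logistic classifier that ranks unobserved gene pairs by
their probability of interacting — a way to prioritize missing or not-yet-
curated interactions for experimental follow-up.

## The model

Each gene *vᵢ* has two encoder inputs: a one-hot identity vector and its
expression profile *xᵢ* ∈ ℝᴱ. The identity is embedded by table lookup,
`vᵢ⁽ˢ⁾ = W_id · onehot(i)`, the expression by a non-linear transform
`vᵢ⁽ᵃ⁾ = ELU(W_att · xᵢ)`. The two are fused early — concatenated as
`vᵢ = [vᵢ⁽ˢ⁾ ; λ·vᵢ⁽ᵃ⁾]`, where λ ≥ 0 sets the importance of expression
relative to topology — and passed through *k* hidden layers
`h⁽ᵏ⁾ = tanh(W_k h⁽ᵏ⁻¹⁾ + b⁽ᵏ⁾)` to a node representation `hᵢ ∈ ℝᵈ`.

A second table `W_out` holds each gene's representation *as a neighbor*,
`ṽⱼ`. The proximity score of a pair is `f(vᵢ, vⱼ) = ṽⱼ · hᵢ`, and
training maximizes the likelihood of each gene's observed neighborhood
under the softmax `p(vⱼ|vᵢ) = exp(f)/Σⱼ′ exp(f′)`, approximated with
skip-gram negative sampling: for every directed training edge i→j,

    loss = − log σ(ṽⱼ·hᵢ) − Σₙ log σ(−ṽₙ·hᵢ),

with noise genes *n* drawn from a degree^0.75 unigram distribution outside
the neighborhood of *i*. Optimization is mini-batch Adam. The final
embedding is `yᵢ = hᵢ + ṽᵢ`; a pair (i, j) becomes the Hadamard feature
`yᵢ ∘ yⱼ` for an L2-regularized logistic classifier, and ranking quality is
reported as AUROC and AUPR.

The implementation is compact, fully vectorized numpy with hand-derived
gradients (verified against finite differences), bit-reproducible given a
seed.

## Worked example

```python
import gne

cfg = gne.SyntheticConfig(n_genes=80, n_modules=4, p_in=0.3, p_out=0.03,
                          n_experiments=100, seed=1)
net, expr, truth = gne.generate_dataset(cfg)   # modular network + expression
net, expr = gne.align(net, expr)               # shared gene order, z-scored rows
split = gne.split_edges(net, val_frac=0.0, test_frac=0.3, seed=1)

hyper = gne.GNEHyper(d=32, batch_size=64, epochs=15, num_neg=5, seed=1)
params, history = gne.train(net, expr, hyper, split.train_pos)
emb = gne.final_embeddings(params, net, expr, hyper)
report = gne.evaluate(emb, net, split, seed=7)
print(report.auroc, report.aupr)
```

Running this (it is `examples/01_train_and_evaluate.py`) prints:

```
dataset: 80 genes, 290 interactions, 100 experiments
training loss: 3.989 (epoch 1) -> 1.764 (epoch 15)
held-out link prediction: AUROC 0.746, AUPR 0.732
expression-correlation baseline AUROC: 0.711
```

AUROC 0.746 means a held-out true interaction outranks a random
non-interacting pair 74.6% of the time — here beating the classical
expression-correlation baseline (0.711) by combining topology with
expression. The other scripts in `examples/` demonstrate the λ sweep
(expression matters most when the training network is sparse), temporal
holdout (predicting interactions that appear only in a newer network
snapshot) and ranking/auditing candidate novel interactions.

## Command line

A thin CLI wraps the same functions:

```bash
gne simulate --config sim.yaml --out data/
gne split    --edges data/edges.tsv --test-frac 0.3 --seed 5 --out split/
gne train    --edges data/edges.tsv --expression data/expression.tsv \
             --config hyper.yaml --split-dir split/ --out run/
gne evaluate --embeddings run/embeddings.tsv --edges data/edges.tsv \
             --split-dir split/ --out report.json
gne sweep --kind lambda ... ; gne temporal ... ; gne predict ...
```

Real data drop in directly: `--dialect biogrid_tab` parses official BioGRID
tab exports (systematic-name columns), and expression TSVs follow the
DREAM5 layout (gene id first column, one column per experiment).

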