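"""How much does expression data help? Sweep the importance weight lam.

lam scales the expression-derived half of the fused representation: lam=0
is a topology-only model, lam=1 weighs expression fully. The benefit of
expression is largest when the training network is sparse.
"""

import gne

cfg = gne.SyntheticConfig(n_genes=80, n_modules=4, p_in=0.3, p_out=0.03,
                          n_experiments=100, seed=2)
net, expr, _ = gne.generate_dataset(cfg)
net, expr = gne.align(net, expr)

hyper = gne.GNEHyper(d=32, batch_size=64, epochs=15, num_neg=5)
result = gne.lambda_sweep(
    (net, expr),
    lambdas=[0.0, 0.2, 0.4, 0.6, 0.8, 1.0],
    train_fractions=[0.2, 1.0],
    seeds=[0, 1, 2],
    hyper=hyper,
)
summary = result.table.groupby(["fraction", "lam"])["auroc"].mean().unstack()
print("mean AUROC by training fraction (rows) and lam (columns):")
print(summary.round(3).to_string())
print("\nEach cell averages 3 seeds. Expect the lam=0 column to trail the "
      "lam>0 columns, most clearly in the sparse (0.2) row, where topology "
      "alone cannot place genes.")
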