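"""Desk-scale reproductions of the method's experimental designs.

Three protocols, each returning tidy tables or reports that downstream code
can serialize deterministically:

* sparsity sweep — fix a 10% test holdout, train on a varying share of the
  remaining edges, and compare the full model against its topology-only
  (lam=0) variant as the training network thins out;
* lambda sweep — the same grid with the expression-importance weight lam
  varying over a list of values;
* temporal holdout — train on a sample of an older network snapshot and
  test on the interactions that are present only in a newer snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_io import (
    EdgeSplit,
    GeneNetwork,
    ExpressionMatrix,
    Pair,
    sample_negative_pairs,
    split_edges,
    temporal_new_edges,
)
from .link_prediction import EvalReport, evaluate
from .model import GNEHyper, final_embeddings, train


@dataclass
class SweepResult:
    """Tidy per-(grid cell, seed) metrics plus the configuration snapshot."""

    table: pd.DataFrame
    config: dict


def _train_and_eval(
    net: GeneNetwork,
    expr: ExpressionMatrix,
    hyper: GNEHyper,
    split: EdgeSplit,
    eval_seed: int,
) -> EvalReport:
    params, _ = train(net, expr, hyper, split.train_pos)
    emb = final_embeddings(params, net, expr, hyper)
    return evaluate(emb, net, split, seed=eval_seed)


def _subsample_split(split: EdgeSplit, fraction: float, seed: int) -> EdgeSplit:
    """Keep a seeded prefix of the shuffled training edges; larger fractions
    contain smaller ones, so cells within a seed are nested."""
    n_keep = int(round(fraction * len(split.train_pos)))
    if n_keep < 1:
        raise ValueError(f"training fraction {fraction} leaves no training edge")
    order = np.random.default_rng(seed).permutation(len(split.train_pos))
    kept = sorted(split.train_pos[k] for k in order[:n_keep])
    return replace(split, train_pos=kept)


def sparsity_sweep(
    dataset: tuple[GeneNetwork, ExpressionMatrix],
    fractions: Sequence[float],
    seeds: Sequence[int],
    hyper: GNEHyper,
    lam_star: float = 1.0,
    test_frac: float = 0.1,
) -> SweepResult:
    """Training-network sparsity experiment.

    Per seed: hold out ``test_frac`` of edges as the fixed test set, then for
    each training fraction train both the lam=0 (topology-only) and
    lam=``lam_star`` variants on that share of the remaining edges and
    evaluate on the held-out test set.
    """
    net, expr = dataset
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    for seed in seeds:
        base = split_edges(net, val_frac=0.0, test_frac=test_frac, seed=seed)
        for fraction in fractions:
            sub = _subsample_split(base, fraction, seed=seed + 1)
            for lam in (0.0, lam_star):
                h = replace(hyper, lam=lam, seed=seed)
                report = _train_and_eval(net, expr, h, sub, eval_seed=seed + 2)
                rows.append(
                    {
                        "fraction": fraction,
                        "lam": lam,
                        "seed": seed,
                        "auroc": report.auroc,
                        "aupr": report.aupr,
                    }
                )
    table = pd.DataFrame(rows)
    return SweepResult(table=table, config={
        "kind": "sparsity", "fractions": list(fractions), "seeds": list(seeds),
        "lam_star": lam_star, "test_frac": test_frac, "hyper": vars(hyper).copy(),
    })


def lambda_sweep(
    dataset: tuple[GeneNetwork, ExpressionMatrix],
    lambdas: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    train_fractions: Sequence[float] = (1.0,),
    seeds: Sequence[int] = (0,),
    hyper: GNEHyper = None,
    test_frac: float = 0.1,
) -> SweepResult:
    """Expression-importance experiment over a grid of lam values."""
    net, expr = dataset
    if hyper is None:
        hyper = GNEHyper()
    if any(l < 0 for l in lambdas):
        raise ValueError("lambdas must be >= 0")
    if any(not 0 < f <= 1 for f in train_fractions):
        raise ValueError("train_fractions must lie in (0, 1]")
    rows = []
    for seed in seeds:
        base = split_edges(net, val_frac=0.0, test_frac=test_frac, seed=seed)
        for fraction in train_fractions:
            sub = _subsample_split(base, fraction, seed=seed + 1)
            for lam in lambdas:
                h = replace(hyper, lam=lam, seed=seed)
                report = _train_and_eval(net, expr, h, sub, eval_seed=seed + 2)
                rows.append(
                    {
                        "fraction": fraction,
                        "lam": lam,
                        "seed": seed,
                        "auroc": report.auroc,
                        "aupr": report.aupr,
                    }
                )
    table = pd.DataFrame(rows)
    return SweepResult(table=table, config={
        "kind": "lambda", "lambdas": list(lambdas), "fractions": list(train_fractions),
        "seeds": list(seeds), "test_frac": test_frac, "hyper": vars(hyper).copy(),
    })


def temporal_experiment(
    old_net: GeneNetwork,
    new_net: GeneNetwork,
    expr: ExpressionMatrix,
    hyper: GNEHyper,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> EvalReport:
    """Train on a sample of the old snapshot; test on edges new to the newer.

    Test positives are the newer snapshot's edges absent from the older one
    (restricted to genes the model was trained on); test negatives are an
    equal-sized sample of pairs absent from both snapshots.
    """
    new_pos = temporal_new_edges(old_net, new_net)
    if not new_pos:
        raise ValueError("no new edges between the two snapshots")
    rng = np.random.default_rng(seed)
    edges = sorted(old_net.edges)
    order = rng.permutation(len(edges))
    n_train = max(1, int(round(train_fraction * len(edges))))
    train_pos = [edges[k] for k in order[:n_train]]
    # negatives must be absent from BOTH snapshots
    new_in_old_idx = set(new_pos)
    neg_seed = int(rng.integers(0, 2**31 - 1))
    test_neg = sample_negative_pairs(
        old_net, len(new_pos), exclude=new_in_old_idx, seed=neg_seed
    )
    split = EdgeSplit(
        train_pos=train_pos,
        val_pos=[],
        test_pos=new_pos,
        val_neg=[],
        test_neg=test_neg,
        seed=seed,
    )
    train_net = old_net.subnetwork_edges(train_pos)
    params, _ = train(train_net, expr, hyper, train_pos)
    emb = final_embeddings(params, train_net, expr, hyper)
    return evaluate(
        emb, old_net, split, seed=int(rng.integers(0, 2**31 - 1)),
        extra_exclude=new_pos,
    )
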