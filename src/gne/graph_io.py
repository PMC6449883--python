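"""Network and expression I/O, alignment, and evaluation-split construction.

Gene interaction networks are undirected, unweighted simple graphs: no
self-loops, no duplicate edges, binary adjacency. All unordered gene pairs
are stored canonically as ``(min_index, max_index)`` tuples so deduplication,
exclusion checks and symmetry are O(1) set operations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


def canonical_pair(i: int, j: int) -> Pair:
    """Return the unordered pair (i, j) as (min, max)."""
    return (i, j) if i < j else (j, i)


class GeneNetwork:
    """Undirected gene interaction network with binary edge weights.

    Parameters
    ----------
    genes:
        Ordered unique gene identifiers; position defines the integer index.
    edges:
        Iterable of index pairs. Self-loops raise; duplicates collapse.
    """

    def __init__(self, genes: Sequence[str], edges: Iterable[Pair]):
        self.genes: list[str] = list(genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        self.M: int = len(self.genes)
        edge_set: set[Pair] = set()
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop on index {i}")
            if not (0 <= i < self.M and 0 <= j < self.M):
                raise ValueError(f"edge ({i},{j}) out of range for M={self.M}")
            edge_set.add(canonical_pair(i, j))
        self.edges: set[Pair] = edge_set
        self.neighbors: list[set[int]] = [set() for _ in range(self.M)]
        for i, j in self.edges:
            self.neighbors[i].add(j)
            self.neighbors[j].add(i)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Integer degree of every gene, in gene order."""
        deg = np.zeros(self.M, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (M x M), symmetric, zero diagonal."""
        a = np.zeros((self.M, self.M), dtype=bool)
        for i, j in self.edges:
            a[i, j] = True
            a[j, i] = True
        return a

    def subnetwork_edges(self, pairs: Iterable[Pair]) -> "GeneNetwork":
        """Same gene set, edge set replaced by ``pairs``."""
        return GeneNetwork(self.genes, pairs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork(M={self.M}, edges={self.n_edges})"


@dataclass
class ExpressionMatrix:
    """Gene-by-experiment expression values.

    Row ``i`` is the expression profile x_i of gene ``genes[i]`` across E
    experiments. ``normalized`` records whether rows have been z-scored.
    """

    genes: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x experiments)")
        if self.values.shape[0] != len(self.genes):
            raise ValueError("row count must match number of genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifier in expression matrix")

    @property
    def E(self) -> int:
        return self.values.shape[1]

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def normalize(self) -> "ExpressionMatrix":
        """Per-gene z-score; rows with zero variance map to all-zero rows."""
        v = self.values
        mean = v.mean(axis=1, keepdims=True) if self.E else np.zeros((self.M, 1))
        sd = v.std(axis=1, keepdims=True) if self.E else np.ones((self.M, 1))
        out = np.zeros_like(v)
        nz = (sd > 0).ravel()
        if self.E:
            out[nz] = (v[nz] - mean[nz]) / sd[nz]
        return ExpressionMatrix(list(self.genes), out, normalized=True)


@dataclass
class EdgeSplit:
    """Train/validation/test partition of positive edges plus sampled negatives.

    The three positive lists partition the network's edge set; negatives are
    non-edges, disjoint from each other, matched in size to their positive set.
    """

    train_pos: list[Pair]
    val_pos: list[Pair]
    test_pos: list[Pair]
    val_neg: list[Pair]
    test_neg: list[Pair]
    seed: int = 0


# ---------------------------------------------------------------------------
# Parsing


def _parse_two_col(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-separated two-column files
                parts = line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def _parse_biogrid_tab(path: Path) -> list[tuple[str, str]]:
    """Parse a BioGRID tab-delimited export using the systematic-name columns."""
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        cols = [c.strip().lstrip("#") for c in header_line.split("\t")]
        lower = [c.lower() for c in cols]
        try:
            ia = lower.index("systematic name interactor a")
            ib = lower.index("systematic name interactor b")
        except ValueError:
            # headerless tab3 export: systematic names are columns 6 and 7
            ia, ib = 5, 6
            fh.seek(0)
        rows: list[tuple[str, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) <= max(ia, ib):
                raise ValueError(f"{path}: malformed row at line {lineno}")
            a, b = parts[ia].strip(), parts[ib].strip()
            if not a or not b or a == "-" or b == "-":
                continue  # BioGRID uses '-' for missing systematic names
            rows.append((a, b))
    return rows


def read_edge_list(path: str | Path, dialect: str = "two_col") -> GeneNetwork:
    """Read an undirected edge list into a :class:`GeneNetwork`.

    Self-interactions and redundant (duplicate or reversed) interactions are
    removed, with counts logged. ``dialect`` is ``"two_col"`` (plain TSV) or
    ``"biogrid_tab"`` (official BioGRID tab export, systematic-name columns).
    """
    path = Path(path)
    if dialect == "two_col":
        rows = _parse_two_col(path)
    elif dialect == "biogrid_tab":
        rows = _parse_biogrid_tab(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not rows:
        raise ValueError(f"{path}: no edges found (empty network)")
    genes: list[str] = []
    index: dict[str, int] = {}
    for a, b in rows:
        for g in (a, b):
            if g not in index:
                index[g] = len(genes)
                genes.append(g)
    edges: set[Pair] = set()
    n_self = n_dup = 0
    for a, b in rows:
        i, j = index[a], index[b]
        if i == j:
            n_self += 1
            continue
        p = canonical_pair(i, j)
        if p in edges:
            n_dup += 1
        else:
            edges.add(p)
    if n_self or n_dup:
        logger.info(
            "read_edge_list(%s): dropped %d self-interactions, %d redundant interactions",
            path, n_self, n_dup,
        )
    return GeneNetwork(genes, edges)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-experiment TSV (first column gene id, optional header)."""
    path = Path(path)
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    data_cells = first.iloc[0, 1:]
    has_header = False
    if len(data_cells):
        try:
            data_cells.astype(float)
        except (ValueError, TypeError):
            has_header = True
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype={0: str})
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    dupes = df[gene_col][df[gene_col].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicated gene identifier(s): {list(dupes)[:5]}")
    try:
        values = df.drop(columns=[gene_col]).astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    return ExpressionMatrix(genes, values)


def align(
    net: GeneNetwork,
    expr: ExpressionMatrix,
    missing_policy: str = "zero_fill",
    normalize: bool = True,
) -> tuple[GeneNetwork, ExpressionMatrix]:
    """Bring a network and an expression matrix onto one gene ordering.

    Expression-only genes are dropped (logged). Network genes lacking
    expression either receive an all-zero attribute row (``zero_fill``) or are
    removed together with their incident edges (``drop``). Expression rows are
    then z-scored per gene unless ``normalize`` is False.
    """
    if missing_policy not in ("zero_fill", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    expr_index = {g: r for r, g in enumerate(expr.genes)}
    extra = [g for g in expr.genes if g not in net.index]
    if extra:
        logger.info("align: dropping %d expression-only genes", len(extra))
    missing = [g for g in net.genes if g not in expr_index]
    if missing_policy == "drop" and missing:
        keep = [g for g in net.genes if g in expr_index]
        if not keep:
            raise ValueError("dropping genes without expression leaves an empty network")
        old_to_new = {net.index[g]: k for k, g in enumerate(keep)}
        edges = [
            (old_to_new[i], old_to_new[j])
            for i, j in net.edges
            if i in old_to_new and j in old_to_new
        ]
        net = GeneNetwork(keep, edges)
        logger.info("align: dropped %d network genes without expression", len(missing))
    elif missing:
        logger.info("align: zero-filling expression for %d network genes", len(missing))
    E = expr.E
    values = np.zeros((net.M, E))
    for k, g in enumerate(net.genes):
        r = expr_index.get(g)
        if r is not None:
            values[k] = expr.values[r]
    out = ExpressionMatrix(list(net.genes), values)
    if normalize:
        out = out.normalize()
    return net, out


# ---------------------------------------------------------------------------
# Splits and negative sampling


def sample_negative_pairs(
    net: GeneNetwork,
    n: int,
    exclude: set[Pair] | frozenset[Pair] = frozenset(),
    seed: int = 0,
) -> list[Pair]:
    """Sample ``n`` distinct non-edges uniformly, avoiding ``exclude``.

    Sampled pairs are canonical, never self-pairs, never in ``net.edges`` and
    never in ``exclude``. Deterministic given ``seed``. Raises if fewer than
    ``n`` eligible pairs exist.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    M = net.M
    total = M * (M - 1) // 2
    excluded_nonedges = {
        canonical_pair(*p) for p in exclude
        if p[0] != p[1] and canonical_pair(*p) not in net.edges
    }
    available = total - len(net.edges) - len(excluded_nonedges)
    if n > available:
        raise ValueError(f"requested {n} negative pairs but only {available} are available")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    forbidden = net.edges | excluded_nonedges
    chosen: set[Pair] = set()
    out: list[Pair] = []
    # rejection sampling; fall back to full enumeration if acceptance stalls
    for _ in range(64):
        need = n - len(out)
        if need == 0:
            break
        draw = max(2 * need, 32)
        ii = rng.integers(0, M, size=draw)
        jj = rng.integers(0, M, size=draw)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i == j:
                continue
            p = canonical_pair(i, j)
            if p in forbidden or p in chosen:
                continue
            chosen.add(p)
            out.append(p)
            if len(out) == n:
                break
    if len(out) < n:
        pool = [
            (i, j)
            for i in range(M)
            for j in range(i + 1, M)
            if (i, j) not in forbidden and (i, j) not in chosen
        ]
        idx = rng.choice(len(pool), size=n - len(out), replace=False)
        out.extend(pool[k] for k in sorted(idx.tolist()))
    return out


def split_edges(
    net: GeneNetwork, val_frac: float, test_frac: float, seed: int = 0
) -> EdgeSplit:
    """Randomly partition edges into train/validation/test plus negatives.

    ``val_frac`` and ``test_frac`` are fractions of the full edge set; the
    remainder is the training set. Validation and test negatives are sampled
    uniformly from non-edges, sized to match their positive sets, and are
    disjoint from each other and from every positive edge.
    """
    if val_frac < 0 or test_frac < 0 or val_frac + test_frac >= 1:
        raise ValueError("need val_frac, test_frac >= 0 and val_frac + test_frac < 1")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    order = rng.permutation(len(edges))
    n_val = int(round(val_frac * len(edges)))
    n_test = int(round(test_frac * len(edges)))
    val_pos = [edges[k] for k in order[:n_val]]
    test_pos = [edges[k] for k in order[n_val:n_val + n_test]]
    train_pos = [edges[k] for k in order[n_val + n_test:]]
    sub_seeds = rng.integers(0, 2**31 - 1, size=2)
    val_neg = sample_negative_pairs(net, len(val_pos), seed=int(sub_seeds[0]))
    test_neg = sample_negative_pairs(
        net, len(test_pos), exclude=set(val_neg), seed=int(sub_seeds[1])
    )
    return EdgeSplit(train_pos, val_pos, test_pos, val_neg, test_neg, seed=seed)


def temporal_new_edges(old: GeneNetwork, new: GeneNetwork) -> list[Pair]:
    """Edges present in ``new`` but not ``old``, as index pairs in ``old``.

    Pairs involving genes absent from ``old`` are excluded (no embedding is
    available for an unseen gene) and their count is logged.
    """
    out: list[Pair] = []
    n_unknown = 0
    for i, j in sorted(new.edges):
        a, b = new.genes[i], new.genes[j]
        ia, ib = old.index.get(a), old.index.get(b)
        if ia is None or ib is None:
            n_unknown += 1
            continue
        p = canonical_pair(ia, ib)
        if p not in old.edges:
            out.append(p)
    if n_unknown:
        logger.info("temporal_new_edges: skipped %d pairs with genes absent from the old network", n_unknown)
    return sorted(out)


# ---------------------------------------------------------------------------
# Embedding and split serialization


def write_embeddings(genes: Sequence[str], Y: np.ndarray, path: str | Path) -> None:
    """Write embeddings as TSV: gene id then d floats, 17 significant digits."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(genes):
        raise ValueError("embedding row count must match number of genes")
    d = Y.shape[1]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(f"e{k}" for k in range(d)) + "\n")
        for g, row in zip(genes, Y):
            fh.write(g + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV written by :func:`write_embeddings`."""
    genes: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        d = len(header) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    Y = np.array(rows, dtype=float) if rows else np.zeros((0, d))
    return genes, Y


_SPLIT_PARTS = ("train_pos", "val_pos", "test_pos", "val_neg", "test_neg")


def save_split(split: EdgeSplit, genes: Sequence[str], out_dir: str | Path) -> None:
    """Serialize a split as per-part gene-id pair TSVs plus meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for part in _SPLIT_PARTS:
        with open(out / f"{part}.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for i, j in getattr(split, part):
                fh.write(f"{genes[i]}\t{genes[j]}\n")
    (out / "meta.json").write_text(json.dumps({"seed": split.seed}) + "\n")


def load_split(in_dir: str | Path, index: dict[str, int]) -> EdgeSplit:
    """Load a split saved by :func:`save_split`, mapping ids through ``index``."""
    src = Path(in_dir)
    parts: dict[str, list[Pair]] = {}
    for part in _SPLIT_PARTS:
        pairs: list[Pair] = []
        p = src / f"{part}.tsv"
        if p.exists():
            for line in p.read_text(encoding="utf-8").splitlines():
                if not line:
                    continue
                a, b = line.split("\t")
                pairs.append(canonical_pair(index[a], index[b]))
        parts[part] = pairs
    meta = src / "meta.json"
    seed = json.loads(meta.read_text())["seed"] if meta.exists() else 0
    return EdgeSplit(seed=seed, **parts)
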