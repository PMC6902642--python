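"""ARACNe-style mutual-information network inference.

Pairwise mutual information between every TF and every gene is estimated
with a rank-based (equal-frequency) joint histogram, significance is
assessed against a pooled permutation null, and indirect edges are pruned
with the data-processing-inequality (DPI) rule at a multiplicative
tolerance.

The MI estimator is the plug-in entropy of the joint counts on an
``n_bins x n_bins`` grid whose cells are empirical rank quantiles; being
rank-based it is invariant under strictly monotone transforms of either
profile. Ties receive average ranks before binning; bin cells are
right-closed at the empirical quantile edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset

DEFAULT_ALPHA = 0.005
DEFAULT_DPI_TOLERANCE = 0.2


def default_n_bins(n_samples: int) -> int:
    """Heuristic bin count: ~sqrt(n/5), at least 2.

    Keeps expected counts per joint cell around 5 so the plug-in estimate
    is stable at desk-scale sample sizes.
    """
    return max(2, int(np.floor(np.sqrt(n_samples / 5))))


def _rank_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per sample, from average ranks."""
    r = stats.rankdata(v, method="average")
    if r.max() == r.min():
        raise ValueError("constant expression profile; MI undefined")
    edges = np.quantile(r, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, r, side="left")


def _mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (nats) of a joint count table."""
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * (np.log(p[nz]) - np.log((px * py)[nz]))).sum())
    return max(mi, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """MI (nats) between two expression profiles on the rank-quantile grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    n = x.size
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} samples for {n_bins} bins")
    bx = _rank_bins(x, n_bins)
    by = _rank_bins(y, n_bins)
    counts = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins)
    return _mi_from_counts(counts.reshape(n_bins, n_bins).astype(float))


def _binned_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin every row of a genes x samples matrix; int16 bin indices."""
    out = np.empty(values.shape, dtype=np.int16)
    for i in range(values.shape[0]):
        out[i] = _rank_bins(values[i], n_bins)
    return out


def _mi_one_vs_many(b: np.ndarray, B: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of one binned profile against many, via a single bincount."""
    g, n = B.shape
    k2 = n_bins * n_bins
    code = (np.arange(g, dtype=np.int64)[:, None] * k2) + (
        b.astype(np.int64) * n_bins + B
    )
    counts = np.bincount(code.ravel(), minlength=g * k2).reshape(g, n_bins, n_bins)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log(p) - np.log(px * py))
    term[~(p > 0)] = 0.0
    return np.maximum(term.sum(axis=(1, 2)), 0.0)


@dataclass
class MiNull:
    """Pooled null distribution of MI values from permuted gene pairs."""

    null_mis: np.ndarray  # sorted ascending
    n_perm_pairs: int

    def __post_init__(self) -> None:
        self.null_mis = np.sort(np.asarray(self.null_mis, dtype=float))
        if self.null_mis.size == 0:
            raise ValueError("empty MI null")

    def p_values(self, mis: np.ndarray) -> np.ndarray:
        """Empirical upper-tail p: (1 + #{null >= mi}) / (1 + |null|)."""
        mis = np.asarray(mis, dtype=float)
        n_ge = self.null_mis.size - np.searchsorted(self.null_mis, mis, side="left")
        return (1.0 + n_ge) / (1.0 + self.null_mis.size)


@dataclass
class MiNetwork:
    """Significant-MI network: unordered edges, each touching >= 1 TF."""

    edges: pd.DataFrame  # columns gene_a, gene_b, mi, p_value
    tf_genes: list[str]
    n_bins: int = 0
    _adj: dict[str, dict[str, float]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["gene_a"] == e["gene_b"]).any():
                raise ValueError("self-edge in MI network")
            mis = e["mi"].to_numpy()
            if not (np.isfinite(mis).all() and (mis >= 0).all()):
                raise ValueError("MI values must be finite and >= 0")
            tfs = set(self.tf_genes)
            touches = e["gene_a"].isin(tfs) | e["gene_b"].isin(tfs)
            if not touches.all():
                raise ValueError("every edge must touch at least one TF gene")

    def n_edges(self) -> int:
        return len(self.edges)

    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    def adjacency(self) -> dict[str, dict[str, float]]:
        if self._adj is None:
            adj: dict[str, dict[str, float]] = {}
            for row in self.edges.itertuples(index=False):
                adj.setdefault(row.gene_a, {})[row.gene_b] = row.mi
                adj.setdefault(row.gene_b, {})[row.gene_a] = row.mi
            self._adj = adj
        return self._adj


def build_mi_null(
    dataset: ExpressionDataset,
    n_bins: int | None = None,
    n_perm_pairs: int = 10_000,
    seed: int = 0,
) -> MiNull:
    """Pooled MI null from randomly chosen, independently permuted pairs.

    For each of ``n_perm_pairs`` draws two distinct genes are picked and
    one profile's samples are permuted, destroying any dependence while
    preserving both marginals. Deterministic given ``seed``.
    """
    if dataset.n_genes < 2:
        raise ValueError("need at least 2 genes to build an MI null")
    if n_perm_pairs < 1_000:
        raise ValueError("n_perm_pairs must be >= 1000 for a usable null")
    n = dataset.n_samples
    if n_bins is None:
        n_bins = default_n_bins(n)
    B = _binned_matrix(dataset.values.to_numpy(), n_bins)
    rng = np.random.default_rng(seed)
    g = B.shape[0]
    i = rng.integers(0, g, size=n_perm_pairs)
    j = rng.integers(0, g - 1, size=n_perm_pairs)
    j[j >= i] += 1
    nulls = np.empty(n_perm_pairs, dtype=float)
    chunk = 2_000
    for lo in range(0, n_perm_pairs, chunk):
        hi = min(lo + chunk, n_perm_pairs)
        permuted = rng.permuted(B[j[lo:hi]], axis=1)
        # pairwise MI of B[i] against the matching permuted row
        for t in range(hi - lo):
            counts = np.bincount(
                B[i[lo + t]].astype(np.int64) * n_bins + permuted[t],
                minlength=n_bins * n_bins,
            )
            nulls[lo + t] = _mi_from_counts(
                counts.reshape(n_bins, n_bins).astype(float)
            )
    return MiNull(nulls, n_perm_pairs)


def build_mi_network(
    dataset: ExpressionDataset,
    tfs: list[str],
    null: MiNull,
    n_bins: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> MiNetwork:
    """All TF x gene MI values, keeping edges with empirical p < alpha.

    TF-TF pairs are evaluated once. TFs absent from the dataset are
    dropped; if none remain an error is raised.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    gene_index = {g: i for i, g in enumerate(dataset.genes)}
    tfs_present = [t for t in tfs if t in gene_index]
    if not tfs_present:
        raise ValueError("no TF from the list is present in the dataset")
    n = dataset.n_samples
    if n_bins is None:
        n_bins = default_n_bins(n)
    values = dataset.values.to_numpy()
    B = _binned_matrix(values, n_bins)
    genes = dataset.genes
    tf_pos = {t: gene_index[t] for t in tfs_present}
    seen_tf: set[str] = set()
    rows_a: list[str] = []
    rows_b: list[str] = []
    mis_all: list[np.ndarray] = []
    pair_b_names: list[list[str]] = []
    for tf in tfs_present:
        # skip self and TF-TF pairs already evaluated
        others = [
            g for g in genes if g != tf and not (g in tf_pos and g in seen_tf)
        ]
        seen_tf.add(tf)
        if not others:
            continue
        idx = np.array([gene_index[g] for g in others])
        mis = _mi_one_vs_many(B[tf_pos[tf]], B[idx], n_bins)
        rows_a.extend([tf] * len(others))
        mis_all.append(mis)
        pair_b_names.append(others)
    for names in pair_b_names:
        rows_b.extend(names)
    mi_flat = np.concatenate(mis_all) if mis_all else np.empty(0)
    pvals = null.p_values(mi_flat)
    keep = pvals < alpha
    edges = pd.DataFrame(
        {
            "gene_a": np.array(rows_a, dtype=object)[keep],
            "gene_b": np.array(rows_b, dtype=object)[keep],
            "mi": mi_flat[keep],
            "p_value": pvals[keep],
        }
    ).reset_index(drop=True)
    return MiNetwork(edges, tfs_present, n_bins)


def apply_dpi(network: MiNetwork, tolerance: float = DEFAULT_DPI_TOLERANCE) -> MiNetwork:
    """Prune likely-indirect edges with the data processing inequality.

    For every triangle, the edge (i, j) is marked when its MI is below
    ``(1 - tolerance)`` times BOTH other edges' MI; all marks are computed
    on the input network and removed simultaneously.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    adj = network.adjacency()
    factor = 1.0 - tolerance
    drop = np.zeros(len(network.edges), dtype=bool)
    for pos, row in enumerate(network.edges.itertuples(index=False)):
        a, b, mab = row.gene_a, row.gene_b, row.mi
        na, nb = adj[a], adj[b]
        if len(nb) < len(na):
            na, nb = nb, na
        for k, mak in na.items():
            if k == a or k == b:
                continue
            mbk = nb.get(k)
            if mbk is not None and mab < factor * mak and mab < factor * mbk:
                drop[pos] = True
                break
    edges = network.edges.loc[~drop].reset_index(drop=True)
    return MiNetwork(edges, list(network.tf_genes), network.n_bins)
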