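"""Master-regulator analysis: GSEA-style regulon enrichment on a signature.

Each TF's regulon is scored against the molecular signature with a
weighted Kolmogorov-Smirnov running sum (Subramanian-style, weight
exponent 1 on |z|): genes are ranked by z, the running sum climbs by the
normalized |z| of member genes and falls by 1/(n - m) at non-members, and
the enrichment score (ES) is the signed deviation of maximum magnitude.

Because a regulon carries signed modes, the enrichment is two-tailed:
positive-mode targets are scored on the z-descending ranking and
negative-mode targets on the z-ascending one, and the two ES values are
combined weighted by subset sizes. A positive combined ES means the
targets move as an active TF predicts; negative, as an inactivated one.

Significance comes from recomputing each regulon's ES on every column of
the permutation null model: NES = (ES - mean) / sd of the null ES, and
p = 2 * (1 - Phi(|NES|)) under a Gaussian approximation of the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .regulons import RegulonSet, regulon_signature_size
from .signature import MolecularSignature, NullModel

DEFAULT_MIN_TARGETS = 20

MRA_COLUMNS = ["regulon", "size", "total_size", "es", "nes", "p_value", "fdr", "rank"]


def _ranked_order(z: np.ndarray, symbols: np.ndarray) -> np.ndarray:
    """Indices sorting by z descending, ties broken by gene symbol."""
    return np.lexsort((symbols, -z))


def _running_sum_es(
    hit: np.ndarray, scores: np.ndarray, hit_weights: np.ndarray
) -> float:
    """ES from an already-ranked universe.

    ``hit`` marks member positions, ``scores`` are the ranking scores and
    ``hit_weights`` multiplicative per-position weights (1 when unused).
    """
    n = hit.size
    m = int(hit.sum())
    w = np.abs(scores) * hit_weights
    w_hits = w * hit
    total = w_hits.sum()
    if total > 0:
        inc = w_hits / total
    else:  # all member scores zero: fall back to unweighted steps
        inc = hit / m
    miss = (~hit.astype(bool)).astype(float) / (n - m)
    running = np.cumsum(inc - miss)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


def gsea_es(
    gene_scores: MolecularSignature | pd.Series,
    member_set: list[str] | set[str],
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted-KS enrichment score of a gene set in a ranked signature.

    Genes are ranked by z descending (ties by symbol); member positions
    contribute |z| (optionally scaled by per-gene ``weights``), non-members
    1/(n - m). Returns the signed running-sum deviation of maximum
    magnitude, in [-1, 1].
    """
    z = gene_scores.z if isinstance(gene_scores, MolecularSignature) else gene_scores
    symbols = np.asarray(z.index, dtype=object)
    members = set(member_set) & set(z.index)
    if not members:
        raise ValueError("member set is empty after intersecting the signature")
    if len(members) >= len(z):
        raise ValueError("member set equals the whole signature universe")
    order = _ranked_order(z.to_numpy(dtype=float), symbols.astype(str))
    sym_sorted = symbols[order]
    hit = np.isin(sym_sorted, list(members)).astype(float)
    scores = z.to_numpy(dtype=float)[order]
    if weights is None:
        hw = np.ones_like(scores)
    else:
        hw = np.array([weights.get(s, 1.0) for s in sym_sorted])
    return _running_sum_es(hit, scores, hw)


def regulon_es(
    targets: list[str],
    modes: np.ndarray,
    weights: np.ndarray,
    signature: MolecularSignature | pd.Series,
    use_weights: bool = True,
) -> float:
    """Two-tailed combined ES of a regulon against the signature.

    Targets are split by mode sign (ties counted as positive): the
    positive set is scored on z descending, the negative set on z
    ascending, and the results are combined weighted by subset sizes.
    MI-derived interaction weights multiplicatively scale the |z| hit
    increments when ``use_weights`` is on.
    """
    z = signature.z if isinstance(signature, MolecularSignature) else signature
    in_sig = set(z.index)
    keep = [i for i, t in enumerate(targets) if t in in_sig]
    if not keep:
        raise ValueError("regulon has no targets in the signature")
    modes = np.asarray(modes, dtype=float)
    pos = [targets[i] for i in keep if modes[i] >= 0]
    neg = [targets[i] for i in keep if modes[i] < 0]
    wmap = (
        {targets[i]: float(weights[i]) for i in keep} if use_weights else None
    )
    parts = []
    if pos:
        parts.append((len(pos), gsea_es(z, pos, wmap)))
    if neg:
        parts.append((len(neg), gsea_es(-z, neg, wmap)))
    total = sum(n for n, _ in parts)
    return float(sum(n * es for n, es in parts) / total)


def nes_and_p(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """Standardize an ES against its null and convert to a two-sided p.

    NES = (es - mean(null)) / sd(null); p = 2 * (1 - Phi(|NES|)), a
    Gaussian approximation of the null ES distribution.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size < 100:
        raise ValueError("need >= 100 null ES values")
    sd = null_es.std(ddof=1)
    if sd == 0 or np.all(null_es == null_es[0]):
        raise ValueError("null ES distribution has zero variance")
    nes = (es - null_es.mean()) / sd
    return float(nes), p_from_nes(nes)


def p_from_nes(nes: float) -> float:
    """Two-sided Gaussian tail probability of a normalized ES."""
    return float(min(1.0, 2.0 * stats.norm.sf(abs(nes))))


def _es_at_positions(
    hit_pos: np.ndarray, hit_w: np.ndarray, abs_sorted: np.ndarray, n: int
) -> float:
    """Running-sum ES given member positions inside a ranked universe."""
    m = hit_pos.size
    vals = abs_sorted[hit_pos] * hit_w
    total = vals.sum()
    base = np.full(n, -1.0 / (n - m))
    if total > 0:
        base[hit_pos] = vals / total
    else:
        base[hit_pos] = 1.0 / m
    running = np.cumsum(base)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


def run_mra(
    regulons: RegulonSet,
    signature: MolecularSignature,
    null: NullModel,
    min_targets: int = DEFAULT_MIN_TARGETS,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Rank regulons by signature enrichment calibrated on the null model.

    Only regulons with at least ``min_targets`` targets inside the
    signature are tested. Each passing regulon's ES is recomputed on every
    null-model column to form its null ES distribution; FDR is
    Benjamini-Hochberg across tested regulons; ranking is by ascending p,
    ties by descending |NES| then TF symbol.
    """
    sizes = regulon_signature_size(regulons, signature.genes)
    tested = sorted(tf for tf, s in sizes.items() if s >= min_targets)
    if not tested:
        raise ValueError(
            f"no regulon has >= {min_targets} targets in the signature"
        )
    genes = np.asarray(signature.z.index, dtype=object)
    sym_key = genes.astype(str)
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}

    # per-TF member index sets, split by mode sign (ties positive)
    tf_parts: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for tf in tested:
        inters = [i for i in regulons[tf] if i.target in gene_pos]
        pos = [(gene_pos[i.target], i.weight) for i in inters if i.mode >= 0]
        neg = [(gene_pos[i.target], i.weight) for i in inters if i.mode < 0]
        tf_parts[tf] = (
            np.array([p for p, _ in pos], dtype=int),
            np.array([w for _, w in pos] if use_weights else [1.0] * len(pos)),
            np.array([p for p, _ in neg], dtype=int),
            np.array([w for _, w in neg] if use_weights else [1.0] * len(neg)),
        )

    def column_es(zc: np.ndarray) -> dict[str, float]:
        order_d = np.lexsort((sym_key, -zc))
        order_a = np.lexsort((sym_key, zc))
        inv_d = np.empty(n, dtype=int)
        inv_d[order_d] = np.arange(n)
        inv_a = np.empty(n, dtype=int)
        inv_a[order_a] = np.arange(n)
        abs_d = np.abs(zc[order_d])
        abs_a = np.abs(zc[order_a])
        out = {}
        for tf, (ip, wp, ineg, wneg) in tf_parts.items():
            parts = []
            if ip.size:
                parts.append((ip.size, _es_at_positions(inv_d[ip], wp, abs_d, n)))
            if ineg.size:
                parts.append(
                    (ineg.size, _es_at_positions(inv_a[ineg], wneg, abs_a, n))
                )
            tot = sum(c for c, _ in parts)
            out[tf] = sum(c * e for c, e in parts) / tot
        return out

    obs = column_es(signature.z.to_numpy(dtype=float))
    if not signature.z.index.equals(null.z.index):
        raise ValueError("null model gene universe differs from the signature")
    null_mat = null.z.to_numpy(dtype=float)
    null_es_by_tf: dict[str, list[float]] = {tf: [] for tf in tested}
    for j in range(null_mat.shape[1]):
        col = column_es(null_mat[:, j])
        for tf in tested:
            null_es_by_tf[tf].append(col[tf])
    rows = []
    for tf in tested:
        nes, p = nes_and_p(obs[tf], np.array(null_es_by_tf[tf]))
        rows.append(
            (tf, sizes[tf], len(regulons[tf]), obs[tf], nes, p)
        )
    table = pd.DataFrame(
        rows, columns=["regulon", "size", "total_size", "es", "nes", "p_value"]
    )
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    order = np.lexsort(
        (table["regulon"], -np.abs(table["nes"]), table["p_value"])
    )
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[MRA_COLUMNS]


def coverage_curve(
    result: pd.DataFrame, regulons: RegulonSet, signature_genes: list[str]
) -> pd.DataFrame:
    """Fraction of the signature covered by the top-k regulons' targets.

    For k = 1..n (by MRA rank), ``covered`` is the size of the union of
    the top-k regulons' target lists intersected with the signature.
    """
    if len(result) == 0:
        raise ValueError("empty MRA result")
    sig = set(signature_genes)
    union: set[str] = set()
    rows = []
    ordered = result.sort_values("rank")
    for k, tf in enumerate(ordered["regulon"], start=1):
        union |= set(regulons.targets(tf)) & sig
        rows.append((k, len(union), len(union) / len(sig)))
    return pd.DataFrame(rows, columns=["k", "covered", "fraction"])
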