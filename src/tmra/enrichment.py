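"""Hypergeometric over-representation analysis with BH-FDR.

Given a query gene list, a reference universe and a gene-set collection,
each set is tested for containing more query genes than random sampling
from the reference would give: the upper tail P(X >= k) of a
hypergeometric(N, M, s) variable, with N the reference size, M the set
size inside the reference, s the query size and k the observed overlap.
Tail probabilities are accumulated in log space for numerical stability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection

logger = logging.getLogger(__name__)

ORA_COLUMNS = ["name", "k", "s", "M", "N", "p_value", "fdr", "enrichment_ratio"]


def _log_hypergeom_pmf(j: np.ndarray, N: int, M: int, s: int) -> np.ndarray:
    """log P(X = j) via log-gamma; valid only on the support."""
    j = np.asarray(j, dtype=float)
    return (
        gammaln(M + 1)
        - gammaln(j + 1)
        - gammaln(M - j + 1)
        + gammaln(N - M + 1)
        - gammaln(s - j + 1)
        - gammaln(N - M - (s - j) + 1)
        - (gammaln(N + 1) - gammaln(s + 1) - gammaln(N - s + 1))
    )


def hypergeom_tail(k: int, N: int, M: int, s: int) -> float:
    """Upper-tail P(X >= k) of a hypergeometric(N, M, s) distribution.

    ``N`` population size, ``M`` marked genes in the population, ``s``
    sample (query) size, ``k`` observed marked genes in the sample.
    """
    for name, v in (("k", k), ("N", N), ("M", M), ("s", s)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if s > N or M > N or k > s:
        raise ValueError(
            f"invalid hypergeometric parameters: k={k}, N={N}, M={M}, s={s}"
        )
    lo = max(0, s - (N - M))  # smallest attainable overlap
    hi = min(M, s)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    j = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(j, N, M, s)))))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input-order aligned."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: list[str],
    reference: list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Over-representation of each gene set in the query vs the reference.

    Query genes outside the reference are dropped (count logged). Results
    are sorted by FDR, then p, then set name; ``enrichment_ratio`` is
    (k/s) / (M/N), the observed over expected overlap fraction.
    """
    ref = list(dict.fromkeys(reference))
    if not ref:
        raise ValueError("empty reference universe")
    ref_set = set(ref)
    q = [g for g in dict.fromkeys(query) if g in ref_set]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("dropped %d query genes absent from the reference", dropped)
    if not q:
        raise ValueError("query is empty after intersecting the reference")
    N, s = len(ref_set), len(q)
    q_set = set(q)
    rows = []
    for gs in sets:
        members = set(gs.genes) & ref_set
        M = len(members)
        if M < min_set_size:
            continue
        k = len(members & q_set)
        p = hypergeom_tail(k, N, M, s) if M else 1.0
        ratio = (k / s) / (M / N) if k > 0 else 0.0
        rows.append((gs.name, k, s, M, N, p, ratio))
    frame = pd.DataFrame(
        rows, columns=["name", "k", "s", "M", "N", "p_value", "enrichment_ratio"]
    )
    frame["fdr"] = bh_fdr(frame["p_value"].to_numpy()) if len(frame) else []
    frame["significant"] = frame["fdr"] <= alpha
    frame = frame.sort_values(
        ["fdr", "p_value", "name"], kind="mergesort"
    ).reset_index(drop=True)
    return frame[ORA_COLUMNS + ["significant"]]
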