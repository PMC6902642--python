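"""Pathway-restricted molecular signature and its permutation null model.

The signature is a per-gene differential-expression z-score between case
and control samples, restricted to the union of a gene-set collection
(e.g. the signal-transduction pathways). Each gene gets a Welch two-sample
t statistic (case minus control) whose two-sided p-value is mapped to the
standard-normal scale: ``z = sign(t) * Phi^-1(1 - p/2)``. This makes z
exactly standard normal under the null regardless of the per-gene degrees
of freedom, which is what cross-gene comparability requires; |z| is
clamped at 8 to avoid infinities when p underflows.

The null model recomputes the whole signature under random case/control
label permutations that preserve class sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset, GeneSetCollection

Z_CLAMP = 8.0
DEFAULT_PERMUTATIONS = 1_000


def gene_ttest(case_values: np.ndarray, control_values: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic (case minus control) and two-sided p.

    Zero variance in both groups with equal means is a defined degenerate
    case (t = 0, p = 1); zero variance with different means has no finite
    t and is an error.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group for a t-test")
    t, p = _welch_rows(x[None, :], y[None, :])
    return float(t[0]), float(p[0])


def _welch_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test of two genes x samples matrices."""
    n1, n2 = X.shape[1], Y.shape[1]
    m1 = X.mean(axis=1)
    m2 = Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    degenerate = se2 == 0
    if degenerate.any() and (diff[degenerate] != 0).any():
        raise ValueError(
            "zero variance in both groups with different means; t undefined"
        )
    ok = ~degenerate
    if ok.any():
        t[ok] = diff[ok] / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    return t, p


def _z_from_tp(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Signed standard-normal quantile of the two-sided p, clamped at |8|."""
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.clip(p, 1e-300, None) / 2.0)
    z = np.clip(z, -Z_CLAMP, Z_CLAMP)
    return np.sign(t) * z


@dataclass
class MolecularSignature:
    """Per-gene signed z-scores on a restricted gene universe."""

    z: pd.Series  # index gene, value z
    case_n: int
    control_n: int
    restricted_to: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("non-finite z in molecular signature")

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class NullModel:
    """Signature replicates under case/control label permutation."""

    z: pd.DataFrame  # genes x permutations
    seed: int

    def __post_init__(self) -> None:
        if self.z.shape[1] < 100:
            raise ValueError("null model needs >= 100 permutations")

    @property
    def n_permutations(self) -> int:
        return self.z.shape[1]


def _restricted_genes(
    dataset: ExpressionDataset, restriction: GeneSetCollection
) -> list[str]:
    in_data = set(dataset.genes)
    genes = [g for g in restriction.union_genes() if g in in_data]
    if not genes:
        raise ValueError("restriction gene sets do not intersect the dataset")
    # keep matrix row order for determinism
    order = {g: i for i, g in enumerate(dataset.genes)}
    return sorted(genes, key=order.__getitem__)


def compute_signature(
    dataset: ExpressionDataset, restriction: GeneSetCollection
) -> MolecularSignature:
    """Welch-t z-score signature on (union of restriction sets) ∩ genes."""
    dataset.require_two_classes()
    genes = _restricted_genes(dataset, restriction)
    case = dataset.values.loc[genes, dataset.case_samples].to_numpy()
    ctrl = dataset.values.loc[genes, dataset.control_samples].to_numpy()
    t, p = _welch_rows(case, ctrl)
    z = pd.Series(_z_from_tp(t, p), index=pd.Index(genes, name="gene"), name="z")
    return MolecularSignature(
        z, case.shape[1], ctrl.shape[1], tuple(restriction.names)
    )


def build_null_model(
    dataset: ExpressionDataset,
    restriction: GeneSetCollection,
    k: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> NullModel:
    """k label permutations (class sizes preserved), one signature each."""
    if k < 100:
        raise ValueError("need k >= 100 permutations")
    dataset.require_two_classes()
    n_case = len(dataset.case_samples)
    n_total = dataset.n_samples
    if math.comb(n_total, n_case) < k:
        raise ValueError(
            f"only {math.comb(n_total, n_case)} distinct label assignments exist "
            f"but k={k}; use exact enumeration for designs this small"
        )
    genes = _restricted_genes(dataset, restriction)
    X = dataset.values.loc[genes].to_numpy()
    rng = np.random.default_rng(seed)
    cols = np.empty((len(genes), k))
    for j in range(k):
        perm = rng.permutation(n_total)
        case_idx = perm[:n_case]
        ctrl_idx = perm[n_case:]
        t, p = _welch_rows(X[:, case_idx], X[:, ctrl_idx])
        cols[:, j] = _z_from_tp(t, p)
    frame = pd.DataFrame(
        cols, index=pd.Index(genes, name="gene"),
        columns=[f"perm{j:04d}" for j in range(k)],
    )
    return NullModel(frame, seed)
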