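"""Core in-memory containers shared by every stage of the pipeline.

The substrate of the analysis is a log-scale gene-by-sample expression
matrix with a two-class phenotype (``case`` vs ``control``), together with
gene lists (e.g. transcription factors) and named gene-set collections
(e.g. signal-transduction pathways in GMT form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped and uppercased."""
    return symbol.strip().upper()


def normalize_gene_list(genes: Iterable[str]) -> list[str]:
    """Normalize symbols, preserving order; raise on duplicates.

    Duplicates after normalization are an error rather than silently
    collapsed — a duplicate usually indicates an upstream quantification
    or mapping mistake.
    """
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        s = normalize_symbol(g)
        if not s:
            raise ValueError("empty gene symbol in gene list")
        if s in seen:
            raise ValueError(f"duplicate gene symbol {s!r} in gene list")
        seen.add(s)
        out.append(s)
    if not out:
        raise ValueError("gene list is empty")
    return out


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a two-class sample annotation.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index are gene symbols,
        columns are sample identifiers, entries log-scale expression.
    labels
        Series indexed by sample id with values ``"case"`` / ``"control"``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r} in expression matrix")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in expression matrix")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        if set(self.labels.index) != set(cols):
            missing = set(cols) ^ set(self.labels.index)
            raise ValueError(f"sample/label mismatch for: {sorted(missing)[:5]}")
        # align label order with the matrix columns
        self.labels = self.labels.reindex(cols)
        extra = set(self.labels.unique()) - {CASE, CONTROL}
        if extra:
            raise ValueError(f"unknown class labels {sorted(extra)}")

    # -- convenience ----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_samples(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])

    @property
    def case_samples(self) -> list[str]:
        return self.class_samples(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.class_samples(CONTROL)

    def require_two_classes(self) -> None:
        """Every statistical operation needs >= 2 samples per class."""
        for cls in (CASE, CONTROL):
            n = int((self.labels == cls).sum())
            if n < 2:
                raise ValueError(f"class {cls!r} has {n} samples; need >= 2")

    def matrix(self, genes: Iterable[str] | None = None) -> pd.DataFrame:
        if genes is None:
            return self.values
        return self.values.loc[list(genes)]


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, deduplicated members."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        sets = {}
        for name, genes in mapping.items():
            members = _dedup_normalized(genes)
            sets[name] = GeneSet(name, "", members)
        return cls(sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def union_genes(self) -> list[str]:
        """Union of all member genes, in first-seen order."""
        seen: dict[str, None] = {}
        for gs in self:
            for g in gs.genes:
                seen.setdefault(g)
        return list(seen)


def _dedup_normalized(genes: Iterable[str]) -> list[str]:
    """Normalize and silently drop duplicates, preserving first-seen order."""
    seen: dict[str, None] = {}
    for g in genes:
        s = normalize_symbol(g)
        if s:
            seen.setdefault(s)
    return list(seen)
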