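"""Directed regulons with mode of regulation and interaction weight.

An undirected significant-MI network is converted into per-TF regulons:
direction is imposed TF -> target, the mode of regulation is the Spearman
correlation between TF and target expression (sign = activation/repression),
and the weight is the edge MI normalized to the strongest interaction of
that TF (so every non-empty regulon has max weight exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset

if TYPE_CHECKING:  # pragma: no cover
    from .network import MiNetwork

REGULON_COLUMNS = ["tf", "target", "mode", "weight"]


@dataclass
class Interaction:
    target: str
    mode: float  # Spearman rho in [-1, 1]
    weight: float  # in (0, 1]; max-normalized MI within the regulon


@dataclass
class RegulonSet:
    """Mapping tf -> list of (target, mode, weight) interactions."""

    regulons: dict[str, list[Interaction]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, inters in self.regulons.items():
            targets = [i.target for i in inters]
            if tf in targets:
                raise ValueError(f"TF {tf!r} occurs in its own target list")
            if len(set(targets)) != len(targets):
                raise ValueError(f"duplicate target in regulon of {tf!r}")
            for i in inters:
                if not -1.0 <= i.mode <= 1.0:
                    raise ValueError(
                        f"mode {i.mode} of {tf}->{i.target} outside [-1, 1]"
                    )
                if not 0.0 < i.weight <= 1.0:
                    raise ValueError(
                        f"weight {i.weight} of {tf}->{i.target} outside (0, 1]"
                    )

    # -- container protocol --------------------------------------------
    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self) -> Iterator[str]:
        return iter(self.regulons)

    def __getitem__(self, tf: str) -> list[Interaction]:
        return self.regulons[tf]

    @property
    def tfs(self) -> list[str]:
        return list(self.regulons)

    def targets(self, tf: str) -> list[str]:
        return [i.target for i in self.regulons[tf]]

    def n_edges(self) -> int:
        return sum(len(v) for v in self.regulons.values())

    # -- tabular view ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table (tf, target, mode, weight) sorted for diffs."""
        rows = [
            (tf, i.target, i.mode, i.weight)
            for tf, inters in self.regulons.items()
            for i in inters
        ]
        frame = pd.DataFrame(rows, columns=REGULON_COLUMNS)
        return frame.sort_values(["tf", "target"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegulonSet":
        regulons: dict[str, list[Interaction]] = {}
        for row in frame.itertuples(index=False):
            regulons.setdefault(str(row.tf), []).append(
                Interaction(str(row.target), float(row.mode), float(row.weight))
            )
        return cls(regulons)


def spearman_mode(tf_profile: np.ndarray, target_profile: np.ndarray) -> float:
    """Spearman rank correlation of a TF with one of its targets.

    Average ranks are assigned to ties. The sign is the mode of regulation:
    positive = activation, negative = repression.
    """
    x = np.asarray(tf_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a Spearman mode")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant expression profile; mode undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def build_regulons(network: "MiNetwork", dataset: ExpressionDataset) -> RegulonSet:
    """Orient the MI network TF -> target and attach modes and weights.

    For each TF its regulon is the set of network neighbours; a TF-TF edge
    places each TF in the other's regulon. Weight is edge MI divided by the
    largest MI in that TF's regulon.
    """
    missing = [g for g in network.genes() if g not in set(dataset.genes)]
    if missing:
        raise ValueError(f"network genes absent from dataset: {missing[:5]}")
    values = dataset.values
    tf_set = set(network.tf_genes)
    adj = network.adjacency()
    regulons: dict[str, list[Interaction]] = {}
    for tf in network.tf_genes:
        nbrs = adj.get(tf, {})
        if not nbrs:
            continue
        max_mi = max(nbrs.values())
        inters = []
        tf_prof = values.loc[tf].to_numpy()
        for target in sorted(nbrs):
            rho = spearman_mode(tf_prof, values.loc[target].to_numpy())
            inters.append(Interaction(target, rho, nbrs[target] / max_mi))
        regulons[tf] = inters
    # keep deterministic TF order regardless of adjacency iteration
    ordered = {tf: regulons[tf] for tf in sorted(regulons)}
    del tf_set
    return RegulonSet(ordered)


def regulon_signature_size(
    regulons: RegulonSet, signature_genes: Iterable[str]
) -> dict[str, int]:
    """Number of targets of each TF that fall inside the signature universe."""
    sig = set(signature_genes)
    return {tf: sum(t in sig for t in regulons.targets(tf)) for tf in regulons}
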