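"""Two-condition expression simulator with planted regulatory ground truth.

The generator emulates the shape of a tumor/normal RNA-Seq study at desk
scale: two unbalanced sample groups, a panel of transcription factors with
disjoint target regulons of known mode sign, a subset of TFs whose latent
activity is shifted downward in case samples (so their regulons are the
differential regulators downstream stages should recover), background
genes, and pathway gene sets drawn partly from the planted regulon
targets so that a pathway-restricted signature covers the regulons.

Generative model (all draws from one seeded generator, in documented
order):

* TF latent activity ``a[f, s] ~ N(0, 1)``; for each planted differential
  TF the activity of case samples is shifted by ``-delta``.
* TF expression ``x[f, s] = a[f, s] + N(0, sigma)``.
* Each target t of TF f has a mode sign ``g in {+1, -1}`` (-1 with
  probability ``frac_repressed``) and expression
  ``x[t, s] = beta * g * a[f, s] + N(0, sigma)``.
* Background genes are i.i.d. ``N(0, 1)``.
* Each pathway draws ``pathway_planted_fraction`` of its members from the
  union of regulon targets and the rest from background genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, ExpressionDataset, GeneSetCollection
from .regulons import Interaction, RegulonSet


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset."""

    n_case: int = 120
    n_control: int = 30
    n_tf: int = 50
    targets_per_tf: tuple[int, int] = (50, 80)
    frac_repressed: float = 0.3
    n_diff_tf: int = 10
    activity_shift: float = 1.0  # delta, standardized activity units
    coupling: float = 1.0  # beta
    noise_sd: float = 1.0  # sigma
    n_background_genes: int = 1000
    n_pathways: int = 25
    pathway_size: tuple[int, int] = (80, 140)
    pathway_planted_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("need >= 2 samples per class")
        if self.n_tf < 1 or self.n_background_genes < 0:
            raise ValueError("counts must be positive")
        if not 0 < self.n_diff_tf <= self.n_tf:
            raise ValueError("n_diff_tf must be in [1, n_tf]")
        lo, hi = self.targets_per_tf
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_tf range is empty")
        lo, hi = self.pathway_size
        if not 1 <= lo <= hi:
            raise ValueError("pathway_size range is empty")
        for name in ("frac_repressed", "pathway_planted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.activity_shift < 0:
            raise ValueError(
                "activity_shift must be >= 0; the case-sample direction of "
                "the shift is encoded by construction"
            )
        if self.noise_sd <= 0 or self.coupling < 0:
            raise ValueError("noise_sd must be > 0 and coupling >= 0")


@dataclass
class GroundTruth:
    """Planted structure the downstream stages should recover."""

    regulons: RegulonSet
    diff_tfs: list[str]
    pathways: GeneSetCollection
    tf_genes: list[str] = field(default_factory=list)


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale default preserving the study's qualitative shape.

    Unbalanced groups (cases outnumber controls 4:1), 50 TFs of which 10
    are planted differential regulators, and 25 pathway gene sets.
    """
    return SimulationConfig(seed=seed)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Deterministically generate an expression dataset plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control

    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tf)]
    diff_tfs = tf_names[: config.n_diff_tf]

    # draw 1: regulon sizes; draw 2: mode signs per edge (TF order)
    lo, hi = config.targets_per_tf
    sizes = rng.integers(lo, hi + 1, size=config.n_tf)
    n_targets = int(sizes.sum())
    target_names = [f"TG{i + 1:05d}" for i in range(n_targets)]
    modes = np.where(
        rng.random(n_targets) < config.frac_repressed, -1.0, 1.0
    )
    owner = np.repeat(np.arange(config.n_tf), sizes)  # disjoint regulons

    # draw 3: TF activities, with the planted shift applied to cases
    activity = rng.standard_normal((config.n_tf, n_samples))
    case_cols = np.arange(config.n_case)
    for f in range(config.n_diff_tf):
        activity[f, case_cols] -= config.activity_shift

    # draws 4-6: TF, target and background expression noise
    tf_expr = activity + config.noise_sd * rng.standard_normal(
        (config.n_tf, n_samples)
    )
    target_expr = (
        config.coupling * modes[:, None] * activity[owner]
        + config.noise_sd * rng.standard_normal((n_targets, n_samples))
    )
    bg_names = [f"BG{i + 1:05d}" for i in range(config.n_background_genes)]
    bg_expr = rng.standard_normal((config.n_background_genes, n_samples))

    genes = tf_names + target_names + bg_names
    values = pd.DataFrame(
        np.vstack([tf_expr, target_expr, bg_expr]),
        index=pd.Index(genes, name="gene"),
        columns=[f"S{i + 1:04d}" for i in range(n_samples)],
    )
    labels = pd.Series(
        [CASE] * config.n_case + [CONTROL] * config.n_control,
        index=values.columns,
        name="class",
    )
    dataset = ExpressionDataset(values, labels)

    regulons = RegulonSet(
        {
            tf_names[f]: [
                Interaction(target_names[t], float(modes[t]), 1.0)
                for t in np.flatnonzero(owner == f)
            ]
            for f in range(config.n_tf)
        }
    )

    # draw 7: pathway memberships
    target_pool = np.array(target_names, dtype=object)
    bg_pool = np.array(bg_names, dtype=object)
    sets: dict[str, list[str]] = {}
    lo, hi = config.pathway_size
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_planted = min(
            int(round(size * config.pathway_planted_fraction)), target_pool.size
        )
        n_bg = min(size - n_planted, bg_pool.size)
        members = []
        if n_planted:
            members.extend(
                rng.choice(target_pool, size=n_planted, replace=False).tolist()
            )
        if n_bg:
            members.extend(rng.choice(bg_pool, size=n_bg, replace=False).tolist())
        if not members:
            raise ValueError("pathway ended up empty; enlarge the gene pools")
        sets[f"PATHWAY{p + 1:02d}"] = members
    pathways = GeneSetCollection.from_mapping(sets)

    truth = GroundTruth(regulons, diff_tfs, pathways, tf_genes=tf_names)
    return dataset, truth
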