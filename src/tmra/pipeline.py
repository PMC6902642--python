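"""End-to-end orchestration of the master-regulator analysis.

``run_pipeline`` wires the stages together on a synthetic dataset:
simulate -> MI network + DPI -> regulons -> pathway-restricted signature
and permutation null -> master-regulator ranking and coverage curve ->
pathway deregulation scores -> over-representation of the top regulators'
targets in the pathway collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import ExpressionDataset, GeneSetCollection
from .enrichment import run_ora
from .estimators import (
    MasterRegulatorAnalysis,
    PathwayDeregulation,
    RegulonInference,
)
from .regulons import RegulonSet
from .simulate import GroundTruth, SimulationConfig, default_study_config, generate_dataset


@dataclass
class PipelineResult:
    dataset: ExpressionDataset
    truth: GroundTruth | None
    inference: RegulonInference
    mra: MasterRegulatorAnalysis
    pds: PathwayDeregulation
    ora: pd.DataFrame

    @property
    def regulons(self) -> RegulonSet:
        return self.inference.regulons_

    @property
    def results(self) -> pd.DataFrame:
        return self.mra.results_


def run_analysis(
    dataset: ExpressionDataset,
    tf_genes: list[str],
    pathways: GeneSetCollection,
    seed: int = 0,
    n_null_pairs: int = 10_000,
    n_permutations: int = 1_000,
    min_targets: int = 20,
    top_k_ora: int = 10,
    truth: GroundTruth | None = None,
) -> PipelineResult:
    """Run every analysis stage on an expression dataset."""
    inference = RegulonInference(
        tf_genes=tf_genes, n_null_pairs=n_null_pairs, random_state=seed
    ).fit(dataset)
    mra = MasterRegulatorAnalysis(
        pathways=pathways, min_targets=min_targets,
        n_permutations=n_permutations, random_state=seed + 1,
    ).fit(dataset, regulons=inference.regulons_)
    pds = PathwayDeregulation(pathways=pathways).fit(dataset)
    top = mra.results_.sort_values("rank").head(top_k_ora)
    query: list[str] = []
    for tf in top["regulon"]:
        query.extend(inference.regulons_.targets(tf))
    ora = run_ora(list(dict.fromkeys(query)), dataset.genes, pathways)
    return PipelineResult(dataset, truth, inference, mra, pds, ora)


def run_pipeline(
    config: SimulationConfig | None = None, seed: int | None = None, **kwargs
) -> PipelineResult:
    """Simulate a dataset at the study defaults and analyse it end to end."""
    if config is None:
        config = default_study_config(seed=0 if seed is None else seed)
    elif seed is not None:
        config.seed = seed
    dataset, truth = generate_dataset(config)
    return run_analysis(
        dataset, truth.tf_genes, truth.pathways,
        seed=config.seed + 1, truth=truth, **kwargs,
    )
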