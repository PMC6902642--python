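import numpy as np
import pandas as pd
import pytest

from tmra.datatypes import CASE, CONTROL, ExpressionDataset, GeneSetCollection
from tmra.simulate import SimulationConfig, generate_dataset


def make_dataset(values: np.ndarray, genes, samples, n_case) -> ExpressionDataset:
    frame = pd.DataFrame(values, index=list(genes), columns=list(samples))
    labels = pd.Series(
        [CASE] * n_case + [CONTROL] * (len(samples) - n_case),
        index=frame.columns,
    )
    return ExpressionDataset(frame, labels)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 6 samples, deterministic values, 3 case / 3 control."""
    rng = np.random.default_rng(42)
    return make_dataset(
        rng.standard_normal((3, 6)), ["TP53", "GLI2", "MYC"],
        [f"s{i}" for i in range(6)], 3,
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced-scale study used by unit tests (fast but non-trivial)."""
    base = dict(
        n_case=100, n_control=50, n_tf=15, targets_per_tf=(20, 30),
        n_diff_tf=5, n_background_genes=300, n_pathways=10,
        pathway_size=(40, 60), seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_planted():
    """Shared small planted dataset with ground truth (seed 0)."""
    return generate_dataset(small_config(seed=0))


@pytest.fixture(scope="session")
def small_signature_null(small_planted):
    """Signature + 200-permutation null on the small planted dataset."""
    from tmra.signature import build_null_model, compute_signature

    dataset, truth = small_planted
    sig = compute_signature(dataset, truth.pathways)
    null = build_null_model(dataset, truth.pathways, k=200, seed=123)
    return sig, null


def gene_sets(**mapping) -> GeneSetCollection:
    return GeneSetCollection.from_mapping(mapping)
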