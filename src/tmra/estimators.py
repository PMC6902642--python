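"""Scikit-learn-style estimator façade over the pipeline stages.

Each major stage is exposed as an estimator with ``get_params`` /
``set_params`` and trailing-underscore fitted attributes so the stages
compose with scikit-learn model-selection tooling. ``X`` is an
:class:`~tmra.datatypes.ExpressionDataset` (the field's container for a
labelled expression matrix) rather than a bare samples x features array;
the phenotype labels travel inside it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import mra as _mra
from . import network as _network
from . import pathifier as _pathifier
from . import regulons as _regulons
from . import signature as _signature
from .datatypes import ExpressionDataset, GeneSetCollection


def _seed(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().entropy % (2**31))
    return int(random_state)


class RegulonInference(BaseEstimator):
    """Infer TF regulons from expression via significant MI plus DPI.

    Parameters
    ----------
    tf_genes : list of str
        Transcription-factor symbols to seed the network with.
    n_bins : int or None
        Joint-histogram bins for the MI estimator; None picks
        ``max(2, floor(sqrt(n / 5)))``.
    alpha : float, default 0.005
        Pooled-permutation p-value threshold for keeping an edge.
    dpi_tolerance : float, default 0.2
        DPI tolerance; the weakest triangle edge is removed when below
        ``(1 - tolerance)`` times both others.
    n_null_pairs : int, default 10000
        Permuted gene pairs pooled into the MI null.
    random_state : int or None
        Seed for the permutation null.
    """

    def __init__(
        self,
        tf_genes: list[str] | None = None,
        n_bins: int | None = None,
        alpha: float = _network.DEFAULT_ALPHA,
        dpi_tolerance: float = _network.DEFAULT_DPI_TOLERANCE,
        n_null_pairs: int = 10_000,
        random_state: int | None = None,
    ):
        self.tf_genes = tf_genes
        self.n_bins = n_bins
        self.alpha = alpha
        self.dpi_tolerance = dpi_tolerance
        self.n_null_pairs = n_null_pairs
        self.random_state = random_state

    def fit(self, X: ExpressionDataset, y=None) -> "RegulonInference":
        if not self.tf_genes:
            raise ValueError("tf_genes must be provided")
        null = _network.build_mi_null(
            X, self.n_bins, self.n_null_pairs, _seed(self.random_state)
        )
        raw = _network.build_mi_network(
            X, list(self.tf_genes), null, self.n_bins, self.alpha
        )
        self.mi_null_ = null
        self.raw_network_ = raw
        self.network_ = _network.apply_dpi(raw, self.dpi_tolerance)
        self.regulons_ = _regulons.build_regulons(self.network_, X)
        return self


class MasterRegulatorAnalysis(BaseEstimator):
    """Rank regulons by signature GSEA calibrated on a permutation null.

    ``fit`` builds the pathway-restricted molecular signature and its
    label-permutation null from ``X`` and scores the supplied regulons.

    Parameters
    ----------
    pathways : GeneSetCollection
        Gene sets whose union restricts the signature.
    min_targets : int, default 20
        Minimum signature-restricted regulon size to be tested.
    n_permutations : int, default 1000
        Label permutations for the null model.
    use_weights : bool, default True
        Scale GSEA hit increments by the MI-derived interaction weights.
    """

    def __init__(
        self,
        pathways: GeneSetCollection | None = None,
        min_targets: int = _mra.DEFAULT_MIN_TARGETS,
        n_permutations: int = _signature.DEFAULT_PERMUTATIONS,
        use_weights: bool = True,
        random_state: int | None = None,
    ):
        self.pathways = pathways
        self.min_targets = min_targets
        self.n_permutations = n_permutations
        self.use_weights = use_weights
        self.random_state = random_state

    def fit(
        self, X: ExpressionDataset, y=None, regulons: _regulons.RegulonSet = None
    ) -> "MasterRegulatorAnalysis":
        if self.pathways is None:
            raise ValueError("pathways must be provided")
        if regulons is None:
            raise ValueError("pass regulons=... (e.g. RegulonInference().regulons_)")
        self.signature_ = _signature.compute_signature(X, self.pathways)
        self.null_model_ = _signature.build_null_model(
            X, self.pathways, self.n_permutations, _seed(self.random_state)
        )
        self.results_ = _mra.run_mra(
            regulons, self.signature_, self.null_model_,
            self.min_targets, self.use_weights,
        )
        self.coverage_ = _mra.coverage_curve(
            self.results_, regulons, self.signature_.genes
        )
        return self


class PathwayDeregulation(BaseEstimator, TransformerMixin):
    """Transform samples into per-pathway deregulation scores (PDS).

    ``fit`` learns, per pathway, the control-reference normalization, the
    PCA reduction and the principal curve; ``transform`` projects samples
    onto the stored curves and returns a samples x pathways score matrix.
    """

    def __init__(
        self,
        pathways: GeneSetCollection | None = None,
        var_fraction: float = _pathifier.DEFAULT_VAR_FRACTION,
        max_components: int = _pathifier.DEFAULT_MAX_COMPONENTS,
        max_iter: int = _pathifier.DEFAULT_MAX_ITER,
        tol: float = _pathifier.DEFAULT_TOL,
    ):
        self.pathways = pathways
        self.var_fraction = var_fraction
        self.max_components = max_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: ExpressionDataset, y=None) -> "PathwayDeregulation":
        if self.pathways is None:
            raise ValueError("pathways must be provided")
        result = _pathifier.compute_pds(
            X, self.pathways, self.var_fraction, self.max_components,
            self.max_iter, self.tol,
        )
        self.models_ = result.models
        self.skipped_ = result.skipped
        self.pds_ = result.scores  # pathways x samples, training data
        return self

    def transform(self, X: ExpressionDataset | pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise ValueError("PathwayDeregulation is not fitted")
        values = X.values if isinstance(X, ExpressionDataset) else X
        cols = {
            name: model.score(values) for name, model in self.models_.items()
        }
        return pd.DataFrame(cols, index=values.columns)
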