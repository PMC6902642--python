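"""Per-sample, per-pathway deregulation scores from principal curves.

For each pathway the expression of its genes is standardized against the
control samples, reduced by PCA, and a Hastie-Stuetzle principal curve (a
smooth one-dimensional curve of minimal squared distance to the point
cloud) is fitted to all samples. Each sample is projected onto the curve
and its arc-length position, centred at the control median and normalized
by total curve length, is the pathway deregulation score (PDS): controls
sit near 0 by construction and the curve is oriented so deregulation in
cases is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.decomposition import PCA

from .datatypes import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_VAR_FRACTION = 0.8
DEFAULT_MAX_COMPONENTS = 10
DEFAULT_MAX_ITER = 10
DEFAULT_TOL = 1e-4


def normalize_to_reference(
    dataset: ExpressionDataset, pathway_genes: list[str]
) -> pd.DataFrame:
    """Standardize pathway genes against the control-sample distribution.

    Restricts to pathway genes present in the matrix, subtracts the
    control mean and divides by the control standard deviation per gene.
    Genes absent from the matrix and genes with zero control variance are
    dropped (logged); fewer than 2 usable genes is an error.
    """
    controls = sorted(dataset.control_samples)  # fixed order: deterministic sums
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples for reference normalization")
    in_data = set(dataset.genes)
    present = [g for g in pathway_genes if g in in_data]
    absent = len(pathway_genes) - len(present)
    if absent:
        logger.info("%d pathway genes absent from the matrix", absent)
    if len(present) < 2:
        raise ValueError("fewer than 2 pathway genes present in the matrix")
    sub = dataset.values.loc[present]
    mu = sub[controls].mean(axis=1)
    sd = sub[controls].std(axis=1, ddof=1)
    usable = sd > 0
    if (~usable).any():
        logger.info("dropped %d zero-control-variance genes", int((~usable).sum()))
    if usable.sum() < 2:
        raise ValueError("fewer than 2 pathway genes with control variance")
    sub = sub.loc[usable]
    return sub.sub(mu[usable], axis=0).div(sd[usable], axis=0)


@dataclass
class PrincipalCurve:
    """Polyline representation of a fitted principal curve."""

    vertices: np.ndarray  # (m, d) ordered along the curve
    arc_lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("principal curve needs >= 2 vertices")
        self.vertices = v
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        self.arc_lengths = np.concatenate([[0.0], np.cumsum(seg)])
        if self.length <= 0:
            raise ValueError("principal curve has zero length")

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length position and squared distance of each point.

        Exhaustive search over all polyline segments (sample counts are
        desk-scale); returns (s, d2) arrays of length n_points.
        """
        P = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.vertices[:-1]
        D = np.diff(self.vertices, axis=0)
        L2 = (D**2).sum(axis=1)
        L2safe = np.where(L2 > 0, L2, 1.0)
        diff = P[:, None, :] - A[None, :, :]
        t = np.clip((diff * D[None, :, :]).sum(-1) / L2safe, 0.0, 1.0)
        proj = A[None, :, :] + t[:, :, None] * D[None, :, :]
        d2 = ((P[:, None, :] - proj) ** 2).sum(-1)
        seg = np.argmin(d2, axis=1)
        rows = np.arange(P.shape[0])
        seglen = np.sqrt(L2)
        s = self.arc_lengths[seg] + t[rows, seg] * seglen[seg]
        return s, d2[rows, seg]


def _smooth_coords(
    lam: np.ndarray, X: np.ndarray, penalties: list[float | None]
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth each coordinate against arc length with a cubic spline.

    Duplicate arc-length values are averaged first. The smoothing penalty
    of each coordinate is chosen by generalized cross-validation on its
    first use and reused afterwards (``penalties`` is updated in place);
    the GCV search is by far the most expensive part of a spline fit and
    the optimum drifts little between iterations. With too few distinct
    positions for a smoothing spline the coordinates pass through
    unchanged.
    """
    uniq, inv = np.unique(lam, return_inverse=True)
    if uniq.size < 5:
        order = np.argsort(lam, kind="mergesort")
        return X[order], lam[order]
    Xu = np.zeros((uniq.size, X.shape[1]))
    counts = np.bincount(inv)
    for j in range(X.shape[1]):
        Xu[:, j] = np.bincount(inv, weights=X[:, j]) / counts
    if penalties[0] is None:
        penalties[0] = _select_penalty(uniq, Xu)
    out = np.empty_like(Xu)
    for j in range(X.shape[1]):
        try:
            out[:, j] = make_smoothing_spline(uniq, Xu[:, j], lam=penalties[0])(
                uniq
            )
        except Exception:  # ill-conditioned smoothing: keep coordinate as is
            out[:, j] = Xu[:, j]
    return out, uniq


_PENALTY_GRID = np.logspace(-6, 8, 15)


def _select_penalty(x: np.ndarray, Y: np.ndarray, n_folds: int = 3) -> float:
    """Cross-validated smoothing penalty shared by all curve coordinates.

    The CV error is pooled over coordinates: curve smoothness is a
    property of the curve, not of individual axes, and pooling keeps the
    selection stable when most retained components are noise. Interleaved
    folds along the curve keep held-out points inside the training range,
    so the spline is evaluated by interpolation rather than extrapolation.
    """
    best_lam, best_err = float(_PENALTY_GRID[-1]), np.inf
    idx = np.arange(x.size)
    for lam in _PENALTY_GRID[::-1]:  # smoothest first; ties prefer smooth
        err = 0.0
        for f in range(n_folds):
            test = idx[f::n_folds]
            train = np.setdiff1d(idx, test)
            if train.size < 5:
                return float(lam)
            for j in range(Y.shape[1]):
                spl = make_smoothing_spline(
                    x[train], Y[train, j], lam=float(lam)
                )
                err += float(((spl(x[test]) - Y[test, j]) ** 2).sum())
        if err < best_err:
            best_lam, best_err = float(lam), err
    return best_lam


def fit_principal_curve(
    points: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> PrincipalCurve:
    """Hastie-Stuetzle principal curve of a point cloud.

    Initialized on the first principal component; iterations alternate
    projecting points onto the current polyline and smoothing each
    coordinate against arc length with a cubic smoothing spline whose
    penalty is selected by cross-validation on the first pass and then
    held fixed. An iteration is only accepted if it does not increase
    the total squared projection distance, so the reported distance
    sequence is non-increasing by construction; stops when the relative
    improvement falls below ``tol`` or after ``max_iter`` iterations.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.unique(P, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct points")
    center = P.mean(axis=0)
    X = P - center
    # first principal component via SVD
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    lam = X @ vt[0]
    order = np.argsort(lam, kind="mergesort")
    vertices = center + np.outer(lam[order], vt[0])
    curve = PrincipalCurve(_dedup_vertices(vertices))
    _, d2 = curve.project(P)
    best = curve
    best_d = float(d2.sum())
    scale = float(((P - center) ** 2).sum())
    if best_d <= 1e-12 * max(scale, 1e-300):  # points already on a line
        return best
    penalties: list[float | None] = [None] * P.shape[1]
    for _ in range(max_iter):
        s, _ = best.project(P)
        coords, s_sorted = _smooth_coords(s, P, penalties)
        verts = _dedup_vertices(coords)
        if verts.shape[0] < 2:
            break
        cand = PrincipalCurve(verts)
        _, d2 = cand.project(P)
        d = float(d2.sum())
        if d > best_d:  # smoothing step worsened the fit: stop at the best
            break
        improved = best_d - d
        best, best_d = cand, d
        if best_d < 1e-12 or improved < tol * max(best_d, 1e-12):
            break
    return best


def _dedup_vertices(v: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices (zero-length segments)."""
    if v.shape[0] < 2:
        return v
    keep = np.ones(v.shape[0], dtype=bool)
    keep[1:] = (np.diff(v, axis=0) ** 2).sum(axis=1) > 0
    return v[keep]


@dataclass
class PathwayCurveModel:
    """Fitted per-pathway scorer: normalization, PCA, curve, orientation."""

    name: str
    genes: list[str]
    control_mean: pd.Series
    control_sd: pd.Series
    pca: PCA
    n_components: int
    curve: PrincipalCurve
    flipped: bool
    control_median: float

    def arc_positions(self, values: pd.DataFrame) -> np.ndarray:
        """Oriented arc-length position of each sample column."""
        sub = values.loc[self.genes]
        Z = sub.sub(self.control_mean, axis=0).div(self.control_sd, axis=0)
        Y = self.pca.transform(Z.to_numpy().T)[:, : self.n_components]
        s, _ = self.curve.project(Y)
        if self.flipped:
            s = self.curve.length - s
        return s

    def score(self, values: pd.DataFrame) -> np.ndarray:
        """PDS of each sample column of a genes x samples matrix."""
        s = self.arc_positions(values)
        return (s - self.control_median) / self.curve.length


@dataclass
class PdsResult:
    """Pathway x sample deregulation scores plus per-pathway metadata."""

    scores: pd.DataFrame
    models: dict[str, PathwayCurveModel]
    skipped: dict[str, str]


def _fit_pathway_model(
    dataset: ExpressionDataset,
    name: str,
    genes: list[str],
    var_fraction: float,
    max_components: int,
    max_iter: int,
    tol: float,
) -> PathwayCurveModel:
    # canonicalize gene and sample order so the fitted model (and hence
    # every PDS) is exactly invariant to input ordering
    Z = normalize_to_reference(dataset, sorted(genes))
    sample_order = sorted(dataset.samples)
    Z = Z[sample_order]
    used = list(Z.index)
    controls = sorted(dataset.control_samples)
    sub = dataset.values.loc[used]
    mu = sub[controls].mean(axis=1)
    sd = sub[controls].std(axis=1, ddof=1)
    Y_all = Z.to_numpy().T  # samples x genes
    n_max = min(max_components, min(Y_all.shape) - 1, len(used))
    pca = PCA(n_components=max(1, n_max))
    scores = pca.fit_transform(Y_all)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_fraction) + 1)
    n_comp = min(n_comp, scores.shape[1])
    Y = scores[:, :n_comp]
    curve = fit_principal_curve(Y, max_iter=max_iter, tol=tol)
    s, _ = curve.project(Y)
    sample_index = {smp: i for i, smp in enumerate(sample_order)}
    s_ctrl = s[[sample_index[c] for c in controls]]
    s_case = s[[sample_index[c] for c in dataset.case_samples]]
    flipped = bool(np.median(s_ctrl) > np.median(s_case))
    model = PathwayCurveModel(
        name=name,
        genes=used,
        control_mean=mu,
        control_sd=sd,
        pca=pca,
        n_components=n_comp,
        curve=curve,
        flipped=flipped,
        control_median=0.0,
    )
    # centre at the control median measured through the scoring path, so
    # the control median PDS is exactly zero for the fitted data
    arc = model.arc_positions(dataset.values[sample_order])
    model.control_median = float(
        np.median(arc[[sample_index[c] for c in controls]])
    )
    return model


def compute_pds(
    dataset: ExpressionDataset,
    pathways: GeneSetCollection,
    var_fraction: float = DEFAULT_VAR_FRACTION,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> PdsResult:
    """Pathway deregulation score of every sample for every pathway.

    Pathways that cannot be scored (too few usable genes, degenerate
    geometry) are skipped with a logged reason rather than aborting the
    whole matrix.
    """
    dataset.require_two_classes()
    rows = {}
    models: dict[str, PathwayCurveModel] = {}
    skipped: dict[str, str] = {}
    for gs in pathways:
        try:
            model = _fit_pathway_model(
                dataset, gs.name, gs.genes, var_fraction, max_components,
                max_iter, tol,
            )
        except ValueError as exc:
            logger.warning("skipping pathway %s: %s", gs.name, exc)
            skipped[gs.name] = str(exc)
            continue
        models[gs.name] = model
        rows[gs.name] = model.score(dataset.values)
    if not rows:
        raise ValueError("no pathway could be scored")
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=dataset.samples)
    return PdsResult(scores, models, skipped)
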