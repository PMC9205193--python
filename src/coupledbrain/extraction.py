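"""Network and ROI feature extraction from subjects x voxels gray-matter maps.

The pipeline mirrors source-based morphometry: estimate the number of
components with an eigenvalue-based minimum-description-length (MDL)
criterion, decompose the data with spatial ICA into a mixing matrix (subjects
x components) and source maps (components x voxels), keep the components
whose mixing coefficients differ between groups (two-sample t-test, Bonferroni
corrected), binarize each retained z-scored source map at Z >= 3 to obtain a
network mask, rank the atlas regions inside the mask by overlap size, and
finally average the gray-matter values over mask voxels (network feature) and
over each region-within-mask (ROI feature).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ConvergenceError, DegenerateInputError, ValidationError
from .tables import FeatureTable, NetworkFeatureTable

__all__ = [
    "DecompositionResult",
    "NetworkMask",
    "estimate_component_count",
    "decompose_components",
    "select_discriminative_components",
    "binarize_component_map",
    "select_top_rois",
    "compute_original_features",
    "extract_features",
]

logger = logging.getLogger(__name__)

_ICA_TOL = 1e-6
_ICA_MAX_ITER = 1000
_ICA_MAX_RESTARTS = 5


@dataclass
class DecompositionResult:
    """Spatial ICA factorization ``X_centered ~= mixing @ sources``.

    ``mixing`` is subjects x K (column = subjects' loadings on one component);
    ``sources`` is K x voxels with each row z-scored across voxels and its
    sign fixed so the row skewness is nonnegative.
    """

    mixing: np.ndarray
    sources: np.ndarray

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


@dataclass
class NetworkMask:
    """Binary voxel mask of one network plus its member atlas regions."""

    component: int
    mask: np.ndarray  # boolean, length = voxels
    roi_ids: list[int]  # descending in-mask voxel count, ties ascending id
    roi_voxel_counts: list[int]


def estimate_component_count(X: np.ndarray) -> int:
    """Estimate the number of signal components by the MDL criterion.

    Treats the ``V`` voxels as observations of an ``M``-dimensional variable
    and applies the classic eigenvalue-based MDL order estimator to the
    spectrum of the subjects x subjects covariance: for each candidate order
    ``k`` the criterion trades the log-likelihood of "the smallest ``M - k``
    eigenvalues are equal" (the ratio of their geometric to arithmetic mean)
    against a parameter-count penalty, and the minimizing ``k`` is returned,
    clamped to ``1 <= K < M``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("need a 2-D matrix with at least 3 subjects")
    m, v = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = (Xc @ Xc.T) / v
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    if eigvals[0] <= 0:
        raise DegenerateInputError("constant input: covariance has no positive eigenvalue")
    if eigvals[-1] <= 1e-12 * eigvals[0]:
        raise DegenerateInputError(
            "rank-deficient input: smallest covariance eigenvalue is (numerically) zero"
        )
    log_eig = np.log(eigvals)
    mdl = np.empty(m)  # index k = number of signal components
    for k in range(m):
        tail = eigvals[k:]
        log_geo = log_eig[k:].mean()
        log_arith = np.log(tail.mean())
        # -2 log likelihood-ratio term + MDL penalty
        mdl[k] = -v * (m - k) * (log_geo - log_arith) + 0.5 * k * (2 * m - k + 1) * np.log(v)
    best = int(np.argmin(mdl[: m - 1]))
    return max(best, 1)


def decompose_components(X: np.ndarray, n_components: int, seed: int) -> DecompositionResult:
    """Spatial ICA: independent source maps over voxels.

    Fixed-point (FastICA) estimation with logcosh negentropy contrast and PCA
    whitening to ``n_components``; deterministic for a given ``seed``, with up
    to ``5`` re-seeded restarts on non-convergence.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 1 <= n_components < m:
        raise ValidationError(f"n_components must be in [1, {m - 1}], got {n_components}")
    seeds = np.random.SeedSequence(seed).generate_state(_ICA_MAX_RESTARTS + 1) % (2**31)
    last_warning: str | None = None
    for attempt, sub_seed in enumerate(seeds):
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            tol=_ICA_TOL,
            max_iter=_ICA_MAX_ITER,
            random_state=int(sub_seed),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            voxel_sources = ica.fit_transform(X.T)  # (V, K)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            break
        last_warning = str(caught[-1].message)
        logger.info("ICA restart %d after non-convergence", attempt + 1)
    else:
        raise ConvergenceError(
            f"ICA did not converge in {_ICA_MAX_ITER} iterations (tol={_ICA_TOL}) "
            f"after {_ICA_MAX_RESTARTS} restarts: {last_warning}",
            max_iter=_ICA_MAX_ITER,
            tol=_ICA_TOL,
        )
    sources = voxel_sources.T  # (K, V)
    mixing = np.asarray(ica.mixing_)  # (M, K)

    # z-score source rows, push the scale into the mixing columns, fix signs
    mu = sources.mean(axis=1, keepdims=True)
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources = (sources - mu) / sd
    mixing = mixing * sd.ravel()
    signs = np.where(stats.skew(sources, axis=1) < 0, -1.0, 1.0)
    sources *= signs[:, None]
    mixing *= signs
    return DecompositionResult(mixing=mixing, sources=sources)


def select_discriminative_components(
    mixing: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> list[int]:
    """Indices of components whose mixing coefficients separate the groups.

    Two-sided two-sample t-test per mixing column with a Bonferroni-corrected
    threshold ``alpha / K``; original component order is preserved.
    """
    mixing = np.asarray(mixing, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValidationError(f"need exactly two groups, got {groups.tolist()}")
    a = mixing[labels == groups[0]]
    b = mixing[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    k = mixing.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(a, b, axis=0)
    pvals = np.asarray(result.pvalue)
    if np.isnan(pvals).any():
        bad = np.flatnonzero(np.isnan(pvals)).tolist()
        raise DegenerateInputError(
            f"t-statistic undefined (zero within-group variance) for components {bad}"
        )
    return [int(i) for i in np.flatnonzero(pvals < alpha / k)]


def binarize_component_map(source_row: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of voxels whose z-scored source value is >= ``z_threshold``."""
    source_row = np.asarray(source_row, dtype=float)
    mask = source_row >= z_threshold
    if not mask.any():
        raise DegenerateInputError(
            f"empty mask: no voxel reaches Z >= {z_threshold} in this component map"
        )
    return mask


def select_top_rois(
    mask: np.ndarray, atlas: np.ndarray, k: int = 3
) -> tuple[list[int], list[int]]:
    """The ``k`` atlas regions with the largest overlap with ``mask``.

    Regions are ranked by in-mask voxel count, descending; ties broken by
    ascending region id.  Returns ``(roi_ids, voxel_counts)``; fewer than
    ``k`` overlapping regions yields a shorter list and a logged warning.
    """
    mask = np.asarray(mask, dtype=bool)
    atlas = np.asarray(atlas)
    if mask.shape != atlas.shape:
        raise ValidationError(
            f"atlas length {atlas.shape} does not match mask length {mask.shape}"
        )
    region_ids, inverse = np.unique(atlas, return_inverse=True)
    counts = np.bincount(inverse[mask], minlength=region_ids.size)
    nonzero = np.flatnonzero(counts > 0)
    # stable sort on ascending id, then stable sort on descending count
    order = nonzero[np.argsort(-counts[nonzero], kind="stable")]
    if order.size < k:
        logger.warning(
            "only %d atlas regions overlap the mask (requested %d)", order.size, k
        )
    chosen = order[:k]
    return [int(region_ids[i]) for i in chosen], [int(counts[i]) for i in chosen]


def compute_original_features(
    X: np.ndarray, networks: list[NetworkMask], atlas: np.ndarray, labels: np.ndarray
) -> tuple[FeatureTable, NetworkFeatureTable]:
    """Average gray-matter values into ROI-level and network-level features.

    The ROI feature for region *r* of network *l* is the mean of ``X`` over
    the voxels in ``region r ∩ mask(l)``; the network feature is the mean over
    all mask voxels.
    """
    X = np.asarray(X, dtype=float)
    atlas = np.asarray(atlas)
    if not networks:
        raise ValidationError("need at least one network mask")
    n_per = {len(net.roi_ids) for net in networks}
    if len(n_per) != 1 or 0 in n_per:
        raise ValidationError(
            f"all networks must have the same nonzero ROI count, got {sorted(n_per)}"
        )
    roi_cols, net_cols, network_map, feature_ids = [], [], [], []
    for l, net in enumerate(networks, start=1):
        net_cols.append(X[:, net.mask].mean(axis=1))
        for roi in net.roi_ids:
            vox = net.mask & (atlas == roi)
            if not vox.any():
                raise ValidationError(
                    f"network {net.component}: ROI {roi} has no voxels inside the mask"
                )
            roi_cols.append(X[:, vox].mean(axis=1))
            network_map.append(l)
            feature_ids.append(f"net{l}_roi{roi}")
    table = FeatureTable(
        values=np.column_stack(roi_cols),
        network_map=np.array(network_map),
        labels=labels,
        feature_ids=feature_ids,
    )
    net_table = NetworkFeatureTable(values=np.column_stack(net_cols))
    return table, net_table


def extract_features(
    X: np.ndarray,
    atlas: np.ndarray,
    labels: np.ndarray,
    seed: int,
    *,
    n_components: int | None = None,
    alpha: float = 0.05,
    z_threshold: float = 3.0,
    top_k: int = 3,
) -> tuple[FeatureTable, NetworkFeatureTable, list[NetworkMask]]:
    """Full extraction pipeline: MDL -> ICA -> group test -> masks -> features."""
    if n_components is None:
        n_components = estimate_component_count(X)
    decomp = decompose_components(X, n_components, seed)
    selected = select_discriminative_components(decomp.mixing, labels, alpha)
    if not selected:
        raise DegenerateInputError("no component shows a significant group difference")
    networks = []
    for comp in selected:
        mask = binarize_component_map(decomp.sources[comp], z_threshold)
        roi_ids, counts = select_top_rois(mask, atlas, top_k)
        networks.append(
            NetworkMask(component=comp, mask=mask, roi_ids=roi_ids, roi_voxel_counts=counts)
        )
    table, net_table = compute_original_features(X, networks, atlas, labels)
    return table, net_table, networks
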