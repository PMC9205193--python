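"""Intra-network coupled representation of ROI-level features.

Within each brain network the ROI features are power-expanded up to order E1,
every pair of expanded columns is correlated (Pearson r, revised to exactly 0
when its two-sided p-value exceeds alpha — only statistically supported
couplings are kept), and each subject's expanded vector is re-weighted by the
coupling matrices under Taylor-like damping weights omega = (1/1!, ..., 1/E1!).

For feature k of a network with n ROIs the coupled vector is

    u(k) = (x_own  * omega) @ R_intra(k).T  +  (x_other * [omega]*(n-1)) @ R_inter(k).T

where ``x_own`` holds the E1 powers of feature k, ``x_other`` the E1 powers of
the other n-1 features (feature-major order), ``R_intra(k)`` the revised
correlations between k's own powers and ``R_inter(k)`` those between k's
powers and the other features' powers.  Concatenating u(k) over k gives the
network block; concatenating blocks over networks gives the intra-coupled
design matrix U (no coupling is ever computed across networks).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ValidationError
from .tables import FeatureTable

__all__ = [
    "ScalingParams",
    "ExpandedBlock",
    "CouplingWeights",
    "IntraRepresentation",
    "taylor_weights",
    "scale_features",
    "apply_scaling",
    "expand_block",
    "compute_coupling_weights",
    "couple_block",
    "build_intra_representation",
]


def taylor_weights(order: int) -> np.ndarray:
    """Damping weights ``(1/1!, 1/2!, ..., 1/order!)``."""
    return np.array([1.0 / math.factorial(e) for e in range(1, order + 1)])


#: Default min-max target range.  [-1, 1] rather than [0, 1]: a feature scaled
#: to a range symmetric about zero is nearly uncorrelated with its own square,
#: so the power expansion contributes genuinely new directions; powers of a
#: [0, 1]-scaled feature are ~0.97 collinear with the feature itself and the
#: curvature information is numerically buried.
FEATURE_RANGE: tuple[float, float] = (-1.0, 1.0)


@dataclass
class ScalingParams:
    """Per-feature min-max parameters estimated on the fitting rows."""

    minimum: np.ndarray
    span: np.ndarray  # max - min; 0 flags a constant feature (mapped to midpoint)
    feature_range: tuple[float, float] = FEATURE_RANGE


@dataclass
class ExpandedBlock:
    """Power expansion of one network's ROI columns.

    ``values`` is ``(M, n*E1)`` with feature-major, power-minor column order:
    columns ``k*E1 + (e-1)`` hold feature k (0-based) raised to power e.
    """

    network: int
    n_features: int
    order: int
    values: np.ndarray


@dataclass
class CouplingWeights:
    """Revised-correlation weight matrices for one network block.

    ``intra[k]`` is ``(E1, E1)``: correlations among feature k's own powers
    (unit diagonal).  ``inter[k]`` is ``(E1, E1*(n-1))``: correlations between
    feature k's powers (rows) and the powers of every other feature, in
    ascending feature order (columns).  Entries with p > alpha are exactly 0.
    """

    network: int
    n_features: int
    order: int
    intra: list[np.ndarray]
    inter: list[np.ndarray]
    alpha: float

    @property
    def omega(self) -> np.ndarray:
        return taylor_weights(self.order)


@dataclass
class IntraRepresentation:
    """Column-concatenation of all networks' coupled blocks.

    ``block_slices[l]`` gives network l's columns inside ``values``; column
    names follow ``net{l}_roi{k}_p{e}``.
    """

    values: np.ndarray
    block_slices: dict[int, slice]
    order: int
    column_names: list[str]


# ---------------------------------------------------------------------------
# scaling


def scale_features(
    table: FeatureTable,
    fit_rows: np.ndarray | None = None,
    feature_range: tuple[float, float] = FEATURE_RANGE,
) -> tuple[FeatureTable, ScalingParams]:
    """Min-max scale every feature column to ``feature_range``.

    Parameters are estimated on ``fit_rows`` only (all rows when ``None``) and
    applied to every row; held-out values may fall outside the range and are
    not clipped.  Constant features map to the range midpoint with a warning.
    """
    rows = np.arange(table.n_subjects) if fit_rows is None else np.asarray(fit_rows)
    if rows.size == 0:
        raise ValidationError("fit_rows must be nonempty")
    params = fit_scaling(table.values, rows, feature_range)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns stay constant (midpoint)
        scaled = replace(table, values=apply_scaling(table.values, params))
    return scaled, params


def fit_scaling(
    values: np.ndarray,
    fit_rows: np.ndarray,
    feature_range: tuple[float, float] = FEATURE_RANGE,
) -> ScalingParams:
    sub = values[fit_rows]
    lo = sub.min(axis=0)
    span = sub.max(axis=0) - lo
    if np.any(span == 0):
        warnings.warn("constant feature column(s) under min-max scaling; mapped to midpoint")
    return ScalingParams(minimum=lo, span=span, feature_range=feature_range)


def apply_scaling(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    a, b = params.feature_range
    span = np.where(params.span == 0, 1.0, params.span)
    out = a + (b - a) * (values - params.minimum) / span
    out[:, params.span == 0] = 0.5 * (a + b)
    return out


# ---------------------------------------------------------------------------
# expansion and coupling


def expand_block(block: np.ndarray, order: int, network: int = 1) -> ExpandedBlock:
    """Elementwise powers 1..order of each column, feature-major order."""
    if order < 1:
        raise ValidationError(f"expansion order must be >= 1, got {order}")
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValidationError("block must be 2-D (subjects x features)")
    m, n = block.shape
    powers = block[:, :, None] ** np.arange(1, order + 1)  # (M, n, E1)
    return ExpandedBlock(
        network=network, n_features=n, order=order, values=powers.reshape(m, n * order)
    )


def _revised_correlations(values: np.ndarray, alpha: float) -> np.ndarray:
    """Pearson correlations among columns, zeroed where p > alpha.

    p-values come from the exact t-transform ``t = r * sqrt((M-2)/(1-r^2))``
    with M-2 degrees of freedom, two-sided.  Zero-variance columns get zero
    correlation with everything (warning); the diagonal is exactly 1.
    """
    m = values.shape[0]
    if m < 4:
        raise ValidationError(f"need at least 4 rows for coupling weights, got {m}")
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance expanded column(s); "
                      "their coupling weights are set to 0")
    safe = values.copy()
    safe[:, degenerate] = np.random.default_rng(0).standard_normal(m)[:, None]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(safe, rowvar=False)
    corr = np.clip(np.nan_to_num(corr), -1.0, 1.0)
    r2 = np.minimum(corr**2, 1.0 - 1e-15)
    t = np.abs(corr) * np.sqrt((m - 2) / (1.0 - r2))
    pvals = 2.0 * stats.t.sf(t, df=m - 2)
    corr[pvals > alpha] = 0.0
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def compute_coupling_weights(expanded: ExpandedBlock, alpha: float = 0.05) -> CouplingWeights:
    """Revised-Pearson coupling matrices for one expanded network block."""
    n, e1 = expanded.n_features, expanded.order
    corr = _revised_correlations(expanded.values, alpha)
    intra, inter = [], []
    for k in range(n):
        own = slice(k * e1, (k + 1) * e1)
        others = np.concatenate(
            [np.arange(t * e1, (t + 1) * e1) for t in range(n) if t != k]
        ) if n > 1 else np.array([], dtype=int)
        intra.append(corr[own, own].copy())
        inter.append(corr[own, :][:, others].copy())
    return CouplingWeights(
        network=expanded.network, n_features=n, order=e1, intra=intra, inter=inter,
        alpha=alpha,
    )


def couple_block(expanded: ExpandedBlock, weights: CouplingWeights) -> np.ndarray:
    """Taylor-weighted coupled block ``(M, n*E1)`` for one network."""
    n, e1 = expanded.n_features, expanded.order
    if (weights.n_features, weights.order) != (n, e1):
        raise ValidationError(
            f"weights built for (n={weights.n_features}, E1={weights.order}) do not "
            f"match block (n={n}, E1={e1})"
        )
    omega = weights.omega
    omega_rep = np.tile(omega, max(n - 1, 0))
    z = expanded.values
    out = np.empty_like(z)
    for k in range(n):
        own = slice(k * e1, (k + 1) * e1)
        others = np.concatenate(
            [np.arange(t * e1, (t + 1) * e1) for t in range(n) if t != k]
        ) if n > 1 else np.array([], dtype=int)
        u_k = (z[:, own] * omega) @ weights.intra[k].T
        if others.size:
            u_k = u_k + (z[:, others] * omega_rep) @ weights.inter[k].T
        out[:, own] = u_k
    return out


def build_intra_representation(
    table: FeatureTable,
    order: int,
    fit_rows: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
    scale: bool = True,
) -> IntraRepresentation:
    """Scale, expand, weight and couple every network block; concatenate.

    Coupling weights (and scaling parameters) are estimated on ``fit_rows``
    only and applied to all rows.  ``order == 1`` short-circuits to the scaled
    original features — the representation without coupled interaction
    analysis.
    """
    if order < 1:
        raise ValidationError(f"expansion order must be >= 1, got {order}")
    rows = np.arange(table.n_subjects) if fit_rows is None else np.asarray(fit_rows)
    work = scale_features(table, rows)[0] if scale else table
    blocks, slices, names = [], {}, []
    start = 0
    for l in range(1, table.n_networks + 1):
        cols = table.network_columns(l)
        block = work.values[:, cols]
        if order == 1:
            coupled = block
        else:
            expanded = expand_block(block, order, network=l)
            fit_expanded = replace(expanded, values=expanded.values[rows])
            weights = compute_coupling_weights(fit_expanded, alpha)
            coupled = couple_block(expanded, weights)
        blocks.append(coupled)
        slices[l] = slice(start, start + coupled.shape[1])
        start += coupled.shape[1]
        for k in range(1, cols.size + 1):
            names.extend(f"net{l}_roi{k}_p{e}" for e in range(1, order + 1))
    return IntraRepresentation(
        values=np.hstack(blocks), block_slices=slices, order=order, column_names=names
    )
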