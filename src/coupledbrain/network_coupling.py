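"""Inter-network coupled representation via pairwise canonical correlations.

Networks interact through their ROI blocks: for every unordered pair of
networks, canonical correlation analysis (CCA) of the two blocks yields a
descending spectrum of canonical correlations, of which the top E2 are
retained (zero-padded when fewer exist).  The inter-coupled feature of
subject i for network l sums, over the other networks l', the powers 1..E2 of
the scaled network-level feature v_{i,l'} damped by 1/e! and weighted by the
e-th retained canonical correlation of the (l, l') pair:

    f_i(l) = sum_{l' != l} sum_{e=1..E2} (1/e!) * v_{i,l'}^e * rho_e(l, l')

The module also assembles the four benchmark design matrices: the original
ROI features (OFM_ROI), the original network features (OFM_network), the
whole-brain ROI coupling that ignores network structure (CFM_ROI), and the
two-level coupled matrix [U, f] (CFM_network).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .errors import ValidationError
from .roi_coupling import (
    IntraRepresentation,
    build_intra_representation,
    scale_features,
    taylor_weights,
)
from .tables import FeatureTable, NetworkFeatureTable

__all__ = [
    "CCAResult",
    "InterRepresentation",
    "AssembledDesign",
    "DESIGN_KINDS",
    "pairwise_cca",
    "build_inter_representation",
    "assemble",
    "build_design",
]

logger = logging.getLogger(__name__)

DESIGN_KINDS = ("OFM_ROI", "OFM_network", "CFM_ROI", "CFM_network")

_RIDGE = 1e-8


@dataclass
class CCAResult:
    """Canonical correlations between two networks' ROI blocks.

    ``correlations`` is descending in [0, 1], length ``min(n1, n2)``;
    ``retained`` holds the top E2 values, zero-padded when the spectrum is
    shorter than E2.  Symmetric in the pair order.
    """

    pair: tuple[int, int]
    correlations: np.ndarray
    retained: np.ndarray


@dataclass
class InterRepresentation:
    """Inter-coupled network features ``f`` (``(M, L)``) with its E2 and omega."""

    values: np.ndarray
    order: int

    @property
    def omega(self) -> np.ndarray:
        return taylor_weights(self.order)


@dataclass
class AssembledDesign:
    """A design matrix plus the block structure the boosted classifier uses.

    ``blocks`` maps a block name to a column slice: one block per network plus
    an ``"inter"`` block for CFM_network; a single ``"all"`` block otherwise.
    """

    kind: str
    matrix: np.ndarray
    blocks: dict[str, slice]
    column_names: list[str]


def _inv_sqrt(cov: np.ndarray, ridge: float) -> np.ndarray:
    cov = cov + ridge * np.eye(cov.shape[0])
    vals, vecs = linalg.eigh(cov)
    vals = np.maximum(vals, ridge)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def pairwise_cca(
    block1: np.ndarray, block2: np.ndarray, pair: tuple[int, int] = (1, 2)
) -> CCAResult:
    """Canonical correlations of two feature blocks observed on the same rows.

    Computed as the singular values of the whitened cross-covariance
    ``C11^{-1/2} C12 C22^{-1/2}`` with a ridge of 1e-8 on each within-block
    covariance; values clipped to [0, 1], descending.
    """
    b1 = np.asarray(block1, dtype=float)
    b2 = np.asarray(block2, dtype=float)
    if b1.ndim != 2 or b2.ndim != 2 or b1.shape[0] != b2.shape[0]:
        raise ValidationError("blocks must be 2-D with equal row counts")
    m = b1.shape[0]
    if m <= max(b1.shape[1], b2.shape[1]) + 1:
        raise ValidationError(
            f"{m} samples are too few for CCA on blocks of width "
            f"{b1.shape[1]} and {b2.shape[1]}; provide more samples"
        )
    b1 = b1 - b1.mean(axis=0)
    b2 = b2 - b2.mean(axis=0)
    c11 = (b1.T @ b1) / (m - 1)
    c22 = (b2.T @ b2) / (m - 1)
    c12 = (b1.T @ b2) / (m - 1)
    k = _inv_sqrt(c11, _RIDGE) @ c12 @ _inv_sqrt(c22, _RIDGE)
    sv = linalg.svd(k, compute_uv=False)
    correlations = np.clip(np.sort(sv)[::-1], 0.0, 1.0)
    return CCAResult(pair=pair, correlations=correlations, retained=correlations)


def _retain(result: CCAResult, order: int) -> np.ndarray:
    rho = result.correlations
    out = np.zeros(order)
    out[: min(order, rho.size)] = rho[:order]
    return out


def build_inter_representation(
    table: FeatureTable,
    net_table: NetworkFeatureTable,
    order: int,
    fit_rows: np.ndarray | None = None,
    *,
    scale: bool = True,
) -> InterRepresentation:
    """Inter-coupled network feature matrix ``f`` (``(M, L)``).

    CCA is fitted on ``fit_rows`` for every unordered network pair; network-
    level features are min-max scaled with parameters from ``fit_rows``.
    """
    if order < 1:
        raise ValidationError(f"E2 must be >= 1, got {order}")
    L = table.n_networks
    if L < 2:
        raise ValidationError("need at least 2 networks for inter-coupling")
    m = table.n_subjects
    rows = np.arange(m) if fit_rows is None else np.asarray(fit_rows)
    scaled = scale_features(table, rows)[0] if scale else table
    if scale:
        from .roi_coupling import apply_scaling, fit_scaling

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = apply_scaling(net_table.values, fit_scaling(net_table.values, rows))
    else:
        v = net_table.values

    retained: dict[tuple[int, int], np.ndarray] = {}
    padded = False
    for l1 in range(1, L + 1):
        for l2 in range(l1 + 1, L + 1):
            res = pairwise_cca(
                scaled.network_block(l1)[rows], scaled.network_block(l2)[rows],
                pair=(l1, l2),
            )
            padded = padded or order > res.correlations.size
            w = _retain(res, order)
            retained[(l1, l2)] = w
            retained[(l2, l1)] = w
    if padded:
        warnings.warn(
            f"E2={order} exceeds the available canonical correlations for some "
            "network pairs; missing positions are zero-padded"
        )

    omega = taylor_weights(order)
    powers = v[:, :, None] ** np.arange(1, order + 1)  # (M, L, E2)
    f = np.zeros((m, L))
    for l in range(1, L + 1):
        for lp in range(1, L + 1):
            if lp == l:
                continue
            f[:, l - 1] += powers[:, lp - 1, :] @ (omega * retained[(l, lp)])
    return InterRepresentation(values=f, order=order)


def assemble(
    kind: str,
    *,
    intra: IntraRepresentation | None = None,
    inter: InterRepresentation | None = None,
    table: FeatureTable | None = None,
    net_table: NetworkFeatureTable | None = None,
    fit_rows: np.ndarray | None = None,
    scale: bool = True,
) -> AssembledDesign:
    """Assemble one of the four benchmark design matrices.

    OFM_ROI / OFM_network are the scaled original tables; CFM_ROI is the
    intra-coupling of all ROI features treated as one whole-brain block;
    CFM_network is ``[U, f]`` with per-network blocks plus the inter block.
    """
    if kind not in DESIGN_KINDS:
        raise ValidationError(f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}")
    if kind == "OFM_ROI":
        if table is None:
            raise ValidationError("OFM_ROI requires the ROI feature table")
        rows = np.arange(table.n_subjects) if fit_rows is None else np.asarray(fit_rows)
        scaled = scale_features(table, rows)[0] if scale else table
        return AssembledDesign(
            kind=kind,
            matrix=scaled.values.copy(),
            blocks={"all": slice(0, table.n_features)},
            column_names=list(table.feature_ids),
        )
    if kind == "OFM_network":
        if net_table is None:
            raise ValidationError("OFM_network requires the network feature table")
        m = net_table.n_subjects
        rows = np.arange(m) if fit_rows is None else np.asarray(fit_rows)
        if scale:
            from .roi_coupling import apply_scaling, fit_scaling

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = apply_scaling(net_table.values, fit_scaling(net_table.values, rows))
        else:
            vals = net_table.values.copy()
        return AssembledDesign(
            kind=kind,
            matrix=vals,
            blocks={"all": slice(0, net_table.n_networks)},
            column_names=[f"net{l}" for l in net_table.network_ids],
        )
    if kind == "CFM_ROI":
        if intra is None:
            raise ValidationError("CFM_ROI requires a whole-brain intra representation")
        return AssembledDesign(
            kind=kind,
            matrix=intra.values.copy(),
            blocks={"all": slice(0, intra.values.shape[1])},
            column_names=list(intra.column_names),
        )
    # CFM_network
    if intra is None or inter is None:
        raise ValidationError("CFM_network requires both intra (U) and inter (f) parts")
    if intra.values.shape[0] != inter.values.shape[0]:
        raise ValidationError("U and f row counts differ")
    u_width = intra.values.shape[1]
    blocks = {f"net{l}": s for l, s in intra.block_slices.items()}
    blocks["inter"] = slice(u_width, u_width + inter.values.shape[1])
    names = list(intra.column_names) + [
        f"inter_net{j}" for j in range(1, inter.values.shape[1] + 1)
    ]
    return AssembledDesign(
        kind=kind,
        matrix=np.hstack([intra.values, inter.values]),
        blocks=blocks,
        column_names=names,
    )


def build_design(
    kind: str,
    table: FeatureTable,
    net_table: NetworkFeatureTable,
    *,
    e1: int = 3,
    e2: int = 2,
    fit_rows: np.ndarray | None = None,
    alpha: float = 0.05,
    scale: bool = True,
) -> AssembledDesign:
    """One-call construction of any of the four designs from the raw tables."""
    if kind == "OFM_ROI":
        return assemble(kind, table=table, fit_rows=fit_rows, scale=scale)
    if kind == "OFM_network":
        return assemble(kind, net_table=net_table, fit_rows=fit_rows, scale=scale)
    if kind == "CFM_ROI":
        flat = replace(table, network_map=np.ones(table.n_features, dtype=int))
        intra = build_intra_representation(flat, e1, fit_rows, alpha=alpha, scale=scale)
        return assemble(kind, intra=intra)
    if kind == "CFM_network":
        intra = build_intra_representation(table, e1, fit_rows, alpha=alpha, scale=scale)
        inter = build_inter_representation(table, net_table, e2, fit_rows, scale=scale)
        return assemble(kind, intra=intra, inter=inter)
    raise ValidationError(f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}")
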