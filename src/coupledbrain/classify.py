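"""Block-wise boosted linear-SVM classification and cross-validated evaluation.

The ensemble runs one AdaBoost pass over the design matrix's feature blocks in
a fixed order (networks ascending, inter block last): at each step a
sample-weighted linear SVM is fitted on that block's columns only, its
weighted training error epsilon sets the vote weight
alpha = 0.5 * ln((1 - epsilon) / epsilon) (0 when epsilon >= 0.5), and the
sample weights are re-normalized with misclassified subjects up-weighted.
For the two-level coupled design this yields L + 1 base learners — one per
network's intra-coupled block plus one for the inter-coupled block.

Evaluation is stratified 10-fold cross-validation in which scaling, coupling
weights, CCA spectra and the ensemble are all fitted on the training rows of
each fold only (a ``transductive`` switch reproduces whole-dataset fitting);
the grid search sweeps the expansion order E1 over {2, 3, 4} and the retained
canonical-correlation count E2 over {1, ..., 5}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError
from .network_coupling import DESIGN_KINDS, AssembledDesign, build_design
from .tables import FeatureTable, NetworkFeatureTable

__all__ = [
    "BaseLearner",
    "BoostedEnsemble",
    "MetricSet",
    "GridResult",
    "train_block_boosted_svm",
    "predict",
    "compute_metrics",
    "evaluate_cv",
    "grid_search",
    "vote_weight",
]

logger = logging.getLogger(__name__)

_EPS_CLIP = 1e-10

E1_GRID_DEFAULT = (2, 3, 4)
E2_GRID_DEFAULT = (1, 2, 3, 4, 5)


@dataclass
class BaseLearner:
    block: str
    columns: slice
    model: SVC
    alpha: float
    train_error: float


@dataclass
class BoostedEnsemble:
    """Ordered base learners plus the AdaBoost sample-weight history."""

    learners: list[BaseLearner]
    classes: tuple
    positive_label: object
    weight_history: np.ndarray  # (rounds*blocks + 1, M)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([lrn.alpha for lrn in self.learners])


@dataclass
class MetricSet:
    """Accuracy / sensitivity / specificity as proportions, plus per-fold detail."""

    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        return {
            "ACC (%)": 100 * self.accuracy,
            "SEN (%)": 100 * self.sensitivity,
            "SPE (%)": 100 * self.specificity,
        }


@dataclass
class GridResult:
    """Cross-validated metrics for every (kind, E1, E2) cell."""

    cells: dict[tuple[str, int | None, int | None], MetricSet]
    best: tuple[str, int | None, int | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (kind, e1, e2), ms in self.cells.items():
            rows.append(
                {"kind": kind, "E1": e1, "E2": e2, **ms.as_percent(),
                 "best": (kind, e1, e2) == self.best}
            )
        return pd.DataFrame(rows)


def _signed(y: np.ndarray, positive_label) -> np.ndarray:
    return np.where(np.asarray(y) == positive_label, 1.0, -1.0)


def vote_weight(error: float) -> float:
    """AdaBoost vote weight ``0.5 * ln((1 - eps) / eps)``; 0 for eps >= 0.5."""
    eps = float(np.clip(error, _EPS_CLIP, 1 - _EPS_CLIP))
    return 0.5 * float(np.log((1 - eps) / eps)) if eps < 0.5 else 0.0


def train_block_boosted_svm(
    design: AssembledDesign,
    labels: np.ndarray,
    positive_label,
    *,
    C: float = 1.0,
    rounds: int = 1,
) -> BoostedEnsemble:
    """One (or more) sequential AdaBoost pass(es) over the design's blocks."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, got {classes.tolist()}")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValidationError("need at least 2 subjects per class")
    x = design.matrix
    m = x.shape[0]
    ysig = _signed(y, positive_label)
    w = np.full(m, 1.0 / m)
    history = [w.copy()]
    learners: list[BaseLearner] = []
    def _order(name: str) -> tuple:
        # networks in ascending numeric order, the inter block last
        return (name == "inter", int(name[3:]) if name.startswith("net") else 0, name)

    block_order = sorted(design.blocks, key=_order)
    for _ in range(rounds):
        for name in block_order:
            cols = design.blocks[name]
            svm = SVC(kernel="linear", C=C)
            svm.fit(x[:, cols], ysig, sample_weight=w)
            pred = svm.predict(x[:, cols])
            miss = pred != ysig
            eps = float(np.clip(w[miss].sum(), _EPS_CLIP, 1 - _EPS_CLIP))
            alpha = vote_weight(eps)
            learners.append(
                BaseLearner(block=name, columns=cols, model=svm, alpha=alpha,
                            train_error=eps)
            )
            w = w * np.exp(alpha * miss)
            w = w / w.sum()
            history.append(w.copy())
    return BoostedEnsemble(
        learners=learners,
        classes=tuple(classes),
        positive_label=positive_label,
        weight_history=np.array(history),
    )


def predict(ensemble: BoostedEnsemble, design: AssembledDesign) -> np.ndarray:
    """Weighted-vote prediction; a score of exactly 0 goes to the positive class."""
    names = {lrn.block for lrn in ensemble.learners}
    if not names.issubset(design.blocks):
        raise ValidationError(
            f"design blocks {sorted(design.blocks)} do not cover ensemble blocks "
            f"{sorted(names)}"
        )
    x = design.matrix
    score = np.zeros(x.shape[0])
    for lrn in ensemble.learners:
        if lrn.alpha == 0.0:
            continue
        score += lrn.alpha * lrn.model.predict(x[:, design.blocks[lrn.block]])
    if not np.any(ensemble.alphas > 0):
        warnings.warn("all vote weights are zero; predicting the positive class")
    positive, = [c for c in ensemble.classes if c == ensemble.positive_label]
    negative, = [c for c in ensemble.classes if c != ensemble.positive_label]
    return np.where(score >= 0, positive, negative)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive_label) -> MetricSet:
    """Accuracy, sensitivity (patient recall) and specificity (control recall)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    pos = y_true == positive_label
    if pos.all() or not pos.any():
        raise ValidationError(
            "y_true contains a single class; sensitivity/specificity undefined"
        )
    pred_pos = y_pred == positive_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    return MetricSet(
        accuracy=(tp + tn) / len(y_true),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


def evaluate_cv(
    table: FeatureTable,
    net_table: NetworkFeatureTable,
    kind: str,
    *,
    e1: int = 3,
    e2: int = 2,
    n_folds: int = 10,
    seed: int = 0,
    positive_label=1,
    C: float = 1.0,
    rounds: int = 1,
    alpha: float = 0.05,
    scale: bool = True,
    transductive: bool = False,
) -> MetricSet:
    """Stratified k-fold cross-validation of one representation.

    By default every fold re-fits scaling, coupling weights, CCA spectra and
    the ensemble on its training rows only; ``transductive=True`` fits the
    representation on all rows (the classifier is still fold-fitted).
    """
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, got {classes.tolist()}")
    if counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} subjects < {n_folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet] = []
    for train_idx, test_idx in skf.split(table.values, y):
        fit_rows = None if transductive else train_idx
        design = build_design(
            kind, table, net_table, e1=e1, e2=e2, fit_rows=fit_rows,
            alpha=alpha, scale=scale,
        )
        train_design = AssembledDesign(
            kind=kind, matrix=design.matrix[train_idx], blocks=design.blocks,
            column_names=design.column_names,
        )
        test_design = AssembledDesign(
            kind=kind, matrix=design.matrix[test_idx], blocks=design.blocks,
            column_names=design.column_names,
        )
        ensemble = train_block_boosted_svm(
            train_design, y[train_idx], positive_label, C=C, rounds=rounds
        )
        y_pred = predict(ensemble, test_design)
        fold_metrics.append(compute_metrics(y[test_idx], y_pred, positive_label))
    return MetricSet(
        accuracy=float(np.mean([f.accuracy for f in fold_metrics])),
        sensitivity=float(np.mean([f.sensitivity for f in fold_metrics])),
        specificity=float(np.mean([f.specificity for f in fold_metrics])),
        per_fold=[
            {"accuracy": f.accuracy, "sensitivity": f.sensitivity,
             "specificity": f.specificity}
            for f in fold_metrics
        ],
    )


def grid_search(
    table: FeatureTable,
    net_table: NetworkFeatureTable,
    kinds: tuple[str, ...] = DESIGN_KINDS,
    *,
    e1_grid: tuple[int, ...] = E1_GRID_DEFAULT,
    e2_grid: tuple[int, ...] = E2_GRID_DEFAULT,
    n_folds: int = 10,
    seed: int = 0,
    positive_label=1,
    C: float = 1.0,
    rounds: int = 1,
    alpha: float = 0.05,
    scale: bool = True,
    transductive: bool = False,
) -> GridResult:
    """Sweep (kind, E1, E2); E1 is ignored for original-feature designs and E2
    for designs without the inter block.  Best cell by accuracy; ties go to the
    smaller E1 then the smaller E2."""
    if not e1_grid or not e2_grid or not kinds:
        raise ValidationError("kinds, e1_grid and e2_grid must be nonempty")
    for kind in kinds:
        if kind not in DESIGN_KINDS:
            raise ValidationError(f"unknown design kind {kind!r}")
    cells: dict[tuple[str, int | None, int | None], MetricSet] = {}
    for kind in kinds:
        e1s: tuple[int | None, ...] = (None,) if kind.startswith("OFM") else tuple(e1_grid)
        e2s: tuple[int | None, ...] = tuple(e2_grid) if kind == "CFM_network" else (None,)
        for e1 in e1s:
            for e2 in e2s:
                cells[(kind, e1, e2)] = evaluate_cv(
                    table, net_table, kind,
                    e1=e1 or 1, e2=e2 or 1, n_folds=n_folds, seed=seed,
                    positive_label=positive_label, C=C, rounds=rounds,
                    alpha=alpha, scale=scale, transductive=transductive,
                )
                logger.debug("grid cell %s: %s", (kind, e1, e2),
                             cells[(kind, e1, e2)].as_percent())
    best = max(
        cells,
        key=lambda key: (
            cells[key].accuracy,
            -(key[1] or 0),
            -(key[2] or 0),
        ),
    )
    return GridResult(cells=cells, best=best)
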