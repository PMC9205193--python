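"""In-memory containers for ROI-level and network-level feature tables.

The central object is :class:`FeatureTable`: a subjects x ROI-features matrix
of mean gray-matter values, together with a map assigning every ROI feature to
a brain network (1..L, the same number n of ROIs per network) and a binary
group label per subject.  :class:`NetworkFeatureTable` holds the matching
subjects x networks matrix of network-level features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FeatureTable", "NetworkFeatureTable"]


@dataclass
class FeatureTable:
    """Subjects x ROI features with network assignment and group labels.

    Parameters
    ----------
    values
        ``(M, N)`` float array; entry ``(i, k)`` is the mean gray-matter value
        of ROI feature *k* for subject *i*.
    network_map
        Length-``N`` integer array mapping each feature column to a network id
        in ``1..L``.  Every network must contain the same number of features.
    labels
        Length-``M`` integer array of group labels (two groups).
    subject_ids, feature_ids
        Optional identifiers; generated as ``s000..`` / ``net{l}_roi{k}`` when
        omitted.
    """

    values: np.ndarray
    network_map: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.network_map = np.asarray(self.network_map, dtype=int)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D subjects x features matrix")
        m, n_feat = self.values.shape
        if self.network_map.shape != (n_feat,):
            raise ValidationError(
                f"network_map length {self.network_map.shape} does not match "
                f"{n_feat} feature columns"
            )
        if self.labels.shape != (m,):
            raise ValidationError(f"labels length {self.labels.shape} does not match {m} subjects")
        if np.isnan(self.values).any():
            raise ValidationError("values contain missing entries (NaN)")
        nets = np.unique(self.network_map)
        expected = np.arange(1, nets.size + 1)
        if not np.array_equal(nets, expected):
            raise ValidationError(
                f"network ids must be contiguous 1..L, got {nets.tolist()}"
            )
        counts = np.bincount(self.network_map)[1:]
        if counts.size and not np.all(counts == counts[0]):
            raise ValidationError(
                f"every network must have the same feature count; got {counts.tolist()}"
            )
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(m)]
        if not self.feature_ids:
            within = np.zeros(n_feat, dtype=int)
            for l in nets:
                idx = np.flatnonzero(self.network_map == l)
                within[idx] = np.arange(1, idx.size + 1)
            self.feature_ids = [
                f"net{l}_roi{k}" for l, k in zip(self.network_map, within)
            ]
        if len(self.subject_ids) != m or len(self.feature_ids) != n_feat:
            raise ValidationError("subject_ids/feature_ids lengths do not match values")
        for k in range(n_feat):
            col = self.values[:, k]
            if np.ptp(col) == 0.0:
                warnings.warn(
                    f"feature column {self.feature_ids[k]!r} is constant", stacklevel=2
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_networks(self) -> int:
        return int(self.network_map.max()) if self.network_map.size else 0

    @property
    def rois_per_network(self) -> int:
        return self.n_features // self.n_networks

    def network_columns(self, network: int) -> np.ndarray:
        """Column indices (in stored order) belonging to ``network``."""
        return np.flatnonzero(self.network_map == network)

    def network_block(self, network: int) -> np.ndarray:
        """The ``(M, n)`` sub-matrix of ROI features for one network."""
        return self.values[:, self.network_columns(network)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class NetworkFeatureTable:
    """Subjects x networks matrix of network-level features (``(M, L)``)."""

    values: np.ndarray
    network_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("network values must be a 2-D matrix")
        if not self.network_ids:
            self.network_ids = list(range(1, self.values.shape[1] + 1))
        if len(self.network_ids) != self.values.shape[1]:
            raise ValidationError("network_ids length does not match columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[f"net{l}" for l in self.network_ids])
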