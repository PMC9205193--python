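"""Synthetic two-group datasets with the structure the coupling method assumes.

Two generators are provided:

``generate_feature_tables``
    Draws a subjects x ROI-features table directly.  ROI features within a
    network are equicorrelated Gaussians; networks are independent; affected
    networks carry a standardized group mean shift (gray-matter loss in the
    patient-like group); the network-level feature is the mean of its ROIs.

``generate_voxel_dataset``
    Builds subject gray-matter maps as mixing coefficients times spatial
    component maps plus voxel noise, with the group difference planted in the
    mixing coefficients — the generative model the ICA-based extraction
    pipeline inverts.

All randomness flows through one root :class:`numpy.random.SeedSequence`;
each operation draws from its own child stream so the two generators are
independently reproducible for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .tables import FeatureTable, NetworkFeatureTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_feature_tables",
    "generate_voxel_dataset",
    "coupled_difference_config",
]

# sd of the mixing coefficients in voxel mode; group shifts are expressed in
# units of this sd so effect_size keeps its Cohen's-d meaning in both modes
_MIXING_SD = 1.0
_MIXING_MEAN = 4.0


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generators.

    ``within_network_rho`` may be a single correlation (all networks and both
    groups share it) or a ``(rho_base, rho_affected)`` pair: the patient-like
    group then shows the stronger coupling ``rho_affected`` inside affected
    networks while everything else keeps ``rho_base`` — a group difference
    carried by the within-network correlation structure.
    ``patient_sd_ratio`` scales the patient group's ROI standard deviation on
    affected networks (correlated-variability difference; 1.0 disables it).
    """

    n_per_group: tuple[int, int] = (60, 60)
    n_networks: int = 4
    rois_per_network: int = 3
    within_network_rho: float | tuple[float, float] = 0.5
    affected_networks: frozenset[int] = field(default_factory=lambda: frozenset({1}))
    effect_size: float = 0.8
    noise_sd: float = 1.0
    patient_sd_ratio: float = 1.0
    n_voxels_per_roi: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        m1, m2 = self.n_per_group
        if m1 < 10 or m2 < 10:
            raise ConfigError(f"n_per_group must both be >= 10, got {self.n_per_group}")
        if self.n_networks < 2:
            raise ConfigError(f"n_networks must be >= 2, got {self.n_networks}")
        if self.rois_per_network < 2:
            raise ConfigError(f"rois_per_network must be >= 2, got {self.rois_per_network}")
        for rho in self.rho_per_group:
            if not (0.0 <= rho < 1.0):
                raise ConfigError(f"within_network_rho must lie in [0, 1), got {rho}")
        self.affected_networks = frozenset(int(a) for a in self.affected_networks)
        bad = self.affected_networks - set(range(1, self.n_networks + 1))
        if bad:
            raise ConfigError(
                f"affected_networks {sorted(bad)} outside 1..{self.n_networks}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.patient_sd_ratio <= 0:
            raise ConfigError(
                f"patient_sd_ratio must be positive, got {self.patient_sd_ratio}"
            )
        if self.n_voxels_per_roi < 1:
            raise ConfigError(f"n_voxels_per_roi must be >= 1, got {self.n_voxels_per_roi}")

    @property
    def rho_per_group(self) -> tuple[float, float]:
        rho = self.within_network_rho
        if isinstance(rho, (tuple, list)):
            if len(rho) != 2:
                raise ConfigError(
                    f"within_network_rho pair must have length 2, got {rho}"
                )
            return float(rho[0]), float(rho[1])
        return float(rho), float(rho)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group)

    @property
    def n_roi_features(self) -> int:
        return self.n_networks * self.rois_per_network


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    affected_networks: frozenset[int]
    true_group_means: np.ndarray  # (2, N) per-ROI means for group 0 / group 1
    component_supports: dict[int, np.ndarray] | None = None  # network -> voxel indices
    component_rois: dict[int, list[int]] | None = None  # network -> atlas region ids


def coupled_difference_config(seed: int, n_per_group: tuple[int, int] = (60, 60)) -> SyntheticConfig:
    """Study conditions where the group difference lives in within-network coupling.

    One affected network in which the patient group shows strongly correlated,
    more variable gray matter (rho 0.3 -> 0.8, sd x1.8) on top of a modest
    mean shift (d = 0.5); the remaining networks are identical across groups.
    Pure correlation changes leave every ROI marginal untouched and are
    invisible to linear classifiers on original features, so this is the
    regime that separates coupled from original representations.
    """
    return SyntheticConfig(
        n_per_group=n_per_group,
        n_networks=4,
        rois_per_network=3,
        within_network_rho=(0.3, 0.8),
        affected_networks=frozenset({1}),
        effect_size=0.5,
        noise_sd=1.0,
        patient_sd_ratio=1.8,
        seed=seed,
    )


def _equicorrelated_cholesky(n: int, rho: float) -> np.ndarray:
    cov = np.full((n, n), rho)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def generate_feature_tables(
    config: SyntheticConfig,
) -> tuple[FeatureTable, NetworkFeatureTable, GroundTruth]:
    """Draw ROI-level and network-level feature tables for two groups.

    Returns ``(roi_table, network_table, truth)`` where the network table's
    column *j* is exactly the row-wise mean of network *j*'s ROI columns.
    On affected networks the patient-like group (label 1) has its mean lowered
    by ``effect_size * noise_sd`` (atrophy), its within-network correlation
    raised to ``rho_affected`` and its sd scaled by ``patient_sd_ratio``.
    """
    m1, m2 = config.n_per_group
    L, n = config.n_networks, config.rois_per_network
    sd = config.noise_sd
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    baseline = 1.0  # arbitrary gray-matter-volume-like unit
    labels = np.concatenate([np.zeros(m1, dtype=int), np.ones(m2, dtype=int)])
    group_sizes = (m1, m2)
    rho_base, rho_affected = config.rho_per_group
    chol_base = _equicorrelated_cholesky(n, rho_base)
    chol_affected = _equicorrelated_cholesky(n, rho_affected)

    values = np.empty((m1 + m2, L * n))
    true_means = np.full((2, L * n), baseline)
    for l in range(1, L + 1):
        cols = slice((l - 1) * n, l * n)
        affected = l in config.affected_networks
        if affected:
            true_means[1, cols] -= config.effect_size * sd
        blocks = []
        for g, m_g in enumerate(group_sizes):
            patient_side = g == 1 and affected
            chol = chol_affected if patient_side else chol_base
            group_sd = sd * (config.patient_sd_ratio if patient_side else 1.0)
            z = rng.standard_normal((m_g, n)) @ chol.T
            blocks.append(true_means[g, cols] + group_sd * z)
        values[:, cols] = np.vstack(blocks)

    network_map = np.repeat(np.arange(1, L + 1), n)
    table = FeatureTable(values=values, network_map=network_map, labels=labels)
    net_values = values.reshape(m1 + m2, L, n).mean(axis=2)
    net_table = NetworkFeatureTable(values=net_values)
    truth = GroundTruth(
        affected_networks=config.affected_networks, true_group_means=true_means
    )
    return table, net_table, truth


def generate_voxel_dataset(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Build a subjects x voxels gray-matter matrix plus an atlas label vector.

    Each network is a spatial component occupying a contiguous block of
    ``rois_per_network`` atlas regions.  Component map values on the support
    are exponentially distributed (sparse, peaked maps, so the z-scored maps
    have a genuine tail above the binarization threshold); subject maps are
    ``mixing @ components + noise``.  The group difference is planted in the
    mixing coefficients of affected networks.

    Returns ``(X, atlas, labels, truth)``.
    """
    m1, m2 = config.n_per_group
    L, n, vpr = config.n_networks, config.rois_per_network, config.n_voxels_per_roi
    n_vox = L * n * vpr
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    labels = np.concatenate([np.zeros(m1, dtype=int), np.ones(m2, dtype=int)])
    atlas = np.repeat(np.arange(1, L * n + 1), vpr)

    components = np.zeros((L, n_vox))
    supports: dict[int, np.ndarray] = {}
    comp_rois: dict[int, list[int]] = {}
    for j in range(L):
        sup = np.arange(j * n * vpr, (j + 1) * n * vpr)
        components[j, sup] = rng.exponential(scale=1.0, size=sup.size)
        supports[j + 1] = sup
        comp_rois[j + 1] = list(range(j * n + 1, (j + 1) * n + 1))

    mixing = _MIXING_MEAN + _MIXING_SD * rng.standard_normal((m1 + m2, L))
    for net in config.affected_networks:
        mixing[m1:, net - 1] -= config.effect_size * _MIXING_SD

    X = mixing @ components + config.noise_sd * rng.standard_normal((m1 + m2, n_vox))

    true_means = np.empty((2, L * n))
    for j in range(L):
        for r in range(n):
            roi_vox = components[j, (j * n + r) * vpr : (j * n + r + 1) * vpr]
            for g, rows in enumerate((slice(0, m1), slice(m1, None))):
                true_means[g, j * n + r] = mixing[rows, j].mean() * roi_vox.mean()

    truth = GroundTruth(
        affected_networks=config.affected_networks,
        true_group_means=true_means,
        component_supports=supports,
        component_rois=comp_rois,
    )
    return X, atlas, labels, truth
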