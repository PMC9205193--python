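"""Shared fixtures and independent reference implementations.

The naive references deliberately use explicit Python loops and scipy
primitives so they share no code path with the vectorized package internals.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import coupledbrain as cb

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# naive reference implementations (oracles)


def naive_couple_block(
    expanded: np.ndarray,
    n: int,
    e1: int,
    intra: list[np.ndarray],
    inter: list[np.ndarray],
) -> np.ndarray:
    """Triple-loop (subject, feature, power) coupled-block reference."""
    omega = [1.0 / math.factorial(e) for e in range(1, e1 + 1)]
    m = expanded.shape[0]
    out = np.zeros((m, n * e1))
    for i in range(m):
        for k in range(n):
            others = [t for t in range(n) if t != k]
            for p in range(e1):
                val = 0.0
                for q in range(e1):
                    val += expanded[i, k * e1 + q] * omega[q] * intra[k][p, q]
                for j, t in enumerate(others):
                    for q in range(e1):
                        val += expanded[i, t * e1 + q] * omega[q] * inter[k][p, j * e1 + q]
                out[i, k * e1 + p] = val
    return out


def naive_inter_features(
    v: np.ndarray, retained: dict[tuple[int, int], np.ndarray], e2: int
) -> np.ndarray:
    """Loop reference for the inter-coupled network feature vector."""
    m, L = v.shape
    f = np.zeros((m, L))
    for i in range(m):
        for l in range(1, L + 1):
            for lp in range(1, L + 1):
                if lp == l:
                    continue
                key = (min(l, lp), max(l, lp))
                for e in range(1, e2 + 1):
                    f[i, l - 1] += (
                        (1.0 / math.factorial(e)) * v[i, lp - 1] ** e * retained[key][e - 1]
                    )
    return f


def naive_canonical_correlations(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """CCA spectrum from the generalized eigenvalue formulation (independent route)."""
    from scipy import linalg

    b1 = b1 - b1.mean(axis=0)
    b2 = b2 - b2.mean(axis=0)
    c11 = b1.T @ b1
    c22 = b2.T @ b2
    c12 = b1.T @ b2
    mat = np.linalg.solve(c11, c12) @ np.linalg.solve(c22, c12.T)
    eigvals = np.real(linalg.eigvals(mat))
    eigvals = np.clip(eigvals, 0.0, 1.0)
    k = min(b1.shape[1], b2.shape[1])
    return np.sqrt(np.sort(eigvals)[::-1][:k])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def small_config() -> cb.SyntheticConfig:
    return cb.SyntheticConfig(
        n_per_group=(20, 20), n_networks=4, rois_per_network=3, seed=42
    )


@pytest.fixture()
def small_tables(small_config):
    return cb.generate_feature_tables(small_config)


@pytest.fixture()
def random_table():
    """A signal-free table for structural tests."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((24, 12))
    labels = np.repeat([0, 1], 12)
    return cb.FeatureTable(values=values, network_map=np.repeat([1, 2, 3, 4], 3), labels=labels)
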