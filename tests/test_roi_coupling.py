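"""Scaling, power expansion, revised-Pearson weights, coupled blocks."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import coupledbrain as cb
from coupledbrain.roi_coupling import (
    CouplingWeights,
    apply_scaling,
    expand_block,
    fit_scaling,
)

from .conftest import naive_couple_block


def _table(values, n_networks=1):
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // n_networks
    return cb.FeatureTable(
        values=values,
        network_map=np.repeat(np.arange(1, n_networks + 1), n),
        labels=np.repeat([0, 1], values.shape[0] // 2),
    )


class TestScaling:
    def test_affine_map_to_symmetric_range(self):
        table = _table(np.array([[2.0, 2.0], [4.0, 4.0], [6.0, 6.0], [6.0, 2.0]]))
        scaled, _ = cb.scale_features(table, fit_rows=np.arange(3))
        np.testing.assert_allclose(scaled.values[:3, 0], [-1.0, 0.0, 1.0])

    def test_heldout_values_not_clipped(self):
        values = np.array([[0.0], [1.0], [2.0], [10.0]])
        params = fit_scaling(values, np.arange(3))
        out = apply_scaling(values, params)
        assert out[3, 0] > 1.0

    def test_constant_column_maps_to_midpoint(self):
        values = np.c_[np.ones(4), np.arange(4.0)]
        with pytest.warns(UserWarning, match="constant"):
            params = fit_scaling(values, np.arange(4))
        out = apply_scaling(values, params)
        np.testing.assert_array_equal(out[:, 0], 0.0)


class TestExpansion:
    def test_powers_of_scalar(self):
        eb = expand_block(np.array([[2.0]]), 3)
        np.testing.assert_array_equal(eb.values, [[2.0, 4.0, 8.0]])

    def test_order_one_is_identity(self):
        block = np.random.default_rng(0).standard_normal((5, 3))
        np.testing.assert_array_equal(expand_block(block, 1).values, block)

    def test_negative_base(self):
        eb = expand_block(np.array([[-0.5]]), 2)
        np.testing.assert_array_equal(eb.values, [[-0.5, 0.25]])

    def test_invalid_order(self):
        with pytest.raises(cb.ValidationError):
            expand_block(np.zeros((3, 2)), 0)

    @given(st.integers(1, 4), st.integers(0, 100))
    def test_column_e_is_elementwise_power_of_column_one(self, order, seed):
        block = np.random.default_rng(seed).uniform(-1, 1, size=(6, 3))
        eb = expand_block(block, order)
        for k in range(3):
            for e in range(1, order + 1):
                np.testing.assert_allclose(
                    eb.values[:, k * order + (e - 1)],
                    eb.values[:, k * order] ** e,
                    atol=1e-12,
                )


class TestCouplingWeights:
    def test_symmetric_sample_gives_exact_zero(self):
        # x = (-2, -1, 1, 2): sum of cubes is 0, so corr(x, x^2) = 0 exactly
        block = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        w = cb.compute_coupling_weights(expand_block(block, 2))
        assert w.intra[0][0, 1] == 0.0
        assert w.intra[0][1, 0] == 0.0

    def test_significant_correlation_kept(self):
        block = np.array([[1.0], [2.0], [3.0], [4.0]])
        w = cb.compute_coupling_weights(expand_block(block, 2))
        # r(x, x^2) = 0.98437, p = 0.0156 < 0.05 -> kept
        assert w.intra[0][0, 1] == pytest.approx(0.9843740386976971, abs=1e-10)

    def test_unit_diagonal(self):
        block = np.random.default_rng(3).standard_normal((10, 3))
        w = cb.compute_coupling_weights(expand_block(block, 3))
        for k in range(3):
            np.testing.assert_array_equal(np.diag(w.intra[k]), 1.0)

    def test_inter_weight_symmetry(self):
        """delta_pq(k, tau) and delta_qp(tau, k) are the same correlation."""
        rng = np.random.default_rng(4)
        eb = expand_block(rng.uniform(-1, 1, (12, 3)), 2)
        w = cb.compute_coupling_weights(eb)
        n, e1 = 3, 2
        for k in range(n):
            others_k = [t for t in range(n) if t != k]
            for j, tau in enumerate(others_k):
                others_tau = [t for t in range(n) if t != tau]
                jk = others_tau.index(k)
                for p in range(e1):
                    for q in range(e1):
                        assert w.inter[k][p, j * e1 + q] == w.inter[tau][q, jk * e1 + p]

    def test_zero_variance_column_zeroed_with_warning(self):
        block = np.c_[np.ones(8), np.random.default_rng(1).standard_normal(8)]
        with pytest.warns(UserWarning, match="zero-variance"):
            w = cb.compute_coupling_weights(expand_block(block, 2))
        assert np.all(w.inter[0] == 0.0)
        assert w.intra[0][0, 1] == 0.0

    def test_revision_rule_against_independent_pvalues(self):
        rng = np.random.default_rng(6)
        eb = expand_block(rng.uniform(-1, 1, (15, 3)), 3)
        w = cb.compute_coupling_weights(eb)
        z = eb.values
        n, e1 = 3, 3
        for k in range(n):
            for p in range(e1):
                for q in range(e1):
                    r, pval = stats.pearsonr(z[:, k * e1 + p], z[:, k * e1 + q])
                    if p != q and pval > 0.05:
                        assert w.intra[k][p, q] == 0.0
                    elif p != q:
                        assert w.intra[k][p, q] == pytest.approx(r, abs=1e-10)


class TestCoupleBlock:
    def test_identity_intra_zero_inter_gives_taylor_weighted_powers(self):
        eb = expand_block(np.array([[2.0]]), 2)
        w = CouplingWeights(network=1, n_features=1, order=2,
                            intra=[np.eye(2)], inter=[np.zeros((2, 0))], alpha=0.05)
        np.testing.assert_allclose(cb.couple_block(eb, w), [[2.0, 2.0]])

    def test_all_zero_weights_annihilate(self):
        eb = expand_block(np.random.default_rng(0).uniform(-1, 1, (4, 3)), 2)
        w = CouplingWeights(network=1, n_features=3, order=2,
                            intra=[np.zeros((2, 2))] * 3,
                            inter=[np.zeros((2, 4))] * 3, alpha=0.05)
        np.testing.assert_array_equal(cb.couple_block(eb, w), np.zeros((4, 6)))

    def test_matches_naive_loop_reference(self):
        rng = np.random.default_rng(8)
        eb = expand_block(rng.uniform(-1, 1, (4, 3)), 2)
        w = cb.compute_coupling_weights(eb)
        expected = naive_couple_block(eb.values, 3, 2, w.intra, w.inter)
        np.testing.assert_allclose(cb.couple_block(eb, w), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        eb = expand_block(np.zeros((4, 3)), 2)
        w = CouplingWeights(network=1, n_features=2, order=2,
                            intra=[np.eye(2)] * 2, inter=[np.zeros((2, 2))] * 2,
                            alpha=0.05)
        with pytest.raises(cb.ValidationError):
            cb.couple_block(eb, w)


class TestIntraRepresentation:
    def test_order_one_reduces_to_scaled_originals(self, random_table):
        rep = cb.build_intra_representation(random_table, 1)
        scaled, _ = cb.scale_features(random_table)
        np.testing.assert_array_equal(rep.values, scaled.values)

    def test_width_bookkeeping(self):
        table = _table(np.random.default_rng(0).standard_normal((10, 6)), n_networks=2)
        rep = cb.build_intra_representation(table, 3)
        assert rep.values.shape == (10, 18)
        assert rep.block_slices[2] == slice(9, 18)

    def test_network_permutation_permutes_blocks(self, random_table):
        rep = cb.build_intra_representation(random_table, 2)
        # swap networks 1 and 2 in the table: their blocks swap, content intact
        perm_cols = np.r_[np.arange(3, 6), np.arange(0, 3), np.arange(6, 12)]
        swapped = cb.FeatureTable(
            values=random_table.values[:, perm_cols],
            network_map=random_table.network_map,
            labels=random_table.labels,
        )
        rep2 = cb.build_intra_representation(swapped, 2)
        np.testing.assert_allclose(rep2.values[:, rep2.block_slices[1]],
                                   rep.values[:, rep.block_slices[2]])
        np.testing.assert_allclose(rep2.values[:, rep2.block_slices[2]],
                                   rep.values[:, rep.block_slices[1]])

    def test_cross_network_isolation(self, random_table):
        """Perturbing features of one network never touches other blocks."""
        rep = cb.build_intra_representation(random_table, 3)
        perturbed = random_table.values.copy()
        perturbed[:, random_table.network_columns(4)] *= 3.7
        rep2 = cb.build_intra_representation(
            dataclasses.replace(random_table, values=perturbed), 3
        )
        for l in (1, 2, 3):
            np.testing.assert_array_equal(
                rep.values[:, rep.block_slices[l]], rep2.values[:, rep2.block_slices[l]]
            )

    def test_train_only_fitting_ignores_heldout_rows(self, random_table):
        fit_rows = np.arange(16)
        rep = cb.build_intra_representation(random_table, 2, fit_rows)
        tampered = random_table.values.copy()
        tampered[16:] += 100.0
        rep2 = cb.build_intra_representation(
            dataclasses.replace(random_table, values=tampered), 2, fit_rows
        )
        np.testing.assert_array_equal(rep.values[:16], rep2.values[:16])
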