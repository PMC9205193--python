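"""Block-wise boosting, prediction, metrics, cross-validation, grid search."""

import dataclasses
import math

import numpy as np
import pytest

import coupledbrain as cb
from coupledbrain.classify import vote_weight
from coupledbrain.network_coupling import AssembledDesign


def _single_block_design(x):
    x = np.asarray(x, dtype=float)
    return AssembledDesign(
        kind="OFM_ROI", matrix=x, blocks={"all": slice(0, x.shape[1])},
        column_names=[f"c{i}" for i in range(x.shape[1])],
    )


def _two_block_design(x):
    x = np.asarray(x, dtype=float)
    half = x.shape[1] // 2
    return AssembledDesign(
        kind="CFM_network", matrix=x,
        blocks={"net1": slice(0, half), "net2": slice(half, x.shape[1])},
        column_names=[f"c{i}" for i in range(x.shape[1])],
    )


class TestBoosting:
    def test_vote_weight_closed_form(self):
        assert vote_weight(0.25) == pytest.approx(0.5 * math.log(3.0))
        assert vote_weight(0.5) == 0.0
        assert vote_weight(0.7) == 0.0

    def test_separable_data_reaches_zero_training_error(self):
        x = np.r_[np.full((10, 2), -1.0), np.full((10, 2), 1.0)]
        x += 0.01 * np.random.default_rng(0).standard_normal(x.shape)
        y = np.repeat([0, 1], 10)
        design = _single_block_design(x)
        ens = cb.train_block_boosted_svm(design, y, positive_label=1)
        assert np.array_equal(cb.predict(ens, design), y)
        assert ens.learners[0].train_error <= 1e-9

    def test_identical_separable_blocks_give_equal_alphas_and_single_svm_prediction(self):
        # separable data: the first learner has zero error, so the sample
        # weights never move and the identical second block repeats it exactly
        rng = np.random.default_rng(1)
        base = 0.1 * rng.standard_normal((30, 3)) + np.repeat([0, 2.0], 15)[:, None]
        y = np.repeat([0, 1], 15)
        two = _two_block_design(np.hstack([base, base]))
        one = _single_block_design(base)
        ens2 = cb.train_block_boosted_svm(two, y, positive_label=1)
        ens1 = cb.train_block_boosted_svm(one, y, positive_label=1)
        assert ens2.learners[0].alpha == pytest.approx(ens2.learners[1].alpha, rel=1e-6)
        np.testing.assert_array_equal(cb.predict(ens2, two), cb.predict(ens1, one))

    def test_training_error_bound(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 6)) + 0.8 * np.repeat([0, 1.0], 20)[:, None]
        y = np.repeat([0, 1], 20)
        design = _two_block_design(x)
        ens = cb.train_block_boosted_svm(design, y, positive_label=1, rounds=3)
        if np.all(ens.alphas > 0):
            bound = np.prod(
                [2 * math.sqrt(l.train_error * (1 - l.train_error)) for l in ens.learners]
            )
            err = float(np.mean(cb.predict(ens, design) != y))
            assert err <= bound + 1e-12

    def test_sample_weight_history_shape_and_normalization(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 4))
        y = np.repeat([0, 1], 10)
        ens = cb.train_block_boosted_svm(_two_block_design(x), y, positive_label=1)
        assert ens.weight_history.shape == (3, 20)
        np.testing.assert_allclose(ens.weight_history.sum(axis=1), 1.0)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(cb.ValidationError):
            cb.train_block_boosted_svm(_single_block_design(x), np.zeros(10), 1)


class TestPrediction:
    def test_single_learner_matches_its_svm(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 3)) + np.repeat([0, 1.2], 15)[:, None]
        y = np.repeat([0, 1], 15)
        design = _single_block_design(x)
        ens = cb.train_block_boosted_svm(design, y, positive_label=1)
        svm_pred = ens.learners[0].model.predict(x)
        np.testing.assert_array_equal(cb.predict(ens, design), np.where(svm_pred > 0, 1, 0))

    def test_all_zero_alphas_tie_to_positive_class(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 2))  # no signal -> eps ~ 0.5 -> alpha 0
        y = np.repeat([0, 1], 20)
        ens = cb.train_block_boosted_svm(_single_block_design(x), y, positive_label=1)
        if not np.any(ens.alphas > 0):
            with pytest.warns(UserWarning, match="zero"):
                pred = cb.predict(ens, _single_block_design(x))
            assert np.all(pred == 1)

    def test_block_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((20, 4)) + np.repeat([0, 1.0], 10)[:, None]
        y = np.repeat([0, 1], 10)
        ens = cb.train_block_boosted_svm(_two_block_design(x), y, positive_label=1)
        with pytest.raises(cb.ValidationError):
            cb.predict(ens, _single_block_design(x))


class TestMetrics:
    def test_confusion_arithmetic(self):
        y_true = np.r_[np.ones(10), np.zeros(10)]
        y_pred = np.r_[np.ones(9), 0, np.zeros(8), 1, 1]
        m = cb.compute_metrics(y_true, y_pred, positive_label=1)
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)

    def test_perfect_prediction(self):
        y = np.repeat([0, 1], 5)
        m = cb.compute_metrics(y, y, positive_label=1)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_inverted_prediction_complements_accuracy(self):
        y = np.repeat([0, 1], 8)
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 16)
        acc = cb.compute_metrics(y, pred, 1).accuracy
        inv = cb.compute_metrics(y, 1 - pred, 1).accuracy
        assert acc + inv == pytest.approx(1.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(cb.ValidationError):
            cb.compute_metrics(np.ones(5), np.ones(5), positive_label=1)


class TestCrossValidation:
    def test_determinism_and_seed_sensitivity(self, small_tables):
        table, net_table, _ = small_tables
        a = cb.evaluate_cv(table, net_table, "OFM_ROI", seed=3)
        b = cb.evaluate_cv(table, net_table, "OFM_ROI", seed=3)
        assert a.per_fold == b.per_fold
        c = cb.evaluate_cv(table, net_table, "OFM_ROI", seed=4)
        assert a.per_fold != c.per_fold  # different folds in general

    def test_every_fold_scored(self, small_tables):
        table, net_table, _ = small_tables
        m = cb.evaluate_cv(table, net_table, "OFM_network", n_folds=5, seed=0)
        assert len(m.per_fold) == 5
        assert m.accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in m.per_fold])
        )

    def test_class_smaller_than_folds_rejected(self, small_tables):
        table, net_table, _ = small_tables
        with pytest.raises(cb.ValidationError, match="folds"):
            cb.evaluate_cv(table, net_table, "OFM_ROI", n_folds=25, seed=0)

    def test_strong_planted_signal_is_recovered(self):
        accs = []
        for s in range(3):
            cfg = cb.SyntheticConfig(
                n_per_group=(30, 30), within_network_rho=0.8, effect_size=2.0,
                affected_networks=frozenset({1, 2, 3, 4}), seed=500 + s,
            )
            table, net_table, _ = cb.generate_feature_tables(cfg)
            accs.append(
                cb.evaluate_cv(table, net_table, "CFM_network", e1=3, e2=2, seed=s).accuracy
            )
        assert np.mean(accs) >= 0.85

    def test_transductive_switch_changes_fit(self, small_tables):
        table, net_table, _ = small_tables
        a = cb.evaluate_cv(table, net_table, "CFM_network", e1=2, e2=1, seed=0)
        b = cb.evaluate_cv(table, net_table, "CFM_network", e1=2, e2=1, seed=0,
                           transductive=True)
        # same folds, different representation fitting policy
        assert a.per_fold != b.per_fold


class TestGridSearch:
    def test_cell_bookkeeping(self, small_tables):
        table, net_table, _ = small_tables
        g = cb.grid_search(table, net_table, ("OFM_ROI",), seed=0)
        assert len(g.cells) == 1
        g = cb.grid_search(table, net_table, ("CFM_network",),
                           e1_grid=(2, 3, 4), e2_grid=(1, 2, 3, 4, 5), seed=0)
        assert len(g.cells) == 15
        assert g.best in g.cells

    def test_tie_break_prefers_smaller_orders(self, small_tables):
        table, net_table, _ = small_tables
        g = cb.grid_search(table, net_table, ("CFM_network",),
                           e1_grid=(2, 3), e2_grid=(1, 2), seed=1)
        best_acc = g.cells[g.best].accuracy
        for key, ms in g.cells.items():
            if ms.accuracy == best_acc:
                assert (g.best[1], g.best[2]) <= (key[1], key[2])

    def test_empty_grid_rejected(self, small_tables):
        table, net_table, _ = small_tables
        with pytest.raises(cb.ValidationError):
            cb.grid_search(table, net_table, (), seed=0)
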