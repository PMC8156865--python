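"""Coverage-aware metrics, cross-validation, beta sweep."""

import numpy as np
import pytest

from elasticgrade.elastic import ABSTAIN
from elasticgrade.evaluation import (
    FoldOutcome,
    ap,
    beta_sweep,
    classification_metrics,
    crossval_split,
    fold_outcomes,
    waa,
)
from conftest import make_mixed_members, mock_prediction_set


def confusion_oracle(truths, preds, c):
    """Brute-force contingency counting, independent of sklearn."""
    cm = np.zeros((c, c), dtype=int)
    for t, p in zip(truths, preds):
        cm[t, p] += 1
    return cm


class TestClassificationMetrics:
    def test_hand_computed_binary_case(self):
        cm, table, acc = classification_metrics([0, 0, 1, 1], [0, 1, 1, 1], c=2)
        row0, row1 = table.iloc[0], table.iloc[1]
        assert row0.precision == 1.0 and row0.recall == 0.5
        assert row1.precision == pytest.approx(2 / 3)
        assert row1.recall == 1.0
        assert acc == 0.75

    def test_perfect_predictions(self):
        cm, table, acc = classification_metrics([0, 1, 2] * 3, [0, 1, 2] * 3, c=3)
        assert acc == 1.0
        assert (table[["precision", "recall", "f1", "accuracy"]] == 1.0).all().all()

    def test_collapsed_predictions_recall_pattern(self):
        with pytest.warns(UserWarning):
            _, table, _ = classification_metrics([0, 1, 2], [1, 1, 1], c=3)
        assert list(table.recall[:3]) == [0.0, 1.0, 0.0]

    def test_agrees_with_brute_force_oracle_on_random_labels(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            c = int(rng.integers(2, 5))
            n = int(rng.integers(10, 60))
            truths = rng.integers(0, c, n)
            preds = rng.integers(0, c, n)
            oracle = confusion_oracle(truths, preds, c)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cm, table, acc = classification_metrics(truths, preds, c)
            np.testing.assert_array_equal(cm, oracle)
            assert acc == pytest.approx(np.trace(oracle) / n)
            for k in range(c):
                tp = oracle[k, k]
                fp = oracle[:, k].sum() - tp
                fn = oracle[k, :].sum() - tp
                if tp + fp:
                    assert table.precision[k] == pytest.approx(tp / (tp + fp))
                if tp + fn:
                    assert table.recall[k] == pytest.approx(tp / (tp + fn))

    def test_total_row_is_macro_average(self):
        _, table, _ = classification_metrics([0, 0, 1, 1], [0, 1, 1, 1], c=2)
        total = table[table.grade == "Total"].iloc[0]
        assert total.precision == pytest.approx(table.precision[:2].mean())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [0], c=2)


def fo(fold_id, d, r, correct):
    return FoldOutcome(fold_id=fold_id, n_included=d, n_excluded=r,
                       n_correct_included=correct)


class TestWaa:
    def test_equal_weight_folds(self):
        assert waa([fo(0, 10, 0, 10), fo(1, 10, 0, 5)]) == 0.75

    def test_unequal_weights_hand_oracle(self):
        # accuracies (0.9, 0.6) with d = (30, 10): (27 + 6) / 40
        assert waa([fo(0, 30, 0, 27), fo(1, 10, 0, 6)]) == pytest.approx(0.825)

    def test_single_fold_passthrough(self):
        assert waa([fo(0, 20, 5, 13)]) == pytest.approx(13 / 20)

    def test_empty_folds_contribute_nothing(self):
        assert waa([fo(0, 10, 0, 9), fo(1, 0, 10, 0)]) == pytest.approx(0.9)

    def test_all_folds_empty_rejected(self):
        with pytest.raises(ValueError):
            waa([fo(0, 0, 10, 0)])

    def test_equals_pooled_accuracy_without_abstentions(self):
        rng = np.random.default_rng(2)
        folds, hits, total = [], 0, 0
        for i in range(5):
            d = int(rng.integers(5, 40))
            correct = int(rng.integers(0, d + 1))
            folds.append(fo(i, d, 0, correct))
            hits += correct
            total += d
        assert waa(folds) == pytest.approx(hits / total)


class TestAp:
    def test_five_of_three_hundred(self):
        folds = [fo(i, 59, 1, 50) for i in range(5)]
        assert ap(folds, 300) == pytest.approx(100 * 5 / 300)
        assert ap(folds, 300) == pytest.approx(1.6667, abs=1e-4)

    def test_no_exclusions_is_zero(self):
        assert ap([fo(0, 10, 0, 8)], 10) == 0.0

    def test_all_excluded_is_hundred(self):
        assert ap([fo(0, 0, 10, 0)], 10) == 100.0

    def test_inconsistent_dataset_size_rejected(self):
        with pytest.raises(ValueError):
            ap([fo(0, 5, 0, 5)], 300)


def test_fold_outcomes_tally():
    grades = {"a": 0, "b": ABSTAIN, "c": 1, "d": 1}
    truths = {"a": 0, "b": 2, "c": 2, "d": 1}
    fold_of = {"a": 0, "b": 0, "c": 1, "d": 1}
    out = fold_outcomes(grades, truths, fold_of)
    assert out[0].n_included == 1 and out[0].n_excluded == 1
    assert out[0].n_correct_included == 1
    assert out[1].n_included == 2 and out[1].n_correct_included == 1
    assert out[0].accuracy_included == 1.0
    assert fo(0, 0, 3, 0).accuracy_included is None


class TestBetaSweep:
    @pytest.fixture
    def sweep_inputs(self):
        labels = np.repeat([0, 1, 2], 20)
        members = make_mixed_members(run_seed=5)
        preds = mock_prediction_set(members, labels, run_seed=5)
        truths = {f"im{i}": int(y) for i, y in enumerate(labels)}
        folds = {f"im{i}": i % 5 for i in range(len(labels))}
        return preds, truths, folds

    def test_ap_non_increasing_against_brute_force_recount(self, sweep_inputs):
        preds, truths, folds = sweep_inputs
        betas = [1e-8, 0.05, 0.3, 0.8, 1.3, 2.0]
        table = beta_sweep(preds, betas, truths, folds)
        assert list(table.beta) == betas
        assert (np.diff(table.ap.to_numpy()) <= 1e-12).all()
        # brute-force recount of exclusions at each beta
        for row in table.itertuples():
            excluded = sum(
                1 for ps in preds.values()
                if all(p.entropy_bits >= row.beta for p in ps))
            assert row.n_excluded == excluded
            assert row.ap == pytest.approx(100 * excluded / len(preds))

    def test_full_coverage_limit_equals_standard_ensemble(self, sweep_inputs):
        preds, truths, folds = sweep_inputs
        table = beta_sweep(preds, [1.7, 2.0], truths, folds)
        assert (table.ap == 0).all()
        standard_hits = sum(
            int(np.argmax(np.mean([p.probs for p in ps], axis=0))) == truths[i]
            for i, ps in preds.items())
        assert table.waa.iloc[0] == pytest.approx(standard_hits / len(preds))
        assert table.waa.iloc[0] == table.waa.iloc[1]

    def test_vanishing_beta_abstains_everywhere(self, sweep_inputs):
        preds, truths, folds = sweep_inputs
        table = beta_sweep(preds, [1e-12], truths, folds)
        assert table.ap.iloc[0] == 100.0
        assert np.isnan(table.waa.iloc[0])

    def test_empty_beta_list_rejected(self, sweep_inputs):
        preds, truths, folds = sweep_inputs
        with pytest.raises(ValueError):
            beta_sweep(preds, [], truths, folds)


class TestCrossvalSplit:
    def test_300_images_five_folds_of_60(self):
        labels = np.repeat([0, 1, 2], 100)
        folds = crossval_split(labels, k=5, seed=1)
        assert [len(f) for f in folds] == [60] * 5
        # stratified: 20 per grade per fold
        for f in folds:
            _, counts = np.unique(labels[f], return_counts=True)
            assert list(counts) == [20, 20, 20]

    def test_disjoint_and_exhaustive(self):
        labels = np.repeat([0, 1, 2], 10)
        folds = crossval_split(labels, k=5, seed=3)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(30))

    def test_deterministic_given_seed(self):
        labels = np.repeat([0, 1], 15)
        a = crossval_split(labels, k=3, seed=9)
        b = crossval_split(labels, k=3, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_leave_one_out_limit(self):
        labels = np.repeat([0, 1], 3)
        folds = crossval_split(labels, k=6, seed=0)
        assert [len(f) for f in folds] == [1] * 6

    def test_rare_class_falls_back_unstratified(self):
        labels = np.array([0] * 20 + [1] * 2)
        with pytest.warns(UserWarning):
            folds = crossval_split(labels, k=5, seed=0)
        assert sum(len(f) for f in folds) == 22
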