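"""Metrics, paired t-test, table-derived statistics, experiment runner."""

import numpy as np
import pytest
from scipy import stats as sps

from genomogram import tables
from genomogram.evaluation import (
    ConfusionMatrix,
    ExperimentModel,
    accuracy_from_cm,
    confusion_matrix,
    gene_level_accuracy,
    gene_of_class,
    macro_metrics,
    mse_score,
    mutant_gene_recovery,
    paired_t_test,
    roc_curves,
    run_experiment,
)
from genomogram.classifiers import MlpConfig, RbfNetwork


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "b", "c"]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_single_predicted_class_fills_one_row(self):
        cm = confusion_matrix(["a", "b", "c"], ["a", "a", "a"], ["a", "b", "c"])
        assert cm.counts[0].tolist() == [1, 1, 1]
        assert cm.counts[1:].sum() == 0

    def test_total_matches_sample_count(self, rng):
        names = ["a", "b", "c"]
        y_true = rng.choice(names, size=57)
        y_pred = rng.choice(names, size=57)
        cm = confusion_matrix(y_true, y_pred, names)
        assert cm.total == 57
        # column totals are the actual class sizes
        for j, c in enumerate(names):
            assert cm.counts[:, j].sum() == (y_true == c).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestAccuracyAndMacro:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int), ["a", "b", "c"])
        assert accuracy_from_cm(cm) == 1.0
        sens, spec, _ = macro_metrics(cm)
        assert sens == 1.0 and spec == 1.0

    def test_two_class_hand_computation(self):
        cm = ConfusionMatrix(np.array([[9, 1], [3, 7]]), ["p", "q"])
        sens, spec, per = macro_metrics(cm)
        assert per["p"]["sensitivity"] == pytest.approx(9 / 12)
        assert per["q"]["sensitivity"] == pytest.approx(7 / 8)
        assert sens == pytest.approx(0.8125)

    def test_agrees_with_brute_force_from_labels(self, rng):
        names = ["a", "b", "c", "d"]
        y_true = rng.choice(names, size=200)
        y_pred = rng.choice(names, size=200)
        cm = confusion_matrix(y_true, y_pred, names)
        assert accuracy_from_cm(cm) == pytest.approx(
            np.mean(y_true == y_pred)
        )
        sens, _, per = macro_metrics(cm)
        for c in names:
            mask = y_true == c
            assert per[c]["sensitivity"] == pytest.approx(
                np.mean(y_pred[mask] == c)
            )
            tn = np.sum((y_true != c) & (y_pred != c))
            assert per[c]["specificity"] == pytest.approx(
                tn / np.sum(y_true != c)
            )

    def test_transcribed_rbf_matrix_macro_sensitivity(self):
        cm = ConfusionMatrix(tables.CONFUSION_ZCURVE_RBF, tables.CLASS_NAMES)
        sens, _, _ = macro_metrics(cm)
        assert sens == pytest.approx(0.9878, abs=5e-4)


class TestMse:
    def test_zero_when_equal(self, rng):
        y = rng.normal(size=(5, 3))
        assert mse_score(y, y) == 0.0

    def test_uniform_scores_closed_form(self):
        k = 14
        targets = np.zeros((1, k))
        targets[0, 0] = 1.0
        outputs = np.full((1, k), 1 / k)
        expected = ((13 / 14) ** 2 + 13 * (1 / 14) ** 2) / 14
        assert mse_score(targets, outputs) == pytest.approx(expected)
        assert expected == pytest.approx(0.06633, abs=5e-6)

    def test_quadratic_scaling(self, rng):
        t = rng.normal(size=(4, 2))
        o = rng.normal(size=(4, 2))
        assert mse_score(t, t + 2 * (o - t)) == pytest.approx(
            4 * mse_score(t, o)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_score(np.zeros((2, 3)), np.zeros((3, 2)))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        y = np.array(["a", "a", "b", "b"])
        out = roc_curves(scores, y, ["a", "b"])
        assert out["a"]["auc"] == 1.0
        assert out["b"]["auc"] == 1.0

    def test_constant_scores_give_half(self):
        scores = np.full((10, 2), 0.5)
        y = np.array(["a"] * 5 + ["b"] * 5)
        out = roc_curves(scores, y, ["a", "b"])
        assert out["a"]["auc"] == pytest.approx(0.5)

    def test_sign_flip_mirrors_auc(self, rng):
        scores = rng.normal(size=(30, 2))
        y = rng.choice(["a", "b"], size=30)
        if len(set(y)) < 2:
            y[0] = "a"; y[1] = "b"
        auc1 = roc_curves(scores, y, ["a", "b"])["a"]["auc"]
        auc2 = roc_curves(-scores, y, ["a", "b"])["a"]["auc"]
        assert auc1 == pytest.approx(1 - auc2)

    def test_degenerate_class_reported_missing(self):
        scores = np.ones((3, 2))
        y = np.array(["a", "a", "a"])
        out = roc_curves(scores, y, ["a", "b"])
        assert out["b"]["auc"] is None


class TestPairedTTest:
    def test_hand_example(self):
        r = paired_t_test([1, 2, 3], [1, 3, 5])
        assert r.mean_difference == pytest.approx(1.0)
        assert r.sd == pytest.approx(1.0)
        assert r.t == pytest.approx(np.sqrt(3))
        assert r.n == 3

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            r = paired_t_test(a, b)
            t_ref, p_ref = sps.ttest_rel(b, a)
            assert r.t == pytest.approx(t_ref, abs=1e-10)
            assert r.p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_zero_sd(self):
        r = paired_t_test([1.0, 2.0], [1.0, 2.0])
        assert r.degenerate and r.t == 0.0 and r.p == 1.0
        r2 = paired_t_test([1.0, 2.0], [2.0, 3.0])
        assert r2.degenerate and r2.p == 0.0

    def test_length_mismatch_and_n1(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestGeneCollapse:
    def test_class_to_gene(self):
        assert gene_of_class("TP53 Substitution") == "TP53"
        assert gene_of_class("Normal") == "Normal"

    def test_within_gene_confusion_not_penalised(self):
        y_true = ["TP53 Substitution", "TP53 Deletion", "Normal"]
        y_pred = ["TP53 Deletion", "TP53 Substitution", "Normal"]
        assert gene_level_accuracy(y_true, y_pred) == 1.0

    def test_normal_prediction_misses_mutant_recovery(self):
        y_true = ["TP53 Substitution", "EGFR Deletion", "Normal"]
        y_pred = ["Normal", "EGFR Substitution", "TP53 Deletion"]
        # normal sample excluded; TP53 mutant predicted Normal is a miss
        assert mutant_gene_recovery(y_true, y_pred) == pytest.approx(0.5)


@pytest.fixture(scope="module")
def tiny_results():
    """Models 3 and 1 on the scaled-down dataset with short windows."""
    from genomogram.imaging import ImagingConfig
    from conftest import small_config
    from genomogram.sequences import simulate_dataset

    ds = simulate_dataset(small_config(), seed=7)
    kw = dict(imaging=ImagingConfig(window=100, overlap=25),
              mlp=MlpConfig(hidden1=20, hidden2=20, epochs=150))
    r3 = run_experiment(3, ds, seed=7, **kw)
    r1 = run_experiment(1, ds, seed=7, **kw)
    return r3, r1


class TestExperimentRunner:
    def test_pipeline_assignments(self):
        from genomogram.evaluation import MODEL_PIPELINES

        assert MODEL_PIPELINES[3] == ("zcurve", "rbf")
        assert MODEL_PIPELINES[2] == ("tetrahedron", "mlp")

    def test_results_are_consistent(self, tiny_results):
        r3, _ = tiny_results
        assert isinstance(r3.network, RbfNetwork)
        assert r3.confusion.total == len(r3.y_true)
        assert r3.accuracy == pytest.approx(accuracy_from_cm(r3.confusion))
        assert 0.0 <= r3.gene_accuracy <= 1.0
        assert "accuracy" in r3.summary()

    def test_rbf_recovers_genes_on_tiny_dataset(self, tiny_results):
        r3, _ = tiny_results
        assert r3.gene_recovery >= 0.8

    def test_determinism(self, tiny_results):
        from genomogram.imaging import ImagingConfig
        from conftest import small_config
        from genomogram.sequences import simulate_dataset

        r3, _ = tiny_results
        ds = simulate_dataset(small_config(), seed=7)
        again = run_experiment(
            3, ds, seed=7, imaging=ImagingConfig(window=100, overlap=25)
        )
        assert np.array_equal(again.confusion.counts, r3.confusion.counts)
        assert again.accuracy == r3.accuracy

    def test_invalid_model_id(self, small_dataset):
        with pytest.raises(ValueError, match="model_id"):
            run_experiment(5, small_dataset)

    def test_eval_on_full_scores_whole_corpus(self):
        from genomogram.imaging import ImagingConfig
        from conftest import small_config
        from genomogram.sequences import simulate_dataset

        ds = simulate_dataset(small_config(), seed=7)
        res = ExperimentModel(
            ds, transform="zcurve", classifier="rbf",
            imaging=ImagingConfig(window=100, overlap=25), eval_on="full",
        ).fit(seed=7)
        assert res.confusion.total == len(ds)
        for j, cls in enumerate(ds.class_names):
            assert res.confusion.counts[:, j].sum() == ds.counts[cls]
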