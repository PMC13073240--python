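import numpy as np
import pytest

import scposition as sp
from scposition.classify import _report, stratified_split
from scposition.containers import ExpressionMatrix


def _separable(seed=0, n_per_class=100, n_genes=6):
    """3 linearly separable classes carried by 2 informative genes."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["A", "B", "C"], n_per_class)
    centers = {"A": (0, 0), "B": (4, 0), "C": (0, 4)}
    vals = rng.gamma(2, 0.5, (3 * n_per_class, n_genes))
    for i, lab in enumerate(labels):
        vals[i, 0] += centers[lab][0]
        vals[i, 1] += centers[lab][1]
    m = ExpressionMatrix(
        [f"c{i}" for i in range(len(labels))],
        [f"g{i}" for i in range(n_genes)],
        vals,
        layer="lognorm",
    )
    return m, sp.CellAnnotation(m.cell_ids, labels)


FAST = sp.TrainingConfig(seed=0, hidden_sizes=[16], max_epochs=60, batch_size=32)


class TestTrainPredict:
    def test_training_is_deterministic(self):
        m, ann = _separable()
        gs = sp.GeneSet("s", list(m.gene_ids))
        m1 = sp.train_position_model(m, ann, gs, FAST)
        m2 = sp.train_position_model(m, ann, gs, FAST)
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])
        np.testing.assert_array_equal(
            sp.predict(m1, m).probabilities, sp.predict(m2, m).probabilities
        )

    def test_separable_data_fits_well(self):
        m, ann = _separable()
        model = sp.train_position_model(m, ann, sp.GeneSet("s", list(m.gene_ids)), FAST)
        rep = sp.evaluate(sp.predict(model, m), ann)
        assert rep.overall_accuracy >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(5):
            m, ann = _separable(seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = sp.CellAnnotation(
                ann.cell_ids, rng.permutation(ann.compartment), label_set=ann.label_set
            )
            tr, te = stratified_split(shuffled.compartment, 0.8, rng)
            m_tr = m.subset_cells(np.isin(np.arange(m.n_cells), tr))
            m_te = m.subset_cells(np.isin(np.arange(m.n_cells), te))
            cfg = sp.TrainingConfig(seed=seed, hidden_sizes=[16], max_epochs=60, batch_size=32)
            model = sp.train_position_model(
                m_tr, shuffled.aligned_to(m_tr.cell_ids), sp.GeneSet("s", list(m.gene_ids)), cfg
            )
            rep = sp.evaluate(sp.predict(model, m_te), shuffled.aligned_to(m_te.cell_ids))
            accs.append(rep.overall_accuracy)
        assert 0.25 <= np.median(accs) <= 0.45

    def test_probabilities_normalized_and_finite(self, small_model, small_lognorm):
        lognorm, _, _ = small_lognorm
        pred = sp.predict(small_model, lognorm)
        assert np.isfinite(pred.probabilities).all()
        np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_all_zero_cell_yields_valid_probabilities(self, small_model):
        genes = small_model.gene_order
        m = ExpressionMatrix(["z"], genes, np.zeros((1, len(genes))), layer="lognorm")
        pred = sp.predict(small_model, m)
        assert np.isfinite(pred.probabilities).all()
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_gene_column_shuffle_invariance(self, small_model, small_lognorm):
        lognorm, _, _ = small_lognorm
        perm = np.random.default_rng(0).permutation(lognorm.n_genes)
        shuffled = ExpressionMatrix(
            lognorm.cell_ids, lognorm.gene_ids[perm], lognorm.values[:, perm], "lognorm"
        )
        np.testing.assert_array_equal(
            sp.predict(small_model, lognorm).probabilities,
            sp.predict(small_model, shuffled).probabilities,
        )

    def test_low_coverage_errors(self, small_model):
        genes = small_model.gene_order[: len(small_model.gene_order) // 3]
        m = ExpressionMatrix(["c"], genes, np.zeros((1, len(genes))), layer="lognorm")
        with pytest.raises(ValueError, match="covers only"):
            sp.predict(small_model, m)

    def test_single_class_training_rejected(self):
        m, ann = _separable()
        mono = sp.CellAnnotation(ann.cell_ids, ["A"] * ann.n_cells)
        with pytest.raises(ValueError, match="2 compartment"):
            sp.train_position_model(m, mono, sp.GeneSet("s", list(m.gene_ids)), FAST)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = np.array(["A", "B", "A"], dtype=object)
        probs = np.array([[0.9, 0.1], [0.1, 0.9], [0.8, 0.2]])
        rep = _report(truth, truth.copy(), probs, ["A", "B"])
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.per_class_auc.values())
        assert np.trace(rep.confusion.to_numpy()) == 3

    def test_count_oracle_accuracy(self):
        truth = np.array(list("AAABBBCCC"), dtype=object)
        pred = np.array(list("AAABBACBA"), dtype=object)  # exactly 6 of 9 correct
        probs = np.full((9, 3), 1 / 3)
        rep = _report(truth, pred, probs, ["A", "B", "C"])
        assert rep.overall_accuracy == pytest.approx(2 / 3, abs=1e-12)

    def test_confusion_row_sums_equal_class_counts(self, small_model, small_lognorm):
        lognorm, ann, _ = small_lognorm
        rep = sp.evaluate(sp.predict(small_model, lognorm), ann)
        import pandas as pd

        counts = pd.Series(ann.compartment).value_counts()
        for label in rep.confusion.index:
            assert rep.confusion.loc[label].sum() == counts[label]
        assert np.trace(rep.confusion.to_numpy()) / rep.n_cells == pytest.approx(
            rep.overall_accuracy
        )

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="outside model class order"):
            _report(
                np.array(["X"], dtype=object),
                np.array(["A"], dtype=object),
                np.array([[1.0, 0.0]]),
                ["A", "B"],
            )


class TestRepeatedHoldout:
    def test_single_repeat_matches_direct_evaluation(self):
        m, ann = _separable(n_per_class=40)
        gs = sp.GeneSet("s", list(m.gene_ids))
        rep = sp.repeated_holdout(m, ann, gs, FAST, n_repeats=1)
        rng = np.random.default_rng(FAST.seed)
        tr, te = stratified_split(ann.compartment, 0.8, rng)
        m_tr = m.subset_cells(np.isin(np.arange(m.n_cells), tr))
        m_te = m.subset_cells(np.isin(np.arange(m.n_cells), te))
        model = sp.train_position_model(m_tr, ann.aligned_to(m_tr.cell_ids), gs, FAST)
        direct = sp.evaluate(sp.predict(model, m_te), ann.aligned_to(m_te.cell_ids))
        assert rep.repeats["accuracies"] == [direct.overall_accuracy]
        assert rep.repeats["median"] == direct.overall_accuracy

    def test_repeat_distribution_summary(self):
        m, ann = _separable(n_per_class=40)
        rep = sp.repeated_holdout(
            m, ann, sp.GeneSet("s", list(m.gene_ids)), FAST, n_repeats=3
        )
        accs = np.array(rep.repeats["accuracies"])
        assert rep.repeats["median"] == np.median(accs)
        assert rep.repeats["sem"] == pytest.approx(accs.std(ddof=1) / np.sqrt(3))
        assert np.trace(rep.confusion.to_numpy()) / rep.n_cells == pytest.approx(
            rep.overall_accuracy
        )


class TestBaselines:
    def test_all_seven_models_present_and_separable_sanity(self):
        m, ann = _separable(n_per_class=50)
        reports = sp.train_baselines(m, ann, sp.GeneSet("s", list(m.gene_ids)), seed=0)
        assert set(reports) == set(sp.classify.BASELINE_NAMES)
        for name, rep in reports.items():
            assert rep.overall_accuracy >= 0.9, name

    def test_signal_free_data_scores_at_chance(self):
        rng = np.random.default_rng(0)
        n_per = 300
        vals = rng.gamma(2, 1, (3 * n_per, 8))
        m = ExpressionMatrix(
            [f"c{i}" for i in range(3 * n_per)],
            [f"g{i}" for i in range(8)],
            vals,
            layer="lognorm",
        )
        ann = sp.CellAnnotation(m.cell_ids, np.repeat(["A", "B", "C"], n_per))
        reports = sp.train_baselines(m, ann, sp.GeneSet("s", list(m.gene_ids)), seed=0)
        for name, rep in reports.items():
            assert 0.25 <= rep.overall_accuracy <= 0.45, name


class TestSimulatedDefaults:
    def test_selector_ordering_hvg_at_least_comparable(self):
        """The HVG selector transfers at least as well (within 0.05) as the
        marker-gene, RFE and mutual-information comparison selectors."""
        from scposition.protocols import selector_comparison

        runs = [selector_comparison(seed) for seed in range(3)]
        medians = {
            m: np.median([r[m] for r in runs]) for m in ("hvg", "fam", "rfe", "mir")
        }
        for other in ("fam", "rfe", "mir"):
            assert medians["hvg"] >= medians[other] - 0.05, medians

    def test_repeated_holdout_sem_is_small(self):
        from scposition.preprocess import log_normalize, qc_filter
        from scposition.simulate import SimConfig

        datasets, _ = sp.simulate(SimConfig(seed=4, n_datasets=1))
        m, ann = datasets[0]
        lognorm = log_normalize(qc_filter(m)[0])
        ann = ann.aligned_to(lognorm.cell_ids)
        geneset = sp.hvg_rank(lognorm, n_top=100)[0]
        rep = sp.repeated_holdout(
            lognorm, ann, geneset, sp.TrainingConfig(seed=4), n_repeats=5
        )
        assert rep.repeats["sem"] < 0.02


class TestCompareAccuracies:
    def test_identical_groups_and_worked_case(self):
        df = sp.compare_accuracies(
            [([1, 2, 3], [1, 2, 3]), ([1, 2, 3], [4, 5, 6])]
        )
        assert df["t"][0] == 0.0 and df["p"][0] == 1.0
        assert df["t"][1] == pytest.approx(-3.674, abs=1e-3)
        assert df["p"][1] == pytest.approx(0.0214, abs=1e-4)

    def test_bh_applied_across_batch(self):
        groups = [([0.0, 1.0], [0.0, 1.0])] * 4
        df = sp.compare_accuracies(groups)
        np.testing.assert_allclose(df["p_adj"], df["p"])
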