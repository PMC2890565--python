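import numpy as np
import pytest

from neighbourgo.evaluation import (
    ClassMetrics,
    ExperimentGrid,
    gene_level_accuracy,
    grouped_split_indices,
    instance_accuracy,
    mean_result,
    per_class_f,
    run_experiment,
    split_indices,
    split_instances,
)
from neighbourgo.instances import DatasetSpec, TrainingInstance
from neighbourgo.ensemble import BoostParams

from conftest import random_genome


def _inst(gene, aspect, term):
    return TrainingInstance(gene_aspect=aspect, class_term=term, gene_id=gene)


class TestSplit:
    def test_66_percent_of_100_gives_66_34(self):
        tr, te = split_indices(100, 0.66, np.random.default_rng(0))
        assert len(tr) == 66 and len(te) == 34
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(100))

    def test_same_seed_same_split(self):
        a = split_indices(50, 0.66, np.random.default_rng(7))
        b = split_indices(50, 0.66, np.random.default_rng(7))
        assert a[0].tolist() == b[0].tolist() and a[1].tolist() == b[1].tolist()

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_indices(10, 0.01, np.random.default_rng(0))  # empty train
        with pytest.raises(ValueError):
            split_indices(1, 0.66, np.random.default_rng(0))  # empty part at n=1

    def test_split_instances_partitions_the_dataset(self):
        rows = [_inst(f"g{i}", "P", "t") for i in range(10)]
        tr, te = split_instances(rows, 0.66, np.random.default_rng(1))
        assert len(tr) == 6 and len(te) == 4

    def test_grouped_split_keeps_gene_rows_together(self):
        gene_ids = [f"g{i // 3}" for i in range(30)]  # 10 genes x 3 rows
        tr, te = grouped_split_indices(gene_ids, 0.66, np.random.default_rng(2))
        tr_genes = {gene_ids[i] for i in tr}
        te_genes = {gene_ids[i] for i in te}
        assert not tr_genes & te_genes


class TestInstanceAccuracy:
    @pytest.mark.parametrize(
        "preds,truths,expected",
        [
            (list("aaaa"), list("aaaa"), 100.0),
            (list("aaaa"), list("bbbb"), 0.0),
            (list("aaab"), list("aaaa"), 75.0),
        ],
    )
    def test_percent_correct(self, preds, truths, expected):
        assert instance_accuracy(preds, truths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            instance_accuracy([], [])


class TestPerClassF:
    def test_perfect_predictions_give_unit_f(self):
        metrics, wf = per_class_f(list("abab"), list("abab"), ["a", "b"])
        assert all(m.f_measure == 1.0 for m in metrics) and wf == 1.0

    def test_counts_match_direct_arithmetic(self):
        # class "a": TP=3, FP=1, FN=2 -> p=0.75, r=0.6, f=2*.45/1.35
        preds = ["a", "a", "a", "a", "b", "b", "b"]
        truth = ["a", "a", "a", "b", "a", "a", "b"]
        metrics, _ = per_class_f(preds, truth, ["a", "b"])
        m = metrics[0]
        assert (m.true_positives, m.false_positives, m.false_negatives) == (3, 1, 2)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f_measure == pytest.approx(2 * 0.45 / 1.35)

    def test_absent_class_scores_zero_not_nan(self):
        metrics, _ = per_class_f(["a"], ["a"], ["a", "ghost"])
        ghost = metrics[1]
        assert ghost.precision == ghost.recall == ghost.f_measure == 0.0

    def test_weighted_f_is_support_weighted_mean(self):
        preds = ["a", "a", "b", "b", "b", "b"]
        truth = ["a", "b", "b", "b", "b", "b"]
        metrics, wf = per_class_f(preds, truth, ["a", "b"])
        supports = [m.support for m in metrics]
        expected = sum(m.support * m.f_measure for m in metrics) / sum(supports)
        assert wf == pytest.approx(expected)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(0)
        labels = ["a", "b", "c", "d"]
        truth = [labels[i] for i in rng.integers(0, 4, 200)]
        preds = [labels[i] for i in rng.integers(0, 4, 200)]
        metrics, wf = per_class_f(preds, truth, labels)
        p, r, f, s = precision_recall_fscore_support(
            truth, preds, labels=labels, zero_division=0
        )
        for i, m in enumerate(metrics):
            assert m.precision == pytest.approx(p[i])
            assert m.recall == pytest.approx(r[i])
            assert m.f_measure == pytest.approx(f[i])
            assert m.support == s[i]
        _, _, wf_sk, _ = precision_recall_fscore_support(
            truth, preds, labels=labels, average="weighted", zero_division=0
        )
        assert wf == pytest.approx(wf_sk)

    def test_micro_recall_equals_instance_accuracy(self):
        rng = np.random.default_rng(1)
        labels = ["a", "b", "c"]
        truth = [labels[i] for i in rng.integers(0, 3, 99)]
        preds = [labels[i] for i in rng.integers(0, 3, 99)]
        metrics, _ = per_class_f(preds, truth, labels)
        micro = sum(m.true_positives for m in metrics) / sum(
            m.true_positives + m.false_negatives for m in metrics
        )
        assert micro * 100 == pytest.approx(instance_accuracy(preds, truth))


class TestGeneLevelAccuracy:
    def test_single_correct_instance_makes_gene_correct(self):
        rows = [_inst("g1", "P", "t1")]
        assert gene_level_accuracy(rows, ["t1"]) == 100.0

    def test_uncovered_term_fails_the_gene(self):
        rows = [_inst("g1", "P", "t1"), _inst("g1", "P", "t2")]
        assert gene_level_accuracy(rows, ["t1", "t1"]) == 0.0

    def test_extra_predictions_do_not_penalize(self):
        rows = [_inst("g1", "P", "t1"), _inst("g1", "P", "t1")]
        assert gene_level_accuracy(rows, ["t1", "t3"]) == 100.0

    def test_exact_mode_penalizes_extras(self):
        rows = [_inst("g1", "P", "t1"), _inst("g1", "P", "t1")]
        assert gene_level_accuracy(rows, ["t1", "t3"], exact=True) == 0.0

    def test_aspect_matters_in_the_pair_sets(self):
        # correct term string predicted under the wrong aspect is not coverage
        rows = [_inst("g1", "P", "t1"), _inst("g1", "C", "t1")]
        assert gene_level_accuracy(rows, ["t1", "t1"]) == 100.0
        rows2 = [_inst("g1", "P", "t1"), _inst("g1", "C", "c1")]
        assert gene_level_accuracy(rows2, ["t1", "t1"]) == 0.0

    def test_untagged_instances_rejected(self):
        with pytest.raises(ValueError):
            gene_level_accuracy([TrainingInstance(gene_aspect="P", class_term="t")], ["t"])


@pytest.fixture(scope="module")
def genome():
    return random_genome(21, n_chromosomes=2, max_genes=12)


class TestRunExperiment:

    def test_single_run_average_equals_the_run(self, genome):
        exp = run_experiment(
            genome, DatasetSpec(k=1), BoostParams(T=2), runs=1, base_seed=5
        )
        assert exp.mean.instance_accuracy == exp.runs[0].instance_accuracy
        assert exp.mean.gene_accuracy == exp.runs[0].gene_accuracy

    def test_mean_result_averages_scalars(self):
        from neighbourgo.evaluation import RunResult

        r1 = ClassMetrics.from_counts("t", 1, 1, 1)

        a = RunResult(1, 10, 5, 80.0, 0.8, 60.0, (r1,))
        b = RunResult(2, 10, 5, 60.0, 0.6, 40.0, (r1,))
        m = mean_result([a, b])
        assert m.seed is None
        assert m.instance_accuracy == 70.0
        assert m.weighted_f == pytest.approx(0.7)
        assert m.gene_accuracy == 50.0

    def test_grid_cells_enumerate_the_cross_product(self):
        grid = ExperimentGrid(ks=(0, 2), scopes=("genome", "one"), include_location=(True, False))
        assert len(grid.cells()) == 8

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            ExperimentGrid(runs=0)
        with pytest.raises(ValueError):
            ExperimentGrid(train_fraction=1.5)
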