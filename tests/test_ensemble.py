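import numpy as np
import pytest
from scipy import stats

from neighbourgo.ensemble import (
    BoostParams,
    PERFECT_VOTE,
    adaboost_step,
    train_adaboost,
    train_multiboost,
    wagging_weights,
)
from neighbourgo.tree import grow_tree, prune_tree, tree_equal

from test_tree import make_dataset


def _noisy_dataset(seed, n=150, flip=0.25):
    """Two informative binary attributes + numeric, with label noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        a, b = rng.integers(2), rng.integers(2)
        label = (a ^ b) if rng.random() > flip else rng.integers(2)
        rows.append((str(a), str(b), float(rng.normal()), str(label)))
    return make_dataset(rows, ["a", "b", "v"], numeric=("v",))


class TestWaggingWeights:
    def test_single_instance_gets_weight_one(self):
        rng = np.random.default_rng(0)
        assert wagging_weights(1, rng).tolist() == [1.0]

    def test_rescaled_to_sum_n_and_positive(self):
        rng = np.random.default_rng(1)
        w = wagging_weights(1000, rng)
        assert w.sum() == pytest.approx(1000.0, abs=1e-9)
        assert (w > 0).all()

    def test_pre_rescale_distribution_is_exponential(self):
        # the raw draws are -ln U ~ Exponential(1); KS on a large sample
        rng = np.random.default_rng(2)
        u = 1.0 - rng.random(100_000)
        raw = -np.log(u)
        _, p = stats.kstest(raw, "expon")
        assert p > 0.01


class TestAdaboostStep:
    def test_separable_data_gives_perfect_reset(self):
        ds = make_dataset([("a", "x")] * 5 + [("b", "y")] * 5, ["f"])
        step = adaboost_step(ds, np.ones(10), BoostParams())
        assert step.status == "reset_perfect"
        assert step.vote == PERFECT_VOTE
        assert step.error == 0.0

    def test_balanced_labels_with_useless_feature_reset_fail(self):
        # a majority leaf on a 50/50 class mix has weighted error exactly 1/2
        rows = [("a", "0")] * 100 + [("a", "1")] * 100
        ds = make_dataset(rows, ["f"])
        step = adaboost_step(ds, np.ones(200), BoostParams())
        assert step.status == "reset_fail"
        assert step.tree is None

    def test_update_conserves_weight_sum(self):
        ds = _noisy_dataset(4)
        step = adaboost_step(ds, np.ones(len(ds)), BoostParams())
        assert step.status == "ok"
        assert 0 < step.error < 0.5
        assert step.weights.sum() == pytest.approx(len(ds), abs=1e-9)
        # misclassified instances were up-weighted
        miss = step.tree.predict_dataset(ds) != ds.y
        assert (step.weights[miss] > step.weights[~miss].min()).all()


class TestTrainMultiboost:
    def test_t1_committee_is_the_single_pruned_tree(self):
        ds = _noisy_dataset(5)
        committee = train_multiboost(ds, BoostParams(T=1, n_subcommittees=1), seed=0)
        assert len(committee.members) == 1
        solo = prune_tree(grow_tree(ds, np.ones(len(ds))), 0.25)
        assert tree_equal(committee.members[0][0].root, solo.root)

    def test_invalid_t_rejected(self):
        with pytest.raises(ValueError):
            BoostParams(T=0)

    def test_weight_sum_conserved_after_every_update(self):
        ds = _noisy_dataset(6)
        committee = train_multiboost(ds, BoostParams(T=10, n_subcommittees=3), seed=1)
        assert committee.weight_sums  # audited at every update and reset
        assert all(abs(s - len(ds)) < 1e-9 for s in committee.weight_sums)

    def test_identical_seed_gives_identical_committee(self):
        ds = _noisy_dataset(7)
        c1 = train_multiboost(ds, BoostParams(), seed=9)
        c2 = train_multiboost(ds, BoostParams(), seed=9)
        assert len(c1.members) == len(c2.members)
        for (t1, v1), (t2, v2) in zip(c1.members, c2.members):
            assert v1 == v2 and tree_equal(t1.root, t2.root)
        ds2 = _noisy_dataset(8)
        assert c1.predict_dataset(ds2).tolist() == c2.predict_dataset(ds2).tolist()

    def test_single_subcommittee_without_resets_is_adaboost(self):
        ds = _noisy_dataset(9, n=200)
        params = BoostParams(T=5, n_subcommittees=1)
        mb = train_multiboost(ds, params, seed=3)
        ab = train_adaboost(ds, params, seed=3)
        assert not mb.reset_iterations
        assert len(mb.members) == len(ab.members)
        for (t1, v1), (t2, v2) in zip(mb.members, ab.members):
            assert v1 == pytest.approx(v2)
            assert tree_equal(t1.root, t2.root)

    def test_boosting_does_not_hurt_training_error(self):
        # over many seeds, committee training error <= single-tree error (ties ok)
        wins = ties = losses = 0
        for seed in range(20):
            ds = _noisy_dataset(100 + seed, n=120)
            solo = prune_tree(grow_tree(ds, np.ones(len(ds))), 0.25)
            err_solo = (solo.predict_dataset(ds) != ds.y).mean()
            committee = train_multiboost(ds, BoostParams(), seed=seed)
            err_comm = (committee.predict_dataset(ds) != ds.y).mean()
            if err_comm < err_solo - 1e-12:
                wins += 1
            elif err_comm > err_solo + 1e-12:
                losses += 1
            else:
                ties += 1
        assert losses == 0, f"boosting raised training error in {losses}/20 runs"

    def test_separable_data_reaches_perfect_training_accuracy(self):
        ds = make_dataset(
            [("a", "l", "x")] * 6 + [("a", "r", "y")] * 6 + [("b", "l", "y")] * 6
            + [("b", "r", "x")] * 6,
            ["f", "g"],
        )
        committee = train_multiboost(ds, BoostParams(), seed=0)
        assert (committee.predict_dataset(ds) == ds.y).all()

    def test_scores_sum_member_votes(self):
        ds = _noisy_dataset(11)
        committee = train_multiboost(ds, BoostParams(T=3), seed=2)
        scores = committee.scores(ds.X_cat, ds.X_num)
        expected = np.zeros_like(scores)
        for tree, vote in committee.members:
            pred = tree.predict_dataset(ds)
            expected[np.arange(len(ds)), pred] += vote
        assert np.allclose(scores, expected)
        assert scores.sum() == pytest.approx(
            len(ds) * sum(v for _, v in committee.members)
        )
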