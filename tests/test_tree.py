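import math

import numpy as np
import pytest

from neighbourgo.tree import (
    Attribute,
    AttributeSchema,
    EncodedDataset,
    GrowParams,
    Leaf,
    entropy,
    evaluate_split,
    grow_tree,
    prune_tree,
    tree_equal,
)


def make_dataset(rows, attr_names, class_values=None, numeric=()):
    """Tiny helper: rows of (feature..., class) string/float tuples."""
    n_attrs = len(attr_names)
    cols = list(zip(*rows))
    attrs = []
    X_cat_cols, X_num_cols, cat_idx, num_idx = [], [], [], []
    for ai, name in enumerate(attr_names):
        if name in numeric:
            attrs.append(Attribute(name, "numeric"))
            X_num_cols.append(np.array([float("nan") if v is None else float(v) for v in cols[ai]]))
            num_idx.append(ai)
        else:
            vals = sorted({str(v) for v in cols[ai] if v is not None})
            if any(v is None for v in cols[ai]):
                vals.append("?")
            attrs.append(Attribute(name, "categorical", tuple(vals)))
            lookup = {v: i for i, v in enumerate(vals)}
            X_cat_cols.append(
                np.array([lookup["?" if v is None else str(v)] for v in cols[ai]], dtype=np.int64)
            )
            cat_idx.append(ai)
    classes = class_values or tuple(sorted({str(v) for v in cols[-1]}))
    schema = AttributeSchema(tuple(attrs), "class", tuple(classes))
    y = np.array([classes.index(str(v)) for v in cols[-1]], dtype=np.int64)
    X_cat = np.stack(X_cat_cols, axis=1) if X_cat_cols else np.empty((len(rows), 0), dtype=np.int64)
    X_num = np.stack(X_num_cols, axis=1) if X_num_cols else np.empty((len(rows), 0))
    return EncodedDataset(schema, X_cat, X_num, y, tuple(cat_idx), tuple(num_idx))


class TestEntropy:
    def test_single_class_is_zero_bits(self):
        assert entropy([7.0]) == 0.0

    def test_even_two_class_split_is_one_bit(self):
        assert entropy([5, 5]) == pytest.approx(1.0)

    def test_nine_five_matches_direct_formula(self):
        p1, p2 = 9 / 14, 5 / 14
        expected = -(p1 * math.log2(p1) + p2 * math.log2(p2))
        assert entropy([9, 5]) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_weights_undefined(self):
        with pytest.raises(ValueError):
            entropy([0.0, 0.0])


class TestEvaluateSplit:
    def test_attribute_identical_to_class_gains_parent_entropy(self):
        ds = make_dataset([("a", "x"), ("a", "x"), ("b", "y"), ("b", "y")], ["f"])
        ev = evaluate_split(ds, np.ones(4), "f")
        assert ev.usable
        assert ev.gain == pytest.approx(1.0)
        assert ev.gain_ratio == pytest.approx(1.0)

    def test_class_independent_attribute_is_unusable(self):
        ds = make_dataset(
            [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")], ["f"]
        )
        ev = evaluate_split(ds, np.ones(4), "f")
        assert not ev.usable and ev.gain == 0.0

    def test_constant_attribute_flagged_unusable(self):
        ds = make_dataset([("a", "x"), ("a", "y")], ["f"])
        assert not evaluate_split(ds, np.ones(2), "f").usable

    def test_numeric_threshold_at_midpoint_of_adjacent_values(self):
        ds = make_dataset(
            [(1.0, "x"), (2.0, "x"), (10.0, "y"), (11.0, "y")], ["v"], numeric=("v",)
        )
        ev = evaluate_split(ds, np.ones(4), "v")
        assert ev.usable
        assert ev.threshold == pytest.approx(6.0)
        assert ev.gain == pytest.approx(1.0)


class TestGrowTree:
    def test_pure_dataset_yields_single_leaf(self):
        ds = make_dataset([("a", "x"), ("b", "x")], ["f"])
        tree = grow_tree(ds, np.ones(2))
        assert isinstance(tree.root, Leaf)
        assert tree.predict_dataset(ds).tolist() == [0, 0]

    def test_xor_collapses_to_leaf_under_zero_gain_stopping(self):
        # both attributes have zero marginal information gain on XOR, so
        # greedy induction (like C4.5) stops at a majority leaf
        rows = [("0", "0", "n"), ("0", "1", "y"), ("1", "0", "y"), ("1", "1", "n")]
        ds = make_dataset(rows, ["a", "b"])
        tree = grow_tree(ds, np.ones(4), GrowParams(min_leaf_weight=1))
        assert isinstance(tree.root, Leaf)

    def test_conjunction_needs_depth_two_and_fits_perfectly(self):
        rows = [("0", "0", "n"), ("0", "1", "n"), ("1", "0", "n"), ("1", "1", "y")]
        ds = make_dataset(rows, ["a", "b"])
        tree = grow_tree(ds, np.ones(4), GrowParams(min_leaf_weight=1))
        assert (tree.predict_dataset(ds) == ds.y).all()
        depths = []

        def depth(node, d=0):
            if isinstance(node, Leaf):
                depths.append(d)
            else:
                for ch in node.children.values():
                    depth(ch, d + 1)

        depth(tree.root)
        assert max(depths) == 2

    def test_identical_features_mixed_classes_yield_majority_leaf(self):
        ds = make_dataset([("a", "x"), ("a", "x"), ("a", "y")], ["f"])
        tree = grow_tree(ds, np.ones(3))
        assert isinstance(tree.root, Leaf)
        assert tree.predict_dataset(ds).tolist() == [0, 0, 0]

    def test_weights_change_the_majority(self):
        ds = make_dataset([("a", "x"), ("a", "y")], ["f"])
        tree = grow_tree(ds, np.array([1.0, 3.0]))
        assert tree.predict_dataset(ds).tolist() == [1, 1]

    def test_deterministic_given_same_inputs(self):
        rng = np.random.default_rng(0)
        rows = [
            (str(rng.integers(2)), float(rng.normal()), str(rng.integers(3)))
            for _ in range(60)
        ]
        ds = make_dataset(rows, ["c", "v"], numeric=("v",))
        t1 = grow_tree(ds, np.ones(60))
        t2 = grow_tree(ds, np.ones(60))
        assert tree_equal(t1.root, t2.root)


class TestPruneTree:
    def test_same_class_children_collapse(self):
        # split has positive gain, but both children predict class "x"
        rows = [("a", "x")] * 3 + [("a", "y")] + [("b", "x")] * 4
        ds = make_dataset(rows, ["f"])
        tree = grow_tree(ds, np.ones(8))
        assert not isinstance(tree.root, Leaf)
        pruned = prune_tree(tree, 0.25)
        assert pruned.n_nodes() <= tree.n_nodes()
        assert isinstance(pruned.root, Leaf)

    def test_none_confidence_disables_pruning(self):
        rows = [("a", "x"), ("a", "x"), ("b", "y"), ("b", "y")]
        ds = make_dataset(rows, ["f"])
        tree = grow_tree(ds, np.ones(4))
        assert prune_tree(tree, None) is tree

    def test_pruning_never_grows_the_tree_on_noisy_data(self):
        rng = np.random.default_rng(1)
        rows = [
            (str(rng.integers(2)), str(rng.integers(2)), float(rng.normal()),
             str(rng.integers(2)))
            for _ in range(120)
        ]
        ds = make_dataset(rows, ["a", "b", "v"], numeric=("v",))
        tree = grow_tree(ds, np.ones(120))
        pruned = prune_tree(tree, 0.25)
        assert pruned.n_nodes() <= tree.n_nodes()


class TestMissingValueRouting:
    def test_unseen_category_routes_to_heaviest_branch(self):
        rows = [("a", "x")] * 5 + [("b", "y")] * 3
        ds = make_dataset(rows, ["f"])
        tree = grow_tree(ds, np.ones(8))
        # craft a dataset with an out-of-vocabulary code (-1)
        probe = EncodedDataset(
            ds.schema,
            np.array([[-1]], dtype=np.int64),
            np.empty((1, 0)),
            np.array([0], dtype=np.int64),
            ds.cat_attr_indices,
            ds.num_attr_indices,
        )
        assert tree.predict_dataset(probe).tolist() == [0]  # majority side = "x"

    def test_missing_numeric_follows_heavier_child(self):
        rows = [(1.0, "x")] * 6 + [(10.0, "y")] * 3
        ds = make_dataset(rows, ["v"], numeric=("v",))
        tree = grow_tree(ds, np.ones(9))
        probe = EncodedDataset(
            ds.schema,
            np.empty((1, 0), dtype=np.int64),
            np.array([[float("nan")]]),
            np.array([0], dtype=np.int64),
            ds.cat_attr_indices,
            ds.num_attr_indices,
        )
        assert tree.predict_dataset(probe).tolist() == [0]
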