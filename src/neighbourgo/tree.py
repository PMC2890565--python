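"""C4.5-style decision trees on weighted instances.

Attributes are either categorical (multiway split over the categories
observed at a node, with the missing-value literal ``?`` acting as a
first-class category) or numeric (binary split at the best midpoint
between adjacent distinct sorted values). The split attribute is chosen
by information gain or, by default, gain ratio — gain divided by the
split information — among attributes whose gain is positive and whose
split produces at least two sufficiently heavy branches. Growth stops
on class-pure nodes, nodes below the minimum leaf weight, or when no
usable split remains; pruning is bottom-up pessimistic-error pruning
(upper binomial confidence bound, default confidence 0.25).

Instance weights are first-class throughout: all counts, entropies and
error estimates are weighted, which is what lets boosting work by
reweighting rather than resampling.

Deviations from canonical C4.5, chosen for determinism: missing
categorical values form their own branch instead of being split
fractionally; missing numeric values are routed en bloc to the heavier
child; subtree raising is not performed; the average-gain pre-filter on
gain-ratio selection is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np
from scipy.stats import norm

MISSING = "?"
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Schema and encoding

@dataclass(frozen=True)
class Attribute:
    name: str
    kind: Literal["categorical", "numeric"]
    #: category vocabulary (categoricals only); includes "?" when missing occurs
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"{self.name}: categorical attribute needs a vocabulary")


@dataclass(frozen=True)
class AttributeSchema:
    """Feature attributes plus the single class attribute."""

    attributes: tuple[Attribute, ...]
    class_name: str
    class_values: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.class_values:
            raise ValueError("class vocabulary is empty")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names) or self.class_name in names:
            raise ValueError("attribute names must be unique and distinct from the class")

    @property
    def n_classes(self) -> int:
        return len(self.class_values)

    def attribute(self, name: str) -> tuple[int, Attribute]:
        for i, a in enumerate(self.attributes):
            if a.name == name:
                return i, a
        raise KeyError(name)


class EncodedDataset:
    """Column-encoded instances: int codes for categoricals, floats (NaN =
    missing) for numerics, int class codes. Rows align with the source
    instance list."""

    def __init__(
        self,
        schema: AttributeSchema,
        X_cat: np.ndarray,
        X_num: np.ndarray,
        y: np.ndarray,
        cat_attr_indices: tuple[int, ...],
        num_attr_indices: tuple[int, ...],
    ):
        self.schema = schema
        self.X_cat = X_cat
        self.X_num = X_num
        self.y = y
        self.cat_attr_indices = cat_attr_indices
        self.num_attr_indices = num_attr_indices
        # schema attribute index -> ("categorical", cat column) / ("numeric", num column)
        self.attr_column: dict[int, tuple[str, int]] = {}
        for col, ai in enumerate(cat_attr_indices):
            self.attr_column[ai] = ("categorical", col)
        for col, ai in enumerate(num_attr_indices):
            self.attr_column[ai] = ("numeric", col)

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            self.schema,
            self.X_cat[idx],
            self.X_num[idx],
            self.y[idx],
            self.cat_attr_indices,
            self.num_attr_indices,
        )


# ---------------------------------------------------------------------------
# Entropy and split evaluation

def entropy(weights) -> float:
    """Shannon entropy in bits of a weighted class distribution."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero weights")
    p = w[w > 0] / total
    return float(-(p * np.log2(p)).sum())


def _rows_entropy(M: np.ndarray, row_w: np.ndarray) -> np.ndarray:
    """Entropy (bits) of each row of a (rows, classes) weighted count matrix."""
    safe_w = np.where(row_w > 0, row_w, 1.0)
    P = M / safe_w[:, None]
    logP = np.log2(P, out=np.zeros_like(P), where=P > 0)
    return -(P * logP).sum(axis=1)


def _entropy_fast(w: np.ndarray) -> float:
    """entropy() without validation, for hot paths (assumes positive total)."""
    p = w[w > 0]
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class SplitEval:
    """Outcome of evaluating one attribute at one node."""

    attribute: str
    usable: bool
    gain: float = 0.0
    gain_ratio: float = 0.0
    #: numeric splits: the chosen threshold; categorical: None
    threshold: float | None = None
    description: str = ""


def _eval_categorical(codes, K, y, w, C, min_leaf, parent=None):
    M = np.bincount(codes * C + y, weights=w, minlength=K * C).reshape(K, C)
    cw = M.sum(axis=1)
    present = cw > 0
    if int(present.sum()) < 2 or int((cw >= min_leaf).sum()) < 2:
        return None
    W = cw.sum()
    h_children = _rows_entropy(M, cw)
    info = float((cw * h_children).sum() / W)
    if parent is None:
        parent = _entropy_fast(M.sum(axis=0))
    gain = parent - info
    split_info = _entropy_fast(cw[present])
    return gain, split_info, M, cw


def _eval_numeric(v, y, w, C, min_leaf):
    known = ~np.isnan(v)
    n_known = int(known.sum())
    if n_known < 2:
        return None
    vk, yk, wk = v[known], y[known], w[known]
    Wk = wk.sum()
    Wm = w[~known].sum()
    W = Wk + Wm
    if Wk <= 0:
        return None
    order = np.argsort(vk, kind="stable")
    vs, ys, ws = vk[order], yk[order], wk[order]
    cum = np.zeros((n_known, C))
    cum[np.arange(n_known), ys] = ws
    np.cumsum(cum, axis=0, out=cum)
    boundary = np.nonzero(vs[:-1] < vs[1:])[0]  # split between i and i+1
    if boundary.size == 0:
        return None
    L = cum[boundary]
    total = cum[-1]
    R = total - L
    lw = L.sum(axis=1)
    rw = R.sum(axis=1)
    valid = (lw >= min_leaf) & (rw >= min_leaf)
    if not valid.any():
        return None
    hl = _rows_entropy(L, lw)
    hr = _rows_entropy(R, rw)
    info = (lw * hl + rw * hr) / Wk
    parent_known = _entropy_fast(total)
    gains = np.where(valid, (Wk / W) * (parent_known - info), -np.inf)
    best = int(np.argmax(gains))
    gain = float(gains[best])
    thr = float((vs[boundary[best]] + vs[boundary[best] + 1]) / 2)
    # split info over the left/right branches (plus a missing branch when present)
    branch_w = [lw[best], rw[best]] + ([Wm] if Wm > 0 else [])
    split_info = _entropy_fast(np.asarray(branch_w))
    return gain, split_info, thr, lw[best] >= rw[best]


def evaluate_split(ds: EncodedDataset, weights: np.ndarray, attribute: str,
                   min_leaf_weight: float = 2.0) -> SplitEval:
    """Evaluate splitting the whole dataset on one attribute.

    Returns gain (bits), gain ratio and a split description; a constant
    attribute, or one whose best split leaves fewer than two branches of
    at least ``min_leaf_weight``, is flagged unusable with zero gain.
    """
    ai, attr = ds.schema.attribute(attribute)
    kind, col = ds.attr_column[ai]
    y = ds.y
    C = ds.schema.n_classes
    w = np.asarray(weights, dtype=float)
    if kind == "categorical":
        res = _eval_categorical(ds.X_cat[:, col], len(attr.categories), y, w, C, min_leaf_weight)
        if res is None:
            return SplitEval(attribute, usable=False)
        gain, split_info, _, _ = res
        if gain <= _EPS:
            return SplitEval(attribute, usable=False)
        return SplitEval(
            attribute, True, gain, gain / split_info if split_info > 0 else 0.0,
            None, f"multiway on {attribute}",
        )
    res = _eval_numeric(ds.X_num[:, col], y, w, C, min_leaf_weight)
    if res is None:
        return SplitEval(attribute, usable=False)
    gain, split_info, thr, _ = res
    if gain <= _EPS:
        return SplitEval(attribute, usable=False)
    return SplitEval(
        attribute, True, gain, gain / split_info if split_info > 0 else 0.0,
        thr, f"{attribute} <= {thr:g}",
    )


# ---------------------------------------------------------------------------
# Tree nodes

@dataclass
class Leaf:
    counts: np.ndarray  # weighted class counts at training time
    weight: float = field(init=False)
    dist: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weight = float(self.counts.sum())
        if self.weight > 0:
            self.dist = self.counts / self.weight
        else:  # empty leaf: uniform fallback (never produced by growth)
            self.dist = np.full(len(self.counts), 1.0 / len(self.counts))

    @property
    def prediction(self) -> int:
        return int(np.argmax(self.dist))


@dataclass
class CatSplit:
    attr_index: int
    cat_col: int
    children: dict[int, "Node"]
    default_code: int  # heaviest branch; routes unseen/absent-"?" codes
    counts: np.ndarray

    @property
    def weight(self) -> float:
        return float(self.counts.sum())


@dataclass
class NumSplit:
    attr_index: int
    num_col: int
    threshold: float
    left: "Node"
    right: "Node"
    missing_left: bool  # missing values follow the heavier child
    counts: np.ndarray

    @property
    def weight(self) -> float:
        return float(self.counts.sum())


Node = Leaf | CatSplit | NumSplit


@dataclass(frozen=True)
class GrowParams:
    min_leaf_weight: float = 2.0
    selection: Literal["gain", "gain_ratio"] = "gain_ratio"


@dataclass
class DecisionTree:
    root: Node
    schema: AttributeSchema

    def predict_batch(self, X_cat: np.ndarray, X_num: np.ndarray) -> np.ndarray:
        """Predicted class codes for encoded rows."""
        n = len(X_cat)
        out = np.empty(n, dtype=np.int64)
        _route(self.root, np.arange(n), X_cat, X_num, out)
        return out

    def predict_dataset(self, ds: EncodedDataset) -> np.ndarray:
        return self.predict_batch(ds.X_cat, ds.X_num)

    def n_nodes(self) -> int:
        return sum(1 for _ in iter_nodes(self.root))

    def n_leaves(self) -> int:
        return sum(1 for nd in iter_nodes(self.root) if isinstance(nd, Leaf))

    def dump(self) -> str:
        """Human-readable indented text rendering."""
        lines: list[str] = []
        _dump(self.root, self.schema, lines, "")
        return "\n".join(lines)


def iter_nodes(node: Node) -> Iterator[Node]:
    yield node
    if isinstance(node, CatSplit):
        for code in sorted(node.children):
            yield from iter_nodes(node.children[code])
    elif isinstance(node, NumSplit):
        yield from iter_nodes(node.left)
        yield from iter_nodes(node.right)


def _dump(node: Node, schema: AttributeSchema, lines: list[str], indent: str) -> None:
    if isinstance(node, Leaf):
        cls = schema.class_values[node.prediction]
        lines.append(f"{indent}-> {cls} ({node.weight:g})")
        return
    if isinstance(node, CatSplit):
        attr = schema.attributes[node.attr_index]
        for code in sorted(node.children):
            lines.append(f"{indent}{attr.name} = {attr.categories[code]}:")
            _dump(node.children[code], schema, lines, indent + "    ")
        return
    attr = schema.attributes[node.attr_index]
    lines.append(f"{indent}{attr.name} <= {node.threshold:g}:")
    _dump(node.left, schema, lines, indent + "    ")
    lines.append(f"{indent}{attr.name} > {node.threshold:g}:")
    _dump(node.right, schema, lines, indent + "    ")


def tree_equal(a: Node, b: Node) -> bool:
    """Structural equality of two trees (splits, thresholds, leaf counts)."""
    if type(a) is not type(b):
        return False
    if isinstance(a, Leaf):
        return np.allclose(a.counts, b.counts)
    if isinstance(a, CatSplit):
        return (
            a.attr_index == b.attr_index
            and a.default_code == b.default_code
            and set(a.children) == set(b.children)
            and all(tree_equal(a.children[c], b.children[c]) for c in a.children)
        )
    assert isinstance(a, NumSplit)
    return (
        a.attr_index == b.attr_index
        and np.isclose(a.threshold, b.threshold)
        and a.missing_left == b.missing_left
        and tree_equal(a.left, b.left)
        and tree_equal(a.right, b.right)
    )


# ---------------------------------------------------------------------------
# Growth

def grow_tree(
    ds: EncodedDataset,
    weights: np.ndarray,
    params: GrowParams = GrowParams(),
) -> DecisionTree:
    """Top-down recursive induction on weighted instances."""
    if len(ds) == 0:
        raise ValueError("cannot grow a tree on an empty dataset")
    w = np.asarray(weights, dtype=float)
    if w.shape != ds.y.shape:
        raise ValueError("weights must align with instances")
    C = ds.schema.n_classes
    used_cat = np.zeros(len(ds.schema.attributes), dtype=bool)
    root = _grow(ds, np.arange(len(ds)), w, used_cat, C, params)
    return DecisionTree(root=root, schema=ds.schema)


def _node_counts(y, w, C):
    return np.bincount(y, weights=w, minlength=C)


def _grow(ds, idx, w, used_cat, C, params) -> Node:
    y = ds.y[idx]
    wi = w[idx]
    counts = _node_counts(y, wi, C)
    W = counts.sum()
    # a split needs >= 2 branches of min_leaf_weight, so below twice that
    # no attribute can be usable and the node is a leaf immediately
    if W < 2 * params.min_leaf_weight or (counts > 0).sum() <= 1:
        return Leaf(counts=counts)

    # restrict to the classes present at this node: deep nodes see few of
    # the global classes and every evaluation below scales with that count
    present = counts > 0
    remap = np.cumsum(present) - 1
    y_local = remap[y]
    CL = int(present.sum())
    parent_h = _entropy_fast(counts[present])

    best = None  # (criterion value, attr_index, kind, payload)
    for ai, attr in enumerate(ds.schema.attributes):
        kind, col = ds.attr_column[ai]
        if kind == "categorical":
            if used_cat[ai]:
                continue
            res = _eval_categorical(
                ds.X_cat[idx, col], len(attr.categories), y_local, wi, CL,
                params.min_leaf_weight, parent=parent_h,
            )
            if res is None:
                continue
            gain, split_info, M, cw = res
            if gain <= _EPS:
                continue
            crit = gain / split_info if params.selection == "gain_ratio" and split_info > 0 else gain
            cand = (crit, ai, "categorical", (col, cw))
        else:
            res = _eval_numeric(ds.X_num[idx, col], y_local, wi, CL, params.min_leaf_weight)
            if res is None:
                continue
            gain, split_info, thr, missing_left = res
            if gain <= _EPS:
                continue
            crit = gain / split_info if params.selection == "gain_ratio" and split_info > 0 else gain
            cand = (crit, ai, "numeric", (col, thr, missing_left))
        if best is None or cand[0] > best[0] + _EPS:
            best = cand

    if best is None:
        return Leaf(counts=counts)

    _, ai, kind, payload = best
    if kind == "categorical":
        col, cw = payload
        codes = ds.X_cat[idx, col]
        used_cat = used_cat.copy()
        used_cat[ai] = True
        children: dict[int, Node] = {}
        for code in np.nonzero(cw > 0)[0]:
            sub = idx[codes == code]
            children[int(code)] = _grow(ds, sub, w, used_cat, C, params)
        default_code = int(np.argmax(cw))
        return CatSplit(
            attr_index=ai, cat_col=col, children=children,
            default_code=default_code, counts=counts,
        )
    col, thr, missing_left = payload
    v = ds.X_num[idx, col]
    nan = np.isnan(v)
    go_left = (v <= thr) | (nan & missing_left)
    left = _grow(ds, idx[go_left], w, used_cat, C, params)
    right = _grow(ds, idx[~go_left], w, used_cat, C, params)
    return NumSplit(
        attr_index=ai, num_col=col, threshold=thr,
        left=left, right=right, missing_left=missing_left, counts=counts,
    )


# ---------------------------------------------------------------------------
# Pessimistic-error pruning

_Z_CACHE: dict[float, float] = {}


def _z_of(cf: float) -> float:
    z = _Z_CACHE.get(cf)
    if z is None:
        z = _Z_CACHE[cf] = float(norm.ppf(1.0 - cf))
    return z


def _add_errs(N: float, e: float, cf: float) -> float:
    """Extra errors granted by the upper binomial confidence bound
    (the C4.5 pessimistic-error correction, continuity-corrected)."""
    if N <= 0:
        return 0.0
    if e == 0.0:
        return N * (1.0 - cf ** (1.0 / N))
    if e < 1.0:
        base = N * (1.0 - cf ** (1.0 / N))
        return base + e * (_add_errs(N, 1.0, cf) - base)
    if e + 0.5 >= N:
        return max(N - e, 0.0)
    z = _z_of(cf)
    f = (e + 0.5) / N
    r = (f + z * z / (2 * N) + z * np.sqrt(f / N - f * f / N + z * z / (4 * N * N))) / (
        1 + z * z / N
    )
    return r * N - e


def _leaf_estimate(counts: np.ndarray, cf: float) -> float:
    W = float(counts.sum())
    e = W - float(counts.max()) if W > 0 else 0.0
    return e + _add_errs(W, e, cf)


def _prune(node: Node, cf: float) -> tuple[Node, float]:
    if isinstance(node, Leaf):
        return node, _leaf_estimate(node.counts, cf)
    if isinstance(node, CatSplit):
        pruned = {}
        subtree_est = 0.0
        for code, child in node.children.items():
            pc, est = _prune(child, cf)
            pruned[code] = pc
            subtree_est += est
        leaf_est = _leaf_estimate(node.counts, cf)
        if leaf_est <= subtree_est:
            return Leaf(counts=node.counts), leaf_est
        return (
            CatSplit(node.attr_index, node.cat_col, pruned, node.default_code, node.counts),
            subtree_est,
        )
    assert isinstance(node, NumSplit)
    left, le = _prune(node.left, cf)
    right, re_ = _prune(node.right, cf)
    subtree_est = le + re_
    leaf_est = _leaf_estimate(node.counts, cf)
    if leaf_est <= subtree_est:
        return Leaf(counts=node.counts), leaf_est
    return (
        NumSplit(node.attr_index, node.num_col, node.threshold, left, right,
                 node.missing_left, node.counts),
        subtree_est,
    )


def prune_tree(tree: DecisionTree, confidence: Optional[float] = 0.25) -> DecisionTree:
    """Bottom-up pessimistic pruning; ``confidence=None`` disables pruning."""
    if confidence is None:
        return tree
    if not 0 < confidence <= 0.5:
        raise ValueError("pruning confidence must lie in (0, 0.5]")
    root, _ = _prune(tree.root, confidence)
    return DecisionTree(root=root, schema=tree.schema)


# ---------------------------------------------------------------------------
# Prediction routing

def _route(node: Node, idx: np.ndarray, X_cat, X_num, out: np.ndarray) -> None:
    if idx.size == 0:
        return
    if isinstance(node, Leaf):
        out[idx] = node.prediction
        return
    if isinstance(node, CatSplit):
        codes = X_cat[idx, node.cat_col]
        handled = np.zeros(idx.size, dtype=bool)
        for code, child in node.children.items():
            m = codes == code
            if m.any():
                _route(child, idx[m], X_cat, X_num, out)
                handled |= m
        if not handled.all():
            # unseen category / missing with no "?" branch -> heaviest branch
            _route(node.children[node.default_code], idx[~handled], X_cat, X_num, out)
        return
    v = X_num[idx, node.num_col]
    nan = np.isnan(v)
    go_left = (v <= node.threshold) | (nan & node.missing_left)
    _route(node.left, idx[go_left], X_cat, X_num, out)
    _route(node.right, idx[~go_left], X_cat, X_num, out)
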