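"""MultiBoost committees of C4.5-style trees.

MultiBoosting runs AdaBoost.M1 in contiguous sub-committees: the T
boosting iterations are cut into n sub-committees, and at every
sub-committee boundary the instance weights are re-randomized by
wagging (each weight drawn from the continuous Exponential(1)
distribution via w = −ln u, then rescaled to sum n), giving the
variance reduction of bagging on top of boosting's bias reduction.
Within a sub-committee, standard AdaBoost reweighting applies: a tree
is grown and pruned on the weighted instances, its weighted training
error ε gives the member its vote log((1−ε)/ε), and misclassified
instances are up-weighted by (1−ε)/ε before renormalizing the weights
to sum n. Degenerate iterations reset the weights by wagging: a perfect
tree (ε = 0) is kept with a large capped vote, a useless one (ε ≥ 1/2)
is discarded. The base learner always sees every instance with its
weight — reweighting, never resampling.

With one sub-committee and no degenerate iterations the procedure *is*
AdaBoost.M1 (no wagging draw ever happens), which
:func:`train_adaboost` exposes directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .tree import DecisionTree, EncodedDataset, GrowParams, grow_tree, prune_tree

logger = logging.getLogger(__name__)

#: vote assigned to a perfect (ε = 0) member: large but finite
PERFECT_VOTE = math.log(1e10)

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class BoostParams:
    """Learner configuration, defaults mirroring the usual MultiBoost/J48 setup."""

    T: int = 10
    n_subcommittees: int = 3
    pruning_confidence: Optional[float] = 0.25
    min_leaf_weight: float = 2.0
    selection: Literal["gain", "gain_ratio"] = "gain_ratio"

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_subcommittees < 1:
            raise ValueError("n_subcommittees must be >= 1")

    @property
    def grow(self) -> GrowParams:
        return GrowParams(min_leaf_weight=self.min_leaf_weight, selection=self.selection)


@dataclass
class Committee:
    """Weighted-vote committee of decision trees."""

    members: list[tuple[DecisionTree, float]]
    params: BoostParams
    seed: int | None = None
    #: Σ weights after every update/reset, for the conservation audit
    weight_sums: list[float] = field(default_factory=list)
    #: iterations (1-based) at which a wagging reset occurred
    reset_iterations: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a committee needs at least one member")

    def scores(self, X_cat: np.ndarray, X_num: np.ndarray) -> np.ndarray:
        """(n, n_classes) matrix of summed member votes."""
        schema = self.members[0][0].schema
        out = np.zeros((len(X_cat), schema.n_classes))
        rows = np.arange(len(X_cat))
        for tree, vote in self.members:
            pred = tree.predict_batch(X_cat, X_num)
            out[rows, pred] += vote
        return out

    def predict_codes(self, X_cat: np.ndarray, X_num: np.ndarray) -> np.ndarray:
        """Class codes maximizing the vote sum (ties: class vocabulary order)."""
        return np.argmax(self.scores(X_cat, X_num), axis=1)

    def predict_dataset(self, ds: EncodedDataset) -> np.ndarray:
        return self.predict_codes(ds.X_cat, ds.X_num)

    def predict_terms(self, ds: EncodedDataset) -> list[str]:
        schema = self.members[0][0].schema
        return [schema.class_values[c] for c in self.predict_dataset(ds)]


@dataclass
class StepResult:
    tree: DecisionTree | None
    vote: float | None
    weights: np.ndarray | None  # updated weights (None on reset)
    status: Literal["ok", "reset_perfect", "reset_fail"]
    error: float


def wagging_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Continuous Poisson-style wagging weights: −ln U, rescaled to sum n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = 1.0 - rng.random(n)  # uniform on (0, 1]
    w = -np.log(u)
    return w * (n / w.sum())


def adaboost_step(
    ds: EncodedDataset,
    weights: np.ndarray,
    params: BoostParams,
) -> StepResult:
    """One AdaBoost.M1 iteration on weighted instances.

    Grows and prunes a tree, computes its weighted training error ε and
    either returns the updated (renormalized) weights, or signals a
    reset: ``reset_perfect`` keeps the tree with the capped vote,
    ``reset_fail`` discards it.
    """
    n = len(ds)
    w = np.asarray(weights, dtype=float)
    tree = prune_tree(grow_tree(ds, w, params.grow), params.pruning_confidence)
    miss = tree.predict_dataset(ds) != ds.y
    eps = float(w[miss].sum() / w.sum())
    if eps <= 0.0:
        return StepResult(tree, PERFECT_VOTE, None, "reset_perfect", eps)
    if eps >= 0.5:
        return StepResult(None, None, None, "reset_fail", eps)
    vote = math.log((1.0 - eps) / eps)
    w_new = w.copy()
    w_new[miss] *= (1.0 - eps) / eps
    w_new *= n / w_new.sum()
    return StepResult(tree, vote, w_new, "ok", eps)


def _subcommittee_starts(T: int, n_sub: int) -> set[int]:
    """1-based iterations that open a new sub-committee (excluding t=1)."""
    return {math.ceil(j * T / n_sub) + 1 for j in range(1, n_sub)} - {1}


def train_multiboost(
    ds: EncodedDataset,
    params: BoostParams = BoostParams(),
    seed: int = 0,
) -> Committee:
    """Train a MultiBoost committee: AdaBoost sub-committees with wagging resets."""
    n = len(ds)
    rng = np.random.default_rng(seed)
    starts = _subcommittee_starts(params.T, params.n_subcommittees)
    w = np.ones(n)
    members: list[tuple[DecisionTree, float]] = []
    weight_sums: list[float] = []
    resets: list[int] = []
    for t in range(1, params.T + 1):
        if t in starts:
            w = wagging_weights(n, rng)
            weight_sums.append(float(w.sum()))
            resets.append(t)
        step = adaboost_step(ds, w, params)
        if step.status == "ok":
            members.append((step.tree, step.vote))
            w = step.weights
        else:
            if step.status == "reset_perfect":
                members.append((step.tree, step.vote))
            logger.debug("iteration %d: ε=%.4f, %s", t, step.error, step.status)
            w = wagging_weights(n, rng)
            resets.append(t)
        weight_sums.append(float(w.sum()))
    if not members:
        # every iteration failed (ε >= 0.5 throughout): fall back to the
        # single pruned tree on uniform weights so prediction stays defined
        tree = prune_tree(grow_tree(ds, np.ones(n), params.grow), params.pruning_confidence)
        members = [(tree, 1.0)]
        logger.warning("no boosting iteration produced a usable member; using one plain tree")
    return Committee(members=members, params=params, seed=seed,
                     weight_sums=weight_sums, reset_iterations=resets)


def train_adaboost(
    ds: EncodedDataset,
    params: BoostParams = BoostParams(),
    seed: int = 0,
) -> Committee:
    """Plain AdaBoost.M1 (stops at a degenerate iteration)."""
    n = len(ds)
    w = np.ones(n)
    members: list[tuple[DecisionTree, float]] = []
    weight_sums: list[float] = []
    for _ in range(params.T):
        step = adaboost_step(ds, w, params)
        if step.status == "ok":
            members.append((step.tree, step.vote))
            w = step.weights
            weight_sums.append(float(w.sum()))
            continue
        if step.status == "reset_perfect":
            members.append((step.tree, step.vote))
        break
    if not members:
        tree = prune_tree(grow_tree(ds, np.ones(n), params.grow), params.pruning_confidence)
        members = [(tree, 1.0)]
    return Committee(members=members, params=params, seed=seed, weight_sums=weight_sums)
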