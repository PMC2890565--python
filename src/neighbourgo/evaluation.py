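"""Evaluation metrics and the repeated-holdout experiment protocol.

Each experiment cell (neighbourhood size k, scope, location ablation
flag) is evaluated by randomizing the instance order, putting the first
66% of instances in the training part and the rest in the test part,
training a MultiBoost committee and measuring: the percentage of
correctly classified instances, per-term precision/recall/F-measure
(F = 2pr/(p+r)) with their support-weighted mean, and the gene-level
accuracy — a test gene counts as correctly classified only when *all*
of its GO Slim terms were predicted among its test instances (coverage;
extra predictions are not penalized, exact set equality is available as
an option). Cells are averaged over ten randomized runs by default.

The split is instance-level, exactly as the protocol states: sibling
rows of one gene can land on both sides, so instance-level numbers are
optimistic about generalization to unseen genes. A gene-level split
mode (`grouped=True`) keeps each gene's rows together for an honest
variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome
from .instances import DatasetSpec, TrainingInstance
from .ensemble import BoostParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class ClassMetrics:
    term: str
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f_measure: float
    support: int

    @classmethod
    def from_counts(cls, term: str, tp: int, fp: int, fn: int) -> "ClassMetrics":
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(term, tp, fp, fn, p, r, f, support=tp + fn)


def instance_accuracy(predictions: Sequence[str], truths: Sequence[str]) -> float:
    """Percentage of correctly classified instances."""
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be equal-length and non-empty")
    correct = sum(p == t for p, t in zip(predictions, truths))
    return 100.0 * correct / len(truths)


def per_class_f(
    predictions: Sequence[str],
    truths: Sequence[str],
    class_values: Sequence[str],
) -> tuple[list[ClassMetrics], float]:
    """Per-class precision/recall/F plus the support-weighted mean F."""
    if len(predictions) != len(truths):
        raise ValueError("length mismatch")
    per_class: list[ClassMetrics] = []
    for c in class_values:
        tp = sum(p == c and t == c for p, t in zip(predictions, truths))
        fp = sum(p == c and t != c for p, t in zip(predictions, truths))
        fn = sum(p != c and t == c for p, t in zip(predictions, truths))
        per_class.append(ClassMetrics.from_counts(c, tp, fp, fn))
    total_support = sum(m.support for m in per_class)
    weighted_f = (
        sum(m.support * m.f_measure for m in per_class) / total_support
        if total_support else 0.0
    )
    return per_class, weighted_f


def gene_level_accuracy(
    test_instances: Sequence[TrainingInstance],
    predictions: Sequence[str],
    exact: bool = False,
) -> float:
    """Percentage of test genes with all their (aspect, term) labels predicted.

    A gene's true set is the set of (gene aspect, class term) pairs over
    its test instances; its predicted set pairs each instance's gene
    aspect with the predicted term. Correct means true ⊆ predicted
    (or equality with ``exact=True``). Genes with no test instance are
    outside the denominator.
    """
    if len(test_instances) != len(predictions):
        raise ValueError("length mismatch")
    true_sets: dict[str, set] = {}
    pred_sets: dict[str, set] = {}
    for inst, pred in zip(test_instances, predictions):
        if inst.gene_id is None:
            raise ValueError("gene-level accuracy needs gene_id-tagged instances")
        true_sets.setdefault(inst.gene_id, set()).add((inst.gene_aspect, inst.class_term))
        pred_sets.setdefault(inst.gene_id, set()).add((inst.gene_aspect, pred))
    if not true_sets:
        raise ValueError("no test genes")
    correct = 0
    for gid, truth in true_sets.items():
        pred = pred_sets[gid]
        correct += (truth == pred) if exact else truth <= pred
    return 100.0 * correct / len(true_sets)


# ---------------------------------------------------------------------------
# Splitting

def split_indices(n: int, fraction: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random permutation; first ⌊fraction·n⌋ indices train, rest test."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n_train = int(fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} leaves an empty train or test part (n={n})")
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def split_instances(
    dataset: Sequence[TrainingInstance],
    fraction: float,
    rng: np.random.Generator,
) -> tuple[list[TrainingInstance], list[TrainingInstance]]:
    """Instance-level random holdout split (the default protocol)."""
    tr, te = split_indices(len(dataset), fraction, rng)
    return [dataset[i] for i in tr], [dataset[i] for i in te]


def grouped_split_indices(
    gene_ids: Sequence[str], fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-level holdout: all rows of one gene land on the same side."""
    genes = list(dict.fromkeys(gene_ids))
    n_train_genes = int(fraction * len(genes))
    if n_train_genes == 0 or n_train_genes == len(genes):
        raise ValueError("fraction leaves an empty train or test part at the gene level")
    perm = rng.permutation(len(genes))
    train_genes = {genes[i] for i in perm[:n_train_genes]}
    ids = np.arange(len(gene_ids))
    mask = np.array([g in train_genes for g in gene_ids])
    return ids[mask], ids[~mask]


# ---------------------------------------------------------------------------
# Run results

@dataclass(frozen=True)
class RunResult:
    """Metrics of one randomized train/test run (or a mean over runs)."""

    seed: Optional[int]
    n_train: int
    n_test: int
    instance_accuracy: float  # percent
    weighted_f: float
    gene_accuracy: float  # percent
    per_term: tuple[ClassMetrics, ...] = ()

    def as_row(self) -> dict:
        return {
            "run_seed": "mean" if self.seed is None else self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "instance_accuracy_pct": self.instance_accuracy,
            "weighted_f": self.weighted_f,
            "gene_accuracy_pct": self.gene_accuracy,
        }


def mean_result(runs: Sequence[RunResult]) -> RunResult:
    """Arithmetic mean over runs; per-term metrics averaged term-wise."""
    if not runs:
        raise ValueError("no runs to average")
    terms: dict[str, list[ClassMetrics]] = {}
    for r in runs:
        for m in r.per_term:
            terms.setdefault(m.term, []).append(m)
    mean_terms = tuple(
        ClassMetrics(
            term=t,
            true_positives=int(round(np.mean([m.true_positives for m in ms]))),
            false_positives=int(round(np.mean([m.false_positives for m in ms]))),
            false_negatives=int(round(np.mean([m.false_negatives for m in ms]))),
            precision=float(np.mean([m.precision for m in ms])),
            recall=float(np.mean([m.recall for m in ms])),
            f_measure=float(np.mean([m.f_measure for m in ms])),
            support=int(round(np.mean([m.support for m in ms]))),
        )
        for t, ms in sorted(terms.items())
    )
    return RunResult(
        seed=None,
        n_train=int(round(np.mean([r.n_train for r in runs]))),
        n_test=int(round(np.mean([r.n_test for r in runs]))),
        instance_accuracy=float(np.mean([r.instance_accuracy for r in runs])),
        weighted_f=float(np.mean([r.weighted_f for r in runs])),
        gene_accuracy=float(np.mean([r.gene_accuracy for r in runs])),
        per_term=mean_terms,
    )


# ---------------------------------------------------------------------------
# Experiment grid

@dataclass(frozen=True)
class ExperimentGrid:
    """The full experiment sweep: k × scope × ablation, repeated runs."""

    ks: tuple[int, ...] = (0, 1, 2, 5)
    scopes: tuple[str, ...] = ("genome",)
    include_location: tuple[bool, ...] = (True,)
    runs: int = 10
    train_fraction: float = 0.66
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def cells(self) -> list[DatasetSpec]:
        return [
            DatasetSpec(k=k, scope=s, include_location=loc)
            for s in self.scopes
            for k in self.ks
            for loc in self.include_location
        ]


@dataclass
class ExperimentResult:
    spec: DatasetSpec
    runs: list[RunResult]
    mean: RunResult = field(init=False)

    def __post_init__(self) -> None:
        self.mean = mean_result(self.runs)


def run_experiment(
    genome: AnnotatedGenome,
    spec: DatasetSpec,
    params: BoostParams = BoostParams(),
    runs: int = 10,
    train_fraction: float = 0.66,
    base_seed: int = 0,
    grouped: bool = False,
) -> ExperimentResult:
    """Average `runs` randomized holdout runs of one experiment cell."""
    from .model import GeneFunctionModel  # deferred: model builds on this module

    model = GeneFunctionModel(genome, spec, params)
    results = [
        model.fit(seed=base_seed + i, train_fraction=train_fraction, grouped=grouped).run_result
        for i in range(1, runs + 1)
    ]
    return ExperimentResult(spec=spec, runs=results)


def sweep(
    genome: AnnotatedGenome,
    grid: ExperimentGrid,
    params: BoostParams = BoostParams(),
    term_aspects: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell; returns (results table, per-term table).

    The results table has one row per run plus a "mean" row per cell;
    the per-term table holds the across-run mean per-term metrics.
    Cells whose scope holds no instances are skipped with a warning.
    """
    if term_aspects is None:
        term_aspects = term_aspect_map(genome)
    result_rows: list[dict] = []
    term_rows: list[dict] = []
    for cell_index, spec in enumerate(grid.cells()):
        base = grid.base_seed + 10_000 * cell_index
        try:
            exp = run_experiment(
                genome, spec, params,
                runs=grid.runs, train_fraction=grid.train_fraction, base_seed=base,
            )
        except ValueError as exc:
            logger.warning("skipping cell %s: %s", spec, exc)
            continue
        cell = {"scope": spec.scope, "k": spec.k, "include_location": spec.include_location}
        for rr in exp.runs + [exp.mean]:
            result_rows.append({**cell, **rr.as_row()})
        for m in exp.mean.per_term:
            term_rows.append(
                {
                    **cell,
                    "aspect": term_aspects.get(m.term, "?"),
                    "term": m.term,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f": m.f_measure,
                    "support": m.support,
                }
            )
    return pd.DataFrame(result_rows), pd.DataFrame(term_rows)


def term_aspect_map(genome: AnnotatedGenome) -> dict[str, str]:
    """GO Slim term -> aspect, from the genome's annotations."""
    out: dict[str, str] = {}
    for anns in genome.annotations.values():
        for a in anns:
            out.setdefault(a.term, a.aspect)
    return out
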