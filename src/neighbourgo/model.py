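"""Model/Results interface over the classification pipeline.

:class:`GeneFunctionModel` holds the data side of one experiment cell —
an annotated genome plus a :class:`~neighbourgo.instances.DatasetSpec`
(neighbourhood size k, scope, location ablation) — and builds the
long-format instance table and its encoding once, lazily.  Each call to
:meth:`~GeneFunctionModel.fit` performs one randomized holdout run:
split, train a MultiBoost committee of C4.5-style trees, score the test
part, and return a :class:`GeneFunctionResults` carrying the committee,
the predictions and all metrics, with a ``summary()`` table.

    >>> model = GeneFunctionModel(genome, DatasetSpec(k=2))
    >>> res = model.fit(seed=1)
    >>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .encoding import encode_instances
from .ensemble import BoostParams, Committee, train_multiboost
from .evaluation import (
    RunResult,
    gene_level_accuracy,
    grouped_split_indices,
    instance_accuracy,
    per_class_f,
    split_indices,
)
from .genome import AnnotatedGenome
from .instances import DatasetSpec, TrainingInstance, build_dataset
from .io import (
    FeatureDialect,
    GO_SLIM_DIALECT,
    MappingDialect,
    SGD_FEATURES_DIALECT,
    parse_gene_features,
    parse_go_slim,
)
from .tree import AttributeSchema, EncodedDataset


class GeneFunctionModel:
    """GO Slim term classification from gene location and neighbour context."""

    def __init__(
        self,
        genome: AnnotatedGenome,
        spec: DatasetSpec,
        params: BoostParams = BoostParams(),
    ):
        self.genome = genome
        self.spec = spec
        self.params = params
        self._instances: list[TrainingInstance] | None = None
        self._encoded: EncodedDataset | None = None

    @classmethod
    def from_files(
        cls,
        features_path,
        go_slim_path,
        spec: DatasetSpec,
        params: BoostParams = BoostParams(),
        feature_dialect: FeatureDialect = SGD_FEATURES_DIALECT,
        mapping_dialect: MappingDialect = GO_SLIM_DIALECT,
        keep_unannotated: bool = False,
    ) -> "GeneFunctionModel":
        features, _ = parse_gene_features(features_path, feature_dialect)
        annotations, _ = parse_go_slim(go_slim_path, mapping_dialect)
        genome = AnnotatedGenome.build(features, annotations, keep_unannotated=keep_unannotated)
        return cls(genome, spec, params)

    @property
    def instances(self) -> list[TrainingInstance]:
        if self._instances is None:
            self._instances = build_dataset(self.genome, self.spec)
            if not self._instances:
                raise ValueError(f"no instances in scope {self.spec.scope!r}")
        return self._instances

    @property
    def encoded(self) -> EncodedDataset:
        if self._encoded is None:
            self._encoded = encode_instances(self.instances)
        return self._encoded

    @property
    def schema(self) -> AttributeSchema:
        return self.encoded.schema

    def fit(
        self,
        seed: int = 0,
        train_fraction: float = 0.66,
        grouped: bool = False,
    ) -> "GeneFunctionResults":
        """One randomized holdout run; all randomness derives from ``seed``."""
        ss = np.random.SeedSequence(seed)
        split_state, train_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        rng = np.random.default_rng(split_state)
        enc = self.encoded
        if grouped:
            tr, te = grouped_split_indices(
                [i.gene_id for i in self.instances], train_fraction, rng
            )
        else:
            tr, te = split_indices(len(enc), train_fraction, rng)
        committee = train_multiboost(enc.take(tr), self.params, seed=train_seed)
        test_instances = [self.instances[i] for i in te]
        predictions = committee.predict_terms(enc.take(te))
        truths = [i.class_term for i in test_instances]
        per_term, weighted_f = per_class_f(predictions, truths, enc.schema.class_values)
        run = RunResult(
            seed=seed,
            n_train=len(tr),
            n_test=len(te),
            instance_accuracy=instance_accuracy(predictions, truths),
            weighted_f=weighted_f,
            gene_accuracy=gene_level_accuracy(test_instances, predictions),
            per_term=tuple(per_term),
        )
        return GeneFunctionResults(
            model=self,
            committee=committee,
            run_result=run,
            train_indices=tr,
            test_indices=te,
            predictions=predictions,
        )


@dataclass
class GeneFunctionResults:
    """Fitted committee plus holdout metrics for one run."""

    model: GeneFunctionModel
    committee: Committee
    run_result: RunResult
    train_indices: np.ndarray
    test_indices: np.ndarray
    predictions: list[str] = field(repr=False)

    def predict(self, instances: list[TrainingInstance]) -> list[str]:
        """Predicted GO Slim terms for new instances (same schema)."""
        enc = encode_instances(instances, schema=self.model.schema)
        return self.committee.predict_terms(enc)

    def summary(self) -> str:
        spec = self.model.spec
        rr = self.run_result
        lines = [
            "GO Slim Neighbourhood Classification Results",
            "=" * 52,
            f"{'Scope:':<28}{spec.scope}",
            f"{'Neighbourhood size k:':<28}{spec.k}",
            f"{'Location attributes:':<28}{'included' if spec.include_location else 'removed'}",
            f"{'Committee members:':<28}{len(self.committee.members)}",
            f"{'Boost iterations (T):':<28}{self.model.params.T}",
            f"{'Sub-committees:':<28}{self.model.params.n_subcommittees}",
            f"{'Run seed:':<28}{rr.seed}",
            f"{'Train / test instances:':<28}{rr.n_train} / {rr.n_test}",
            "-" * 52,
            f"{'Instance accuracy:':<28}{rr.instance_accuracy:.2f} %",
            f"{'Weighted F-measure:':<28}{rr.weighted_f:.4f}",
            f"{'Gene-level accuracy:':<28}{rr.gene_accuracy:.2f} %",
            "=" * 52,
        ]
        return "\n".join(lines)
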