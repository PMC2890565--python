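"""Bridge between long-format instances and the learner's encoded arrays.

The attribute layout mirrors the instance CSV column order; which blocks
are present follows the instances themselves (k = 0 rows carry no
neighbour block, ablated rows no location block). Categorical
vocabularies are the observed values plus ``?`` whenever a value is
missing; the class vocabulary is the sorted set of observed GO Slim
terms across all three aspects combined.
"""

from __future__ import annotations

import numpy as np

from .instances import TrainingInstance
from .tree import Attribute, AttributeSchema, EncodedDataset

MISSING = "?"

CLASS_NAME = "GO Slim term"

_LOCATION_FIELDS = (
    ("Chromosome Number", "chromosome", "categorical"),
    ("Start", "start", "numeric"),
    ("Stop", "stop", "numeric"),
    ("Strand", "strand", "categorical"),
)
_NEIGHBOUR_FIELDS = (
    ("Neighbour number", "neighbour_number", "categorical"),
    ("Neighbour strand", "neighbour_strand", "categorical"),
    ("Distance", "distance", "numeric"),
    ("Neighbour GO aspect", "neighbour_aspect", "categorical"),
    ("Neighbour GO Slim term", "neighbour_term", "categorical"),
)
_GENE_FIELDS = (("GO aspect", "gene_aspect", "categorical"),)


def _field_layout(instances: list[TrainingInstance]):
    first = instances[0]
    layout = []
    if first.has_location:
        layout += _LOCATION_FIELDS
    if first.has_neighbour_block:
        layout += _NEIGHBOUR_FIELDS
    layout += _GENE_FIELDS
    return layout


def build_schema(instances: list[TrainingInstance]) -> AttributeSchema:
    if not instances:
        raise ValueError("cannot build a schema from zero instances")
    layout = _field_layout(instances)
    attrs: list[Attribute] = []
    for name, attr_field, kind in layout:
        if kind == "numeric":
            attrs.append(Attribute(name=name, kind="numeric"))
            continue
        values = {getattr(i, attr_field) for i in instances}
        has_missing = None in values
        values.discard(None)
        cats = sorted(str(v) for v in values)
        if has_missing:
            cats.append(MISSING)
        if not cats:
            cats = [MISSING]
        attrs.append(Attribute(name=name, kind="categorical", categories=tuple(cats)))
    class_values = tuple(sorted({i.class_term for i in instances}))
    return AttributeSchema(attributes=tuple(attrs), class_name=CLASS_NAME,
                           class_values=class_values)


def encode_instances(
    instances: list[TrainingInstance],
    schema: AttributeSchema | None = None,
) -> EncodedDataset:
    """Encode instances against a schema (built from them if not given).

    With an explicit schema, categorical values outside the vocabulary
    encode as the ``?`` code when present, else -1 (prediction routes
    those like missing values); an unseen class term is an error.
    """
    if not instances:
        raise ValueError("cannot encode zero instances")
    if schema is None:
        schema = build_schema(instances)
    layout = _field_layout(instances)
    if len(layout) != len(schema.attributes) or any(
        l[0] != a.name for l, a in zip(layout, schema.attributes)
    ):
        raise ValueError("instance layout does not match the schema")

    n = len(instances)
    cat_cols: list[np.ndarray] = []
    num_cols: list[np.ndarray] = []
    cat_attr_indices: list[int] = []
    num_attr_indices: list[int] = []
    for ai, ((name, attr_field, kind), attr) in enumerate(zip(layout, schema.attributes)):
        if kind == "numeric":
            col = np.array(
                [np.nan if (v := getattr(i, attr_field)) is None else float(v) for i in instances]
            )
            num_cols.append(col)
            num_attr_indices.append(ai)
        else:
            lookup = {c: k for k, c in enumerate(attr.categories)}
            fallback = lookup.get(MISSING, -1)
            col = np.array(
                [
                    fallback if (v := getattr(i, attr_field)) is None
                    else lookup.get(str(v), fallback)
                    for i in instances
                ],
                dtype=np.int64,
            )
            cat_cols.append(col)
            cat_attr_indices.append(ai)

    class_lookup = {c: k for k, c in enumerate(schema.class_values)}
    try:
        y = np.array([class_lookup[i.class_term] for i in instances], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"class term {exc} not in schema vocabulary") from None

    X_cat = np.stack(cat_cols, axis=1) if cat_cols else np.empty((n, 0), dtype=np.int64)
    X_num = np.stack(num_cols, axis=1) if num_cols else np.empty((n, 0))
    return EncodedDataset(
        schema, X_cat, X_num, y,
        tuple(cat_attr_indices), tuple(num_attr_indices),
    )
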