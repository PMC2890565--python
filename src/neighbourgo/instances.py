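"""Long-format training instances.

Each gene is expanded into one row per (neighbour rank, neighbour
annotation, gene annotation) combination: the class label is the gene's
own GO Slim term, the features are the gene's location block
(chromosome, start, stop, strand — optional, the ablation toggle), the
neighbour block (rank, strand, midpoint distance, neighbour GO aspect
and GO Slim term) and the gene's GO aspect. A neighbour with no known
annotation still contributes rows, with its GO fields missing; a rank
beyond the chromosome's gene count contributes rows with the whole
neighbour block missing except the rank itself. Missing values
serialize as the literal ``?``.

With neighbourhood size k = 0 (the no-neighbour baseline) a gene
contributes exactly one row per annotation and the rows carry no
neighbour block at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .genome import (
    AnnotatedGenome,
    CHROMOSOME_LABELS,
    GeneFeature,
    GoSlimAnnotation,
    sort_annotations,
)
from .neighbourhood import Neighbourhood, k_nearest

logger = logging.getLogger(__name__)

GENOME_SCOPE = "genome"


@dataclass(frozen=True)
class TrainingInstance:
    """One long-format row: features plus the class label.

    ``gene_id`` is bookkeeping for gene-level evaluation; it is not a
    training attribute, is not serialized, and does not participate in
    equality.
    """

    gene_aspect: str
    class_term: str
    chromosome: str | None = None
    start: int | None = None
    stop: int | None = None
    strand: str | None = None
    neighbour_number: int | None = None
    neighbour_strand: str | None = None
    distance: float | None = None
    neighbour_aspect: str | None = None
    neighbour_term: str | None = None
    gene_id: str | None = field(default=None, compare=False)

    @property
    def has_location(self) -> bool:
        return self.chromosome is not None

    @property
    def has_neighbour_block(self) -> bool:
        """True for rows built with k > 0 (rank is set even for absent neighbours)."""
        return self.neighbour_number is not None


@dataclass(frozen=True)
class DatasetSpec:
    """What dataset to build: neighbourhood size, scope, ablation flag."""

    k: int
    scope: str = GENOME_SCOPE
    include_location: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("neighbourhood size k must be >= 0")
        if self.scope != GENOME_SCOPE and self.scope not in CHROMOSOME_LABELS:
            raise ValueError(f"scope must be 'genome' or a chromosome label, got {self.scope!r}")


def expand_instances(
    gene: GeneFeature,
    gene_annotations: list[GoSlimAnnotation],
    neighbourhood: Neighbourhood,
    neighbour_annotations_by_id: dict[str, list[GoSlimAnnotation]],
    spec: DatasetSpec,
) -> list[TrainingInstance]:
    """Expand one gene into its long-format rows.

    Row order: neighbour rank, then neighbour annotation (aspect C, F, P,
    term lexicographic), then gene annotation (same order) — the order
    the instance-file example prints.
    """
    gene_annotations = sort_annotations(gene_annotations)
    if not gene_annotations:
        return []

    loc: dict = {}
    if spec.include_location:
        loc = dict(
            chromosome=gene.chromosome, start=gene.start, stop=gene.stop, strand=gene.strand
        )

    def gene_rows(**neighbour_fields) -> list[TrainingInstance]:
        return [
            TrainingInstance(
                gene_aspect=ann.aspect,
                class_term=ann.term,
                gene_id=gene.gene_id,
                **loc,
                **neighbour_fields,
            )
            for ann in gene_annotations
        ]

    if spec.k == 0:
        return gene_rows()

    out: list[TrainingInstance] = []
    for rank in range(1, spec.k + 1):
        if rank <= len(neighbourhood.neighbours):
            nb = neighbourhood.neighbours[rank - 1]
            nb_anns = sort_annotations(neighbour_annotations_by_id.get(nb.neighbour_id, []))
            positional = dict(
                neighbour_number=rank,
                neighbour_strand=nb.neighbour_strand,
                distance=nb.distance,
            )
            if nb_anns:
                for nb_ann in nb_anns:
                    out.extend(
                        gene_rows(
                            **positional,
                            neighbour_aspect=nb_ann.aspect,
                            neighbour_term=nb_ann.term,
                        )
                    )
            else:
                # Neighbour exists but its GO Slim terms are unknown:
                # keep strand/distance, leave the GO fields missing.
                out.extend(gene_rows(**positional))
        else:
            # No rank-r gene on this chromosome at all.
            out.extend(gene_rows(neighbour_number=rank))
    return out


def build_dataset(genome: AnnotatedGenome, spec: DatasetSpec) -> list[TrainingInstance]:
    """Expand every annotated gene in scope, in deterministic order.

    Gene order: chromosome, start, gene id. Genes without annotations are
    never expanded (they can still appear as neighbours).
    """
    if not genome.genes:
        raise ValueError("genome is empty")
    genes = genome.annotated_genes()
    if spec.scope != GENOME_SCOPE:
        genes = [g for g in genes if g.chromosome == spec.scope]
        if not genes:
            logger.warning("scope %r contains no annotated genes", spec.scope)
            return []
    out: list[TrainingInstance] = []
    skipped = 0
    for gene in genes:
        anns = genome.annotations_for(gene.gene_id)
        if not anns:
            skipped += 1
            continue
        nbh = k_nearest(genome, gene.gene_id, spec.k)
        out.extend(expand_instances(gene, anns, nbh, genome.annotations, spec))
    if skipped:
        logger.info("skipped %d genes with no annotations", skipped)
    return out


def strip_location(instances: list[TrainingInstance]) -> list[TrainingInstance]:
    """Drop the four location attributes from every row (ablation helper)."""
    return [
        replace(i, chromosome=None, start=None, stop=None, strand=None) for i in instances
    ]


def expected_instance_count(
    genome: AnnotatedGenome, spec: DatasetSpec
) -> int:
    """Closed-form row count: Σ_genes a·max(1, Σ_r max(m_r, 1)) (k=0: Σ a)."""
    genes = genome.annotated_genes()
    if spec.scope != GENOME_SCOPE:
        genes = [g for g in genes if g.chromosome == spec.scope]
    total = 0
    for gene in genes:
        a = len(genome.annotations_for(gene.gene_id))
        if spec.k == 0:
            total += a
            continue
        nbh = k_nearest(genome, gene.gene_id, spec.k)
        per_rank = 0
        for rank in range(1, spec.k + 1):
            if rank <= len(nbh.neighbours):
                m = len(genome.annotations_for(nbh.neighbours[rank - 1].neighbour_id))
                per_rank += max(m, 1)
            else:
                per_rank += 1
        total += a * per_rank
    return total
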