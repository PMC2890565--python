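"""k-nearest gene neighbourhoods by midpoint distance.

A gene's neighbours are the other genes on the *same* chromosome, from
either strand and either direction, ranked by the absolute distance
between gene midpoints (bp). Rank 1 is the closest neighbour. Distance
ties are broken deterministically: upstream (lower midpoint) before
downstream, then Watson before Crick, then gene id. Chromosomes with
fewer than k other genes yield short lists; neighbour lists never cross
chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import AnnotatedGenome, GeneFeature


class UnknownGeneError(KeyError):
    """Unknown gene id."""


def midpoint(gene: GeneFeature) -> float:
    """Gene midpoint in bp: (start + stop) / 2, regardless of strand."""
    return (gene.start + gene.stop) / 2


@dataclass(frozen=True)
class NeighbourRef:
    """A ranked neighbour of a focal gene."""

    rank: int
    neighbour_id: str
    neighbour_strand: str
    distance: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class Neighbourhood:
    """Ordered neighbour list of one gene (possibly shorter than k)."""

    gene_id: str
    neighbours: tuple[NeighbourRef, ...]

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbours):
            if nb.rank != i + 1:
                raise ValueError("neighbour ranks must be consecutive from 1")
            if i and nb.distance < self.neighbours[i - 1].distance:
                raise ValueError("neighbour distances must be non-decreasing with rank")


def k_nearest(genome: AnnotatedGenome, gene_id: str, k: int) -> Neighbourhood:
    """The k nearest same-chromosome genes of ``gene_id`` by |Δmidpoint|.

    Candidates come from both strands and both directions, merged into a
    single ranking. Ties: upstream first, then strand W before C, then
    lexicographic gene id.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    focal = genome.genes.get(gene_id)
    if focal is None:
        raise UnknownGeneError(gene_id)
    if k == 0:
        return Neighbourhood(gene_id=gene_id, neighbours=())
    fm = midpoint(focal)
    candidates = [g for g in genome.genes_on(focal.chromosome) if g.gene_id != gene_id]

    def key(g: GeneFeature):
        gm = midpoint(g)
        return (
            abs(gm - fm),
            0 if gm < fm else 1,           # upstream (lower midpoint) first
            0 if g.strand == "W" else 1,   # Watson before Crick
            g.gene_id,
        )

    candidates.sort(key=key)
    refs = tuple(
        NeighbourRef(
            rank=i + 1,
            neighbour_id=g.gene_id,
            neighbour_strand=g.strand,
            distance=abs(midpoint(g) - fm),
        )
        for i, g in enumerate(candidates[:k])
    )
    return Neighbourhood(gene_id=gene_id, neighbours=refs)


def neighbour_table(genome: AnnotatedGenome, k: int):
    """All neighbourhoods as a tidy table (debug dump).

    Returns a pandas DataFrame with columns
    (gene_id, rank, neighbour_id, neighbour_strand, distance).
    """
    import pandas as pd

    rows = []
    for chrom in genome.chromosomes():
        for gene in genome.genes_on(chrom):
            for nb in k_nearest(genome, gene.gene_id, k).neighbours:
                rows.append(
                    (gene.gene_id, nb.rank, nb.neighbour_id, nb.neighbour_strand, nb.distance)
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "rank", "neighbour_id", "neighbour_strand", "distance"]
    )
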