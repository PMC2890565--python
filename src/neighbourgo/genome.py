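"""Domain types for annotated genomes.

Genes live on one of seventeen chromosomes (``"one"`` .. ``"seventeen"``,
the last being the mitochondrial chromosome) with 1-based start/stop
coordinates and a strand: ``"W"`` (Watson) genes run 5'→3' left to right
(start < stop), ``"C"`` (Crick) genes are stored with start > stop, the
SGD coordinate convention.

GO Slim annotations assign a gene a high-level Gene Ontology term in one
of the three aspects: cellular component (``"C"``), biological process
(``"P"``) or molecular function (``"F"``). A gene typically carries
several annotations across aspects, which is what makes the
classification problem multi-label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Chromosome vocabulary; index i holds the word label of chromosome i+1.
CHROMOSOME_LABELS: tuple[str, ...] = (
    "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen",
    "fifteen", "sixteen", "seventeen",
)

MITOCHONDRIAL_LABEL = "seventeen"

ASPECTS: tuple[str, ...] = ("C", "P", "F")

#: Ordering used when a gene's annotations are listed (aspect C, F, P then
#: term lexicographic) — the order the instance file prints rows in.
ASPECT_SORT_ORDER: dict[str, int] = {"C": 0, "F": 1, "P": 2}

STRANDS: tuple[str, ...] = ("W", "C")

_MITO_ALIASES = {"17", "chrmt", "mito", "mt", "chrmito", "seventeen"}


class GenomeError(ValueError):
    """Invalid genome data."""


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to its word form (``"one"``..``"seventeen"``).

    Accepts arabic numerals ``"1"``..``"17"``, the word forms themselves,
    and common mitochondrial aliases (``chrmt``, ``Mito``, ``17``).

    Raises :class:`GenomeError` for anything outside the 17-chromosome
    vocabulary (e.g. the 2-micron plasmid).
    """
    s = str(label).strip().lower()
    if s in CHROMOSOME_LABELS:
        return s
    if s in _MITO_ALIASES:
        return MITOCHONDRIAL_LABEL
    if s.isdigit():
        n = int(s)
        if 1 <= n <= len(CHROMOSOME_LABELS):
            return CHROMOSOME_LABELS[n - 1]
    raise GenomeError(f"unrecognized chromosome label: {label!r}")


def chromosome_index(label: str) -> int:
    """0-based index of a word-form chromosome label (for sorting)."""
    return CHROMOSOME_LABELS.index(label)


@dataclass(frozen=True)
class GeneFeature:
    """One gene's coordinates and strand on a chromosome."""

    gene_id: str
    chromosome: str
    start: int
    stop: int
    strand: str

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOME_LABELS:
            raise GenomeError(
                f"{self.gene_id}: chromosome {self.chromosome!r} not in vocabulary"
            )
        if self.strand not in STRANDS:
            raise GenomeError(f"{self.gene_id}: strand must be W or C, got {self.strand!r}")
        if self.start == self.stop:
            raise GenomeError(f"{self.gene_id}: start == stop ({self.start})")
        if self.strand == "W" and not self.start < self.stop:
            raise GenomeError(f"{self.gene_id}: Watson gene requires start < stop")
        if self.strand == "C" and not self.start > self.stop:
            raise GenomeError(f"{self.gene_id}: Crick gene requires start > stop")

    @property
    def midpoint(self) -> float:
        """Midpoint coordinate in bp, (start + stop) / 2; strand-independent."""
        return (self.start + self.stop) / 2


@dataclass(frozen=True)
class GoSlimAnnotation:
    """One (gene, aspect, GO Slim term) assignment."""

    gene_id: str
    aspect: str
    term: str

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise GenomeError(f"{self.gene_id}: aspect must be one of C/P/F, got {self.aspect!r}")
        if not self.term:
            raise GenomeError(f"{self.gene_id}: empty GO Slim term")

    @property
    def sort_key(self) -> tuple[int, str]:
        return (ASPECT_SORT_ORDER[self.aspect], self.term)


def sort_annotations(annotations: list[GoSlimAnnotation]) -> list[GoSlimAnnotation]:
    """Deterministic annotation order: aspect C, F, P, then term lexicographic."""
    return sorted(annotations, key=lambda a: a.sort_key)


@dataclass
class AnnotatedGenome:
    """A set of genes joined with their GO Slim annotations.

    Annotations referencing unknown genes are dropped (with a logged
    count). Genes with zero annotations are dropped by default; with
    ``keep_unannotated=True`` they are retained as neighbour candidates
    but are never themselves expanded into training instances.
    """

    genes: dict[str, GeneFeature]
    annotations: dict[str, list[GoSlimAnnotation]]
    n_dropped_genes: int = 0
    n_orphan_annotations: int = 0
    _by_chromosome: dict[str, list[GeneFeature]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @classmethod
    def build(
        cls,
        features: list[GeneFeature],
        annotations: list[GoSlimAnnotation],
        keep_unannotated: bool = False,
    ) -> "AnnotatedGenome":
        genes = {f.gene_id: f for f in features}
        ann_map: dict[str, list[GoSlimAnnotation]] = {}
        orphans = 0
        for ann in annotations:
            if ann.gene_id not in genes:
                orphans += 1
                continue
            ann_map.setdefault(ann.gene_id, []).append(ann)
        for gid in ann_map:
            ann_map[gid] = sort_annotations(ann_map[gid])
        dropped = 0
        if not keep_unannotated:
            unann = [gid for gid in genes if gid not in ann_map]
            dropped = len(unann)
            for gid in unann:
                del genes[gid]
        if orphans:
            logger.info("dropped %d annotations for unknown genes", orphans)
        if dropped:
            logger.info("dropped %d genes with no GO Slim annotation", dropped)
        return cls(
            genes=genes,
            annotations=ann_map,
            n_dropped_genes=dropped,
            n_orphan_annotations=orphans,
        )

    def annotations_for(self, gene_id: str) -> list[GoSlimAnnotation]:
        return self.annotations.get(gene_id, [])

    def chromosomes(self) -> list[str]:
        present = {g.chromosome for g in self.genes.values()}
        return [c for c in CHROMOSOME_LABELS if c in present]

    def genes_on(self, chromosome: str) -> list[GeneFeature]:
        """Genes on one chromosome, sorted by midpoint (ties by gene_id)."""
        cached = self._by_chromosome.get(chromosome)
        if cached is None:
            cached = sorted(
                (g for g in self.genes.values() if g.chromosome == chromosome),
                key=lambda g: (g.midpoint, g.gene_id),
            )
            self._by_chromosome[chromosome] = cached
        return cached

    def annotated_genes(self) -> list[GeneFeature]:
        """Genes with ≥1 annotation, in (chromosome, start, gene_id) order."""
        return sorted(
            (g for gid, g in self.genes.items() if gid in self.annotations),
            key=lambda g: (chromosome_index(g.chromosome), g.start, g.gene_id),
        )

    def __len__(self) -> int:
        return len(self.genes)
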