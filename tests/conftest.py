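"""Shared fixtures: the printed worked example and small random genomes."""

from __future__ import annotations

import numpy as np
import pytest

from neighbourgo.genome import AnnotatedGenome, GeneFeature, GoSlimAnnotation
from neighbourgo.instances import TrainingInstance


@pytest.fixture
def table1_genome() -> AnnotatedGenome:
    """A 3-gene chromosome reproducing the published worked example.

    The focal gene sits on chromosome ten at 18536..16767 (Crick) with
    three GO Slim annotations. Its two nearest neighbours are both
    Watson-strand genes at midpoint distance exactly 2697 bp, one
    upstream (annotated: plasma membrane / transporter activity /
    transport) and one downstream (no known GO Slim terms).
    """
    focal = GeneFeature("g_focal", "ten", 18536, 16767, "C")     # midpoint 17651.5
    nb1 = GeneFeature("g_nb1", "ten", 13955, 15954, "W")         # midpoint 14954.5
    nb2 = GeneFeature("g_nb2", "ten", 19349, 21348, "W")         # midpoint 20348.5
    annotations = [
        GoSlimAnnotation("g_focal", "C", "cellular component"),
        GoSlimAnnotation("g_focal", "F", "hydrolase activity"),
        GoSlimAnnotation("g_focal", "P", "biological process"),
        GoSlimAnnotation("g_nb1", "C", "plasma membrane"),
        GoSlimAnnotation("g_nb1", "F", "transporter activity"),
        GoSlimAnnotation("g_nb1", "P", "transport"),
    ]
    return AnnotatedGenome.build([focal, nb1, nb2], annotations, keep_unannotated=True)


def table1_expected_rows() -> list[TrainingInstance]:
    """The twelve printed rows, field for field."""
    loc = dict(chromosome="ten", start=18536, stop=16767, strand="C")
    gene_anns = [
        ("C", "cellular component"),
        ("F", "hydrolase activity"),
        ("P", "biological process"),
    ]
    nb1_anns = [("C", "plasma membrane"), ("F", "transporter activity"), ("P", "transport")]
    rows = []
    for nb_aspect, nb_term in nb1_anns:
        for ga, gt in gene_anns:
            rows.append(
                TrainingInstance(
                    gene_aspect=ga, class_term=gt, **loc,
                    neighbour_number=1, neighbour_strand="W", distance=2697.0,
                    neighbour_aspect=nb_aspect, neighbour_term=nb_term,
                )
            )
    for ga, gt in gene_anns:
        rows.append(
            TrainingInstance(
                gene_aspect=ga, class_term=gt, **loc,
                neighbour_number=2, neighbour_strand="W", distance=2697.0,
                neighbour_aspect=None, neighbour_term=None,
            )
        )
    return rows


def random_genome(
    seed: int,
    n_chromosomes: int = 2,
    max_genes: int = 12,
    annotation_prob: float = 0.7,
    vocab: int = 4,
) -> AnnotatedGenome:
    """Small random genome for brute-force/property tests."""
    rng = np.random.default_rng(seed)
    from neighbourgo.genome import CHROMOSOME_LABELS

    features, annotations = [], []
    for ci in range(n_chromosomes):
        chrom = CHROMOSOME_LABELS[ci]
        n = int(rng.integers(1, max_genes + 1))
        pos = 1
        for gi in range(n):
            length = int(rng.integers(50, 500))
            gap = int(rng.integers(1, 300))
            lo, hi = pos, pos + length
            pos = hi + gap
            gid = f"r{seed}c{ci}g{gi}"
            if rng.random() < 0.5:
                features.append(GeneFeature(gid, chrom, lo, hi, "W"))
            else:
                features.append(GeneFeature(gid, chrom, hi, lo, "C"))
            for aspect in ("C", "P", "F"):
                if rng.random() < annotation_prob:
                    term = f"{aspect.lower()}t{int(rng.integers(vocab))}"
                    annotations.append(GoSlimAnnotation(gid, aspect, term))
    return AnnotatedGenome.build(features, annotations, keep_unannotated=True)
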