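# neighbourgo

Predicting a gene's **Gene Ontology (GO) Slim terms from its genomic
context**: its own location (chromosome, start, stop, strand) and the GO
Slim annotations of its k nearest neighbouring genes. In compact
eukaryotic genomes such as *Saccharomyces cerevisiae*, genes of related
function often sit close together on a chromosome, so the neighbourhood
of a gene carries information about what the gene does. This package
turns that observation into a tested classification pipeline for
computational biologists who want to evaluate how much functional signal
genomic context carries — on real SGD-style annotation tables or on
synthetic genomes with planted, tunable functional clustering.

## The method

Each annotated gene is expanded into long-format training instances, one
row per (neighbour rank *r*, neighbour annotation, gene annotation)
combination:

| feature | meaning |
|---|---|
| chromosome, start, stop, strand | the gene's location (the ablation toggle) |
| neighbour number *r* | rank by midpoint distance, 1 = closest, any strand/direction |
| neighbour strand, distance | context geometry; distance = \|m(g) − m(n)\| with m = (start+stop)/2 |
| neighbour GO aspect, neighbour GO Slim term | the neighbour's annotation |
| gene GO aspect | which ontology (C / P / F) the class label lives in |
| **GO Slim term** | the **class** — the gene's own term |

Missing values (a neighbour with no known annotation, or a rank beyond
the chromosome) are the literal `?`. The classifier is a from-scratch
**MultiBoost committee of C4.5-style decision trees**: T = 10 AdaBoost.M1
iterations partitioned into 3 sub-committees whose instance weights are
re-randomized by *wagging* (wᵢ = −ln Uᵢ, rescaled to Σw = n) at
sub-committee boundaries; trees split categoricals multiway and numerics
at the best midpoint threshold, select attributes by gain ratio, treat
`?` as a first-class category, and are pruned by pessimistic-error
pruning (confidence 0.25). Boosting uses **reweighting, never
resampling** — every tree sees all instances with their weights. A
member with weighted error ε votes with log((1−ε)/ε).

Evaluation follows a repeated-holdout protocol: 10 randomized
instance-level 66/34 splits per experiment cell, reporting the
percentage of correctly classified instances, per-term precision /
recall / F (F = 2pr/(p+r)) with their support-weighted mean, and
**gene-level accuracy** — a test gene counts as correct only when *all*
of its (aspect, term) labels are predicted among its test instances.

## Worked example

```python
import neighbourgo as ng

sim = ng.simulate_genome(ng.SimulationConfig(
    n_chromosomes=2, genes_per_chromosome=120, clustering_strength=0.9,
    location_anchored=True, seed=7))
model = ng.GeneFunctionModel(sim.genome, ng.DatasetSpec(k=2))
res = model.fit(seed=1)
print(res.summary())
```

```
GO Slim Neighbourhood Classification Results
====================================================
Scope:                      genome
Neighbourhood size k:       2
Location attributes:        included
Committee members:          10
Boost iterations (T):       10
Sub-committees:             3
Run seed:                   1
Train / test instances:     2574 / 1327
----------------------------------------------------
Instance accuracy:          61.79 %
Weighted F-measure:         0.6184
Gene-level accuracy:        55.00 %
====================================================
```

61.8% of the 1327 held-out rows get their GO Slim term right (the
support-weighted mean F-measure 0.618 summarizes per-term precision and
recall), and for 55% of the test genes *every* annotated term was
recovered. The simulated genome plants clustering strength ρ = 0.9 in
contiguous functional domains, which the concordance diagnostic makes
visible — ~65–74% of rank-1/2 neighbour pairs share a term per aspect:

```python
print(ng.neighbour_term_concordance(sim.genome, max_rank=2))
#  rank aspect  n_pairs  concordance
#     1      C      210     0.652381
#     1      F      222     0.725225
#     ...
```

The same pipeline runs from the shell: `neighbourgo simulate` writes
SGD-style `SGD_features.tab` / `go_slim_mapping.tab` files,
`neighbourgo build` turns any such pair into instance CSVs,
`neighbourgo run --config experiment.yaml` executes a full
(k × scope × ablation) grid with 10 runs per cell and writes tidy
results/per-term TSVs plus a manifest, and `neighbourgo inspect-tree`
prints a trained tree.

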