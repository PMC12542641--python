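# tierminer

Tiered discovery, validation, classification and quantification of soluble
di-iron monooxygenase (SDIMO) alpha-hydroxylase genes in assembled
metagenomes, plus gene-neighborhood analysis on the contigs that carry them.

Given assembled contigs, predicted proteins, gene coordinates, per-sample
read counts and a labeled reference panel, the pipeline:

1. **screens** every predicted protein against the panel (exact local
   alignment, BLOSUM62/11/1; precomputed 12-column tabular hits can be
   ingested instead, gated at e-value ≤ 1e−50);
2. **tiers** the hits — Tier 1 needs ≥90% identity, ≥125 aligned columns,
   ≥60% query coverage and at least one intact D-E-x-R-H di-iron center
   motif; Tier 2 covers the [50, 90)% identity window with the same
   length/coverage gates; contigs with a Tier-1 gene are excluded from
   Tier 2;
3. **dereplicates** Tier-1 contigs (greedy incremental clustering,
   c = 0.999, aS = 0.999, shorter-sequence identity denominator) and builds
   the identity ladder (c = 1, 0.99, 0.97, 0.95, 0.9);
4. **classifies** Tier-1 proteins by neighbor-joining tree with the panel,
   roots on the Group V outgroups, and calls each query CDDP-like /
   outgroup-like / ambiguous from its minimal enclosing clade, with an
   SDIMO group I–VI;
5. **quantifies** contigs as RPKM per sample, aggregates clade × sample
   abundance matrices (origin-sample attribution only) and selects clade
   representatives (most abundant member whose first di-iron motif is not
   gapped);
6. **analyzes neighborhoods**: consensus annotation voting across
   annotators, four-subunit operon-order conformance (alpha, reductase,
   beta, coupling), inverted terminal repeat detection, and exact
   fixed-length terminal overlap (assembly break) detection.

A synthetic-metagenome module generates multi-sample fixtures with planted
operons of controlled amino-acid divergence, optional motif ablations,
terminal transposase pairs in reverse complement, paired contigs with exact
127-bp terminal overlaps, and negative-binomial count profiles — with full
ground truth for every planted gene.

## CLI

```sh
tierminer simulate --config sim.yaml --outdir data/        # synthetic data
tierminer screen --queries proteins.faa --panel panel.faa \
    --panel-labels panel_labels.tsv -o hits.tsv
tierminer tier --hits hits.tsv --proteins proteins.faa --features features.tsv \
    --panel panel.faa --panel-labels panel_labels.tsv -o tiers.tsv
tierminer cluster --in contigs.fna --space nucleotide --c 0.999 --as 0.999 -o clusters.tsv
tierminer ladder --in proteins.faa --labels labels.tsv -o table1.tsv
tierminer classify --tier1 tier1.faa --panel panel.faa --labels panel_labels.tsv \
    -o cladecalls.tsv --tree tree.nwk
tierminer abundance --counts counts.tsv --totals totals.tsv --contigs contigs.fna -o rpkm.tsv
tierminer neighborhood --contigs contigs.fna --features features.tsv --votes votes.tsv -o report.tsv
tierminer run --config pipeline.yaml --outdir run/         # everything at once
```

A `simulate` config looks like:

```yaml
seed: 1
n_samples: 4
n_contigs_per_sample: 2
planted_operons:
  - {reference_id: REF_V_CDDP1, target_identity: 95}
  - {reference_id: REF_II_CDDP1, target_identity: 70, paired_overlap_len: 127}
```

A `run` config carries the seven input paths (`contigs`, `proteins`,
`features`, `counts`, `totals`, `panel`, `panel_labels`) plus optional
`hits`, `votes` and threshold overrides; the resolved config is snapshotted
into the run directory.

## Layout

```
src/tierminer/
  formats_io.py      FASTA / tabular-hit / TSV / newick / config I/O
  synthetic_data.py  seeded synthetic metagenomes + reference panel + truth
  homology.py        pairwise alignment, hit statistics, panel screening
  tiering.py         tier gates + di-iron motif validation
  clustering.py      greedy identity clustering, dereplication, ladder
  phylo.py           p-distances, NJ, rooting, clade calls, representatives
  abundance.py       RPKM and clade×sample aggregation
  neighborhood.py    consensus votes, operon order, ITR / overlap detection
  pipeline.py        orchestration
  cli.py             click entry points
```
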